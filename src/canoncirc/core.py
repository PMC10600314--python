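"""Canonical E-I node dynamics.

The computational node at the heart of every model here is a pair of coupled
excitatory (E) and inhibitory (I) state variables per spatial position and
feature channel, evolving as shunting leaky integrators:

    tau_r * dr/dt = -alpha * r + (beta - r) * P(F, r, z_fb)
                    - (delta + r) * [F (*) Lambda^-]
                    - r * g_q(q)

    tau_q * dq/dt = -alpha_q * q + beta_q * [g(r) (*) Lambda^pool] + I_c
                    [- g_q(q)  if I-I self-inhibition is enabled]

with the driving function

    P(F, r, z_fb) = [F + kappa * (g(r) (*) Lambda^lat)] * (1 + lambda_fb * z_fb)

where (*) denotes space(-feature) correlation with reflective spatial
boundaries.  The multiplicative (shunting) structure bounds r to
[-delta, beta] for non-negative inputs, the r * g_q(q) term implements
divisive pool normalization at equilibrium, and the (1 + lambda_fb * z_fb)
factor implements modulatory feedback: feedback can only amplify activity
that driving input has already created (the "no-strong-loop" property).

Dynamic synaptic efficacy follows transmitter production/depletion dynamics

    tau_w * dw/dt = alpha_w * (1 - w) - beta_w * w * s(t)

with steady state w_eq = alpha_w / (alpha_w + beta_w * s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .kernels import Kernel


class FeatureAxis(str, Enum):
    ORIENTATION = "orientation"
    DIRECTION = "direction"
    DIRECTION_SPEED = "direction_speed"
    SCALAR = "scalar"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass
class FeatureField:
    """Real-valued activity over a 2-D grid x feature channels: (H, W, C)."""

    values: np.ndarray
    feature_axis_meaning: FeatureAxis = FeatureAxis.SCALAR

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 2:
            v = v[:, :, None]
        if v.ndim != 3:
            raise ValueError("FeatureField values must be (H, W, C)")
        if not np.all(np.isfinite(v)):
            raise ValueError("FeatureField values must be finite")
        self.values = v

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @classmethod
    def zeros(cls, height: int, width: int, n_features: int,
              meaning: FeatureAxis = FeatureAxis.SCALAR) -> "FeatureField":
        return cls(np.zeros((height, width, n_features)), meaning)

    @classmethod
    def _wrap(cls, values: np.ndarray,
              meaning: FeatureAxis) -> "FeatureField":
        """Wrap an already-validated array without copying or re-checking."""
        obj = object.__new__(cls)
        obj.values = values
        obj.feature_axis_meaning = meaning
        return obj


def _vals(x) -> np.ndarray:
    """Accept a FeatureField or a bare array."""
    return x.values if isinstance(x, FeatureField) else np.asarray(x, float)


@dataclass
class FiringRateSpec:
    """Descriptor of the pointwise firing-rate function g.

    shapes: "linear" (rectified-linear above threshold), "power"
    (rectified input raised to ``exponent``), "sigmoid"
    (gain / (1 + exp(-(x - threshold) / slope)) minus its value at rest so
    g(0) = 0 when threshold >= 0).
    """

    shape: str = "linear"
    threshold: float = 0.0
    gain: float = 1.0
    exponent: float = 2.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("linear", "power", "sigmoid"):
            raise ValueError(f"unknown firing-rate shape {self.shape!r}")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.shape == "linear":
            return self.gain * np.maximum(x - self.threshold, 0.0)
        if self.shape == "power":
            return self.gain * np.maximum(x - self.threshold, 0.0) ** self.exponent
        raw = 1.0 / (1.0 + np.exp(-(x - self.threshold) / self.slope))
        rest = 1.0 / (1.0 + np.exp(self.threshold / self.slope))
        return self.gain * np.maximum(raw - rest, 0.0)


def firing_rate(x, g_spec: FiringRateSpec) -> np.ndarray:
    """Pointwise firing-rate function; non-negative, monotone non-decreasing."""
    if not isinstance(g_spec, FiringRateSpec):
        raise TypeError("g_spec must be a FiringRateSpec")
    return g_spec(_vals(x))


@dataclass
class EILayerParams:
    """Constants of one E-I sheet (time constants in ms)."""

    tau_r: float = 10.0
    tau_q: float = 20.0
    alpha: float = 1.0
    alpha_q: float = 1.0
    beta: float = 1.0
    beta_q: float = 1.0
    delta: float = 1.0
    kappa: float = 0.0
    lambda_fb: float = 0.0
    I_c: float = 0.0
    g_spec: FiringRateSpec = field(default_factory=FiringRateSpec)
    gq_spec: FiringRateSpec = field(default_factory=FiringRateSpec)
    self_excitation: float = 0.0   # optional E-E gain, default off
    self_inhibition: float = 0.0   # optional I-I gain, default off

    def __post_init__(self) -> None:
        if self.tau_r <= 0 or self.tau_q <= 0:
            raise ValueError("time constants tau_r, tau_q must be positive")
        for name in ("alpha", "alpha_q", "beta", "beta_q", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa < 0 or self.lambda_fb < 0:
            raise ValueError("kappa and lambda_fb must be non-negative")


@dataclass
class KernelSet:
    """Connection kernels of one layer.

    lambda_minus: surround-inhibition kernel applied to the driving input;
    lambda_lat: lateral integration kernel applied to the layer's own output;
    lambda_pool: normalization-pool kernel (unit sum over its support);
    fb_alignment: descriptor for re-entering feedback (spatial upsampling
    factor + optional per-channel displacement), consumed by the simulator.
    """

    lambda_minus: Kernel | None = None
    lambda_lat: Kernel | None = None
    lambda_pool: Kernel | None = None
    fb_alignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("lambda_minus", "lambda_lat", "lambda_pool"):
            k = getattr(self, name)
            if k is not None and np.any(k.full_weights() < 0):
                raise ValueError(f"{name} weights must be non-negative")
        if self.lambda_pool is not None:
            s = self.lambda_pool.full_weights().sum()
            if not math.isclose(s, 1.0, abs_tol=1e-8):
                raise ValueError("lambda_pool must sum to 1 over its support")


@dataclass
class EILayerState:
    """State of one E-I sheet at simulated time t (ms)."""

    r: FeatureField
    q: FeatureField
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.r.values.shape != self.q.values.shape:
            raise ValueError("r and q must share spatial/feature shape")

    @classmethod
    def zeros(cls, height: int, width: int, n_features: int,
              meaning: FeatureAxis = FeatureAxis.SCALAR) -> "EILayerState":
        return cls(FeatureField.zeros(height, width, n_features, meaning),
                   FeatureField.zeros(height, width, n_features, meaning))

    def output(self, params: EILayerParams) -> np.ndarray:
        """Reported activity is the E-state passed through g."""
        return params.g_spec(self.r.values)


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def modulate(b, a, lambda_fb: float) -> np.ndarray:
    """Modulatory feedback combination b * (1 + lambda_fb * a).

    Driving input b gates the feedback a: the result is exactly zero wherever
    b is zero, for arbitrary non-negative a.
    """
    bv, av = _vals(b), _vals(a)
    if bv.shape != av.shape:
        raise ValueError("modulate: b and a must share shape")
    if lambda_fb < 0:
        raise ValueError("modulate: lambda_fb must be non-negative")
    if np.any(bv < 0) or np.any(av < 0):
        raise ValueError("modulate: inputs must be non-negative")
    return bv * (1.0 + lambda_fb * av)


def drive(F, r, z_fb, kernels: KernelSet, kappa: float,
          lambda_fb: float) -> np.ndarray:
    """Driving function P: lateral-augmented input under modulatory feedback.

    P = [F + kappa * (r (*) Lambda^lat)] * (1 + lambda_fb * z_fb).
    ``r`` is the layer's (post firing-rate) output activity.
    """
    Fv, rv, zv = _vals(F), _vals(r), _vals(z_fb)
    if not (Fv.shape == rv.shape == zv.shape):
        raise ValueError("drive: F, r, z_fb must share shape")
    lat = 0.0
    if kappa != 0.0 and kernels.lambda_lat is not None:
        lat = kappa * kernels.lambda_lat.apply(rv)
    return (Fv + lat) * (1.0 + lambda_fb * zv)


class StabilityError(RuntimeError):
    pass


def step_layer(state: EILayerState, F, z_fb, params: EILayerParams,
               kernels: KernelSet, dt: float) -> EILayerState:
    """One explicit-Euler update of the E-I pair.

    Raises :class:`StabilityError` if ``dt`` violates the tau/10 guard or if
    the per-step contraction condition is broken (which would let the Euler
    step overshoot the shunting bounds), and names the offending term if the
    state stops being finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > params.tau_r / 10.0 + 1e-12 or dt > params.tau_q / 10.0 + 1e-12:
        raise StabilityError(
            f"dt={dt} violates the stability guard dt <= tau/10 "
            f"(tau_r={params.tau_r}, tau_q={params.tau_q})")
    r = state.r.values
    q = state.q.values
    Fv, zv = _vals(F), _vals(z_fb)
    if Fv.shape != r.shape or zv.shape != r.shape:
        raise ValueError("step_layer: field shapes inconsistent with state")

    out = params.g_spec(r)
    P = drive(Fv, out, zv, kernels, params.kappa, params.lambda_fb)
    if params.self_excitation:
        P = P + params.self_excitation * out
    surround = (kernels.lambda_minus.apply(Fv)
                if kernels.lambda_minus is not None else np.zeros_like(r))
    gq = params.gq_spec(q)

    # per-step contraction guard: total multiplicative load on r
    load = dt / params.tau_r * (params.alpha + P + surround + gq)
    if np.any(load > 1.0):
        raise StabilityError(
            "Euler step too large for the shunting bound: "
            "dt/tau_r * (alpha + P + surround + g_q(q)) exceeds 1; "
            "reduce dt or the input gains")

    dr = (-params.alpha * r + (params.beta - r) * P
          - (params.delta + r) * surround - r * gq) / params.tau_r
    pool = (kernels.lambda_pool.apply(out)
            if kernels.lambda_pool is not None else np.zeros_like(r))
    dq = (-params.alpha_q * q + params.beta_q * pool + params.I_c) / params.tau_q
    if params.self_inhibition:
        dq = dq - params.self_inhibition * gq / params.tau_q

    r_new = r + dt * dr
    q_new = q + dt * dq
    for name, arr in (("E-state r", r_new), ("I-state q", q_new)):
        if not np.all(np.isfinite(arr)):
            raise StabilityError(f"non-finite values appeared in {name}")
    new = object.__new__(EILayerState)
    new.r = FeatureField._wrap(r_new, state.r.feature_axis_meaning)
    new.q = FeatureField._wrap(q_new, state.q.feature_axis_meaning)
    new.t = state.t + dt
    return new


@dataclass
class EquilibriumInfo:
    converged: bool
    steps: int
    criterion: str
    max_delta: float


def run_to_equilibrium(state: EILayerState, F, z_fb, params: EILayerParams,
                       kernels: KernelSet, dt: float, tol: float = 1e-6,
                       max_steps: int = 2000
                       ) -> tuple[EILayerState, EquilibriumInfo]:
    """Iterate :func:`step_layer` under constant input until |dr| < tol.

    Non-convergence within ``max_steps`` is reported via the returned
    :class:`EquilibriumInfo` (criterion "max_steps"), never silently.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    delta = np.inf
    for step in range(1, max_steps + 1):
        new = step_layer(state, F, z_fb, params, kernels, dt)
        delta = float(np.max(np.abs(new.r.values - state.r.values)))
        state = new
        if delta < tol:
            return state, EquilibriumInfo(True, step, "tol", delta)
    return state, EquilibriumInfo(False, max_steps, "max_steps", delta)


# --------------------------------------------------------------------------
# Dynamic synaptic efficacy
# --------------------------------------------------------------------------

@dataclass
class AdaptiveSynapse:
    """Synaptic efficacy w in (0, 1] with production/depletion dynamics.

    ``w`` may be a scalar or an array (a bank of per-channel efficacies all
    sharing the same rate constants).
    """

    w: float | np.ndarray = 1.0
    alpha_w: float = 1.0
    beta_w: float = 1.0
    tau_w: float = 100.0

    def __post_init__(self) -> None:
        if self.alpha_w <= 0:
            raise ValueError("alpha_w must be positive")
        if self.beta_w < 0 or self.tau_w <= 0:
            raise ValueError("beta_w must be >= 0 and tau_w > 0")
        w = np.asarray(self.w, dtype=float)
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("initial efficacy must lie in (0, 1]")


def steady_state_weight(s, alpha_w: float, beta_w: float):
    """Equilibrium efficacy alpha_w / (alpha_w + beta_w * s)."""
    if alpha_w <= 0:
        raise ValueError("alpha_w must be positive")
    if beta_w < 0:
        raise ValueError("beta_w must be non-negative")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise ValueError("presynaptic signal must be non-negative")
    out = alpha_w / (alpha_w + beta_w * s)
    return float(out) if out.ndim == 0 else out


def adapt_weight(syn: AdaptiveSynapse, s, dt: float,
                 scheme: str = "exact") -> AdaptiveSynapse:
    """Advance the efficacy one step under presynaptic signal s >= 0.

    The depletion ODE is linear in w, so the default scheme integrates it
    exactly over the step (w relaxes exponentially toward the steady state
    alpha_w / (alpha_w + beta_w * s)); this keeps w in (0, 1] for any dt and
    any s >= 0.  ``scheme="euler"`` gives the plain explicit-Euler update,
    subject to the dt <= tau_w/10 guard.
    """
    sv = np.asarray(s, dtype=float)
    if np.any(sv < 0):
        raise ValueError("presynaptic signal must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > syn.tau_w / 10.0 + 1e-12:
        raise ValueError("dt violates the stability guard dt <= tau_w/10")
    w = np.asarray(syn.w, dtype=float)
    if scheme == "euler":
        w_new = w + dt / syn.tau_w * (syn.alpha_w * (1.0 - w)
                                      - syn.beta_w * w * sv)
    elif scheme == "exact":
        rate = (syn.alpha_w + syn.beta_w * sv) / syn.tau_w
        w_eq = syn.alpha_w / (syn.alpha_w + syn.beta_w * sv)
        w_new = w_eq + (w - w_eq) * np.exp(-rate * dt)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if w_new.ndim == 0:
        w_new = float(w_new)
    return replace(syn, w=w_new)
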