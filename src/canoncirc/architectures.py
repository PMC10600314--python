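"""Model architectures: multilayer graphs of E-I sheets.

Composes the canonical E-I node (see :mod:`canoncirc.core`) into the model
families studied here:

* contour model  — V1 (oriented filtering + pool normalization) and V2
  (long-range collinear grouping) with topographic modulatory V2->V1
  feedback;
* texture model  — adds a V4 stage of orientation-contrast units on a
  coarser grid with V4->V2 and V2->V1 modulatory feedback;
* motion model   — V1 (correlation-based motion detectors), MT
  (space-velocity integration on a coarser grid) and optionally MSTl
  (large-field direction integration with mutual competition), with
  velocity-displaced modulatory feedback implementing a linear forward
  prediction;
* adaptation variants 1-5 — the two-layer motion model with adaptive
  synapses placed on the feedforward and/or feedback pathway.

Every inter-layer (and lateral) connection is an explicit, individually
removable :class:`ConnectionSpec`, so ablation studies are pure graph
surgery.  Simulation advances all layers with one explicit-Euler step per
``dt``, propagating driving signals in topological order within the step and
modulatory feedback with exactly one step of latency.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import (AdaptiveSynapse, EILayerParams, EILayerState, FeatureAxis,
                   FeatureField, FiringRateSpec, KernelSet, StabilityError,
                   adapt_weight, step_layer)
from .kernels import (Kernel, MotionDetectorBank, bipole_kernel,
                      gaussian_kernel, identity_kernel,
                      motion_detect_events, motion_detect_frames,
                      oriented_filter_bank, apply_filter_bank, pool_kernel,
                      _wrapped_gaussian)
from .stimuli import EventStream, Stimulus

DRIVING = "driving_forward"
FEEDBACK = "modulatory_feedback"
LATERAL = "lateral"


# --------------------------------------------------------------------------
# Graph types
# --------------------------------------------------------------------------

@dataclass
class LayerSpec:
    """One E-I sheet: parameters, kernels, grid shape and semantics."""

    params: EILayerParams
    kernels: KernelSet
    shape: tuple[int, int, int]            # (H, W, C)
    meaning: FeatureAxis = FeatureAxis.SCALAR
    scale: int = 1                          # grid coarsening vs the input


@dataclass
class ConnectionSpec:
    """A directed edge of the layer graph.

    ``kind`` is driving_forward, modulatory_feedback or lateral (lateral
    edges have source == target and install the layer's lateral kernel).
    ``channel_map`` aligns feature axes between layers: identity,
    sum_speeds (direction x speed -> direction), broadcast_speeds
    (direction -> direction x speed) or broadcast (1 -> C).
    ``displacement`` enables the linear forward-prediction shift of feedback
    re-entry locations by each channel's preferred velocity; it requires a
    direction(x speed) source.  ``synapse`` optionally attaches adaptive
    efficacies (one per source channel).
    """

    source: str
    target: str
    kind: str
    kernel: Kernel | None = None
    gain: float = 1.0
    channel_map: str = "identity"
    displacement: bool = False
    synapse: AdaptiveSynapse | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.source, self.target, self.kind)


@dataclass
class Frontend:
    """Input stage turning a stimulus into the first layer's driving field."""

    kind: str                               # "oriented" | "motion"
    n_orientations: int = 8
    scale: float = 2.0
    bank: MotionDetectorBank | None = None
    gain: float = 1.0

    def compute(self, stim) -> np.ndarray:
        """Driving fields, one per simulation frame: (T_drive, H, W, C).

        Accepts a frame :class:`Stimulus`; motion frontends additionally
        accept an :class:`EventStream`, which is processed with the
        event-sampled detector on time bins of the default frame interval.
        """
        if isinstance(stim, EventStream):
            if self.kind != "motion":
                raise ValueError("event input needs a motion frontend")
            resp, _ = motion_detect_events(stim, self.bank, bin_ms=20.0)
            # event-count surfaces are not luminance-bounded; rescale the
            # sparse code so its upper range matches the frame-based drive
            peak = np.percentile(resp[resp > 0], 99.0) if resp.any() else 1.0
            return self.gain * 0.2 * resp / max(peak, 1e-12)
        if self.kind == "oriented":
            filters = oriented_filter_bank(self.n_orientations, self.scale)
            resp = apply_filter_bank(stim.frames[0], filters, rectify=True)
            return self.gain * resp[None]
        if self.kind == "motion":
            if stim.n_frames < 2:
                raise ValueError("motion frontend needs at least 2 frames")
            return self.gain * motion_detect_frames(stim.frames, self.bank)
        raise ValueError(f"unknown frontend kind {self.kind!r}")


@dataclass
class Architecture:
    """A directed multilayer graph of E-I sheets.

    Driving edges must form an acyclic graph; cycles may only pass through
    modulatory feedback edges (checked on construction via topo-sort).
    """

    layers: dict[str, LayerSpec]
    connections: list[ConnectionSpec]
    frontend: Frontend
    input_layer: str
    readout: dict = field(default_factory=dict)
    bank: MotionDetectorBank | None = None
    name: str = "architecture"

    def __post_init__(self) -> None:
        self.topo_order()                    # validates acyclicity
        for conn in self.connections:
            if conn.source not in self.layers or conn.target not in self.layers:
                raise ValueError(f"edge references unknown layer: {conn.key()}")
            if conn.kind == LATERAL and conn.source != conn.target:
                raise ValueError("lateral edges must have source == target")

    def topo_order(self) -> list[str]:
        """Layer ids in driving topological order (ties broken by id)."""
        ids = list(self.layers)
        deps = {i: set() for i in ids}
        for c in self.connections:
            if c.kind == DRIVING:
                deps[c.target].add(c.source)
        order: list[str] = []
        while deps:
            ready = sorted(i for i, d in deps.items() if not d)
            if not ready:
                raise ValueError("driving edges must form an acyclic graph")
            for i in ready:
                order.append(i)
                del deps[i]
            for d in deps.values():
                d.difference_update(ready)
        return order

    def find_edges(self, source=None, target=None, kind=None
                   ) -> list[ConnectionSpec]:
        out = []
        for c in self.connections:
            if ((source is None or c.source == source)
                    and (target is None or c.target == target)
                    and (kind is None or c.kind == kind)):
                out.append(c)
        return out


def ablate(arch: Architecture,
           edges: list[tuple[str, str, str]]) -> Architecture:
    """Copy of the architecture with the named edges removed.

    Each entry is (source, target, kind); naming a non-existent edge raises,
    it is never silently ignored.  The original is untouched.
    """
    out = copy.deepcopy(arch)
    for key in edges:
        matches = [c for c in out.connections if c.key() == tuple(key)]
        if not matches:
            raise ValueError(f"no such edge to ablate: {key}")
        for m in matches:
            out.connections.remove(m)
    return out


# --------------------------------------------------------------------------
# Resampling / channel alignment helpers
# --------------------------------------------------------------------------

def _downsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean spatial pooling of a (H, W, C) array."""
    if factor == 1:
        return x
    H, W, C = x.shape
    return x.reshape(H // factor, factor, W // factor, factor, C).mean((1, 3))


def _upsample(x: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor spatial upsampling of a (H, W, C) array."""
    if factor == 1:
        return x
    return np.repeat(np.repeat(x, factor, axis=0), factor, axis=1)


def _map_channels(x: np.ndarray, how: str, n_target: int,
                  bank: MotionDetectorBank | None) -> np.ndarray:
    if how == "identity":
        return x
    if how == "broadcast":
        if x.shape[2] != 1:
            x = x.sum(axis=2, keepdims=True)
        return np.repeat(x, n_target, axis=2)
    if how == "sum_speeds":
        n_sp = len(bank.speeds)
        H, W, C = x.shape
        return x.reshape(H, W, C // n_sp, n_sp).sum(axis=3)
    if how == "broadcast_speeds":
        n_sp = n_target // x.shape[2]
        return np.repeat(x, n_sp, axis=2)
    raise ValueError(f"unknown channel_map {how!r}")


def _displace_channels(x: np.ndarray, bank: MotionDetectorBank,
                       scale: int, frames: float = 1.0) -> np.ndarray:
    """Shift each direction(x speed) channel along its preferred velocity.

    Implements the linear forward prediction of motion feedback: activity of
    a channel tuned to velocity v re-enters at positions displaced by
    v * frames (in the target grid's pixels, hence the ``scale`` divisor),
    using bilinear interpolation.
    """
    out = np.empty_like(x)
    n_sp = len(bank.speeds)
    for c in range(x.shape[2]):
        vx, vy = bank.channel_velocity(c % (bank.n_directions * n_sp))
        out[:, :, c] = ndimage.shift(
            x[:, :, c], (vy * frames / scale, vx * frames / scale),
            order=1, mode="constant")
    return out


# --------------------------------------------------------------------------
# Simulation
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Per-layer output time series plus diagnostics."""

    times: np.ndarray                       # ms, strictly increasing
    outputs: dict[str, np.ndarray]          # layer id -> (T_rec, H, W, C)
    synapse_traces: dict[tuple, np.ndarray] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("recording time axis must be strictly increasing")


class SimulationDiverged(RuntimeError):
    pass


def simulate(arch: Architecture, stim: Stimulus, duration: float | None = None,
             record_stride: int = 1, dt: float = 10.0,
             steps_per_frame: int = 2,
             initial_synapse_state: dict | None = None,
             initial_layer_states: dict | None = None,
             freeze_synapses: bool = False,
             record: bool = True) -> Recording:
    """Run the full architecture on a stimulus.

    Per simulation step: the frontend drive for the current frame feeds the
    input layer; layers update in driving topological order using the
    *previous* step's outputs for modulatory feedback (one-step latency);
    adaptive synapses then integrate their presynaptic signals.  Frame
    sequences advance one frame every ``steps_per_frame`` steps; a static
    (single-frame) stimulus is held constant for ``duration`` ms.

    Deterministic given the stimulus and configuration.  Raises
    :class:`SimulationDiverged` if any |r| exceeds beta + delta + 0.01.
    """
    drive_seq = arch.frontend.compute(stim)
    n_drive = drive_seq.shape[0]
    if n_drive == 1:
        if duration is None:
            raise ValueError("static stimulus needs an explicit duration")
        n_steps = max(1, int(round(duration / dt)))
        frame_of_step = np.zeros(n_steps, dtype=int)
    else:
        n_steps = n_drive * steps_per_frame
        frame_of_step = np.repeat(np.arange(n_drive), steps_per_frame)

    order = arch.topo_order()
    if initial_layer_states is not None:
        states = {i: copy.deepcopy(initial_layer_states[i])
                  for i in arch.layers}
    else:
        states = {i: EILayerState.zeros(*spec.shape, meaning=spec.meaning)
                  for i, spec in arch.layers.items()}
    outputs = {i: states[i].output(spec.params)
               for i, spec in arch.layers.items()}
    synapses: dict[tuple, AdaptiveSynapse] = {}
    for c in arch.connections:
        if c.synapse is not None:
            syn = copy.deepcopy(c.synapse)
            if initial_synapse_state and c.key() in initial_synapse_state:
                syn = replace(syn, w=np.array(initial_synapse_state[c.key()],
                                              dtype=float))
            else:
                n_ch = arch.layers[c.source].shape[2]
                if np.ndim(syn.w) == 0:
                    syn = replace(syn, w=np.full(n_ch, float(syn.w)))
            synapses[c.key()] = syn

    rec_times, rec_out = [], {i: [] for i in arch.layers}
    syn_traces = {k: [] for k in synapses}

    lateral_kernels = {}
    for i in arch.layers:
        lat = arch.find_edges(source=i, target=i, kind=LATERAL)
        lateral_kernels[i] = lat[0].kernel if lat else None

    t = 0.0
    for step in range(n_steps):
        prev_outputs = outputs
        new_outputs = {}
        frame = frame_of_step[step]
        for lid in order:
            spec = arch.layers[lid]
            # ---- driving input ------------------------------------------
            if lid == arch.input_layer:
                F = drive_seq[frame]
            else:
                F = np.zeros(spec.shape)
            for c in arch.find_edges(target=lid, kind=DRIVING):
                src_spec = arch.layers[c.source]
                sig = new_outputs[c.source]      # updated within this step
                if c.kernel is not None:
                    sig = c.kernel.apply(sig)
                sig = _map_channels(sig, c.channel_map, spec.shape[2],
                                    arch.bank)
                ratio = spec.scale // src_spec.scale
                if ratio > 1:
                    sig = _downsample(sig, ratio)
                elif spec.scale < src_spec.scale:
                    sig = _upsample(sig, src_spec.scale // spec.scale)
                if c.key() in synapses:
                    sig = sig * synapses[c.key()].w[None, None, :]
                F = F + c.gain * sig
            # ---- modulatory feedback (previous step's outputs) ----------
            z = np.zeros(spec.shape)
            for c in arch.find_edges(target=lid, kind=FEEDBACK):
                src_spec = arch.layers[c.source]
                sig = prev_outputs[c.source]
                if c.key() in synapses:
                    sig = sig * synapses[c.key()].w[None, None, :]
                if c.kernel is not None:
                    sig = c.kernel.apply(sig)
                sig = _map_channels(sig, c.channel_map, spec.shape[2],
                                    arch.bank)
                if src_spec.scale > spec.scale:
                    sig = _upsample(sig, src_spec.scale // spec.scale)
                elif src_spec.scale < spec.scale:
                    sig = _downsample(sig, spec.scale // src_spec.scale)
                if c.displacement and arch.bank is not None:
                    sig = _displace_channels(sig, arch.bank, spec.scale)
                z = z + c.gain * sig
            # ---- E-I update ---------------------------------------------
            eff_kernels = replace(spec.kernels, lambda_lat=lateral_kernels[lid])
            try:
                states[lid] = step_layer(states[lid], F, z, spec.params,
                                         eff_kernels, dt)
            except StabilityError as exc:
                raise StabilityError(
                    f"layer {lid!r} at t={t:.1f} ms: {exc}") from exc
            r = states[lid].r.values
            lim = spec.params.beta + spec.params.delta + 0.01
            if np.any(np.abs(r) > lim):
                raise SimulationDiverged(
                    f"layer {lid!r} exceeded |r| > beta+delta+0.01 at "
                    f"t={t + dt:.1f} ms (max |r| = {np.max(np.abs(r)):.3f})")
            new_outputs[lid] = states[lid].output(spec.params)
        outputs = new_outputs
        # ---- adaptive synapses -----------------------------------------
        for key, syn in synapses.items():
            if freeze_synapses:
                break
            src = key[0]
            s_ch = outputs[src].mean(axis=(0, 1))
            # habituation is driven by each channel's share of the total
            # presynaptic signal (transmitter resources are depleted in
            # proportion to relative, not absolute, drive)
            tot = s_ch.sum()
            if tot > 0:
                s_ch = s_ch / tot
            gain = arch.readout.get("synapse_drive_gain", 1.0)
            synapses[key] = adapt_weight(syn, gain * s_ch, dt)
        t += dt
        if record and (step % record_stride == record_stride - 1
                       or step == n_steps - 1):
            rec_times.append(t)
            for i in arch.layers:
                rec_out[i].append(outputs[i])
            for k in synapses:
                syn_traces[k].append(np.array(synapses[k].w))

    return Recording(
        times=np.asarray(rec_times),
        outputs={i: (np.stack(v) if v else np.zeros((0,) + arch.layers[i].shape))
                 for i, v in rec_out.items()},
        synapse_traces={k: np.asarray(v) for k, v in syn_traces.items()},
        diagnostics=dict(
            n_steps=n_steps, dt=dt,
            final_synapses={k: np.array(s.w) for k, s in synapses.items()},
            final_states=states,
            stimulus=stim.provenance))


# --------------------------------------------------------------------------
# Model builders
# --------------------------------------------------------------------------

def _ei_params(tau: float = 100.0, beta_q: float = 1.0, kappa: float = 0.0,
               lambda_fb: float = 0.0, gq_gain: float = 1.0,
               tau_q: float | None = None) -> EILayerParams:
    return EILayerParams(
        tau_r=tau, tau_q=tau_q if tau_q is not None else tau,
        alpha=1.0, alpha_q=1.0, beta=1.0, beta_q=beta_q,
        delta=1.0, kappa=kappa, lambda_fb=lambda_fb, I_c=0.0,
        g_spec=FiringRateSpec("linear"),
        gq_spec=FiringRateSpec("linear", gain=gq_gain))


def build_contour_model(config: dict | None = None) -> Architecture:
    """Two-layer V1-V2 contour-grouping model.

    V1: oriented contrast filtering with divisive pool normalization over a
    space-orientation neighborhood.  V2: long-range collinear (bipole)
    grouping of V1 output with lateral recurrence.  V2 output re-enters V1
    topographically, same orientation channel, as modulatory feedback.
    """
    cfg = dict(shape=(128, 128), n_orientations=8, filter_scale=2.0,
               pool_sigma=10.0, pool_feature_sigma=8.0, pool_gain=120.0,
               bipole_reach=24.0, bipole_inner=7.0,
               bipole_tolerance=math.pi / 9, lambda_fb=2.0, v2_kappa=0.3,
               frontend_gain=3.0, v2_gain=3.0, fb_gain=1.0, tau=100.0)
    cfg.update(config or {})
    H, W = cfg["shape"]
    C = cfg["n_orientations"]
    if min(H, W) < 2 * cfg["bipole_reach"]:
        raise ValueError("grid too small for the bipole reach")

    v1_params = _ei_params(tau=cfg["tau"], lambda_fb=cfg["lambda_fb"],
                           gq_gain=cfg["pool_gain"])
    v1_kernels = KernelSet(
        lambda_pool=pool_kernel(cfg["pool_sigma"], cfg["pool_feature_sigma"], C))
    v2_params = _ei_params(tau=cfg["tau"], kappa=cfg["v2_kappa"], gq_gain=4.0)
    v2_kernels = KernelSet(
        lambda_pool=pool_kernel(cfg["pool_sigma"] / 2, 2.0, C))

    layers = {
        "V1": LayerSpec(v1_params, v1_kernels, (H, W, C),
                        FeatureAxis.ORIENTATION, scale=1),
        "V2": LayerSpec(v2_params, v2_kernels, (H, W, C),
                        FeatureAxis.ORIENTATION, scale=1),
    }
    connections = [
        ConnectionSpec("V1", "V2", DRIVING,
                       kernel=OrientedBipoleStack(
                           C, cfg["bipole_reach"], cfg["bipole_tolerance"],
                           inner_radius=cfg["bipole_inner"]),
                       gain=cfg["v2_gain"]),
        ConnectionSpec("V2", "V2", LATERAL,
                       kernel=OrientedBipoleStack(
                           C, cfg["bipole_reach"], cfg["bipole_tolerance"],
                           inner_radius=cfg["bipole_inner"])),
        ConnectionSpec("V2", "V1", FEEDBACK, kernel=identity_kernel(),
                       gain=cfg["fb_gain"]),
    ]
    frontend = Frontend("oriented", n_orientations=C,
                        scale=cfg["filter_scale"], gain=cfg["frontend_gain"])
    return Architecture(layers, connections, frontend, "V1",
                        readout=dict(config=cfg), name="contour")


class OrientedBipoleStack(Kernel):
    """Per-orientation bipole kernels applied channel-wise.

    Each orientation channel is integrated with its own bipole field (lobes
    along that channel's orientation), with a narrow circular coupling to
    neighboring orientation channels.
    """

    def __init__(self, n_orientations: int, reach: float,
                 angular_tolerance: float, feature_sigma: float = 0.7,
                 inner_radius: float = 0.0):
        self.kernels = [
            bipole_kernel(i * math.pi / n_orientations, reach,
                          angular_tolerance, inner_radius=inner_radius)
            for i in range(n_orientations)]
        self.feature_profile = _wrapped_gaussian(n_orientations, feature_sigma)
        self.feature_profile /= self.feature_profile.sum()
        super().__init__(weights=self.kernels[0].weights)

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float)
        C = x.shape[2]
        # couple neighboring orientation channels first (circular)
        from .kernels import _feature_correlate
        mixed = _feature_correlate(x, self.feature_profile, wrap=True)
        out = np.empty_like(x)
        for c in range(C):
            out[:, :, c] = self.kernels[c]._spatial_correlate(mixed[:, :, c])
        return out


def build_texture_model(config: dict | None = None) -> Architecture:
    """Three-layer V1-V2-V4 texture boundary detection model.

    Extends the contour model with a V4 stage of orientation-contrast units
    (juxtaposed excitatory/inhibitory subfields of increased size) on a
    4x coarser grid, plus V4->V2 and V2->V1 modulatory feedback.
    """
    cfg = dict(shape=(128, 128), n_orientations=8, filter_scale=2.0,
               pool_sigma=8.0, pool_feature_sigma=1.5, pool_gain=40.0,
               bipole_reach=10.0, bipole_tolerance=math.pi / 9,
               lambda_fb_v1=1.0, lambda_fb_v2=15.0, v4_scale=4,
               oc_filter_scale=24.0, v2_gain=1.0, v2_pool_gain=30.0,
               v4_gain=4.0, v4_fb_gain=8.0, v4_pool_gain=2.0,
               frontend_gain=3.0, tau=200.0)
    cfg.update(config or {})
    if cfg["oc_filter_scale"] <= cfg["bipole_reach"]:
        raise ValueError("orientation-contrast filter scale must exceed the "
                         "V2 bipole reach")
    H, W = cfg["shape"]
    C = cfg["n_orientations"]
    f4 = cfg["v4_scale"]

    v1_params = _ei_params(tau=cfg["tau"], lambda_fb=cfg["lambda_fb_v1"],
                           gq_gain=cfg["pool_gain"])
    v1_kernels = KernelSet(
        lambda_pool=pool_kernel(cfg["pool_sigma"], cfg["pool_feature_sigma"], C))
    v2_params = _ei_params(tau=cfg["tau"], lambda_fb=cfg["lambda_fb_v2"],
                           gq_gain=cfg["v2_pool_gain"])
    v2_kernels = KernelSet(lambda_pool=pool_kernel(cfg["pool_sigma"] / 2,
                                                   2.0, C))
    v4_params = _ei_params(tau=cfg["tau"], gq_gain=cfg["v4_pool_gain"])
    v4_kernels = KernelSet(
        lambda_pool=gaussian_kernel(2.0, n_features=4, feature_sigma=10.0))

    layers = {
        "V1": LayerSpec(v1_params, v1_kernels, (H, W, C),
                        FeatureAxis.ORIENTATION, scale=1),
        "V2": LayerSpec(v2_params, v2_kernels, (H, W, C),
                        FeatureAxis.ORIENTATION, scale=1),
        "V4": LayerSpec(v4_params, v4_kernels, (H // f4, W // f4, 4),
                        FeatureAxis.SCALAR, scale=f4),
    }
    connections = [
        ConnectionSpec("V1", "V2", DRIVING,
                       kernel=OrientedBipoleStack(
                           C, cfg["bipole_reach"], cfg["bipole_tolerance"]),
                       gain=cfg["v2_gain"]),
        ConnectionSpec("V2", "V4", DRIVING,
                       kernel=OrientationContrastStack(
                           C, cfg["oc_filter_scale"]),
                       gain=cfg["v4_gain"]),
        ConnectionSpec("V4", "V2", FEEDBACK, kernel=gaussian_kernel(1.0),
                       channel_map="broadcast", gain=cfg["v4_fb_gain"]),
        ConnectionSpec("V2", "V1", FEEDBACK, kernel=identity_kernel(),
                       gain=1.0),
    ]
    frontend = Frontend("oriented", n_orientations=C,
                        scale=cfg["filter_scale"], gain=cfg["frontend_gain"])
    return Architecture(layers, connections, frontend, "V1",
                        readout=dict(config=cfg), name="texture")


class OrientationContrastStack(Kernel):
    """Orientation-contrast filtering from an orientation field.

    For each of four subfield-displacement axes (0, 45, 90, 135 deg) and
    each input orientation, the unit compares Gaussian-pooled activity of
    that orientation on the two sides of its subfield boundary and rectifies
    the difference; responses are summed over orientations, yielding one
    output channel per axis.  This is the efficient separable form of the
    dense juxtaposed-subfield kernels built by
    :func:`canoncirc.kernels.orientation_contrast_filter`.
    """

    def __init__(self, n_orientations: int, scale: float, n_axes: int = 4,
                 power: float = 2.0):
        self.n_axes = n_axes
        self.offset = scale / 2.0
        self.sigma = scale / 2.0
        self.power = power
        super().__init__(weights=np.ones((1, 1)))

    def apply(self, values: np.ndarray) -> np.ndarray:
        x = np.asarray(values, dtype=float) ** self.power
        H, W, C = x.shape
        blurred = np.empty_like(x)
        for c in range(C):
            blurred[:, :, c] = ndimage.gaussian_filter(
                x[:, :, c], self.sigma, mode="reflect", truncate=2.0)
        out = np.zeros((H, W, self.n_axes))
        for a in range(self.n_axes):
            ang = a * math.pi / self.n_axes
            ex = self.offset * math.cos(ang)
            ey = -self.offset * math.sin(ang)
            for c in range(C):
                pos = ndimage.shift(blurred[:, :, c], (-ey, -ex), order=1,
                                    mode="reflect")
                neg = ndimage.shift(blurred[:, :, c], (ey, ex), order=1,
                                    mode="reflect")
                out[:, :, a] += np.abs(pos - neg)
        return out / C


def build_motion_model(config: dict | None = None,
                       include_mst: bool = True) -> Architecture:
    """V1-MT(-MSTl) motion detection and integration model.

    V1 holds correlation-detector responses (direction x speed channels)
    normalized over a space-direction pool; MT integrates V1 over a larger
    neighborhood on a coarser grid with space-velocity pool normalization;
    MSTl (optional) integrates MT over a large field per direction with
    mutual competition.  Feedback MT->V1 (and MSTl->MT) is modulatory, with
    MT->V1 re-entry displaced by each channel's linear forward prediction.
    """
    cfg = dict(shape=(128, 128), n_directions=8, speeds=(2.0,),
               detector_scale=1.5, v1_pool_sigma=1.0, v1_pool_gain=800.0,
               v1_gain=1.5, mt_scale=4, mt_sigma=1.5, mt_gain=120.0,
               mt_pool_sigma=2.0, mt_pool_gain=300.0, mst_scale=8,
               mst_gain=4.0, lambda_fb_v1=10.0, lambda_fb_mt=5.0,
               fb_gain_v1=8.0, fb_gain_mt=1.0, mt_kappa=0.3,
               mt_g_exponent=3.0, frontend_gain=1.5, displace_v1_fb=True,
               tau=600.0, tau_q=50.0)
    cfg.update(config or {})
    H, W = cfg["shape"]
    D = cfg["n_directions"]
    speeds = tuple(cfg["speeds"])
    C = D * len(speeds)
    bank = MotionDetectorBank(n_directions=D, speeds=speeds,
                              spatial_scale=cfg["detector_scale"])
    fmt = cfg["mt_scale"]

    v1_params = _ei_params(tau=cfg["tau"], tau_q=cfg["tau_q"],
                           lambda_fb=cfg["lambda_fb_v1"],
                           gq_gain=cfg["v1_pool_gain"])
    v1_kernels = KernelSet(
        lambda_pool=pool_kernel(cfg["v1_pool_sigma"], 10.0, C))
    mt_params = _ei_params(tau=cfg["tau"], tau_q=cfg["tau_q"],
                           lambda_fb=cfg["lambda_fb_mt"],
                           kappa=cfg["mt_kappa"], gq_gain=cfg["mt_pool_gain"])
    if cfg["mt_g_exponent"] != 1.0:
        mt_params.g_spec = FiringRateSpec("power",
                                          exponent=cfg["mt_g_exponent"])
    mt_kernels = KernelSet(
        lambda_pool=pool_kernel(cfg["mt_pool_sigma"], 10.0, C))

    layers = {
        "V1": LayerSpec(v1_params, v1_kernels, (H, W, C),
                        FeatureAxis.DIRECTION_SPEED, scale=1),
        "MT": LayerSpec(mt_params, mt_kernels, (H // fmt, W // fmt, C),
                        FeatureAxis.DIRECTION_SPEED, scale=fmt),
    }
    connections = [
        ConnectionSpec("V1", "MT", DRIVING,
                       kernel=gaussian_kernel(cfg["mt_sigma"] * fmt),
                       gain=cfg["mt_gain"]),
        ConnectionSpec("MT", "MT", LATERAL,
                       kernel=gaussian_kernel(cfg["mt_sigma"])),
        ConnectionSpec("MT", "V1", FEEDBACK,
                       kernel=gaussian_kernel(1.0),
                       displacement=cfg["displace_v1_fb"],
                       gain=cfg["fb_gain_v1"]),
    ]
    if include_mst:
        fms = cfg["mst_scale"]
        mst_params = _ei_params(tau=cfg["tau"], tau_q=cfg["tau_q"],
                                gq_gain=20.0)
        mst_kernels = KernelSet(
            lambda_pool=pool_kernel(max(2.0, H / fms / 2.0), 10.0, D))
        layers["MSTl"] = LayerSpec(mst_params, mst_kernels,
                                   (H // fms, W // fms, D),
                                   FeatureAxis.DIRECTION, scale=fms)
        connections += [
            ConnectionSpec("MT", "MSTl", DRIVING,
                           kernel=gaussian_kernel(3.0),
                           channel_map="sum_speeds", gain=cfg["mst_gain"]),
            ConnectionSpec("MSTl", "MT", FEEDBACK,
                           kernel=gaussian_kernel(1.0),
                           channel_map="broadcast_speeds",
                           gain=cfg["fb_gain_mt"]),
        ]
    frontend = Frontend("motion", bank=bank, gain=cfg["frontend_gain"])
    return Architecture(layers, connections, frontend, "V1",
                        readout=dict(config=cfg), bank=bank,
                        name="motion" + ("_mst" if include_mst else ""))


def build_adaptation_model(variant: int,
                           config: dict | None = None) -> Architecture:
    """Two-layer motion model with adaptive synapses, variants 1-5.

    1: feedforward-only graph, fast adaptation on V1->MT;
    2: feedforward-only graph, slow adaptation on V1->MT;
    3: recurrent graph, fast adaptation on V1->MT;
    4: recurrent graph, slow adaptation on MT->V1 feedback;
    5: recurrent graph, fast V1->MT and slow MT->V1 adaptation.

    The decision readout (whole-field opponent pooling + softmax) is applied
    to MT output by the experiment driver.
    """
    if variant not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown adaptation model variant {variant!r}")
    cfg = dict(shape=(48, 48), n_directions=8, speeds=(2.0,),
               tau_fast=50.0, tau_slow=4000.0, alpha_w=1.0,
               beta_fast=0.04, beta_slow=0.5, beta_fb=1.0,
               fb_gain_v1=30.0, frontend_gain=0.15)
    cfg.update(config or {})
    base = dict(shape=cfg["shape"], n_directions=cfg["n_directions"],
                speeds=cfg["speeds"], mt_scale=2, tau=50.0, tau_q=50.0,
                frontend_gain=cfg["frontend_gain"], v1_pool_gain=30.0,
                mt_gain=20.0, mt_pool_gain=12.0, mt_g_exponent=2.0,
                fb_gain_v1=cfg["fb_gain_v1"])
    arch = build_motion_model(base, include_mst=False)
    arch.name = f"adaptation_v{variant}"
    fast = AdaptiveSynapse(w=1.0, alpha_w=cfg["alpha_w"],
                           beta_w=cfg["beta_fast"], tau_w=cfg["tau_fast"])
    slow = AdaptiveSynapse(w=1.0, alpha_w=cfg["alpha_w"],
                           beta_w=cfg["beta_slow"], tau_w=cfg["tau_slow"])
    slow_fb = AdaptiveSynapse(w=1.0, alpha_w=cfg["alpha_w"],
                              beta_w=cfg["beta_fb"], tau_w=cfg["tau_slow"])
    ff = arch.find_edges("V1", "MT", DRIVING)[0]
    fb = arch.find_edges("MT", "V1", FEEDBACK)[0]
    if variant in (1, 2):
        arch = ablate(arch, [fb.key()])
        ff = arch.find_edges("V1", "MT", DRIVING)[0]
        ff.synapse = fast if variant == 1 else slow
    elif variant == 3:
        ff.synapse = fast
    elif variant == 4:
        fb.synapse = slow_fb
    else:
        ff.synapse = fast
        fb.synapse = slow_fb
    arch.readout["variant"] = variant
    arch.readout["synapse_drive_gain"] = 8.0
    return arch
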