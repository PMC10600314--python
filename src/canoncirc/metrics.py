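"""Read-out metrics and scripted experiments.

Metrics: contextual-modulation index (percent change relative to the
isolated-bar reference), figure-ground segregation ratio, circular angular
error and endpoint error of velocity estimates, population speed read-out,
softmax direction decisions, hysteresis switch point, and psychometric
(Gaussian-CDF) fits with the point of subjective equality (PSE).

Experiments: each driver reproduces one protocol end to end — build the
stimuli and the architecture, simulate, compute the read-outs — and returns
a long-format metrics table plus provenance.  All stochastic pieces take
explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

from . import stimuli as stim_mod
from .architectures import (DRIVING, FEEDBACK, LATERAL, Architecture,
                            ablate, build_adaptation_model,
                            build_contour_model, build_motion_model,
                            build_texture_model, simulate)
from .core import adapt_weight
from .kernels import MotionDetectorBank


# --------------------------------------------------------------------------
# Scalar / field metrics
# --------------------------------------------------------------------------

def relative_response(response: float, reference: float) -> float:
    """Percent change relative to a reference response (reference -> 0%)."""
    if reference <= 0:
        raise ValueError("reference response must be positive")
    return 100.0 * (response - reference) / reference


def segregation_metric(v4_field: np.ndarray, figure_mask: np.ndarray,
                       boundary_mask: np.ndarray) -> tuple[float, str]:
    """Figure-ground segregation ratio of a response field.

    Mean activity over figure-plus-boundary divided by mean activity over
    the background.  Returns (ratio, status); a zero background mean is
    flagged as status "background_zero" with an infinite ratio.
    """
    act = np.asarray(v4_field, dtype=float)
    if act.ndim == 3:
        act = act.sum(axis=2)
    fig = np.asarray(figure_mask, bool) | np.asarray(boundary_mask, bool)
    bg = ~fig
    if not bg.any() or not fig.any():
        raise ValueError("masks must leave both regions non-empty")
    bg_mean = act[bg].mean()
    fig_mean = act[fig].mean()
    if bg_mean <= 0:
        return math.inf, "background_zero"
    return float(fig_mean / bg_mean), "ok"


def angular_error(estimated: np.ndarray, truth: np.ndarray,
                  support_mask: np.ndarray) -> float:
    """Mean absolute circular difference between direction fields, degrees."""
    est = np.asarray(estimated, float)
    tru = np.broadcast_to(np.asarray(truth, float), est.shape)
    mask = np.asarray(support_mask, bool)
    if not mask.any():
        raise ValueError("support mask is empty")
    d = np.angle(np.exp(1j * (est[mask] - tru[mask])))
    return float(np.degrees(np.mean(np.abs(d))))


def endpoint_error(estimated: np.ndarray, truth: np.ndarray,
                   support_mask: np.ndarray) -> float:
    """Mean Euclidean distance between velocity fields (px/frame)."""
    est = np.asarray(estimated, float)
    tru = np.broadcast_to(np.asarray(truth, float), est.shape)
    mask = np.asarray(support_mask, bool)
    if not mask.any():
        raise ValueError("support mask is empty")
    diff = est[mask] - tru[mask]
    return float(np.mean(np.linalg.norm(diff, axis=-1)))


def population_velocity(field: np.ndarray,
                        bank: MotionDetectorBank) -> np.ndarray:
    """Activity-weighted population velocity (H, W, 2) as (vx, vy)."""
    x = np.asarray(field, float)
    vs = np.array([bank.channel_velocity(c) for c in range(x.shape[2])])
    total = x.sum(axis=2)
    vel = np.tensordot(x, vs, axes=([2], [0]))
    with np.errstate(invalid="ignore", divide="ignore"):
        vel = np.where(total[..., None] > 0, vel / total[..., None], 0.0)
    return vel


def population_direction(field: np.ndarray,
                         bank: MotionDetectorBank) -> np.ndarray:
    """Population vector direction (radians, CCW, 0 = rightward) per pixel."""
    v = population_velocity(field, bank)
    return np.arctan2(-v[..., 1], v[..., 0])


def population_speed_readout(responses: np.ndarray,
                             speed_channels: np.ndarray) -> float:
    """Activity-weighted mean preferred speed of a speed-tuned population."""
    r = np.asarray(responses, float)
    s = np.asarray(speed_channels, float)
    if r.shape != s.shape:
        raise ValueError("responses and speed_channels must share shape")
    if np.any(r < 0):
        raise ValueError("responses must be non-negative")
    tot = r.sum()
    if tot <= 0:
        raise ValueError("responses must not be all zero")
    return float((r * s).sum() / tot)


# --------------------------------------------------------------------------
# Decision read-outs
# --------------------------------------------------------------------------

@dataclass
class DecisionTrace:
    """Per-frame decision variables and softmax choices."""

    values: np.ndarray                  # (T, n_alternatives)
    probabilities: np.ndarray           # (T, n_alternatives)
    choices: np.ndarray                 # (T,) argmax index, tie-broken
    temperature: float


def direction_decision(pooled, temperature: float = 1.0,
                       previous_choice: int | None = None
                       ) -> tuple[np.ndarray, int]:
    """Softmax over pooled per-alternative activity plus an argmax choice.

    Exact ties retain ``previous_choice`` when given (hysteresis-neutral
    tie-break); the very first tie goes to the lowest index.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    v = np.asarray(pooled, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("decision variables must be finite")
    z = v / temperature
    z = z - z.max()
    p = np.exp(z)
    p /= p.sum()
    best = np.flatnonzero(v == v.max())
    if len(best) > 1 and previous_choice in best:
        choice = int(previous_choice)
    else:
        choice = int(best[0])
    return p, choice


def decide_sequence(values: np.ndarray, temperature: float = 1.0
                    ) -> DecisionTrace:
    """Apply :func:`direction_decision` frame by frame."""
    values = np.asarray(values, float)
    probs = np.empty_like(values)
    choices = np.empty(len(values), dtype=int)
    prev = None
    for t in range(len(values)):
        probs[t], choices[t] = direction_decision(values[t], temperature, prev)
        prev = choices[t]
    return DecisionTrace(values, probs, choices, temperature)


def hysteresis_switch_point(trace: DecisionTrace,
                            truth_fraction_per_frame: np.ndarray,
                            persistence: int = 3) -> tuple[float | None, str]:
    """Reversed-dot fraction at the first stable decision flip.

    Returns (percent, "switch") for the first frame where the choice flips
    away from the initial alternative and stays flipped for at least
    ``persistence`` consecutive frames, or (None, "no switch").
    """
    frac = np.asarray(truth_fraction_per_frame, float)
    ch = trace.choices
    if len(frac) != len(ch):
        raise ValueError("trace and truth schedule lengths differ")
    initial = ch[0]
    for t in range(1, len(ch)):
        if ch[t] != initial and np.all(ch[t:t + persistence] != initial) \
                and len(ch) - t >= persistence:
            return float(100.0 * frac[t]), "switch"
    return None, "no switch"


# --------------------------------------------------------------------------
# Psychometric fit
# --------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    levels: np.ndarray
    fractions: np.ndarray
    pse: float
    spread: float
    ci_low: float | None = None
    ci_high: float | None = None
    in_range: bool = True


def _gauss_cdf(x, mu, sigma):
    return stats.norm.cdf(x, loc=mu, scale=sigma)


def psychometric_pse(levels, choice_fractions, n_trials: int | None = None,
                     n_boot: int = 200, seed: int = 0) -> PsychometricFit:
    """Least-squares Gaussian-CDF fit of a psychometric curve.

    ``levels`` is the stimulus axis, ``choice_fractions`` the fraction of
    one alternative chosen per level.  The fitted mean is the PSE.  When
    ``n_trials`` is given a seeded parametric bootstrap (binomial resampling
    of the fitted curve, ``n_boot`` replicates) yields a 95% CI of the PSE.
    """
    x = np.asarray(levels, float)
    y = np.asarray(choice_fractions, float)
    if len(x) < 4:
        raise ValueError("need at least 4 stimulus levels")
    if y.min() > 0.5 or y.max() < 0.5:
        raise ValueError("levels must span both choice majorities")

    def fit(xv, yv):
        sigma0 = max((xv.max() - xv.min()) / 4.0, 1e-6)
        mu0 = xv[np.argmin(np.abs(yv - 0.5))]
        popt, _ = optimize.curve_fit(
            _gauss_cdf, xv, yv, p0=(mu0, sigma0),
            bounds=((xv.min() - 5 * sigma0, 1e-9),
                    (xv.max() + 5 * sigma0, np.inf)), maxfev=5000)
        return popt

    mu, sg = fit(x, y)
    ci_low = ci_high = None
    if n_trials is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        p_fit = np.clip(_gauss_cdf(x, mu, sg), 1e-6, 1 - 1e-6)
        boots = []
        for _ in range(n_boot):
            yb = rng.binomial(n_trials, p_fit) / n_trials
            try:
                boots.append(fit(x, yb)[0])
            except RuntimeError:
                continue
        if boots:
            ci_low, ci_high = np.percentile(boots, [2.5, 97.5])
    in_range = bool(x.min() <= mu <= x.max())
    return PsychometricFit(x, y, float(mu), float(sg), ci_low, ci_high,
                           in_range)


# --------------------------------------------------------------------------
# Experiment drivers
# --------------------------------------------------------------------------

def _center_channel_response(rec, arch, cy, cx, channel, window: int = 1):
    """Mean V1 output in a small window at (cy, cx) for one channel."""
    out = rec.outputs["V1"][-1]
    sl = (slice(int(cy) - window, int(cy) + window + 1),
          slice(int(cx) - window, int(cx) + window + 1))
    return float(out[sl][..., channel].mean())


def run_kapadia(config: dict | None = None) -> dict:
    """Contextual modulation of a center bar by flankers and texture.

    Simulates the contour model on the eight bar-display configurations and
    reports the center-cell response relative to the isolated-bar reference
    (0%), for each configured feedback gain.
    """
    cfg = dict(lambdas=(2.0, 6.0), duration=250.0, dt=5.0, seed=0,
               configs=(1, 2, 3, 4, 5, 6, 7, 8), model={})
    cfg.update(config or {})
    rows = []
    for lam in cfg["lambdas"]:
        arch = build_contour_model({**cfg["model"], "lambda_fb": lam})
        C = arch.layers["V1"].shape[2]
        channel = round((math.pi / 2) / (math.pi / C)) % C
        responses = {}
        for cid in cfg["configs"]:
            stim = stim_mod.kapadia_display(cid, seed=cfg["seed"])
            rec = simulate(arch, stim, duration=cfg["duration"],
                           dt=cfg["dt"], record_stride=10 ** 9)
            cy, cx = stim.ground_truth["center"]
            responses[cid] = _center_channel_response(rec, arch, cy, cx,
                                                      channel)
        ref = responses[cfg["configs"][0]]
        for cid, resp in responses.items():
            rows.append(dict(experiment="kapadia", variant=f"lambda={lam}",
                             parameter=cid,
                             value=relative_response(resp, ref)))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="kapadia", config=cfg))


TEXTURE_VARIANTS = {
    "full": (),
    "no_v2_v1": (("V2", "V1", FEEDBACK),),
    "no_v4_v2": (("V4", "V2", FEEDBACK),),
    "pure_ff": (("V2", "V1", FEEDBACK), ("V4", "V2", FEEDBACK)),
}


def texture_masks(stim, v4_scale: int, boundary_cells: int = 1):
    """Figure / boundary / background masks at the V4 grid resolution."""
    fig = stim.ground_truth["figure_mask"]
    sy, sx = stim.ground_truth["cell_size"]
    n_iter = int(round(boundary_cells * min(sy, sx)))
    dilated = ndimage.binary_dilation(fig, iterations=n_iter)
    boundary = dilated & ~fig
    f = v4_scale

    def down(m):
        H, W = m.shape
        return m.reshape(H // f, f, W // f, f).mean((1, 3)) > 0.5

    return down(fig), down(boundary)


def run_texture_sweep(config: dict | None = None) -> dict:
    """Figure-ground segregation across orientation contrasts and ablations."""
    cfg = dict(oc_values=(60.0,), bn=20.0, variants=tuple(TEXTURE_VARIANTS),
               duration=400.0, dt=5.0, seed=0, model={})
    cfg.update(config or {})
    base = build_texture_model(cfg["model"])
    f4 = base.layers["V4"].scale
    rows = []
    for oc in cfg["oc_values"]:
        stim = stim_mod.texture_figure(oc=oc, bn=cfg["bn"], seed=cfg["seed"])
        fig_m, bnd_m = texture_masks(stim, f4)
        for variant in cfg["variants"]:
            arch = ablate(base, list(TEXTURE_VARIANTS[variant]))
            rec = simulate(arch, stim, duration=cfg["duration"],
                           dt=cfg["dt"], record_stride=10 ** 9)
            ratio, status = segregation_metric(rec.outputs["V4"][-1],
                                               fig_m, bnd_m)
            rows.append(dict(experiment="texture_sweep", variant=variant,
                             parameter=oc, value=ratio, status=status))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="texture_sweep", config=cfg))


def _bar_center_mask(stim, t: int, fraction: float = 1 / 3) -> np.ndarray:
    """Pixels of the central ``fraction`` of the bar at frame t."""
    gt = stim.ground_truth
    cy, cx = gt["centers"][t]
    ori = gt["orientation"]
    length = stim.provenance["length"]
    width = stim.provenance["width"]
    H, W = stim.shape
    ys, xs = np.mgrid[0:H, 0:W]
    u = (xs - cx) * math.cos(ori) - (ys - cy) * math.sin(ori)
    v = (xs - cx) * math.sin(ori) + (ys - cy) * math.cos(ori)
    return (np.abs(u) <= length * fraction / 2.0) & (np.abs(v) <= width)


def run_aperture_bar(config: dict | None = None) -> dict:
    """Aperture-problem dynamics on translating bars of several lengths.

    Tracks the mean angular error of the V1 population direction estimate
    over the bar's central third across time; the disambiguation time is the
    first frame at which that error falls below half its initial value.
    """
    cfg = dict(lengths=(19.0, 31.0, 43.0), speed=2.0,
               direction=math.pi / 4, orientation=math.pi / 2,
               n_frames=28, dt=5.0, steps_per_frame=4, model={},
               variants=("full", "no_fb"))
    cfg.update(config or {})
    model_cfg = dict(shape=(96, 96), speeds=(1.0, 2.0))
    model_cfg.update(cfg["model"])
    rows = []
    for length in cfg["lengths"]:
        stim = stim_mod.translating_bar(
            orientation=cfg["orientation"], direction=cfg["direction"],
            speed=cfg["speed"], length=length, n_frames=cfg["n_frames"],
            shape=model_cfg["shape"])
        for variant in cfg["variants"]:
            arch = build_motion_model(model_cfg, include_mst=True)
            if variant == "no_fb":
                arch = ablate(arch, [("MT", "V1", FEEDBACK),
                                     ("MSTl", "MT", FEEDBACK)])
            rec = simulate(arch, stim, dt=cfg["dt"],
                           steps_per_frame=cfg["steps_per_frame"],
                           record_stride=cfg["steps_per_frame"])
            errs = []
            for t in range(rec.outputs["V1"].shape[0]):
                mask = _bar_center_mask(stim, t + 1)
                act = rec.outputs["V1"][t]
                mask = mask & (act.sum(axis=2) > 1e-9)
                if not mask.any():
                    errs.append(np.nan)
                    continue
                est = population_direction(act, arch.bank)
                errs.append(angular_error(est, cfg["direction"], mask))
            errs = np.asarray(errs)
            valid = ~np.isnan(errs)
            first = errs[valid][0]
            half = first / 2.0
            below = np.flatnonzero(valid & (errs < half))
            t_dis = float(below[0] + 1) if len(below) else float(len(errs))
            for t, e in enumerate(errs):
                rows.append(dict(experiment="aperture_bar", variant=variant,
                                 parameter=length, frame=t + 1, value=e,
                                 measure="angular_error"))
            rows.append(dict(experiment="aperture_bar", variant=variant,
                             parameter=length, frame=-1, value=t_dis,
                             measure="time_to_disambiguation"))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="aperture_bar", config=cfg))


def run_windmill(config: dict | None = None) -> dict:
    """Population speed read-out versus radius on a rotating windmill."""
    cfg = dict(n_arms=4, angular_speed=0.05, radius=40.0, n_frames=16,
               dt=5.0, steps_per_frame=4, model={})
    cfg.update(config or {})
    model_cfg = dict(shape=(96, 96), speeds=(0.5, 1.0, 1.5, 2.0, 2.5))
    model_cfg.update(cfg["model"])
    arch = build_motion_model(model_cfg, include_mst=True)
    stim = stim_mod.windmill(n_arms=cfg["n_arms"],
                             angular_speed=cfg["angular_speed"],
                             radius=cfg["radius"], n_frames=cfg["n_frames"],
                             shape=model_cfg["shape"])
    rec = simulate(arch, stim, dt=cfg["dt"],
                   steps_per_frame=cfg["steps_per_frame"],
                   record_stride=10 ** 9)
    mt = rec.outputs["MT"][-1]
    fmt = arch.layers["MT"].scale
    n_sp = len(arch.bank.speeds)
    rho = stim.ground_truth["radius_map"]
    rho_mt = rho.reshape(rho.shape[0] // fmt, fmt,
                         rho.shape[1] // fmt, fmt).mean((1, 3))
    speeds = np.asarray(arch.bank.speeds)
    act_total = mt.sum(axis=2)
    rows = []
    thresh = 0.1 * act_total.max()
    for (iy, ix) in zip(*np.nonzero(act_total > thresh)):
        r = rho_mt[iy, ix]
        # annular read-out region: exclude the hub (spokes crowd within the
        # detector aperture there) and the rim
        if not (10.0 <= r <= cfg["radius"] - 5.0):
            continue
        resp_by_speed = mt[iy, ix].reshape(-1, n_sp).sum(axis=0)
        readout = population_speed_readout(resp_by_speed, speeds)
        rows.append(dict(experiment="windmill", variant="full",
                         parameter=float(r), value=readout,
                         truth=float(abs(cfg["angular_speed"]) * r)))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="windmill", config=cfg))


MOTION_VARIANTS = {
    "full": (),
    "no_lateral": (("MT", "MT", LATERAL),),
    "no_fb_mt": (("MSTl", "MT", FEEDBACK),),
    "no_fb_v1": (("MT", "V1", FEEDBACK),),
    "no_fb": (("MT", "V1", FEEDBACK), ("MSTl", "MT", FEEDBACK)),
}


def run_ablation_motion(config: dict | None = None) -> dict:
    """Endpoint error of MT velocity estimates under feedback ablations."""
    cfg = dict(length=31.0, speed=2.0, direction=math.pi / 4,
               orientation=math.pi / 2, n_frames=28, dt=5.0,
               steps_per_frame=4, variants=tuple(MOTION_VARIANTS), model={})
    cfg.update(config or {})
    model_cfg = dict(shape=(96, 96), speeds=(1.0, 2.0))
    model_cfg.update(cfg["model"])
    base = build_motion_model(model_cfg, include_mst=True)
    stim = stim_mod.translating_bar(
        orientation=cfg["orientation"], direction=cfg["direction"],
        speed=cfg["speed"], length=cfg["length"], n_frames=cfg["n_frames"],
        shape=model_cfg["shape"])
    truth = np.array(stim.ground_truth["velocity"])
    fmt = base.layers["MT"].scale
    rows = []
    for variant in cfg["variants"]:
        arch = ablate(base, list(MOTION_VARIANTS[variant]))
        rec = simulate(arch, stim, dt=cfg["dt"],
                       steps_per_frame=cfg["steps_per_frame"],
                       record_stride=cfg["steps_per_frame"])
        n_rec = rec.outputs["MT"].shape[0]
        errs = []
        for t in range(2 * n_rec // 3, n_rec):
            mt = rec.outputs["MT"][t]
            act = mt.sum(axis=2)
            mask_full = _bar_center_mask(stim, t + 1, fraction=1.0)
            mask = (mask_full.reshape(mask_full.shape[0] // fmt, fmt,
                                      mask_full.shape[1] // fmt, fmt)
                    .max(axis=(1, 3)) & (act > 1e-9))
            if not mask.any():
                continue
            vel = population_velocity(mt, arch.bank)
            errs.append(endpoint_error(vel, truth, mask))
        rows.append(dict(experiment="ablation_motion", variant=variant,
                         parameter=cfg["length"],
                         value=float(np.mean(errs))))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="ablation_motion", config=cfg))


def run_curveball(config: dict | None = None) -> dict:
    """Curveball illusion: component-motion bias of MT vs V1 estimates.

    Measures, per layer, the mean angular deviation of the population
    velocity (spatially averaged over the envelope region) from the true
    envelope motion direction, for the intact model and with MT->V1
    feedback removed.
    """
    cfg = dict(n_frames=32, dt=5.0, steps_per_frame=4, sigma=6.0,
               wavelength=6.0, component_speed=2.0, model={})
    cfg.update(config or {})
    model_cfg = dict(shape=(96, 96), speeds=(2.0,))
    model_cfg.update(cfg["model"])
    v = cfg["component_speed"]
    stim = stim_mod.gabor_curveball(
        envelope_velocity=(0.0, -v), carrier_drift_velocity=(v, 0.0),
        sigma=cfg["sigma"], wavelength=cfg["wavelength"],
        n_frames=cfg["n_frames"], shape=model_cfg["shape"])
    evx, evy = stim.ground_truth["envelope_velocity"]
    env_dir = math.atan2(-evy, evx)
    sigma = stim.provenance["sigma"]
    rows = []
    for variant in ("full", "no_fb_v1"):
        arch = build_motion_model(model_cfg, include_mst=False)
        if variant == "no_fb_v1":
            arch = ablate(arch, [("MT", "V1", FEEDBACK)])
        rec = simulate(arch, stim, dt=cfg["dt"],
                       steps_per_frame=cfg["steps_per_frame"],
                       record_stride=cfg["steps_per_frame"])
        for layer in ("V1", "MT"):
            scale = arch.layers[layer].scale
            devs = []
            n_rec = rec.outputs[layer].shape[0]
            for t in range(n_rec // 3, n_rec):
                cy, cx = stim.ground_truth["centers"][min(t + 1,
                                                          stim.n_frames - 1)]
                act = rec.outputs[layer][t]
                H, W = act.shape[:2]
                ys, xs = np.mgrid[0:H, 0:W]
                d2 = ((ys * scale - cy) ** 2 + (xs * scale - cx) ** 2)
                mask = (d2 <= (1.5 * sigma) ** 2) & (act.sum(axis=2) > 1e-9)
                if not mask.any():
                    continue
                vel = population_velocity(act, arch.bank)
                mean_v = vel[mask].mean(axis=0)
                est_dir = math.atan2(-mean_v[1], mean_v[0])
                devs.append(abs(math.degrees(
                    np.angle(np.exp(1j * (est_dir - env_dir))))))
            rows.append(dict(experiment="curveball", variant=variant,
                             parameter=layer, value=float(np.mean(devs))))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="curveball", config=cfg))


def rdk_decision_trace(arch: Architecture, stim, dt: float = 5.0,
                       steps_per_frame: int = 2,
                       temperature: float | None = None) -> DecisionTrace:
    """Whole-field opponent decision variables from an RDK simulation.

    Pools MT output over the full field for the two horizontal opponent
    direction channels (all speeds) and applies the per-frame softmax
    decision.  The softmax temperature defaults to a fixed fraction of the
    pooled-activity scale so probabilities stay graded.
    """
    rec = simulate(arch, stim, dt=dt, steps_per_frame=steps_per_frame,
                   record_stride=steps_per_frame)
    mt = rec.outputs["MT"]
    D = arch.bank.n_directions
    n_sp = len(arch.bank.speeds)
    right = mt.reshape(mt.shape[:3] + (D, n_sp))[..., 0, :].sum((1, 2, 3))
    left = mt.reshape(mt.shape[:3] + (D, n_sp))[..., D // 2, :].sum((1, 2, 3))
    values = np.stack([right, left], axis=1)
    if temperature is None:
        temperature = max(1e-9, 0.05 * float(values.max()))
    return decide_sequence(values, temperature)


# the RDK protocol runs the two-layer model in a fast-membrane regime so
# that, without feedback, the whole-field decision tracks the dot fraction;
# hysteresis then arises from the modulatory loop alone
RDK_MODEL = dict(shape=(128, 128), speeds=(2.0,), tau=50.0, tau_q=50.0,
                 frontend_gain=0.15, v1_pool_gain=30.0, mt_gain=20.0,
                 mt_pool_gain=12.0, mt_g_exponent=2.0, fb_gain_v1=8.0)


def run_rdk_hysteresis(config: dict | None = None) -> dict:
    """Perceptual hysteresis in the RDK direction-reversal protocol.

    For each seed and each sequence direction ('a': right-to-left, 'b':
    left-to-right) the two-layer V1-MT model with intact modulatory feedback
    is probed with the 60-frame/60-dot reversal schedule and the stable
    switch point is extracted; the feedback-ablated model is run for the
    no-hysteresis control.
    """
    cfg = dict(seeds=tuple(range(10)), n_frames=60, n_dots=60,
               dot_speed=2.0, dt=5.0, steps_per_frame=4,
               sequences=("a", "b"), variants=("full", "no_fb"), model={})
    cfg.update(config or {})
    model_cfg = dict(RDK_MODEL)
    model_cfg.update(cfg["model"])
    rows = []
    for seed in cfg["seeds"]:
        for seq in cfg["sequences"]:
            init_dir = 0.0 if seq == "a" else math.pi
            stim = stim_mod.rdk_sequence(
                n_frames=cfg["n_frames"], n_dots=cfg["n_dots"],
                initial_direction=init_dir, dot_speed=cfg["dot_speed"],
                shape=model_cfg["shape"], seed=seed)
            frac = stim.ground_truth["reversed_fraction"][1:]
            for variant in cfg["variants"]:
                if variant not in ("full",) and seq == "b":
                    continue        # control only needs one sequence
                arch = build_motion_model(model_cfg, include_mst=False)
                if variant == "no_fb":
                    arch = ablate(arch, [("MT", "V1", FEEDBACK)])
                trace = rdk_decision_trace(
                    arch, stim, dt=cfg["dt"],
                    steps_per_frame=cfg["steps_per_frame"])
                # alternative 0 pools rightward motion; for sequence 'b'
                # the initial direction is leftward (alternative 1)
                switch, status = hysteresis_switch_point(trace, frac)
                rows.append(dict(
                    experiment="rdk_hysteresis", variant=variant,
                    sequence=seq, parameter=seed,
                    value=switch if switch is not None else np.nan,
                    status=status,
                    monotonicity=float(stats.spearmanr(
                        frac, trace.values[:, 1] /
                        np.maximum(trace.values.sum(1), 1e-12)).statistic)))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="rdk_hysteresis", config=cfg))


# --------------------------------------------------------------------------
# Adaptation experiment
# --------------------------------------------------------------------------

ADAPTATION_SCHEDULES = {
    # (exposure frames, post-exposure blank-gap frames); at 5 ms per frame
    # the fast synapse (tau_w = 50 ms) adapts within the brief exposure,
    # the slow synapse (tau_w = 500 ms) only over the prolonged one, and
    # the prolonged gap lets the fast synapse recover fully
    "brief": (3, 0),
    "medium": (50, 4),
    "prolonged": (320, 80),
}


def _probe_fraction_up(arch, synapse_state, level_deg: float, seed: int,
                       n_frames: int, dt: float, temperature: float,
                       layer_states: dict | None = None) -> float:
    """Mean softmax probability of 'up' over one probe sequence.

    The probe drifts at ``level_deg`` degrees above (positive) or below
    (negative) the horizontal, so the level controls the strength of the
    vertical motion signal to be judged.
    """
    direction = math.radians(level_deg)
    stim = stim_mod.drifting_texture(direction=direction, speed=2.0,
                                     n_frames=n_frames,
                                     shape=arch.layers["V1"].shape[:2],
                                     seed=seed)
    rec = simulate(arch, stim, dt=dt, steps_per_frame=1,
                   record_stride=1, initial_synapse_state=synapse_state,
                   initial_layer_states=layer_states, freeze_synapses=True)
    mt = rec.outputs["MT"]
    D = arch.bank.n_directions
    n_sp = len(arch.bank.speeds)
    dirs = arch.bank.directions()
    w_up = np.maximum(np.sin(dirs), 0.0)
    w_down = np.maximum(-np.sin(dirs), 0.0)
    resp = mt.reshape(mt.shape[:3] + (D, n_sp)).sum((1, 2, 4))
    up = resp @ w_up
    down = resp @ w_down
    # synapses are frozen during the probe, so the decision reads the
    # post-exposure efficacy state; skip the onset transient
    probs = []
    for t in range(len(up) // 3, len(up)):
        p, _ = direction_decision([up[t], down[t]], temperature)
        probs.append(p[0])
    return float(np.mean(probs))


def run_adaptation(config: dict | None = None) -> dict:
    """PSE shifts of the five adaptation-model variants.

    Each variant is exposed to vertically sheared (up- or down-skewed)
    drifting texture whose motion statistics are biased toward one vertical
    direction, for three exposure/gap schedules; afterwards probe sequences
    drifting at angles around horizontal are judged up vs down and a
    Gaussian-CDF psychometric fit yields the PSE.  The reported shift is
    PSE(up-adapted) - PSE(down-adapted); adaptation that depresses the
    exposed direction predicts a positive shift (repulsion).
    """
    cfg = dict(variants=(1, 2, 3, 4, 5), schedules=tuple(ADAPTATION_SCHEDULES),
               seeds=(0, 1, 2, 3, 4), levels=(-24, -16, -8, 0, 8, 16, 24),
               probe_frames=12, dt=5.0, skew_magnitude=0.5,
               temperature_scale=0.1, model={})
    cfg.update(config or {})
    rows = []
    for variant in cfg["variants"]:
        arch = build_adaptation_model(variant, cfg["model"])
        shape = arch.layers["V1"].shape[:2]
        for schedule in cfg["schedules"]:
            exp_frames, gap_frames = ADAPTATION_SCHEDULES[schedule]
            for seed in cfg["seeds"]:
                pses = {}
                for skew_dir in ("up", "down"):
                    base = stim_mod.drifting_texture(
                        direction=0.0, speed=2.0, n_frames=exp_frames + 1,
                        shape=shape, seed=seed)
                    exposure = stim_mod.skew_transform(
                        base, skew_dir, cfg["skew_magnitude"])
                    rec = simulate(arch, exposure, dt=cfg["dt"],
                                   steps_per_frame=1, record_stride=10 ** 9)
                    syn_state = {k: v for k, v in
                                 rec.diagnostics["final_synapses"].items()}
                    if gap_frames:
                        # blank-screen rest: presynaptic drive is zero, so
                        # every efficacy relaxes toward 1 under Eq.-style
                        # production dynamics for the gap duration
                        gap_ms = gap_frames * cfg["dt"]
                        for conn in arch.connections:
                            if conn.synapse is None:
                                continue
                            syn = replace(conn.synapse,
                                          w=np.asarray(
                                              syn_state[conn.key()], float))
                            n_sub = max(1, int(math.ceil(
                                gap_ms / (syn.tau_w / 10.0))))
                            for _ in range(n_sub):
                                syn = adapt_weight(syn, 0.0, gap_ms / n_sub)
                            syn_state[conn.key()] = np.asarray(syn.w)
                    fracs = []
                    temp = cfg["temperature_scale"]
                    for lv in cfg["levels"]:
                        fracs.append(_probe_fraction_up(
                            arch, syn_state, lv, seed + 1000,
                            cfg["probe_frames"], cfg["dt"], temp))
                    fit = psychometric_pse(cfg["levels"], fracs, n_boot=0)
                    pses[skew_dir] = fit.pse
                shift = pses["up"] - pses["down"]
                rows.append(dict(experiment="adaptation", variant=variant,
                                 parameter=schedule, seed=seed,
                                 value=shift, pse_up=pses["up"],
                                 pse_down=pses["down"]))
    return dict(metrics=pd.DataFrame(rows),
                provenance=dict(experiment="adaptation", config=cfg))


# --------------------------------------------------------------------------
# Dispatcher
# --------------------------------------------------------------------------

EXPERIMENTS = {
    "kapadia": run_kapadia,
    "texture_sweep": run_texture_sweep,
    "aperture_bar": run_aperture_bar,
    "windmill": run_windmill,
    "ablation_motion": run_ablation_motion,
    "curveball": run_curveball,
    "rdk_hysteresis": run_rdk_hysteresis,
    "adaptation": run_adaptation,
}


def run_experiment(name: str, config: dict | None = None) -> dict:
    """Run a named experiment protocol; see :data:`EXPERIMENTS`."""
    if name not in EXPERIMENTS:
        raise ValueError(
            f"unknown experiment {name!r}; available: "
            + ", ".join(sorted(EXPERIMENTS)))
    return EXPERIMENTS[name](config)
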