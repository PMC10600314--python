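"""Synthetic stimulus generators.

Every experiment in this package runs on internally generated stimuli:
oriented-bar displays (contextual-modulation configurations), texture
figures defined by orientation contrast, translating bars, rotating
windmills, random-dot kinematograms, drifting Gabor patches with
independently moving envelope and carrier, skew-transformed sequences, and
frame-to-address-event conversion.  All generators are pure functions of
their parameters and an explicit integer seed; provenance sufficient for
bit-identical regeneration is attached to every stimulus.

Geometry defaults: 128 x 128 canvas, bar items about 9 x 2 px on a 16-px
texture grid, anti-aliased by 4x supersampled rendering.  Luminance is in
[0, 1] with bright items on a mid-gray or black background as noted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# Containers
# --------------------------------------------------------------------------

@dataclass
class Stimulus:
    """A luminance frame sequence: frames (T, H, W) in [0, 1]."""

    frames: np.ndarray
    frame_interval: float = 20.0            # ms
    provenance: dict = field(default_factory=dict)
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        f = np.asarray(self.frames, dtype=float)
        if f.ndim == 2:
            f = f[None]
        if f.ndim != 3:
            raise ValueError("frames must be (T, H, W)")
        if f.min() < -1e-9 or f.max() > 1.0 + 1e-9:
            raise ValueError("luminance must lie in [0, 1]")
        self.frames = np.clip(f, 0.0, 1.0)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


EVENT_DTYPE = np.dtype([("x", np.int32), ("y", np.int32),
                        ("t_ms", np.float64), ("polarity", np.int8)])


@dataclass
class EventStream:
    """Sparse address-event cloud: records (x, y, t_ms, polarity=+-1)."""

    events: np.ndarray
    shape: tuple[int, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = np.asarray(self.events)
        if ev.dtype != EVENT_DTYPE:
            raise ValueError("events must use the canonical event dtype")
        if len(ev) and np.any(np.diff(ev["t_ms"]) < 0):
            raise ValueError("events must be time-sorted")
        H, W = self.shape
        if len(ev) and (ev["x"].min() < 0 or ev["x"].max() >= W
                        or ev["y"].min() < 0 or ev["y"].max() >= H):
            raise ValueError("event coordinates outside sensor bounds")
        self.events = ev

    def __len__(self) -> int:
        return len(self.events)


# --------------------------------------------------------------------------
# Anti-aliased primitive rendering
# --------------------------------------------------------------------------

_SUPERSAMPLE = 4


def _render_bars(shape: tuple[int, int], bars, luminance: float = 1.0,
                 background: float = 0.0) -> np.ndarray:
    """Render oriented rectangles with 4x supersampled anti-aliasing.

    ``bars`` is an iterable of (cy, cx, orientation, length, width).
    Orientation is CCW from horizontal; rows grow downward.
    """
    s = _SUPERSAMPLE
    H, W = shape
    img = np.full((H * s, W * s), float(background))
    ys_full, xs_full = np.mgrid[0:H * s, 0:W * s]
    for (cy, cx, ori, length, width) in bars:
        half = (length / 2.0 + width / 2.0 + 2.0)
        y0 = max(0, int((cy - half) * s))
        y1 = min(H * s, int((cy + half) * s) + 1)
        x0 = max(0, int((cx - half) * s))
        x1 = min(W * s, int((cx + half) * s) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        ys = (ys_full[y0:y1, x0:x1] + 0.5) / s - cy
        xs = (xs_full[y0:y1, x0:x1] + 0.5) / s - cx
        u = xs * math.cos(ori) - ys * math.sin(ori)
        v = xs * math.sin(ori) + ys * math.cos(ori)
        inside = (np.abs(u) <= length / 2.0) & (np.abs(v) <= width / 2.0)
        patch = img[y0:y1, x0:x1]
        patch[inside] = luminance
    return img.reshape(H, s, W, s).mean(axis=(1, 3))


def _render_dots(shape: tuple[int, int], centers: np.ndarray,
                 radius: float, luminance: float = 1.0,
                 background: float = 0.0) -> np.ndarray:
    """Render filled anti-aliased dots; centers are (N, 2) rows of (y, x)."""
    s = _SUPERSAMPLE
    H, W = shape
    img = np.full((H * s, W * s), float(background))
    for (cy, cx) in centers:
        r = radius + 1.0
        y0 = max(0, int((cy - r) * s)); y1 = min(H * s, int((cy + r) * s) + 1)
        x0 = max(0, int((cx - r) * s)); x1 = min(W * s, int((cx + r) * s) + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        ys, xs = np.mgrid[y0:y1, x0:x1]
        d2 = ((ys + 0.5) / s - cy) ** 2 + ((xs + 0.5) / s - cx) ** 2
        patch = img[y0:y1, x0:x1]
        patch[d2 <= radius ** 2] = luminance
    return img.reshape(H, s, W, s).mean(axis=(1, 3))


# --------------------------------------------------------------------------
# Contextual-modulation bar displays
# --------------------------------------------------------------------------

def kapadia_display(config_id: int, shape: tuple[int, int] = (128, 128),
                    bar_length: float = 9.0, bar_width: float = 2.0,
                    orientation: float = math.pi / 2, gap: float = 6.0,
                    grid_spacing: float = 16.0, seed: int = 0) -> Stimulus:
    """Contextual bar displays for the contour-grouping experiment.

    Configurations: 1 single optimal center bar; 2/3 center bar plus one/two
    pairs of collinear flankers; 4 random texture without the center element;
    5 the same texture with the center bar added; 6/7 texture plus center bar
    plus one/two pairs of collinear flankers; 8 collinear flankers only
    (empty center).  Texture item positions/orientations are jittered under
    ``seed``; configs 4-7 share the identical texture so they differ only in
    the named center/flanker elements.
    """
    if config_id not in range(1, 9):
        raise ValueError("config_id must be in 1..8")
    H, W = shape
    cy, cx = H / 2.0, W / 2.0
    step = bar_length + gap
    # collinear positions along the orientation axis (rows grow downward)
    dy, dx = -math.sin(orientation), math.cos(orientation)

    def collinear(n_pairs):
        pos = []
        for i in range(1, n_pairs + 1):
            pos.append((cy - dy * i * step, cx - dx * i * step))
            pos.append((cy + dy * i * step, cx + dx * i * step))
        return pos

    rng = np.random.default_rng(seed)
    n_cells = int(H // grid_spacing)
    tex = []
    for gi in range(n_cells):
        for gj in range(n_cells):
            ty = (gi + 0.5) * grid_spacing + rng.uniform(-2, 2)
            tx = (gj + 0.5) * grid_spacing + rng.uniform(-2, 2)
            tori = rng.uniform(0, math.pi)
            tex.append((ty, tx, tori, bar_length, bar_width))

    center_bar = (cy, cx, orientation, bar_length, bar_width)
    exclusion = 1.2 * step

    def without_center(items, extra=()):
        keep = []
        protected = [(cy, cx)] + list(extra)
        for it in items:
            if all(math.hypot(it[0] - py, it[1] - px) > exclusion * 0.99
                   for (py, px) in protected):
                keep.append(it)
        return keep

    bars = []
    if config_id == 1:
        bars = [center_bar]
    elif config_id in (2, 3):
        n = 1 if config_id == 2 else 2
        bars = [center_bar] + [(py, px, orientation, bar_length, bar_width)
                               for (py, px) in collinear(n)]
    elif config_id == 8:
        bars = [(py, px, orientation, bar_length, bar_width)
                for (py, px) in collinear(2)]
    else:
        n_pairs = {4: 0, 5: 0, 6: 1, 7: 2}[config_id]
        flank = collinear(n_pairs)
        bars = without_center(tex, extra=flank)
        if config_id != 4:
            bars = bars + [center_bar]
        bars += [(py, px, orientation, bar_length, bar_width)
                 for (py, px) in flank]
    frame = _render_bars(shape, bars)
    return Stimulus(
        frames=frame[None],
        provenance=dict(generator="kapadia_display", config_id=config_id,
                        shape=shape, bar_length=bar_length,
                        bar_width=bar_width, orientation=orientation,
                        gap=gap, grid_spacing=grid_spacing, seed=seed),
        ground_truth=dict(center=(cy, cx), orientation=orientation))


# --------------------------------------------------------------------------
# Texture figure displays
# --------------------------------------------------------------------------

def texture_figure(oc: float, bn: float,
                   figure_rect: tuple[int, int, int, int] = (2, 2, 4, 3),
                   grid: tuple[int, int] = (8, 8),
                   shape: tuple[int, int] = (128, 128),
                   bar_length: float = 9.0, bar_width: float = 2.0,
                   base_orientation: float = 0.0,
                   jitter_px: float = 2.0, jitter_deg: float = 3.0,
                   seed: int = 0) -> Stimulus:
    """Orientation-defined texture figure on a jittered item grid.

    ``oc`` is the orientation contrast (degrees) between the figure's and
    the background's base orientation; ``bn`` is the background-noise
    amplitude: every item's orientation is independently jittered by a
    uniform draw from [-bn, +bn] degrees, so orientation changes between
    neighboring bars within a homogeneous region are on the order of bn
    while the coherent oc offset distinguishes the regions.  ``figure_rect``
    is (row0, col0, n_rows, n_cols) in item-grid cells.  The pixel mask of
    the figure cells is stored as ground truth.
    """
    if not (0 <= oc <= 90) or bn < 0:
        raise ValueError("need 0 <= oc <= 90 and bn >= 0")
    gr, gc = grid
    r0, c0, nr, nc = figure_rect
    if r0 < 0 or c0 < 0 or r0 + nr > gr or c0 + nc > gc:
        raise ValueError("figure rectangle outside the item grid")
    H, W = shape
    sy, sx = H / gr, W / gc
    rng = np.random.default_rng(seed)
    bars = []
    fig_mask = np.zeros((H, W), dtype=bool)
    item_grid = np.zeros((gr, gc), dtype=bool)
    for i in range(gr):
        for j in range(gc):
            ori = math.radians(base_orientation
                               + rng.uniform(-bn, bn))
            in_fig = (r0 <= i < r0 + nr) and (c0 <= j < c0 + nc)
            if in_fig:
                ori += math.radians(oc)
                item_grid[i, j] = True
                y0, y1 = int(i * sy), int((i + 1) * sy)
                x0, x1 = int(j * sx), int((j + 1) * sx)
                fig_mask[y0:y1, x0:x1] = True
            ori += math.radians(rng.uniform(-jitter_deg, jitter_deg))
            cy = (i + 0.5) * sy + rng.uniform(-jitter_px, jitter_px)
            cx = (j + 0.5) * sx + rng.uniform(-jitter_px, jitter_px)
            bars.append((cy, cx, ori % math.pi, bar_length, bar_width))
    frame = _render_bars(shape, bars)
    return Stimulus(
        frames=frame[None],
        provenance=dict(generator="texture_figure", oc=oc, bn=bn,
                        figure_rect=figure_rect, grid=grid, shape=shape,
                        bar_length=bar_length, bar_width=bar_width,
                        base_orientation=base_orientation,
                        jitter_px=jitter_px, jitter_deg=jitter_deg,
                        seed=seed),
        ground_truth=dict(figure_mask=fig_mask, item_grid=item_grid,
                          cell_size=(sy, sx)))


# --------------------------------------------------------------------------
# Motion stimuli
# --------------------------------------------------------------------------

def translating_bar(orientation: float = math.pi / 2,
                    direction: float = 0.0, speed: float = 2.0,
                    length: float = 31.0, width: float = 3.0,
                    n_frames: int = 20,
                    shape: tuple[int, int] = (96, 96)) -> Stimulus:
    """A rigidly translating bar at constant velocity.

    ``direction`` is the motion direction (CCW from rightward); the
    ground-truth velocity (vx, vy) in px/frame (vy downward in image rows)
    and the per-frame bar center are stored.
    """
    H, W = shape
    vx = speed * math.cos(direction)
    vy = -speed * math.sin(direction)
    travel = speed * (n_frames - 1)
    cy0 = H / 2.0 - vy * (n_frames - 1) / 2.0
    cx0 = W / 2.0 - vx * (n_frames - 1) / 2.0
    margin = length / 2.0 + width + 2.0
    for t in (0, n_frames - 1):
        cy, cx = cy0 + vy * t, cx0 + vx * t
        if not (margin <= cy <= H - margin and margin <= cx <= W - margin):
            raise ValueError("bar leaves the frame over its trajectory")
    frames = np.empty((n_frames, H, W))
    centers = []
    for t in range(n_frames):
        cy, cx = cy0 + vy * t, cx0 + vx * t
        frames[t] = _render_bars(shape, [(cy, cx, orientation, length, width)])
        centers.append((cy, cx))
    return Stimulus(
        frames=frames,
        provenance=dict(generator="translating_bar", orientation=orientation,
                        direction=direction, speed=speed, length=length,
                        width=width, n_frames=n_frames, shape=shape),
        ground_truth=dict(velocity=(vx, vy), centers=np.asarray(centers),
                          orientation=orientation, travel=travel))


def windmill(n_arms: int = 4, angular_speed: float = 0.05,
             radius: float = 40.0, n_frames: int = 16,
             shape: tuple[int, int] = (96, 96),
             sharpness: float = 8.0) -> Stimulus:
    """A rotating windmill (spoke) pattern.

    ``angular_speed`` is in rad/frame (positive = counter-clockwise).  The
    ground-truth tangential speed at radius rho is |angular_speed| * rho,
    stored as a per-pixel map together with the radius map.
    """
    if angular_speed == 0:
        raise ValueError("angular_speed must be non-zero")
    H, W = shape
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ys, xs = np.mgrid[0:H, 0:W]
    rho = np.hypot(xs - cx, ys - cy)
    phi = np.arctan2(-(ys - cy), xs - cx)
    aperture = 0.5 * (1.0 + np.tanh((radius - rho)))
    frames = np.empty((n_frames, H, W))
    for t in range(n_frames):
        spokes = 0.5 * (1.0 + np.tanh(
            sharpness * np.sin(n_arms * (phi - angular_speed * t))))
        frames[t] = spokes * aperture
    speed_map = np.abs(angular_speed) * rho
    return Stimulus(
        frames=frames,
        provenance=dict(generator="windmill", n_arms=n_arms,
                        angular_speed=angular_speed, radius=radius,
                        n_frames=n_frames, shape=shape, sharpness=sharpness),
        ground_truth=dict(speed_map=speed_map, radius_map=rho,
                          center=(cy, cx), angular_speed=angular_speed))


def rdk_sequence(n_frames: int = 60, n_dots: int = 60,
                 initial_direction: float = 0.0, dot_speed: float = 2.0,
                 dot_radius: float = 1.5,
                 shape: tuple[int, int] = (128, 128),
                 seed: int = 0) -> Stimulus:
    """Random-dot kinematogram with a one-flip-per-frame reversal schedule.

    All dots start moving in ``initial_direction``; before each motion step
    exactly one not-yet-flipped dot (drawn under ``seed``) reverses its
    direction, so motion step t (t = 1..n_frames) has t/n_dots of the dots
    reversed: 50% at step 30 and 100% at the final step for the default
    60/60 configuration.  The stimulus holds n_frames+1 rendered images
    (= n_frames motion steps); dots wrap around at the borders so the dot
    count is conserved.  The reversed fraction per motion step is stored.
    """
    if n_dots > n_frames:
        raise ValueError("one-flip-per-frame schedule needs n_dots <= n_frames")
    H, W = shape
    rng = np.random.default_rng(seed)
    pos = np.column_stack([rng.uniform(0, H, n_dots),
                           rng.uniform(0, W, n_dots)])
    flip_order = rng.permutation(n_dots)
    # spread the n_dots flips evenly over the n_frames motion steps
    flip_steps = np.linspace(1, n_frames, n_dots).round().astype(int)
    vx = dot_speed * math.cos(initial_direction)
    vy = -dot_speed * math.sin(initial_direction)
    vel = np.tile([vy, vx], (n_dots, 1))
    flipped = np.zeros(n_dots, dtype=bool)
    frames = np.empty((n_frames + 1, H, W))
    frames[0] = _render_dots(shape, pos, dot_radius)
    reversed_fraction = np.empty(n_frames + 1)
    reversed_fraction[0] = 0.0
    k = 0
    for t in range(1, n_frames + 1):
        while k < n_dots and flip_steps[k] <= t:
            d = flip_order[k]
            assert not flipped[d], "duplicate flip"
            vel[d] *= -1.0
            flipped[d] = True
            k += 1
        pos = pos + vel
        pos[:, 0] %= H
        pos[:, 1] %= W
        frames[t] = _render_dots(shape, pos, dot_radius)
        reversed_fraction[t] = flipped.mean()
    return Stimulus(
        frames=frames,
        provenance=dict(generator="rdk_sequence", n_frames=n_frames,
                        n_dots=n_dots, initial_direction=initial_direction,
                        dot_speed=dot_speed, dot_radius=dot_radius,
                        shape=shape, seed=seed),
        ground_truth=dict(reversed_fraction=reversed_fraction,
                          initial_direction=initial_direction,
                          dot_speed=dot_speed))


def gabor_curveball(envelope_velocity: tuple[float, float] = (0.0, -1.5),
                    carrier_drift_velocity: tuple[float, float] = (1.5, 0.0),
                    sigma: float = 10.0, wavelength: float = 8.0,
                    n_frames: int = 24,
                    shape: tuple[int, int] = (96, 96)) -> Stimulus:
    """Drifting sinusoidal carrier inside an independently moving envelope.

    Velocities are (vx, vy) in px/frame with vy downward; the default moves
    the Gaussian envelope vertically while the carrier wave travels
    horizontally at the same speed.  Both component velocities are stored as
    ground truth.
    """
    H, W = shape
    evx, evy = envelope_velocity
    cvx, cvy = carrier_drift_velocity
    cy0 = H / 2.0 - evy * (n_frames - 1) / 2.0
    cx0 = W / 2.0 - evx * (n_frames - 1) / 2.0
    for t in (0, n_frames - 1):
        cy, cx = cy0 + evy * t, cx0 + evx * t
        if not (2 * sigma <= cy <= H - 2 * sigma
                and 2 * sigma <= cx <= W - 2 * sigma):
            raise ValueError("envelope leaves the frame")
    ys, xs = np.mgrid[0:H, 0:W].astype(float)
    frames = np.empty((n_frames, H, W))
    centers = []
    for t in range(n_frames):
        cy, cx = cy0 + evy * t, cx0 + evx * t
        env = np.exp(-0.5 * (((ys - cy) / sigma) ** 2
                             + ((xs - cx) / sigma) ** 2))
        phase = 2.0 * math.pi * ((xs - cvx * t) * 1.0
                                 + (ys - cvy * t) * 0.0) / wavelength
        frames[t] = 0.5 + 0.5 * env * np.cos(phase)
        centers.append((cy, cx))
    return Stimulus(
        frames=frames,
        provenance=dict(generator="gabor_curveball",
                        envelope_velocity=envelope_velocity,
                        carrier_drift_velocity=carrier_drift_velocity,
                        sigma=sigma, wavelength=wavelength,
                        n_frames=n_frames, shape=shape),
        ground_truth=dict(envelope_velocity=envelope_velocity,
                          carrier_drift_velocity=carrier_drift_velocity,
                          centers=np.asarray(centers)))


def drifting_texture(direction: float, speed: float = 2.0,
                     n_frames: int = 20, shape: tuple[int, int] = (48, 48),
                     smooth: float = 1.5, seed: int = 0) -> Stimulus:
    """Band-limited random texture rigidly drifting at constant velocity.

    Used as the controlled-statistics exposure stimulus of the adaptation
    experiments (a synthetic stand-in emulating the direction statistics of
    natural footage).
    """
    H, W = shape
    rng = np.random.default_rng(seed)
    big = ndimage.gaussian_filter(rng.standard_normal((2 * H, 2 * W)), smooth,
                                  mode="wrap")
    big = (big - big.min()) / (big.max() - big.min() + 1e-12)
    vx = speed * math.cos(direction)
    vy = -speed * math.sin(direction)
    frames = np.empty((n_frames, H, W))
    for t in range(n_frames):
        shifted = ndimage.shift(big, (vy * t, vx * t), order=1, mode="grid-wrap")
        frames[t] = shifted[:H, :W]
    return Stimulus(
        frames=frames,
        provenance=dict(generator="drifting_texture", direction=direction,
                        speed=speed, n_frames=n_frames, shape=shape,
                        smooth=smooth, seed=seed),
        ground_truth=dict(velocity=(vx, vy)))


def skew_transform(stim: Stimulus, direction: str, magnitude: float) -> Stimulus:
    """Vertical shear of every frame: y' = y -/+ magnitude * (x - cx).

    ``direction`` "up" shears columns right of center upward (and "down"
    downward); magnitude 0 is the identity.  The transform is recorded in the
    provenance.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    if magnitude == 0.0:
        out = Stimulus(stim.frames.copy(), stim.frame_interval,
                       dict(stim.provenance), dict(stim.ground_truth))
        out.provenance["skew"] = (direction, magnitude)
        return out
    # a feature at column x appears at row y -/+ magnitude*(x - cx); with
    # rows growing downward, "up" needs the positive matrix entry so that
    # rightward-moving structure acquires an upward apparent motion
    sign = 1.0 if direction == "up" else -1.0
    H, W = stim.shape
    cx = (W - 1) / 2.0
    matrix = np.array([[1.0, sign * magnitude], [0.0, 1.0]])
    offset = np.array([-sign * magnitude * cx, 0.0])
    frames = np.empty_like(stim.frames)
    for t in range(stim.n_frames):
        frames[t] = ndimage.affine_transform(
            stim.frames[t], matrix, offset=offset, order=1, mode="reflect")
    return Stimulus(np.clip(frames, 0, 1), stim.frame_interval,
                    {**stim.provenance, "skew": (direction, magnitude)},
                    dict(stim.ground_truth))


# --------------------------------------------------------------------------
# Frame -> event conversion
# --------------------------------------------------------------------------

def frames_to_events(stim: Stimulus, log_threshold: float = 0.15,
                     luminance_floor: float = 1e-3) -> EventStream:
    """Emulate a dynamic vision sensor on a frame sequence.

    Per pixel, an ON (OFF) event is emitted each time the cumulative
    log-intensity change since that pixel's last event exceeds
    +log_threshold (-log_threshold); multiple crossings within one frame
    interval emit multiple events with linearly interpolated timestamps.
    Luminance is floored at ``luminance_floor`` before the log.
    """
    if log_threshold <= 0:
        raise ValueError("log_threshold must be positive")
    logf = np.log(np.maximum(stim.frames, luminance_floor))
    ref = logf[0].copy()
    xs_all, ys_all, ts_all, ps_all = [], [], [], []
    for t in range(1, stim.n_frames):
        delta = logf[t] - ref
        n_cross = np.floor(np.abs(delta) / log_threshold).astype(int)
        yy, xx = np.nonzero(n_cross)
        for (py, px) in zip(yy, xx):
            n = n_cross[py, px]
            pol = 1 if delta[py, px] > 0 else -1
            step = pol * log_threshold
            frac_scale = abs(delta[py, px])
            for k in range(1, n + 1):
                frac = (k * log_threshold) / frac_scale
                ts_all.append((t - 1 + frac) * stim.frame_interval)
                xs_all.append(px)
                ys_all.append(py)
                ps_all.append(pol)
            ref[py, px] += n * step
    ev = np.empty(len(ts_all), dtype=EVENT_DTYPE)
    if len(ts_all):
        order = np.lexsort((xs_all, ys_all, ts_all))
        ev["x"] = np.asarray(xs_all)[order]
        ev["y"] = np.asarray(ys_all)[order]
        ev["t_ms"] = np.asarray(ts_all)[order]
        ev["polarity"] = np.asarray(ps_all)[order]
    return EventStream(
        events=ev, shape=stim.shape,
        provenance={**stim.provenance, "event_log_threshold": log_threshold,
                    "luminance_floor": luminance_floor})
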