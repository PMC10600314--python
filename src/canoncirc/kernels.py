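"""Filter banks and connection kernels.

Builds the weighted connection fields used throughout the circuit models:
oriented contrast filters (Gabor-type, even or odd symmetric), long-range
"bipole" grouping fields linking collinear like-oriented items, separable
space-feature pool kernels for divisive normalization, orientation-contrast
filters with juxtaposed excitatory/inhibitory subfields, and
correlation-based spatiotemporal motion detectors operating on frame
sequences or on sparse address-event streams.

Conventions (documented also in the array sidecar metadata): row 0 is the
top of the image, direction/orientation angles are measured counter-clockwise
with direction channel 0 pointing rightward, orientation channels sample
[0, pi) uniformly and are circular modulo pi, direction channels sample
[0, 2*pi) and are circular modulo 2*pi.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal


# --------------------------------------------------------------------------
# Kernel container
# --------------------------------------------------------------------------

@dataclass
class Kernel:
    """A discrete connection kernel over (row-offset, col-offset[, feature-offset]).

    ``weights`` is either a 2-D spatial array, or a 3-D array whose last axis
    is the feature-offset axis.  When ``separable_feature`` is given,
    ``weights`` holds only the spatial factor and the full kernel is the
    outer product with the 1-D feature profile (this keeps pool kernels cheap
    to apply).  Spatial support must be odd so the center tap is well defined.
    """

    weights: np.ndarray
    feature_wraparound: bool = True
    separable_feature: np.ndarray | None = None
    # fast-path marker: when set, the spatial factor is a truncated Gaussian
    # and apply() delegates to scipy's separable Gaussian filter
    gaussian_sigma: float | None = None
    gaussian_truncate: float = 2.5

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim not in (2, 3):
            raise ValueError("kernel weights must be 2-D or 3-D")
        if w.shape[0] % 2 == 0 or w.shape[1] % 2 == 0:
            raise ValueError("kernel spatial support must be odd")
        if not np.all(np.isfinite(w)):
            raise ValueError("kernel weights must be finite")
        self.weights = w
        if self.separable_feature is not None:
            self.separable_feature = np.asarray(self.separable_feature, float)
            if self.weights.ndim != 2:
                raise ValueError("separable kernels need 2-D spatial weights")

    @property
    def center(self) -> tuple[int, int]:
        return (self.weights.shape[0] // 2, self.weights.shape[1] // 2)

    def full_weights(self, n_features: int | None = None) -> np.ndarray:
        """Dense (ky, kx[, kf]) weight array, for inspection and export."""
        if self.separable_feature is None:
            return self.weights
        return self.weights[:, :, None] * self.separable_feature[None, None, :]

    # -- application ------------------------------------------------------

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Correlate a (H, W, C) activity array with this kernel.

        Boundary rule: reflective padding in space; the feature axis is
        circular when ``feature_wraparound`` is set, else zero-padded.
        """
        x = np.asarray(values, dtype=float)
        if x.ndim != 3:
            raise ValueError("expected (H, W, C) activity array")
        if self.weights.ndim == 2:
            out = np.empty_like(x)
            for c in range(x.shape[2]):
                out[:, :, c] = self._spatial_correlate(x[:, :, c])
            if self.separable_feature is not None:
                out = _feature_correlate(out, self.separable_feature,
                                         self.feature_wraparound)
            return out
        # dense 3-D kernel: pad manually (reflect space, wrap/zero feature)
        ky, kx, kf = self.weights.shape
        py, px, pf = ky // 2, kx // 2, kf // 2
        fmode = "wrap" if self.feature_wraparound else "constant"
        xp = np.pad(x, ((py, py), (px, px), (0, 0)), mode="reflect")
        xp = np.pad(xp, ((0, 0), (0, 0), (pf, pf)), mode=fmode)
        out = ndimage.correlate(xp, self.weights, mode="constant")
        return out[py:-py if py else None, px:-px if px else None,
                   pf:-pf if pf else None]

    def _spatial_correlate(self, img: np.ndarray) -> np.ndarray:
        """2-D spatial correlation with reflective boundaries.

        Large kernels go through an FFT path; kernels flagged as Gaussian use
        scipy's separable Gaussian filter (numerically equivalent to the
        dense truncated-Gaussian weights up to the truncation radius).
        """
        if self.gaussian_sigma is not None:
            return ndimage.gaussian_filter(
                img, self.gaussian_sigma, mode="reflect",
                truncate=self.gaussian_truncate)
        w = self.weights
        if w.size <= 169:
            return ndimage.correlate(img, w, mode="reflect")
        py, px = w.shape[0] // 2, w.shape[1] // 2
        padded = np.pad(img, ((py, py), (px, px)), mode="reflect")
        return signal.fftconvolve(padded, w[::-1, ::-1], mode="valid")


def gaussian_kernel(sigma: float, n_features: int | None = None,
                    feature_sigma: float | None = None,
                    truncate: float = 2.5) -> Kernel:
    """Unit-sum spatial Gaussian (optionally x circular feature Gaussian)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    half = max(1, int(truncate * sigma + 0.5))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    w = np.exp(-0.5 * (ys ** 2 + xs ** 2) / sigma ** 2)
    w /= w.sum()
    sep = None
    if n_features is not None and feature_sigma is not None:
        sep = _wrapped_gaussian(n_features, feature_sigma)
        sep /= sep.sum()
    return Kernel(weights=w, separable_feature=sep, gaussian_sigma=sigma,
                  gaussian_truncate=truncate)


def identity_kernel() -> Kernel:
    """1x1 topographic (identity) connection kernel."""
    return Kernel(weights=np.ones((1, 1)))


def uniform_feature_kernel(n_features: int) -> Kernel:
    """Spatially punctate kernel averaging uniformly over all channels."""
    return Kernel(weights=np.ones((1, 1)),
                  separable_feature=np.full(n_features, 1.0 / n_features))


def _feature_correlate(x: np.ndarray, profile: np.ndarray,
                       wrap: bool) -> np.ndarray:
    """1-D correlation along the feature (last) axis of a (H, W, C) array.

    For the circular (wraparound) case this is a multiplication with the
    circulant matrix of the profile, which is much cheaper than padding.
    """
    k = len(profile)
    p = k // 2
    C = x.shape[2]
    if wrap:
        # circulant mixing matrix M[c_out, c_in]
        mat = np.zeros((C, C))
        for j, wj in enumerate(profile):
            if wj != 0.0:
                mat += wj * np.eye(C, k=j - p)
                if j - p != 0:
                    mat += wj * np.eye(C, k=(j - p) - np.sign(j - p) * C)
        return x @ mat.T
    xp = np.pad(x, ((0, 0), (0, 0), (p, p)), mode="constant")
    out = np.zeros_like(x)
    for j, wj in enumerate(profile):
        if wj != 0.0:
            out += wj * xp[:, :, j:j + C]
    return out


def _wrapped_gaussian(n: int, sigma: float, periods: int = 5) -> np.ndarray:
    """Circular Gaussian profile over n channels, centered on offset 0."""
    off = np.arange(n) - n // 2
    prof = np.zeros(n)
    for k in range(-periods, periods + 1):
        prof += np.exp(-0.5 * ((off + k * n) / sigma) ** 2)
    return prof


# --------------------------------------------------------------------------
# Oriented contrast filters
# --------------------------------------------------------------------------

def oriented_filter(orientation: float, scale: float,
                    symmetry: str = "even") -> Kernel:
    """Gabor-style oriented contrast filter.

    ``orientation`` is the preferred bar/edge orientation in radians
    (counter-clockwise from horizontal).  ``scale`` sets the envelope size in
    pixels.  Even-symmetric filters (cosine phase) have their DC response
    removed so a uniform field yields exactly zero.
    """
    if scale < 1.0:
        raise ValueError("oriented_filter scale must be at least 1 px")
    if symmetry not in ("even", "odd"):
        raise ValueError(f"unknown symmetry {symmetry!r}")
    sigma_u = 1.4 * scale      # along the orientation axis (elongated)
    sigma_v = 0.55 * scale     # across the orientation axis
    wavelength = 2.4 * scale
    half = int(math.ceil(3.0 * sigma_u))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    # image rows grow downward; flip y so angles are counter-clockwise
    u = xs * math.cos(orientation) + (-ys) * math.sin(orientation)
    v = -xs * math.sin(orientation) + (-ys) * math.cos(orientation)
    env = np.exp(-0.5 * ((u / sigma_u) ** 2 + (v / sigma_v) ** 2))
    phase = 2.0 * math.pi * v / wavelength
    if symmetry == "even":
        w = env * np.cos(phase)
        w -= env * (w.sum() / env.sum())   # zero DC under the envelope
    else:
        w = env * np.sin(phase)
    w /= np.abs(w).sum()
    return Kernel(weights=w, feature_wraparound=True)


def oriented_filter_bank(n_orientations: int, scale: float,
                         symmetry: str = "even") -> list[Kernel]:
    """Bank of oriented filters uniformly sampling [0, pi)."""
    return [oriented_filter(i * math.pi / n_orientations, scale, symmetry)
            for i in range(n_orientations)]


def apply_filter_bank(image: np.ndarray, bank: list[Kernel],
                      rectify: bool = True) -> np.ndarray:
    """Filter a 2-D image with every kernel in a bank -> (H, W, C) responses."""
    img = np.asarray(image, dtype=float)
    out = np.stack(
        [ndimage.correlate(img, k.weights, mode="reflect") for k in bank],
        axis=-1)
    if rectify:
        np.abs(out, out=out)
    return out


# --------------------------------------------------------------------------
# Long-range grouping (bipole) kernel
# --------------------------------------------------------------------------

def bipole_kernel(orientation: float, reach: float,
                  angular_tolerance: float = math.pi / 8,
                  n_features: int | None = None,
                  feature_sigma: float = 0.8,
                  inner_radius: float = 0.0) -> Kernel:
    """Bilateral "figure-eight" long-range integration field.

    Two co-axial lobes extend along the preferred orientation axis; weights
    decay with radial distance (Gaussian, sigma = reach/2) and with the
    angular deviation of the connecting line from the orientation axis.  The
    center tap is zero (no self-support), and ``inner_radius`` optionally
    blanks a whole central disk so the long-range field only collects
    support from beyond the classical receptive field.  If ``n_features``
    is given the
    kernel carries a circular feature profile concentrating support on
    like-oriented channels.
    """
    if reach <= 0:
        raise ValueError("bipole reach must be positive")
    if angular_tolerance >= math.pi / 2:
        raise ValueError(
            "angular_tolerance must be < pi/2 to retain orientation selectivity")
    half = int(math.ceil(reach))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    dist = np.hypot(xs, ys)
    pos_angle = np.arctan2(-ys, xs)       # CCW angle of the offset vector
    # deviation from the orientation axis, folded for the bilateral lobes
    dev = np.angle(np.exp(2j * (pos_angle - orientation))) / 2.0
    w = (np.exp(-0.5 * (dist / (reach / 2.0)) ** 2)
         * np.exp(-0.5 * (dev / angular_tolerance) ** 2))
    w[dist > reach] = 0.0
    w[dist < inner_radius] = 0.0
    w[half, half] = 0.0
    w /= w.sum()
    sep = None
    if n_features is not None:
        sep = _wrapped_gaussian(n_features, feature_sigma)
        sep /= sep.sum()
    return Kernel(weights=w, feature_wraparound=True, separable_feature=sep)


# --------------------------------------------------------------------------
# Pool kernel (divisive-normalization neighborhood)
# --------------------------------------------------------------------------

def pool_kernel(spatial_sigma: float, feature_sigma: float,
                n_features: int, truncate: float = 2.5) -> Kernel:
    """Separable Gaussian pool over space x circular feature axis, unit sum."""
    if spatial_sigma <= 0 or feature_sigma <= 0:
        raise ValueError("pool sigmas must be positive")
    half = max(1, int(math.ceil(truncate * spatial_sigma)))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    spat = np.exp(-0.5 * (ys ** 2 + xs ** 2) / spatial_sigma ** 2)
    feat = _wrapped_gaussian(n_features, feature_sigma)
    feat /= feat.sum()
    spat /= spat.sum()
    return Kernel(weights=spat, feature_wraparound=True,
                  separable_feature=feat, gaussian_sigma=spatial_sigma,
                  gaussian_truncate=truncate)


# --------------------------------------------------------------------------
# Orientation-contrast (texture boundary) filter
# --------------------------------------------------------------------------

def orientation_contrast_filter(orientation_pair: tuple[float, float],
                                scale: float,
                                n_features: int = 8,
                                axis: float | None = None,
                                tuning_sigma: float = 0.8) -> Kernel:
    """Paired excitatory/inhibitory subfields selective to orientation change.

    The excitatory subfield (displaced by +scale/2 along ``axis``) samples
    activity tuned to ``orientation_pair[0]``; the inhibitory subfield
    (displaced by -scale/2) samples ``orientation_pair[1]``.  The signed
    response is zero on a uniformly oriented field when both tunings match,
    and largest when the dominant orientation changes across the subfield
    boundary.  ``axis`` is the displacement direction of the subfields
    (default: normal to the first preferred orientation).
    """
    if scale <= 0:
        raise ValueError("orientation_contrast_filter scale must be positive")
    th1, th2 = orientation_pair
    if axis is None:
        axis = th1 + math.pi / 2.0
    offset = scale / 2.0
    sigma = scale / 2.5
    half = int(math.ceil(offset + 2.0 * sigma))
    ys, xs = np.mgrid[-half:half + 1, -half:half + 1]
    ex = offset * math.cos(axis)
    ey = -offset * math.sin(axis)
    g_pos = np.exp(-0.5 * (((xs - ex) ** 2 + (ys - ey) ** 2) / sigma ** 2))
    g_neg = np.exp(-0.5 * (((xs + ex) ** 2 + (ys + ey) ** 2) / sigma ** 2))
    g_pos /= g_pos.sum()
    g_neg /= g_neg.sum()

    def tuning(theta: float) -> np.ndarray:
        centers = np.arange(n_features) * math.pi / n_features
        d = np.angle(np.exp(2j * (centers - theta))) / 2.0
        t = np.exp(-0.5 * (d / (tuning_sigma * math.pi / n_features)) ** 2)
        return t / t.sum()

    w = (g_pos[:, :, None] * tuning(th1)[None, None, :]
         - g_neg[:, :, None] * tuning(th2)[None, None, :])
    return Kernel(weights=w, feature_wraparound=True)


# --------------------------------------------------------------------------
# Spatiotemporal motion detectors
# --------------------------------------------------------------------------

@dataclass
class MotionDetectorBank:
    """Bank of correlation-based (Reichardt-type) motion detectors.

    Channels are laid out direction-major: channel index = d * n_speeds + s,
    direction d sampling [0, 2*pi) counter-clockwise with d=0 rightward.
    """

    n_directions: int = 8
    speeds: tuple[float, ...] = (1.0, 2.0, 3.0)
    spatial_scale: float = 1.5
    temporal_window: int = 2
    mode: str = "frame_correlation"

    def __post_init__(self) -> None:
        self.speeds = tuple(float(s) for s in self.speeds)
        if any(s <= 0 for s in self.speeds):
            raise ValueError("speeds must be strictly positive")
        if any(b <= a for a, b in zip(self.speeds, self.speeds[1:])):
            raise ValueError("speeds must be strictly increasing")
        if self.n_directions < 2 or self.n_directions % 2:
            raise ValueError("n_directions must be even and >= 2")

    @property
    def n_channels(self) -> int:
        return self.n_directions * len(self.speeds)

    def channel_velocity(self, channel: int) -> tuple[float, float]:
        """(vx, vy) in px/frame for a channel; vy grows downward (image rows)."""
        d, s = divmod(channel, len(self.speeds))
        ang = 2.0 * math.pi * d / self.n_directions
        sp = self.speeds[s]
        return (sp * math.cos(ang), -sp * math.sin(ang))

    def directions(self) -> np.ndarray:
        return 2.0 * math.pi * np.arange(self.n_directions) / self.n_directions


def _bandpass(frame: np.ndarray, scale: float) -> np.ndarray:
    """Zero-mean contrast signal: image minus its local (Gaussian) mean."""
    f = np.asarray(frame, dtype=float)
    return f - ndimage.gaussian_filter(f, 2.0 * scale, mode="reflect")


def _shift_exact(img: np.ndarray, dy: float, dx: float) -> np.ndarray:
    """Subpixel translation via Fourier shift.

    Amplitude-preserving for fractional displacements, unlike bilinear
    interpolation which would low-pass diagonal shifts more than
    axis-aligned ones and so bias the detector bank across directions.
    """
    return np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(img),
                                              (dy, dx))).real


def motion_detect_frames(frames: np.ndarray,
                         bank: MotionDetectorBank) -> np.ndarray:
    """Correlation-based motion likelihoods for a frame sequence.

    For each frame pair (t-1, t) and each (direction, speed) channel the
    detector correlates the current contrast signal with the previous one
    shifted along the channel's preferred displacement (delay-and-multiply)
    and subtracts the time-mirrored correlation (the elaborated-Reichardt
    opponent stage), smooths spatially, rectifies, and finally subtracts the
    opposite-direction channel.  Returns (T-1, H, W, C) non-negative
    likelihoods; static inputs cancel exactly in the time-opponent stage.
    """
    f = np.asarray(frames, dtype=float)
    if f.ndim != 3 or f.shape[0] < 2:
        raise ValueError("need a (T, H, W) stack with at least 2 frames")
    if f.shape[0] < bank.temporal_window:
        raise ValueError("fewer frames than the bank's temporal window")
    n_sp = len(bank.speeds)
    T = f.shape[0]
    out = np.zeros((T - 1, f.shape[1], f.shape[2], bank.n_channels))
    prev = _bandpass(f[0], bank.spatial_scale)
    for t in range(1, T):
        cur = _bandpass(f[t], bank.spatial_scale)
        half_resp = np.empty((f.shape[1], f.shape[2], bank.n_channels))
        for c in range(bank.n_channels):
            vx, vy = bank.channel_velocity(c)
            raw = cur * _shift_exact(prev, vy, vx) \
                - prev * _shift_exact(cur, vy, vx)
            half_resp[:, :, c] = ndimage.gaussian_filter(
                raw, bank.spatial_scale, mode="reflect")
        # opponent subtraction: channel (d, s) minus (d + D/2, s)
        opp = np.roll(half_resp.reshape(half_resp.shape[:2]
                                        + (bank.n_directions, n_sp)),
                      bank.n_directions // 2, axis=2)
        resp = half_resp - opp.reshape(half_resp.shape)
        np.maximum(resp, 0.0, out=resp)
        out[t - 1] = resp
        prev = cur
    return out


def motion_detect_events(events, bank: MotionDetectorBank,
                         bin_ms: float = 10.0,
                         age_tau_ms: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Event-driven motion detection on an address-event stream.

    Events are accumulated per polarity into exponentially age-weighted time
    surfaces updated on a fixed ``bin_ms`` grid.  Detector responses are the
    same delay-and-multiply correlations as in :func:`motion_detect_frames`
    but evaluated *only at pixels that carried an event in the current bin*
    (elsewhere the output is exactly zero), honoring the sparse event
    representation.  ON and OFF polarities are correlated in separate
    channels and then summed.

    Returns ``(responses, bin_times)`` with responses of shape
    (n_bins-1, H, W, C).
    """
    ev = events.events if hasattr(events, "events") else events
    x = np.asarray(ev["x"], dtype=int)
    y = np.asarray(ev["y"], dtype=int)
    t = np.asarray(ev["t_ms"], dtype=float)
    pol = np.asarray(ev["polarity"], dtype=int)
    if np.any(np.diff(t) < 0):
        raise ValueError("event stream must be time-sorted")
    shape = events.shape if hasattr(events, "shape") else (
        int(y.max()) + 1 if len(y) else 1, int(x.max()) + 1 if len(x) else 1)
    H, W = shape
    if len(t) == 0:
        return np.zeros((0, H, W, bank.n_channels)), np.zeros(0)
    t0, t1 = t.min(), t.max()
    n_bins = max(2, int(math.ceil((t1 - t0) / bin_ms)) + 1)
    edges = t0 + bin_ms * np.arange(n_bins + 1)
    decay = math.exp(-bin_ms / age_tau_ms)
    surf = {1: np.zeros((H, W)), -1: np.zeros((H, W))}
    prev_surf = None
    out = []
    times = []
    idx = np.searchsorted(t, edges)
    for b in range(n_bins):
        sel = slice(idx[b], idx[b + 1])
        cur_mask = np.zeros((H, W), dtype=bool)
        cur_mask[y[sel], x[sel]] = True
        new = {1: np.zeros((H, W)), -1: np.zeros((H, W))}
        for p in (1, -1):
            psel = pol[sel] == p
            np.add.at(new[p], (y[sel][psel], x[sel][psel]), 1.0)
        cur_surf = {p: surf[p] * decay + new[p] for p in (1, -1)}
        if prev_surf is not None:
            resp = np.zeros((H, W, bank.n_channels))
            for p in (1, -1):
                cur_c = cur_surf[p] - cur_surf[p].mean()
                prev_c = prev_surf[p] - prev_surf[p].mean()
                half = np.empty((H, W, bank.n_channels))
                for c in range(bank.n_channels):
                    vx, vy = bank.channel_velocity(c)
                    shifted = _shift_exact(prev_c, vy, vx)
                    half[:, :, c] = ndimage.gaussian_filter(
                        cur_c * shifted, bank.spatial_scale, mode="reflect")
                opp = np.roll(
                    half.reshape(H, W, bank.n_directions, len(bank.speeds)),
                    bank.n_directions // 2, axis=2).reshape(half.shape)
                resp += np.maximum(half - opp, 0.0)
            resp *= cur_mask[:, :, None]     # sparse support contract
            out.append(resp)
            times.append(edges[b])
        surf = cur_surf
        prev_surf = cur_surf
    return np.asarray(out), np.asarray(times)
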