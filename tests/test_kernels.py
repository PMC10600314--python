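"""Filter banks and motion detectors: construction invariants and responses."""

import math

import numpy as np
import pytest
from scipy import ndimage

from canoncirc.kernels import (Kernel, MotionDetectorBank, bipole_kernel,
                               gaussian_kernel, motion_detect_events,
                               motion_detect_frames, oriented_filter,
                               oriented_filter_bank,
                               orientation_contrast_filter, pool_kernel)
from canoncirc.stimuli import (_render_bars, _render_dots, frames_to_events,
                               translating_bar, Stimulus)


class TestOrientedFilter:
    def test_even_kernel_zero_dc(self):
        k = oriented_filter(0.7, 2.0, "even")
        assert abs(k.weights.sum()) < 1e-10

    def test_preferred_beats_orthogonal(self):
        k = oriented_filter(math.pi / 2, 2.0)
        bar_pref = _render_bars((33, 33), [(16, 16, math.pi / 2, 11, 2)])
        bar_orth = _render_bars((33, 33), [(16, 16, 0.0, 11, 2)])
        rp = abs(ndimage.correlate(bar_pref, k.weights, mode="reflect")[16, 16])
        ro = abs(ndimage.correlate(bar_orth, k.weights, mode="reflect")[16, 16])
        assert rp > 5 * ro

    def test_pi_rotation_invariance_of_even_kernel(self):
        a = oriented_filter(0.3, 2.0, "even")
        b = oriented_filter(0.3 + math.pi, 2.0, "even")
        assert np.allclose(a.weights, b.weights, atol=1e-12)

    def test_too_small_scale_rejected(self):
        with pytest.raises(ValueError):
            oriented_filter(0.0, 0.5)

    def test_rotational_equivariance_one_channel_step(self):
        """Rotating a bar by one channel step permutes bank responses."""
        n = 8
        bank = oriented_filter_bank(n, 2.0)
        img0 = _render_bars((41, 41), [(20, 20, 0.0, 13, 2)])
        img1 = _render_bars((41, 41), [(20, 20, math.pi / n, 13, 2)])
        r0 = [abs(ndimage.correlate(img0, k.weights)[20, 20]) for k in bank]
        r1 = [abs(ndimage.correlate(img1, k.weights)[20, 20]) for k in bank]
        # response profile of the rotated bar equals the rolled profile
        assert np.argmax(np.roll(r0, 1)) == np.argmax(r1)


class TestBipole:
    def test_center_tap_zero_and_point_symmetry(self):
        k = bipole_kernel(0.5, 8.0)
        assert k.weights[k.center] == 0.0
        assert np.allclose(k.weights, k.weights[::-1, ::-1], atol=1e-12)

    def test_collinear_beats_flanking_parallel(self):
        """Support of collinear bars exceeds flanking-parallel placement."""
        k = bipole_kernel(0.0, 12.0)       # horizontal orientation
        coll = _render_bars((41, 41), [(20, 8, 0, 9, 2), (20, 32, 0, 9, 2)])
        par = _render_bars((41, 41), [(8, 20, 0, 9, 2), (32, 20, 0, 9, 2)])
        s_coll = ndimage.correlate(coll, k.weights, mode="reflect")[20, 20]
        s_par = ndimage.correlate(par, k.weights, mode="reflect")[20, 20]
        assert s_coll > 2 * s_par

    def test_angular_tolerance_bound(self):
        with pytest.raises(ValueError):
            bipole_kernel(0.0, 8.0, angular_tolerance=math.pi / 2)


class TestPoolKernel:
    def test_unit_sum(self):
        k = pool_kernel(3.0, 1.5, 8)
        assert k.full_weights().sum() == pytest.approx(1.0, abs=1e-10)

    def test_feature_marginal_symmetric(self):
        k = pool_kernel(2.0, 1.0, 8)
        prof = k.separable_feature
        assert np.allclose(prof, prof[::-1] if len(prof) % 2 else
                           np.roll(prof[::-1], 1), atol=1e-12)

    def test_wide_feature_sigma_approaches_uniform(self):
        k = pool_kernel(2.0, 1e4, 8)
        assert np.allclose(k.separable_feature, 1.0 / 8, atol=1e-6)

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            pool_kernel(0.0, 1.0, 8)


class TestOrientationContrast:
    def _texture(self, theta, shape=(64, 64)):
        bars = [(8 + 16 * i, 8 + 16 * j, theta, 9, 2)
                for i in range(4) for j in range(4)]
        return _render_bars(shape, bars)

    def _respond(self, kern, field):
        return kern.apply(field)

    def _orientation_field(self, img, n=8):
        bank = oriented_filter_bank(n, 2.0)
        from canoncirc.kernels import apply_filter_bank
        return apply_filter_bank(img, bank)

    def test_uniform_texture_yields_near_zero(self):
        k = orientation_contrast_filter((0.0, 0.0), scale=16.0)
        field = self._orientation_field(self._texture(0.0))
        resp = k.apply(field)
        center = resp[24:40, 24:40]
        assert np.abs(center).max() < 0.05 * np.abs(field).max()

    def test_sharper_orientation_step_responds_more(self):
        k = orientation_contrast_filter((0.0, 0.0), scale=16.0, axis=0.0)
        left = [(8 + 16 * i, 8 + 16 * j, 0.0, 9, 2)
                for i in range(4) for j in range(2)]
        for step in (math.radians(30), math.radians(90)):
            right = [(8 + 16 * i, 8 + 16 * j, step, 9, 2)
                     for i in range(4) for j in range(2, 4)]
            img = _render_bars((64, 64), left + right)
            field = self._orientation_field(img)
            resp = np.abs(k.apply(field)).max()
            if step == math.radians(30):
                r30 = resp
            else:
                r90 = resp
        assert r90 > r30

    def test_swapping_subfields_negates_response(self):
        # swapping the preferred orientations AND reversing the displacement
        # axis exchanges the excitatory and inhibitory subfields, so the
        # signed kernel (hence its response) is exactly negated
        k1 = orientation_contrast_filter((0.0, math.pi / 2), scale=12.0,
                                         axis=0.3)
        k2 = orientation_contrast_filter((math.pi / 2, 0.0), scale=12.0,
                                         axis=0.3 + math.pi)
        assert np.allclose(k1.weights, -k2.weights, atol=1e-10)


class TestMotionDetectors:
    def make_dot_frames(self, v=(0.0, 2.0), T=6, shape=(48, 48)):
        vy, vx = v
        return np.stack([
            _render_dots(shape, np.array([[24.0 + vy * t, 12.0 + vx * t]]),
                         2.0) for t in range(T)])

    def test_static_frames_near_zero(self):
        frames = np.tile(self.make_dot_frames()[0], (4, 1, 1))
        bank = MotionDetectorBank(8, (1.0, 2.0))
        resp = motion_detect_frames(frames, bank)
        moving = motion_detect_frames(self.make_dot_frames(), bank)
        assert resp.max() < 0.05 * moving.max()

    def test_rightward_dot_argmax_channel(self):
        bank = MotionDetectorBank(8, (1.0, 2.0, 3.0))
        resp = motion_detect_frames(self.make_dot_frames(), bank)
        r = resp[3]
        iy, ix = 24, 18
        v = r[iy - 2:iy + 3, ix - 2:ix + 3].sum((0, 1))
        d, s = divmod(int(v.argmax()), 3)
        assert d == 0 and bank.speeds[s] == 2.0

    def test_mirror_flip_swaps_left_right(self):
        bank = MotionDetectorBank(8, (2.0,))
        frames = self.make_dot_frames()
        r = motion_detect_frames(frames, bank)
        rf = motion_detect_frames(frames[:, :, ::-1], bank)
        total = r.sum((0, 1, 2))
        total_f = rf.sum((0, 1, 2))
        assert total_f[4] == pytest.approx(total[0], rel=0.05)
        assert total_f[0] == pytest.approx(total[4], rel=0.05)

    def test_fewer_than_two_frames_rejected(self):
        bank = MotionDetectorBank(8, (1.0,))
        with pytest.raises(ValueError):
            motion_detect_frames(self.make_dot_frames()[:1], bank)

    def test_bank_validation(self):
        with pytest.raises(ValueError):
            MotionDetectorBank(8, (2.0, 1.0))
        with pytest.raises(ValueError):
            MotionDetectorBank(8, (0.0, 1.0))

    def test_outputs_nonnegative_finite(self):
        bank = MotionDetectorBank(8, (1.0, 2.0))
        resp = motion_detect_frames(self.make_dot_frames(), bank)
        assert np.all(resp >= 0) and np.all(np.isfinite(resp))


class TestEventDetection:
    def test_empty_stream_empty_output(self):
        from canoncirc.stimuli import EVENT_DTYPE, EventStream
        stream = EventStream(np.empty(0, dtype=EVENT_DTYPE), (16, 16))
        bank = MotionDetectorBank(8, (2.0,))
        out, times = motion_detect_events(stream, bank)
        assert out.shape[0] == 0

    def test_sparsity_support_subset_of_event_pixels(self):
        stim = translating_bar(length=15, n_frames=10, shape=(48, 48))
        stream = frames_to_events(stim, log_threshold=0.2)
        bank = MotionDetectorBank(8, (2.0,))
        out, times = motion_detect_events(stream, bank, bin_ms=20.0)
        ev = stream.events
        for b in range(out.shape[0]):
            support = np.nonzero(out[b].sum(axis=2))
            pix = set(zip(*support))
            allowed = set(zip(ev["y"].tolist(), ev["x"].tolist()))
            assert pix <= allowed

    def test_unsorted_events_rejected(self):
        from canoncirc.stimuli import EVENT_DTYPE
        ev = np.zeros(2, dtype=EVENT_DTYPE)
        ev["t_ms"] = [5.0, 1.0]
        bank = MotionDetectorBank(8, (2.0,))
        with pytest.raises(ValueError):
            motion_detect_events(ev, bank)

    def test_event_frame_argmax_agreement_on_edges(self):
        """Event-sampled and frame-based detection agree on the argmax
        direction (within one 45-degree channel step, the resolution at
        which near-tied adjacent channels are interchangeable) at >=90% of
        event loci on a high-contrast translating bar."""
        stim = translating_bar(length=21, n_frames=12, shape=(64, 64),
                               direction=0.0, speed=2.0)
        bank = MotionDetectorBank(8, (2.0,))
        frame_resp = motion_detect_frames(stim.frames, bank)
        stream = frames_to_events(stim, log_threshold=0.2)
        ev_resp, times = motion_detect_events(stream, bank,
                                              bin_ms=stim.frame_interval)
        agree = total = 0
        D = bank.n_directions
        for b in range(1, ev_resp.shape[0]):
            t_frame = min(int(times[b] / stim.frame_interval),
                          frame_resp.shape[0] - 1)
            mask = ev_resp[b].sum(axis=2) > 0
            fr = frame_resp[t_frame]
            fr_mask = mask & (fr.sum(axis=2) > 1e-9)
            if not fr_mask.any():
                continue
            ev_arg = ev_resp[b].argmax(axis=2)[fr_mask]
            fr_arg = fr.argmax(axis=2)[fr_mask]
            dist = np.minimum((ev_arg - fr_arg) % D, (fr_arg - ev_arg) % D)
            agree += int((dist <= 1).sum())
            total += int(fr_mask.sum())
        assert total > 0
        assert agree / total >= 0.9


class TestKernelContainer:
    def test_even_support_rejected(self):
        with pytest.raises(ValueError):
            Kernel(np.ones((2, 3)))

    def test_gaussian_kernel_unit_sum_and_apply(self):
        k = gaussian_kernel(2.0)
        assert k.weights.sum() == pytest.approx(1.0, abs=1e-10)
        x = np.random.default_rng(0).uniform(0, 1, (16, 16, 2))
        out = k.apply(x)
        assert out.shape == x.shape
        # smoothing preserves the mean under reflective boundaries
        assert out.mean() == pytest.approx(x.mean(), rel=0.05)
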