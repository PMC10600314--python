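"""E-I node dynamics: algebraic contracts, closed forms, shunting bounds."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from canoncirc.core import (AdaptiveSynapse, EILayerParams, EILayerState,
                            FeatureField, FiringRateSpec, KernelSet,
                            StabilityError, adapt_weight, drive, firing_rate,
                            modulate, run_to_equilibrium,
                            steady_state_weight, step_layer)
from canoncirc.kernels import pool_kernel


def _const(shape, value):
    return np.full(shape, float(value))


class TestModulate:
    def test_zero_drive_gates_any_feedback(self):
        b = np.zeros((3, 3, 2))
        a = np.full((3, 3, 2), 1.0)
        assert np.all(modulate(b, a, 10.0) == 0.0)

    @pytest.mark.parametrize("b,a,lam,expected", [
        (1.0, 0.0, 5.0, 1.0),
        (2.0, 0.5, 1.0, 3.0),
    ])
    def test_arithmetic(self, b, a, lam, expected):
        out = modulate(_const((2, 2, 1), b), _const((2, 2, 1), a), lam)
        assert np.allclose(out, expected)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            modulate(np.zeros((2, 2, 1)), np.zeros((2, 3, 1)), 1.0)

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            modulate(_const((2, 2, 1), -1.0), _const((2, 2, 1), 0.0), 1.0)

    @given(st.floats(0.01, 5.0), st.floats(0.0, 5.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_feedback_linear_in_drive(self, b, a, da):
        """Output non-decreasing in a at fixed b > 0, and linear in b."""
        lam = 2.0
        f = _const((1, 1, 1), b)
        low = modulate(f, _const((1, 1, 1), a), lam)
        high = modulate(f, _const((1, 1, 1), a + da), lam)
        assert np.all(high >= low)
        doubled = modulate(2.0 * f, _const((1, 1, 1), a), lam)
        assert np.allclose(doubled, 2.0 * low)


class TestDrive:
    def test_identity_without_lateral_and_feedback(self):
        F = np.random.default_rng(0).uniform(0, 1, (4, 4, 2))
        out = drive(F, np.zeros_like(F), np.zeros_like(F), KernelSet(),
                    kappa=0.0, lambda_fb=1.0)
        assert np.allclose(out, F)

    def test_no_strong_loop(self):
        """Zero driving input yields exactly zero for any feedback."""
        rng = np.random.default_rng(1)
        z = rng.uniform(0, 10, (4, 4, 2))
        out = drive(np.zeros((4, 4, 2)), np.zeros((4, 4, 2)), z,
                    KernelSet(), kappa=2.0, lambda_fb=7.0)
        assert np.all(out == 0.0)

    def test_pointwise_arithmetic(self):
        # F=1, lateral contribution 0.5 via kappa=2 -> bracket 2; feedback
        # z=1 at lambda=1 doubles it
        F = _const((1, 1, 1), 1.0)
        out = (F + 2.0 * 0.5) * (1 + 1.0 * 1.0)
        assert np.allclose(out, 4.0)


class TestFiringRate:
    def test_rectification(self):
        spec = FiringRateSpec("linear")
        assert firing_rate(np.array([[[-1.0]]]), spec) == 0.0
        assert firing_rate(np.array([[[0.0]]]), spec) == 0.0

    def test_power(self):
        spec = FiringRateSpec("power", exponent=2.0)
        assert firing_rate(np.array([[[2.0]]]), spec) == 4.0

    def test_zero_at_zero_for_all_shapes(self):
        for spec in (FiringRateSpec("linear"), FiringRateSpec("power"),
                     FiringRateSpec("sigmoid")):
            assert firing_rate(np.array([[[0.0]]]), spec) == 0.0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            FiringRateSpec("tanh")

    def test_monotone_nonnegative(self):
        x = np.linspace(-3, 3, 41).reshape(1, 1, -1)
        for spec in (FiringRateSpec("linear"), FiringRateSpec("power"),
                     FiringRateSpec("sigmoid")):
            y = firing_rate(x, spec)
            assert np.all(y >= 0)
            assert np.all(np.diff(y.ravel()) >= -1e-12)


class TestStepLayer:
    def test_zero_fixed_point(self):
        p = EILayerParams(tau_r=10, tau_q=10)
        st0 = EILayerState.zeros(3, 3, 2)
        new = step_layer(st0, np.zeros((3, 3, 2)), np.zeros((3, 3, 2)),
                         p, KernelSet(), dt=1.0)
        assert np.all(new.r.values == 0) and np.all(new.q.values == 0)
        assert new.t == 1.0

    def test_dt_guard(self):
        p = EILayerParams(tau_r=10, tau_q=10)
        st0 = EILayerState.zeros(2, 2, 1)
        with pytest.raises(StabilityError):
            step_layer(st0, np.zeros((2, 2, 1)), np.zeros((2, 2, 1)),
                       p, KernelSet(), dt=2.0)

    def test_excitation_only_equilibrium_closed_form(self):
        """With inhibition off, r converges to beta*E/(alpha+E) to 1e-6."""
        E = 2.5
        p = EILayerParams(tau_r=10, tau_q=10, alpha=1.0, beta=1.0)
        st0 = EILayerState.zeros(2, 2, 1)
        final, info = run_to_equilibrium(
            st0, _const((2, 2, 1), E), np.zeros((2, 2, 1)), p, KernelSet(),
            dt=p.tau_r / 100, tol=1e-10, max_steps=50000)
        assert info.converged
        assert np.allclose(final.r.values, 1.0 * E / (1.0 + E), atol=1e-6)

    def test_shunting_bound_random_inputs(self):
        """r stays within [-delta, beta] under randomized drive sequences."""
        rng = np.random.default_rng(42)
        p = EILayerParams(tau_r=20, tau_q=20, beta=1.0, delta=1.0)
        ks = KernelSet(lambda_pool=pool_kernel(1.0, 1.0, 3))
        st0 = EILayerState.zeros(4, 4, 3)
        state = st0
        for _ in range(100):
            F = rng.uniform(0, 3, (4, 4, 3))
            z = rng.uniform(0, 2, (4, 4, 3))
            state = step_layer(state, F, z, p, ks, dt=1.0)
            assert np.all(state.r.values <= p.beta + 1e-12)
            assert np.all(state.r.values >= -p.delta - 1e-12)


class TestRunToEquilibrium:
    def test_zero_input_converges_immediately(self):
        p = EILayerParams(tau_r=10, tau_q=10)
        st0 = EILayerState.zeros(2, 2, 1)
        _, info = run_to_equilibrium(st0, np.zeros((2, 2, 1)),
                                     np.zeros((2, 2, 1)), p, KernelSet(),
                                     dt=1.0, tol=1e-9)
        assert info.converged and info.steps == 1

    def test_fixed_point_idempotent_under_more_steps(self):
        p = EILayerParams(tau_r=10, tau_q=10)
        F = _const((2, 2, 1), 1.0)
        z = np.zeros((2, 2, 1))
        st0 = EILayerState.zeros(2, 2, 1)
        s1, i1 = run_to_equilibrium(st0, F, z, p, KernelSet(), dt=0.5,
                                    tol=1e-9, max_steps=5000)
        s2, _ = run_to_equilibrium(st0, F, z, p, KernelSet(), dt=0.5,
                                   tol=1e-9, max_steps=10000)
        assert i1.converged
        assert np.max(np.abs(s1.r.values - s2.r.values)) < 1e-9

    def test_non_convergence_reported(self):
        p = EILayerParams(tau_r=10, tau_q=10)
        st0 = EILayerState.zeros(2, 2, 1)
        _, info = run_to_equilibrium(st0, _const((2, 2, 1), 2.0),
                                     np.zeros((2, 2, 1)), p, KernelSet(),
                                     dt=0.1, tol=1e-15, max_steps=5)
        assert not info.converged and info.criterion == "max_steps"

    def test_halving_dt_changes_equilibrium_below_tolerance(self):
        """First-order integrator consistency at the fixed point."""
        p = EILayerParams(tau_r=10, tau_q=10)
        F = _const((2, 2, 1), 1.5)
        z = np.zeros((2, 2, 1))
        st0 = EILayerState.zeros(2, 2, 1)
        tol = 1e-8
        a, _ = run_to_equilibrium(st0, F, z, p, KernelSet(), dt=0.5,
                                  tol=tol, max_steps=20000)
        b, _ = run_to_equilibrium(st0, F, z, p, KernelSet(), dt=0.25,
                                  tol=tol, max_steps=40000)
        assert np.max(np.abs(a.r.values - b.r.values)) < 100 * tol


class TestAdaptiveSynapse:
    def test_recovery_toward_one_without_signal(self):
        syn = AdaptiveSynapse(w=0.3, alpha_w=1.0, beta_w=2.0, tau_w=10.0)
        for _ in range(200):
            syn = adapt_weight(syn, 0.0, 1.0)
        assert syn.w == pytest.approx(1.0, abs=1e-6)

    def test_steady_state_half(self):
        syn = AdaptiveSynapse(w=1.0, alpha_w=1.0, beta_w=1.0, tau_w=10.0)
        for _ in range(500):
            syn = adapt_weight(syn, 1.0, 1.0)
        assert syn.w == pytest.approx(0.5, abs=1e-6)
        assert steady_state_weight(1.0, 1.0, 1.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("scheme", ["exact", "euler"])
    def test_long_run_matches_closed_form(self, scheme):
        syn = AdaptiveSynapse(w=1.0, alpha_w=0.7, beta_w=2.3, tau_w=10.0)
        s = 1.7
        for _ in range(3000):
            syn = adapt_weight(syn, s, syn.tau_w / 100, scheme=scheme)
        assert syn.w == pytest.approx(
            steady_state_weight(s, syn.alpha_w, syn.beta_w), abs=1e-6)

    @given(st.floats(0.01, 1.0), st.floats(0.0, 50.0))
    @settings(max_examples=60, deadline=None)
    def test_efficacy_stays_in_unit_interval(self, w0, s):
        syn = AdaptiveSynapse(w=w0, alpha_w=1.0, beta_w=3.0, tau_w=10.0)
        for _ in range(20):
            syn = adapt_weight(syn, s, 1.0)
            assert 0.0 < np.asarray(syn.w) <= 1.0

    def test_steady_state_properties(self):
        assert steady_state_weight(0.0, 1.0, 1.0) == 1.0
        s = np.array([0.0, 1.0, 10.0, 1e6])
        w = steady_state_weight(s, 1.0, 1.0)
        assert np.all(np.diff(w) < 0)          # monotone decreasing
        assert w[-1] < 1e-5                     # s -> inf limit is 0
        with pytest.raises(ValueError):
            steady_state_weight(1.0, 0.0, 1.0)

    def test_negative_signal_rejected(self):
        syn = AdaptiveSynapse()
        with pytest.raises(ValueError):
            adapt_weight(syn, -0.1, 1.0)


class TestFeatureField:
    def test_shape_metadata(self):
        f = FeatureField(np.zeros((4, 5, 3)))
        assert (f.height, f.width, f.n_features) == (4, 5, 3)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            FeatureField(np.array([[[np.nan]]]))

    def test_params_validation(self):
        with pytest.raises(ValueError):
            EILayerParams(tau_r=-1.0)
        with pytest.raises(ValueError):
            EILayerParams(kappa=-0.5)
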