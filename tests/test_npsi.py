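import math
from dataclasses import replace

import numpy as np
import pytest

from loomsim import (ApproachSpec, NPsiParams, PoolParams, equilibrium_V,
                     fit_log_compression, log_compression_curve, make_stimulus,
                     relax, rk4_step, simulate, simulate_spec)
from loomsim.npsi import _rk4_decay_factor


class TestEquilibrium:
    def test_no_input_rests(self, default_params):
        assert equilibrium_V(0.0, 0.0, default_params) == pytest.approx(
            default_params.V_rest)

    def test_strong_excitation_approaches_reversal(self, default_params):
        v = equilibrium_V(1e9, 1.0, default_params)
        assert v == pytest.approx(default_params.V_exc, abs=1e-6)

    def test_hand_computed_value(self, default_params):
        # (1e-5 + 2*1 + 1*(-0.005)) / (1 + 2 + 1)
        assert equilibrium_V(2.0, 1.0, default_params) == pytest.approx(0.4987525)

    def test_bounded_by_reversals(self, default_params):
        rng = np.random.default_rng(0)
        ge, gi = rng.uniform(0, 100, 50), rng.uniform(0, 100, 50)
        v = equilibrium_V(ge, gi, default_params)
        assert np.all(v >= default_params.V_inh) and np.all(v <= default_params.V_exc)


class TestRK4:
    def test_fixed_point(self, default_params):
        v_inf = equilibrium_V(2.0, 1.0, default_params)
        assert rk4_step(v_inf, 2.0, 1.0, default_params, 5e-4) == pytest.approx(
            v_inf, abs=1e-15)

    def test_decay_oracle_coarse_step(self):
        # pure leak, V(0)=1, beta=1, dt=0.5: RK4 approximates exp(-0.5)
        p = NPsiParams(V_rest=0.0, V_inh=0.0)
        out = rk4_step(1.0, 0.0, 0.0, p, 0.5)
        assert out == pytest.approx(math.exp(-0.5), abs=0.5**5 / 120 * 1.1)

    def test_matches_exponential_at_simulation_step(self, default_params):
        # frozen-input decay at dt=500us is exponential to < 1e-8 relative
        dt = 5e-4
        for ge, gi in [(0.0, 0.0), (5.0, 2.0), (80.0, 40.0)]:
            v_inf = equilibrium_V(ge, gi, default_params)
            v0 = 0.3
            exact = v_inf + (v0 - v_inf) * math.exp(-dt * (1 + ge + gi))
            assert rk4_step(v0, ge, gi, default_params, dt) == pytest.approx(
                exact, rel=1e-8)

    def test_first_order_limit(self, default_params):
        dt = 1e-9
        v0, ge, gi = 0.2, 3.0, 1.0
        rhs = (default_params.beta * (default_params.V_rest - v0)
               + ge * (default_params.V_exc - v0) + gi * (default_params.V_inh - v0))
        assert rk4_step(v0, ge, gi, default_params, dt) == pytest.approx(
            v0 + dt * rhs, rel=1e-9)


class TestRelax:
    def test_zero_steps_is_identity(self, default_params):
        assert relax(0.42, 1.0, 1.0, default_params, n_relax=0) == 0.42

    def test_equivalent_to_iterated_rk4(self, default_params):
        v = 0.3
        expected = v
        for _ in range(5):
            expected = rk4_step(expected, 4.0, 2.0, default_params, default_params.dt_rk)
        assert relax(v, 4.0, 2.0, default_params, n_relax=5) == pytest.approx(
            expected, rel=1e-12)

    def test_converges_to_equilibrium_under_decay_bound(self, default_params):
        # (beta + g_exc + g_inh) * n_relax * dt > 25 implies < 1e-10 residual
        ge, gi = 150.0, 100.0
        assert (1 + ge + gi) * 250 * 5e-4 > 25
        v_inf = equilibrium_V(ge, gi, default_params)
        out = relax(0.0, ge, gi, default_params)
        assert abs(out - v_inf) < 1e-10 * abs(0.0 - v_inf)

    def test_no_input_returns_to_rest(self, default_params):
        out = relax(0.5, 0.0, 0.0, default_params, n_relax=100_000)
        assert out == pytest.approx(default_params.V_rest, abs=1e-9)


class TestSimulate:
    def test_empty_trace_raises(self, default_trace, default_params):
        empty = replace(default_trace, times=np.array([]),
                        theta=np.array([]), theta_dot=np.array([]),
                        theta_lp=np.array([]), theta_dot_lp=np.array([]))
        with pytest.raises(ValueError):
            simulate(empty, default_params)

    def test_voltage_bounded_by_reversals(self, default_trace, default_params):
        resp = simulate(default_trace, default_params, seed=0)
        assert np.all(resp.V >= default_params.V_inh - 1e-12)
        assert np.all(resp.V <= default_params.V_exc + 1e-12)
        assert np.all(resp.rate >= 0)

    def test_rate_is_rectified_voltage(self, default_trace, default_params):
        resp = simulate(default_trace, default_params, seed=1)
        assert np.array_equal(resp.rate, np.maximum(resp.V, 0.0))

    def test_seed_reproducibility(self, default_trace, default_params):
        r1 = simulate(default_trace, default_params, seed=7)
        r2 = simulate(default_trace, default_params, seed=7)
        assert np.array_equal(r1.V, r2.V)
        assert r1.t_peak == r2.t_peak

    def test_noise_free_is_seed_independent(self, default_trace):
        p = NPsiParams().with_sigma(0.0)
        r1 = simulate(default_trace, p, seed=0)
        r2 = simulate(default_trace, p, seed=99)
        assert np.array_equal(r1.V, r2.V)

    def test_tracks_equilibrium_at_high_conductance(self, default_trace):
        # late in the approach total conductance is large enough that the
        # relaxation contraction bound guarantees equilibrium to 1e-6
        p = NPsiParams().with_sigma(0.25)
        resp = simulate(default_trace, p, seed=0)
        g_tot = p.beta + resp.g_exc + resp.g_inh
        v_inf = equilibrium_V(resp.g_exc, resp.g_inh, p)
        strong = g_tot * (p.n_relax + 1) * p.dt_rk > 25
        assert strong.sum() > 10
        assert np.max(np.abs(resp.V[strong] - v_inf[strong])) < 1e-6

    def test_trel_annotation(self, default_spec, default_params):
        resp = simulate_spec(default_spec, default_params, seed=0)
        assert resp.t_rel == pytest.approx(default_spec.t_collision - resp.t_peak)

    def test_fresh_noise_mode_differs_but_same_mean_level(self, default_trace):
        p_frozen = NPsiParams()
        p_fresh = replace(p_frozen, noise_time="fresh")
        rf = simulate(default_trace, p_frozen, seed=0)
        rw = simulate(default_trace, p_fresh, seed=0)
        assert not np.array_equal(rf.g_inh, rw.g_inh)
        assert np.mean(rw.g_inh) == pytest.approx(np.mean(rf.g_inh), rel=0.2)

    def test_excitatory_pool_reduces_to_expansion_rate(self, default_trace):
        p = replace(NPsiParams(), exc_noise=NPsiParams.default_exc_noise(0.25))
        resp = simulate(default_trace, p, seed=0)
        strong = default_trace.theta_dot_lp > 2.0
        assert np.allclose(resp.g_exc[strong],
                           default_trace.theta_dot_lp[strong], rtol=0.05)


class TestLogCompression:
    def test_monotone_and_bounded(self, default_params):
        td, V = log_compression_curve(default_params, theta_const=0.65)
        assert np.all(np.diff(V) > 0)
        assert V[-1] < default_params.V_exc

    def test_no_excitation_no_visible_response(self, default_params):
        # shunting inhibition alone leaves the rectified rate at ~zero
        td, V = log_compression_curve(default_params, theta_const=0.65)
        assert abs(V[0]) <= abs(default_params.V_inh) + default_params.V_rest
        assert max(V[0], 0.0) < 1e-3

    @pytest.mark.parametrize("theta_const, r2_min", [
        (0.5, 0.95), (0.65, 0.99), (0.8, 0.95)])
    def test_logarithmic_fit_quality(self, default_params, theta_const, r2_min):
        td, V = log_compression_curve(default_params, theta_const=theta_const)
        _, _, r2 = fit_log_compression(td, V)
        assert r2 > r2_min
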