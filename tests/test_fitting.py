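import numpy as np
import pytest

from loomsim import ApproachSpec, EtaParams, NPsiParams
from loomsim.fitting import (RateTrace, fit_eta, fit_npsi, make_synthetic_rate,
                             npsi_equilibrium_rate, rate_from_spike_trace)


class TestRateFromSpikeTrace:
    def test_zero_input_zero_rate(self):
        out = rate_from_spike_trace(np.zeros(20000))
        assert np.allclose(out, 0.0)

    def test_dc_offset_preserved_as_constant(self):
        out = rate_from_spike_trace(np.full(20000, -0.5))
        mid = out[200:-200]
        assert np.allclose(mid, mid.mean(), rtol=1e-6)
        assert mid.mean() == pytest.approx(0.5, rel=1e-3)

    def test_constant_poisson_rate_recovered_as_constant(self):
        # 300 Hz Poisson spikes at 10 kHz for 2 s: the rate estimate should
        # be flat; quarter-segment means agree within 20 %
        rng = np.random.default_rng(0)
        spikes = (rng.random(20000) < 300.0 / 1e4).astype(float)
        out = rate_from_spike_trace(spikes, window_ms=201)
        segs = np.array_split(out[100:-100], 4)
        means = np.array([s.mean() for s in segs])
        assert np.all(np.abs(means - means.mean()) / means.mean() < 0.2)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            rate_from_spike_trace(np.zeros(100), window_ms=51)


class TestRateTrace:
    def test_validation(self):
        spec = ApproachSpec.from_l_over_v(0.03)
        with pytest.raises(ValueError):
            RateTrace(times=np.array([0.0, 0.0, 1.0]),
                      rate=np.zeros(3), spec=spec)
        with pytest.raises(ValueError):
            RateTrace(times=np.array([0.0, 1.0]),
                      rate=np.array([0.0, np.inf]), spec=spec)

    def test_csv_roundtrip(self, tmp_path):
        tr = make_synthetic_rate("eta_like", seed=0)
        path = tmp_path / "rate.csv"
        tr.to_csv(path)
        back = RateTrace.from_csv(path, tr.spec)
        assert np.allclose(back.rate, tr.rate)


class TestSyntheticRate:
    def test_eta_like_noise_free_equals_scaled_eta(self):
        from loomsim import eta_of_t, make_stimulus
        spec = ApproachSpec.from_l_over_v(0.03)
        tr = make_synthetic_rate("eta_like", spec=spec, amplitude=50.0,
                                 eta_params=EtaParams(alpha=4.7))
        stim = make_stimulus(spec, 0.0, 0.0)
        assert np.allclose(tr.rate, 50.0 * eta_of_t(stim, EtaParams(alpha=4.7)))

    def test_fixed_seed_reproducible(self):
        a = make_synthetic_rate("npsi_like", noise_sd=0.1, seed=4)
        b = make_synthetic_rate("npsi_like", noise_sd=0.1, seed=4)
        assert np.array_equal(a.rate, b.rate)
        assert a.provenance == "synthetic"

    def test_linear_approach_is_falling_sigmoid(self):
        # constant angular velocity: high early plateau, collapse to ~0
        tr = make_synthetic_rate("linear_approach", generator="equilibrium")
        peak = tr.rate.max()
        assert tr.rate[:50].min() > 0.8 * peak
        assert tr.rate[-1] < 0.05 * peak

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            make_synthetic_rate("square_wave")


class TestFitEta:
    def test_self_fit_recovers_parameters(self):
        spec = ApproachSpec.from_l_over_v(0.03)
        tr = make_synthetic_rate("eta_like", spec=spec, amplitude=100.0,
                                 eta_params=EtaParams(alpha=3.1))
        res = fit_eta(tr)
        assert res.estimates["alpha"] == pytest.approx(3.1, rel=1e-3)
        assert res.estimates["amplitude_A"] == pytest.approx(100.0, rel=1e-3)
        assert abs(res.estimates["delta"]) < 1e-3
        assert res.r_squared > 0.9999

    def test_flat_trace_degenerate(self):
        spec = ApproachSpec.from_l_over_v(0.03)
        times = np.arange(0, 0.5, 1e-3)
        tr = RateTrace(times=times, rate=np.full_like(times, 5.0), spec=spec)
        res = fit_eta(tr)
        assert res.degenerate

    def test_empty_mask_no_optimization(self):
        tr = make_synthetic_rate("eta_like", amplitude=1.0)
        res = fit_eta(tr, free_mask=())
        assert res.estimates == {}
        assert res.r_squared > 0.999


class TestFitNPsi:
    def test_self_fit_recovery_equilibrium(self):
        gen = NPsiParams().with_pool(noise_sigma=0.4, threshold_delta0=0.9)
        tr = make_synthetic_rate("npsi_like", generator="equilibrium",
                                 npsi_params=gen)
        res = fit_npsi(tr, ("sigma", "delta0"))
        assert res.estimates["sigma"] == pytest.approx(0.4, rel=0.02)
        assert res.estimates["delta0"] == pytest.approx(0.9, rel=0.02)

    def test_three_parameter_recovery_with_beta(self):
        gen = NPsiParams(beta=1.6).with_pool(noise_sigma=0.35, threshold_delta0=0.8)
        tr = make_synthetic_rate("npsi_like", generator="equilibrium",
                                 npsi_params=gen)
        res = fit_npsi(tr, ("beta", "sigma", "delta0"))
        assert res.estimates["beta"] == pytest.approx(1.6, rel=0.15)
        assert res.estimates["sigma"] == pytest.approx(0.35, rel=0.15)
        assert res.estimates["delta0"] == pytest.approx(0.8, rel=0.15)

    def test_deterministic_objective(self):
        tr = make_synthetic_rate("npsi_like", seed=2)
        r1 = fit_npsi(tr, ("sigma", "delta0"))
        r2 = fit_npsi(tr, ("sigma", "delta0"))
        assert r1.estimates == r2.estimates
        assert r1.residual_norm == r2.residual_norm

    def test_empty_mask_reports_default_goodness(self):
        tr = make_synthetic_rate("npsi_like", generator="equilibrium")
        res = fit_npsi(tr, free_mask=())
        assert res.estimates == {}
        assert res.r_squared > 0.999

    def test_identifiability_improves_with_less_noise(self):
        gen = NPsiParams().with_pool(noise_sigma=0.4, threshold_delta0=0.9)
        errs = []
        for nsd in (0.2, 0.0):
            tr = make_synthetic_rate("npsi_like", generator="equilibrium",
                                     npsi_params=gen, noise_sd=nsd, seed=11)
            res = fit_npsi(tr, ("sigma", "delta0"))
            errs.append(abs(res.estimates["sigma"] - 0.4)
                        + abs(res.estimates["delta0"] - 0.9))
        assert errs[1] <= errs[0] + 1e-6


class TestModelComparison:
    def test_npsi_beats_eta_on_its_own_linear_approach_data(self):
        # trial variability comes from the channel noise itself
        wins = 0
        n_seeds = 10
        for s in range(n_seeds):
            tr = make_synthetic_rate("linear_approach", seed=s)
            r_n = fit_npsi(tr, ("sigma", "delta0")).r_squared
            r_e = fit_eta(tr).r_squared
            wins += r_n >= r_e
        assert wins >= int(0.95 * n_seeds)
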