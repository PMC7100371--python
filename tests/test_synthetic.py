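import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lidkin import (
    DelaySchedule,
    KineticParams,
    expected_channels,
    expected_frr,
    generate_experiment,
    render_spectrum,
    simulate_populations,
)


def ode_populations(tau1: float, tau2: float, t: float):
    """Independent oracle: numerically integrate the two-step scheme."""

    def rhs(_, y):
        c, r, d = y
        return [-c / tau1, c / tau1 - r / tau2, r / tau2]

    sol = solve_ivp(
        rhs, (0.0, t), [1.0, 0.0, 0.0], rtol=1e-11, atol=1e-13, dense_output=True
    )
    return sol.y[:, -1]


class TestPopulations:
    def test_initial_condition(self, default_params):
        assert simulate_populations(default_params, 0.0) == (1.0, 0.0, 0.0)

    def test_long_time_closure(self, default_params):
        c, r, d = simulate_populations(default_params, 1e6 * default_params.tau2)
        assert c == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_matches_ode_oracle(self):
        p = KineticParams(tau1=100e-9, tau2=500e-6)
        t = 500e-6
        c, r, d = simulate_populations(p, t)
        oc, orr, od = ode_populations(p.tau1, p.tau2, t)
        assert r == pytest.approx(orr, abs=1e-8)
        assert c == pytest.approx(oc, abs=1e-8)
        assert d == pytest.approx(od, abs=1e-8)

    def test_equal_tau_limit_matches_ode(self):
        tau = 100e-6
        p = KineticParams(tau1=tau, tau2=tau)
        c, r, d = simulate_populations(p, 2 * tau)
        assert r == pytest.approx(2 * np.exp(-2.0), rel=1e-12)
        assert r == pytest.approx(ode_populations(tau, tau, 2 * tau)[1], abs=1e-8)

    def test_closure_on_grid(self, default_params):
        t = np.geomspace(1e-9, 1e-1, 200)
        c, r, d = simulate_populations(default_params, t)
        assert np.all((c >= 0) & (c <= 1) & (r >= 0) & (r <= 1) & (d >= 0) & (d <= 1))
        assert np.max(np.abs(c + r + d - 1.0)) < 1e-12

    def test_negative_delay_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate_populations(default_params, -1e-6)


class TestParamValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau1": 0.0},
            {"probe_yield_radical": 1.5},
            {"probe_yield_radical": 0.1, "probe_yield_distonic": 0.2},
            {"alpha_true": -0.1},
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            KineticParams(**kwargs)


class TestRenderSpectrum:
    def test_negative_delay_pump_only(self, default_params):
        p = default_params
        means = expected_channels(p, -1e-3)
        assert means["parent"] == p.n0
        free = means["free_129"] + means["free_185"]
        assert free == pytest.approx(p.alpha_true * p.pump_frag_ag, rel=1e-12)
        ag = means["pump_ag_107"] + means["pump_ag_109"]
        assert ag == pytest.approx(p.pump_frag_ag, rel=1e-12)

    def test_noiseless_matches_expectations(self, default_params):
        t = 3e-4
        s = render_spectrum(default_params, t, noise=False)
        means = expected_channels(default_params, t)
        from lidkin.synthetic import channel_positions

        pos = channel_positions(default_params)
        for label, mz in pos.items():
            idx = np.argmin(np.abs(s.mz - mz))
            assert s.intensity[idx] == pytest.approx(means[label], abs=1e-12)

    def test_equal_yields_time_independent(self):
        p = KineticParams(probe_yield_radical=0.2, probe_yield_distonic=0.2)
        ref = expected_channels(p, 100 * p.tau1)
        for t in (1e-4, 1e-3, 1e-2):
            means = expected_channels(p, t)
            assert means["free_129"] == pytest.approx(ref["free_129"], rel=1e-9)

    def test_histidine_free_channels(self):
        p = KineticParams(has_histidine=False)
        s = render_spectrum(p, 1e-4, noise=False)
        assert np.any(np.isclose(s.mz, 130.0))
        assert np.any(np.isclose(s.mz, 186.0))

    def test_seed_determinism(self, default_params):
        a = render_spectrum(default_params, 1e-4, seed=5)
        b = render_spectrum(default_params, 1e-4, seed=5)
        assert np.array_equal(a.mz, b.mz) and np.array_equal(a.intensity, b.intensity)


class TestExpectedFrr:
    def test_mono_exponential_above_transient(self):
        p = KineticParams(tau1=200e-9, tau2=800e-6)
        beta = p.probe_yield_radical - p.probe_yield_distonic
        t = np.geomspace(30e-6, 20e-3, 50)
        frr = np.array([expected_frr(p, float(tt)) for tt in t])
        model = p.probe_yield_radical - beta * (1.0 - np.exp(-t / p.tau2))
        assert np.max(np.abs(frr - model)) < 5e-4

    def test_monotone_decay_beyond_transient(self, default_params):
        t = np.geomspace(10 * default_params.tau1, 0.1, 300)
        frr = np.array([expected_frr(default_params, float(tt)) for tt in t])
        assert np.all(np.diff(frr) <= 1e-15)

    def test_zero_at_negative_delay(self, default_params):
        assert expected_frr(default_params, -1e-6) == 0.0


class TestGenerateExperiment:
    def test_spectrum_count(self, fast_params):
        sched = DelaySchedule(n_delays=10, n_repeats=4, n_negative=2)
        ds = generate_experiment(fast_params, sched, seed=1)
        assert len(ds) == (10 + 2) * 4

    def test_full_schedule_count_arithmetic(self):
        sched = DelaySchedule()
        assert (sched.n_delays + sched.n_negative) * sched.n_repeats == 24_600

    def test_same_seed_bit_identical(self, fast_params, small_schedule):
        a = generate_experiment(fast_params, small_schedule, seed=3)
        b = generate_experiment(fast_params, small_schedule, seed=3)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.mz, sb.mz)
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_log_spacing(self):
        d = DelaySchedule(n_delays=200).positive_delays()
        ratios = d[1:] / d[:-1]
        assert d[0] == pytest.approx(50e-9) and d[-1] == pytest.approx(20e-3)
        assert np.max(np.abs(ratios - ratios[0])) < 1e-9 * ratios[0]

    def test_repeat_extension_preserves_earlier_streams(self, fast_params):
        small = DelaySchedule(n_delays=5, n_repeats=3, n_negative=1)
        big = DelaySchedule(n_delays=5, n_repeats=6, n_negative=1)
        a = generate_experiment(fast_params, small, seed=9)
        b = generate_experiment(fast_params, big, seed=9)
        by_key = {(s.delay, s.replicate_id): s for s in b.spectra}
        for s in a.spectra:
            twin = by_key[(s.delay, s.replicate_id)]
            assert np.array_equal(s.intensity, twin.intensity)

    def test_truth_round_trip(self, fast_params, small_schedule):
        ds = generate_experiment(fast_params, small_schedule, seed=2)
        assert ds.truth["params"]["tau2"] == fast_params.tau2
        assert ds.truth["seed"] == 2
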