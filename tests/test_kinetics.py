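import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lidkin import DelaySchedule, KineticParams, generate_experiment
from lidkin.frr import FrrPoint
from lidkin.kinetics import (
    FitError,
    censor_slow,
    decay_model,
    fit_decay,
    weighted_average,
)
from lidkin.pipeline import analyze_dataset, process_spectra


def _model_curve(offset, amplitude, tau2, sem=0.0, n_points=25, samples=None):
    t = np.geomspace(40e-6, 20e-3, n_points)
    y = decay_model(t, offset, amplitude, tau2)
    return [
        FrrPoint(delay=float(tt), frr_mean=float(yy), frr_sem=sem, n=120, samples=samples)
        for tt, yy in zip(t, y)
    ]


class TestFitDecay:
    def test_noiseless_self_consistency(self):
        points = _model_curve(0.25, 0.15, 500e-6)
        fit = fit_decay(points, n_boot=5, seed=0)
        assert fit.offset == pytest.approx(0.25, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.15, rel=1e-6)
        assert fit.tau2 == pytest.approx(500e-6, rel=1e-6)
        assert not fit.censored

    def test_flat_curve_censored(self):
        rng = np.random.default_rng(0)
        t = np.geomspace(40e-6, 20e-3, 25)
        points = [
            FrrPoint(float(tt), float(0.2 + rng.normal(0, 1e-3)), 1e-3, 120)
            for tt in t
        ]
        fit = fit_decay(points, n_boot=200, seed=1)
        assert fit.censored
        assert fit.bound == pytest.approx(5e-3)

    def test_too_few_points(self):
        with pytest.raises(FitError, match=">= 4"):
            fit_decay(_model_curve(0.25, 0.15, 500e-6, n_points=3), n_boot=2, seed=0)

    def test_seed_determinism(self):
        points = _model_curve(0.25, 0.15, 500e-6, sem=0.003)
        a = fit_decay(points, n_boot=50, seed=7)
        b = fit_decay(points, n_boot=50, seed=7)
        assert a.tau2 == b.tau2 and a.sigma_tau2 == b.sigma_tau2

    def test_nonparametric_bootstrap(self):
        rng = np.random.default_rng(3)
        points = []
        for p in _model_curve(0.25, 0.15, 500e-6):
            samples = tuple(rng.normal(p.frr_mean, 0.01, size=60))
            points.append(
                FrrPoint(p.delay, float(np.mean(samples)),
                         float(np.std(samples, ddof=1) / np.sqrt(60)), 60, samples)
            )
        fit = fit_decay(points, n_boot=200, seed=2, bootstrap="nonparametric")
        assert fit.tau2 == pytest.approx(500e-6, rel=0.15)

    def test_nonparametric_requires_samples(self):
        points = _model_curve(0.25, 0.15, 500e-6, sem=0.003)
        with pytest.raises(FitError, match="keep_samples"):
            fit_decay(points, n_boot=10, seed=0, bootstrap="nonparametric")

    def test_sigma_shrinks_with_more_repeats(self, fast_params):
        sigmas = []
        for n_rep in (10, 90):
            sched = DelaySchedule(n_delays=30, n_repeats=n_rep, n_negative=3)
            ds = generate_experiment(fast_params, sched, seed=17)
            fit, _, _ = analyze_dataset(
                ds.spectra, fast_params.parent_mz, n_boot=150, seed=17
            )
            sigmas.append(fit.sigma_tau2)
        assert sigmas[1] < sigmas[0]
        # ~1/sqrt(9) shrinkage expected; allow a loose band
        assert sigmas[1] < 0.6 * sigmas[0]

    def test_insensitive_to_metastable_transient(self):
        """The >30 μs window shields tau2 from the sub-μs complex dynamics."""
        base = dict(tau2=800e-6, n0=2000.0)
        sched = DelaySchedule(n_delays=40, n_repeats=30, n_negative=3)
        fits = []
        for tau1 in (1e-9, 500e-9):
            params = KineticParams(tau1=tau1, **base)
            ds = generate_experiment(params, sched, seed=23)
            fit, _, _ = analyze_dataset(ds.spectra, params.parent_mz, n_boot=150, seed=23)
            fits.append(fit)
        assert abs(fits[0].tau2 - fits[1].tau2) < max(f.sigma_tau2 for f in fits)


class TestCensorSlow:
    def test_slow_decay_censored(self):
        points = _model_curve(0.25, 0.15, 12e-3, sem=0.002)
        fit = fit_decay(points, n_boot=100, seed=4, auto_censor=False)
        censored = censor_slow(fit)
        assert censored.censored and censored.bound == pytest.approx(5e-3)

    def test_resolved_decay_unchanged(self):
        points = _model_curve(0.25, 0.15, 700e-6, sem=0.002)
        fit = fit_decay(points, n_boot=100, seed=4, auto_censor=False)
        assert fit.amplitude > 10 * fit.sigma_amplitude
        assert censor_slow(fit) == fit

    def test_unresolved_amplitude_censored(self):
        from dataclasses import replace

        points = _model_curve(0.25, 0.15, 700e-6, sem=0.002)
        fit = fit_decay(points, n_boot=50, seed=4, auto_censor=False)
        weak = replace(fit, sigma_amplitude=fit.amplitude / 1.5)
        assert censor_slow(weak).censored

    def test_bound_beyond_window_rejected(self):
        points = _model_curve(0.25, 0.15, 700e-6, sem=0.002)
        fit = fit_decay(points, n_boot=10, seed=0, auto_censor=False)
        with pytest.raises(ValueError):
            censor_slow(fit, t_max_window=20e-3, bound=30e-3)


class TestWeightedAverage:
    def test_published_two_replicate_row(self):
        summary = weighted_average([(1041, 215), (699, 27)])
        assert summary.tau2_mean == pytest.approx(704, abs=1)
        assert summary.sigma == pytest.approx(27, abs=1)

    def test_single_replicate_identity(self):
        summary = weighted_average([(634, 24)])
        assert summary.tau2_mean == 634
        assert summary.sigma == 24

    def test_equal_sigma_limit(self):
        summary = weighted_average([(600, 40), (700, 40)])
        assert summary.tau2_mean == pytest.approx(650)
        assert summary.sigma == pytest.approx(40 / np.sqrt(2))

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(ValueError):
            weighted_average([(600, 0.0)])
        with pytest.raises(ValueError):
            weighted_average([])

    @given(
        st.lists(
            st.tuples(st.floats(10, 5000), st.floats(1, 500)),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=200, derandomize=True)
    def test_convex_hull_and_sigma_bound(self, reps):
        summary = weighted_average(reps)
        taus = [t for t, _ in reps]
        sigmas = [s for _, s in reps]
        assert min(taus) - 1e-9 <= summary.tau2_mean <= max(taus) + 1e-9
        assert summary.sigma <= min(sigmas) + 1e-12
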