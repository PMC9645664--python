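"""Exponential decay fitting, BIC selection, intervals, bootstrap."""

import numpy as np
import pytest

from reachadapt import decayfit as dfit
from reachadapt.synthetic_data import generate_decay_cohort

X75 = np.arange(1, 76, dtype=float)


def _single(x, a0, a1, b1):
    return a0 + a1 * np.exp(b1 * x)


def _dual(x, a0, a1, b1, a2, b2):
    return a0 + a1 * np.exp(b1 * x) + a2 * np.exp(b2 * x)


class TestSingleRate:
    def test_noise_free_recovery(self):
        y = _single(X75, 6.0, 20.0, -0.05)
        f = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
        assert f.converged
        np.testing.assert_allclose(f.params, [6.0, 20.0, -0.05], atol=1e-6)

    def test_constant_series_degenerates_gracefully(self):
        y = np.full(20, 4.2)
        f = dfit.fit_single_rate(dfit.DecaySeries(np.arange(1, 21, dtype=float), y))
        assert f.alpha0 + f.alpha1 * np.exp(f.beta1) == pytest.approx(4.2, abs=1e-6)
        assert abs(f.alpha1) < 1e-6 or abs(f.beta1) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dfit.fit_single_rate(dfit.DecaySeries(np.arange(1.0, 4.0), np.zeros(3)))


class TestDualRate:
    def test_noise_free_recovery_well_separated(self):
        y = _dual(X75, 0.145, 0.05, -0.02, 0.05, -0.8)
        f = dfit.fit_dual_rate(dfit.DecaySeries(X75, y))
        assert f.converged
        assert f.beta1 == pytest.approx(-0.02, abs=1e-4)
        assert f.beta2 == pytest.approx(-0.8, abs=1e-4)

    def test_output_ordered_slow_then_fast(self):
        y = _dual(X75, 0.1, 0.03, -0.6, 0.04, -0.01)  # components swapped
        f = dfit.fit_dual_rate(dfit.DecaySeries(X75, y))
        assert abs(f.beta2) > abs(f.beta1)

    def test_single_generated_data_degenerate_second_component(self, rng):
        y = _single(X75, 6.0, 20.0, -0.05) + rng.normal(0, 0.5, X75.size)
        s = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
        d = dfit.fit_dual_rate(dfit.DecaySeries(X75, y))
        sel, delta = dfit.select_model(s, d)
        assert sel.model == "single"
        assert delta > 0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            dfit.fit_dual_rate(dfit.DecaySeries(np.arange(1.0, 6.0), np.zeros(5)))


class TestBic:
    def test_closed_form_value(self):
        f = dfit.DecayFit(
            model="single", alpha0=0, alpha1=0, beta1=0,
            n_obs=100, k_params=3, rss=100.0, converged=True,
        )
        assert dfit.bic(f) == pytest.approx(3 * np.log(100), abs=1e-12)

    def test_extra_parameter_costs_ln_n(self):
        common = dict(alpha0=0, alpha1=0, beta1=0, n_obs=50, rss=10.0, converged=True)
        f3 = dfit.DecayFit(model="single", k_params=3, **common)
        f5 = dfit.DecayFit(model="dual", alpha2=0, beta2=0, k_params=5, **common)
        assert dfit.bic(f5) - dfit.bic(f3) == pytest.approx(2 * np.log(50), abs=1e-12)

    def test_halved_rss_drops_n_ln2(self):
        a = dfit.DecayFit(model="single", alpha0=0, alpha1=0, beta1=0,
                          n_obs=80, k_params=3, rss=8.0, converged=True)
        b = dfit.DecayFit(model="single", alpha0=0, alpha1=0, beta1=0,
                          n_obs=80, k_params=3, rss=4.0, converged=True)
        assert dfit.bic(a) - dfit.bic(b) == pytest.approx(80 * np.log(2), abs=1e-9)

    def test_formula_audit_on_fitted_object(self, rng):
        y = _single(X75, 2.0, 5.0, -0.1) + rng.normal(0, 0.1, X75.size)
        f = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
        direct = X75.size * np.log(np.sum(f.residuals**2) / X75.size) + 3 * np.log(X75.size)
        assert f.bic == pytest.approx(direct, abs=1e-9)

    def test_zero_rss_guarded(self):
        f = dfit.DecayFit(model="single", alpha0=0, alpha1=0, beta1=0,
                          n_obs=10, k_params=3, rss=0.0, converged=True)
        assert np.isfinite(dfit.bic(f))


class TestSelection:
    def test_dual_data_selects_dual(self, rng):
        y = _dual(X75, 0.145, 0.05, -0.02, 0.05, -0.8) + rng.normal(0, 0.002, X75.size)
        s = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
        d = dfit.fit_dual_rate(dfit.DecaySeries(X75, y))
        sel, delta = dfit.select_model(s, d)
        assert sel.model == "dual" and delta < 0

    def test_tie_breaks_toward_single(self):
        common = dict(alpha0=0, alpha1=0, beta1=0, n_obs=50, rss=10.0, converged=True)
        s = dfit.DecayFit(model="single", k_params=3, **common)
        d = dfit.DecayFit(model="dual", alpha2=0, beta2=0, k_params=3, **common)
        sel, delta = dfit.select_model(s, d)
        assert sel is s and delta == 0

    def test_unconverged_dual_falls_back_to_single(self):
        s = dfit.DecayFit(model="single", alpha0=0, alpha1=0, beta1=0,
                          n_obs=50, k_params=3, rss=10.0, converged=True)
        d = dfit.DecayFit(model="dual", alpha0=0, alpha1=0, beta1=0, alpha2=0,
                          beta2=0, n_obs=50, k_params=5, rss=1.0, converged=False)
        sel, delta = dfit.select_model(s, d)
        assert sel is s and np.isnan(delta)
        with pytest.raises(dfit.FitError):
            dfit.select_model(None, d)

    def test_selection_accuracy_improves_as_noise_vanishes(self, rng):
        """Model-selection consistency: the right generator wins almost
        always at low noise, for both generating families."""
        accs = []
        for sd in (0.5, 0.01):
            hits = 0
            for _ in range(20):
                ys = _single(X75, 6, 20, -0.05) + rng.normal(0, sd, X75.size)
                yd = _dual(X75, 0.145, 5.0, -0.02, 5.0, -0.8) + rng.normal(0, sd, X75.size)
                s, d = (dfit.fit_single_rate(dfit.DecaySeries(X75, ys)),
                        dfit.fit_dual_rate(dfit.DecaySeries(X75, ys)))
                hits += dfit.select_model(s, d)[0].model == "single"
                s, d = (dfit.fit_single_rate(dfit.DecaySeries(X75, yd)),
                        dfit.fit_dual_rate(dfit.DecaySeries(X75, yd)))
                hits += dfit.select_model(s, d)[0].model == "dual"
            accs.append(hits / 40)
        assert accs[-1] >= 0.95
        assert accs[-1] >= accs[0] - 0.05


class TestWaldIntervals:
    def test_widths_shrink_with_noise(self, rng):
        widths = []
        for sd in (0.5, 0.05):
            y = _single(X75, 6, 20, -0.05) + rng.normal(0, sd, X75.size)
            f = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
            lo, hi = dfit.parameter_ci(f)["beta1"]
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_levels_nested(self, rng):
        y = _single(X75, 6, 20, -0.05) + rng.normal(0, 0.3, X75.size)
        f = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
        ci95 = dfit.parameter_ci(f, 0.95)
        ci99 = dfit.parameter_ci(f, 0.99)
        for name in ci95:
            assert ci99[name][0] <= ci95[name][0] <= ci95[name][1] <= ci99[name][1]

    def test_coverage_near_nominal(self):
        """~95% coverage of the true rate over repeated noisy series."""
        rng = np.random.default_rng(7)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            y = _single(X75, 6, 20, -0.05) + rng.normal(0, 0.4, X75.size)
            f = dfit.fit_single_rate(dfit.DecaySeries(X75, y))
            lo, hi = dfit.parameter_ci(f)["beta1"]
            hits += lo <= -0.05 <= hi
        assert hits / n_rep == pytest.approx(0.95, abs=0.04)


class TestBootstrap:
    def test_seeded_reproducibility(self):
        x, Y, _ = generate_decay_cohort(n_participants=10, seed=4)
        series = dfit.DecaySeries.from_cohort(x, Y)
        b1 = dfit.bootstrap_decay(series, n_iter=50, seed=9, model="dual")
        b2 = dfit.bootstrap_decay(series, n_iter=50, seed=9, model="dual")
        np.testing.assert_array_equal(b1.draws, b2.draws)

    def test_identical_participants_collapse_to_point_fit(self):
        y = _single(X75, 6, 20, -0.05)
        Y = np.tile(y, (6, 1))
        series = dfit.DecaySeries.from_cohort(X75, Y)
        point = dfit.fit_single_rate(series)
        boot = dfit.bootstrap_decay(series, n_iter=20, seed=0, model="single")
        for draw in boot.draws:
            np.testing.assert_allclose(draw, point.params, atol=1e-5)

    def test_interval_covers_truth_on_synthetic_cohorts(self):
        """The bootstrap 95% interval covers the generating rates in the
        vast majority of replicate cohorts."""
        hits = 0
        for seed in range(6):
            x, Y, truth = generate_decay_cohort(n_participants=18, seed=seed)
            series = dfit.DecaySeries.from_cohort(x, Y)
            boot = dfit.bootstrap_decay(series, n_iter=100, seed=seed, model="dual")
            assert boot.discarded_fraction <= 0.1
            hits += (
                boot.ci["beta1"][0] <= truth["beta1"] <= boot.ci["beta1"][1]
                and boot.ci["beta2"][0] <= truth["beta2"] <= boot.ci["beta2"][1]
            )
        assert hits >= 5

    def test_needs_participant_matrix(self):
        series = dfit.DecaySeries(X75, _single(X75, 6, 20, -0.05))
        with pytest.raises(ValueError):
            dfit.bootstrap_decay(series, n_iter=10, seed=0)
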