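"""MM/Haldane nonlinear least-squares fitting and model selection."""

import numpy as np
import pytest

from nitrotherm import (KineticDataset, KineticParams, derive_kinetics, fit_haldane, fit_mm,
                        haldane_rate, mm_rate, select_model)
from nitrotherm.fitting import FitResult


def dataset(s_grid, fun, reps=1, noise=0.0, rng=None, guild="AOB"):
    obs = []
    for _ in range(reps):
        for s in s_grid:
            v = fun(float(s))
            if noise > 0:
                v = max(v * (1.0 + noise * rng.standard_normal()), 0.0)
            obs.append((float(s), v))
    return KineticDataset("org", guild, 30.0, tuple(obs))


MM_GRID = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


class TestFitMM:
    def test_noiseless_round_trip(self):
        truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        fit = fit_mm(dataset(MM_GRID, lambda s: mm_rate(truth, s)))
        assert fit.converged
        assert fit.params.vmax == pytest.approx(51.5, rel=1e-6)
        assert fit.params.km == pytest.approx(73.7, rel=1e-6)

    def test_degenerate_saturation_flags_km(self):
        ds = dataset(MM_GRID, lambda s: 12.0)
        fit = fit_mm(ds)
        assert fit.params.vmax == pytest.approx(12.0, rel=1e-3)
        assert any("km" in w for w in fit.warnings)

    def test_noisy_median_recovery(self):
        """5% multiplicative noise: median estimates stay close to truth."""
        truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        vm, km = [], []
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            fit = fit_mm(dataset(MM_GRID, lambda s: mm_rate(truth, s), reps=3,
                                 noise=0.05, rng=rng))
            vm.append(fit.params.vmax)
            km.append(fit.params.km)
        assert abs(np.median(vm) - 51.5) / 51.5 < 0.02
        assert abs(np.median(km) - 73.7) / 73.7 < 0.10

    def test_scale_equivariance(self):
        truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        base = fit_mm(dataset(MM_GRID, lambda s: mm_rate(truth, s)))
        scaled = fit_mm(dataset(MM_GRID, lambda s: 10.0 * mm_rate(truth, s)))
        assert scaled.params.vmax == pytest.approx(10.0 * base.params.vmax, rel=1e-8)
        assert scaled.params.km == pytest.approx(base.params.km, rel=1e-8)

    def test_fitted_efficiency_consistent(self):
        truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        fit = fit_mm(dataset(MM_GRID, lambda s: mm_rate(truth, s)))
        d = derive_kinetics(fit.params)
        assert d.catalytic_efficiency == fit.params.vmax / fit.params.km


H_GRID = tuple(np.geomspace(10, 20000, 12))


class TestFitHaldane:
    truth = KineticParams("org", "NH3_total", 30.0, 100.0, 50.0, 2000.0)

    def test_noiseless_round_trip(self):
        fit = fit_haldane(dataset(H_GRID, lambda s: haldane_rate(self.truth, s)))
        assert fit.model == "Haldane"
        assert fit.params.vmax == pytest.approx(100.0, rel=1e-5)
        assert fit.params.km == pytest.approx(50.0, rel=1e-5)
        assert fit.params.ki == pytest.approx(2000.0, rel=1e-5)

    def test_mm_data_downgrades_to_mm(self):
        mm_truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        fit = fit_haldane(dataset(MM_GRID, lambda s: mm_rate(mm_truth, s)))
        assert fit.model == "MM"
        assert fit.params.ki is None
        assert any("no_detectable_inhibition" in w for w in fit.warnings)

    def test_unsampled_optimum_not_claimed(self):
        """On a noisy design with no concentrations near sqrt(Km·Ki),
        inhibition is either flagged unidentifiable or not reported at all."""
        weak = KineticParams("org", "NH3_total", 30.0, 100.0, 50.0, 2e6)  # s_opt = 1e4
        rng = np.random.default_rng(8)
        fit = fit_haldane(dataset(MM_GRID, lambda s: haldane_rate(weak, s),
                                  reps=3, noise=0.05, rng=rng))
        assert (fit.model == "MM"
                or any("ki_unidentifiable" in w for w in fit.warnings))

    def test_needs_five_concentrations(self):
        with pytest.raises(ValueError, match="5"):
            fit_haldane(dataset((5.0, 10.0, 25.0, 50.0), lambda s: s))


class TestRoundTripProperty:
    def test_random_parameter_draws(self):
        """Noiseless generate-and-fit recovers parameters over wide ranges."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            vmax = float(10 ** rng.uniform(0, 3))
            km = float(10 ** rng.uniform(0, 4))
            ki = float(10 ** rng.uniform(2, 6)) * km ** 0  # µM
            p_mm = KineticParams("org", "NO2", 30.0, vmax, km)
            grid = tuple(np.geomspace(km / 30, km * 100, 10))
            fit = fit_mm(dataset(grid, lambda s: mm_rate(p_mm, s), guild="NOB"))
            assert fit.params.vmax == pytest.approx(vmax, rel=1e-5)
            assert fit.params.km == pytest.approx(km, rel=1e-5)
            if ki > 10 * km:  # identifiable inhibition designs only
                p_h = KineticParams("org", "NO2", 30.0, vmax, km, ki)
                s_opt = float(np.sqrt(km * ki))
                grid_h = tuple(np.geomspace(km / 30, 30 * s_opt, 12))
                fit_h = fit_haldane(dataset(grid_h, lambda s: haldane_rate(p_h, s), guild="NOB"))
                assert fit_h.params.vmax == pytest.approx(vmax, rel=1e-5)
                assert fit_h.params.km == pytest.approx(km, rel=1e-5)
                assert fit_h.params.ki == pytest.approx(ki, rel=1e-5)


class TestSelectModel:
    def test_haldane_data_selects_haldane(self):
        truth = KineticParams("org", "NH3_total", 30.0, 100.0, 50.0, 2000.0)
        wins = 0
        n = 40
        for seed in range(n):
            rng = np.random.default_rng(2000 + seed)
            ds = dataset(H_GRID, lambda s: haldane_rate(truth, s), reps=3, noise=0.05, rng=rng)
            if select_model(fit_mm(ds), fit_haldane(ds)) == "Haldane":
                wins += 1
        assert wins / n >= 0.95

    def test_selection_follows_aic_rule(self):
        """On MM-generated noisy data the choice is exactly the stated rule:
        Haldane only with an AIC margin above 2 and an in-bounds, reported Ki."""
        truth = KineticParams("org", "NH3_total", 30.0, 51.5, 73.7)
        mm_chosen = 0
        n = 40
        for seed in range(n):
            rng = np.random.default_rng(3000 + seed)
            ds = dataset(MM_GRID, lambda s: mm_rate(truth, s), reps=3, noise=0.05, rng=rng)
            mm, h = fit_mm(ds), fit_haldane(ds)
            choice = select_model(mm, h)
            expected = ("Haldane" if h.model == "Haldane" and h.converged
                        and mm.aic - h.aic > 2.0 else "MM")
            assert choice == expected
            mm_chosen += choice == "MM"
        assert mm_chosen / n > 0.5  # parsimony dominates on MM data

    def test_tie_goes_to_mm(self):
        p = KineticParams("org", "NO2", 30.0, 10.0, 10.0, 100.0)
        mm = FitResult(p, {}, 1.0, -10.0, True, "MM")
        h = FitResult(p, {}, 1.0, -10.0, True, "Haldane")
        assert select_model(mm, h) == "MM"


class TestDatasetValidation:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            KineticDataset("o", "AOB", 30.0, ((1.0, -0.5), (2.0, 1.0), (3.0, 1.0), (4.0, 1.0)))

    def test_distinct_concentration_floor(self):
        with pytest.raises(ValueError, match="4 distinct"):
            KineticDataset("o", "AOB", 30.0, ((1.0, 0.5), (1.0, 1.0), (2.0, 1.0), (3.0, 1.0)))
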