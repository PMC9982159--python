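import dataclasses

import numpy as np
import pandas as pd
import pytest

from heatmorb import fitting as ft
from heatmorb import risk_model as rm
from heatmorb import synthetic_data as sd
from heatmorb.errors import InsufficientHistoryError, SingularDesignError
from heatmorb.io import SeasonDataset, split_seasons


@pytest.fixture(scope="module")
def temp_seasons():
    """7 noiseless seasons generated from the default temperature model."""
    sc = sd.WeatherScenario(n_years=7, seed=3)
    spec = sd.default_true_model("average_temperature", noise="none")
    return sd.make_dataset(sc, spec, seed=0), spec


@pytest.fixture(scope="module")
def core_data(hot_exposure, age_pyramid):
    """Exposure + noiseless counts for the core-temperature model."""
    spec = sd.default_true_model("core_temperature_increase", noise="none")
    counts = sd.generate_patient_counts(hot_exposure, age_pyramid, spec)
    seasons = split_seasons(hot_exposure, counts, spec.population, age_pyramid)
    return seasons, spec


def design_for(seasons, spec, location):
    loc = getattr(spec.params, location)
    cfg = ft.FitConfig.for_input(loc.input_kind, location, J=loc.J or 40)
    return ft.build_design(seasons, cfg, location), cfg


class TestFitScaleOffset:
    def test_noiseless_recovery(self, temp_seasons):
        seasons, spec = temp_seasons
        design, cfg = design_for(seasons, spec, "indoor")
        true = spec.params.indoor
        k = true.f * design["A"].to_numpy() + true.g
        a, l = ft.fit_scale_offset(design, k, cfg)
        assert a == pytest.approx(true.a, rel=1e-6)
        assert l == pytest.approx(true.l, rel=1e-6)

    def test_zero_counts_zero_exposure_flagged(self):
        design = pd.DataFrame(
            {"u": np.zeros(20), "A": np.zeros(20), "S": 250.0, "y": np.zeros(20)}
        )
        cfg = ft.FitConfig.for_input("sweating", "indoor", J=3)
        a, l = ft.fit_scale_offset(design, k=np.ones(20), cfg=cfg)
        assert a == 0.0
        assert l == -1.0

    def test_doubling_counts_doubles_a(self, core_data):
        seasons, spec = core_data
        design, cfg = design_for(seasons, spec, "indoor")
        true = spec.params.indoor
        k = true.f * design["A"].to_numpy() + true.g
        a1, l1 = ft.fit_scale_offset(design, k, cfg)
        doubled = design.assign(y=2 * design["y"])
        a2, l2 = ft.fit_scale_offset(doubled, k, cfg)
        assert a2 == pytest.approx(2 * a1, rel=1e-9)
        assert l1 == l2 == -1.0

    def test_constant_exposure_singular(self):
        design = pd.DataFrame(
            {"u": np.ones(20), "A": np.ones(20), "S": 250.0, "y": np.ones(20)}
        )
        cfg = ft.FitConfig(input_kind="average_temperature", J=3, l_policy="free")
        with pytest.raises(SingularDesignError):
            ft.fit_scale_offset(design, k=np.zeros(20), cfg=cfg)


class TestFitAdaptation:
    def test_noiseless_recovery(self, temp_seasons):
        seasons, spec = temp_seasons
        design, cfg = design_for(seasons, spec, "indoor")
        true = spec.params.indoor
        f, g = ft.fit_adaptation(
            design, true.a, true.l, cfg, start=(true.f * 1.2, true.g * 0.9)
        )
        assert f == pytest.approx(true.f, rel=1e-4)
        assert g == pytest.approx(true.g, rel=1e-4)

    def test_f_absent_reduced_model(self, core_data):
        seasons, spec = core_data
        design, cfg = design_for(seasons, spec, "outdoor")
        true = spec.params.outdoor
        f, g = ft.fit_adaptation(design, true.a, true.l, cfg, start=(None, true.g * 1.1))
        assert f is None
        assert g == pytest.approx(true.g, rel=1e-6)

    def test_null_slope_recovered(self, hot_exposure, age_pyramid):
        spec = sd.default_true_model(
            "core_temperature_increase", noise="none", f_indoor=-0.0
        )
        counts = sd.generate_patient_counts(hot_exposure, age_pyramid, spec)
        seasons = split_seasons(hot_exposure, counts, spec.population, age_pyramid)
        cfg = ft.FitConfig.for_input("core_temperature_increase", "indoor", J=40)
        design = ft.build_design(seasons, cfg, "indoor")
        true = spec.params.indoor
        f, g = ft.fit_adaptation(design, true.a, true.l, cfg, start=(0.0, true.g))
        assert abs(f) < 1e-6

    def test_constant_adaptation_singular(self):
        design = pd.DataFrame(
            {
                "u": np.linspace(1, 2, 20),
                "A": np.ones(20),
                "S": 250.0,
                "y": np.linspace(1, 5, 20),
            }
        )
        cfg = ft.FitConfig.for_input("core_temperature_increase", "indoor", J=3)
        with pytest.raises(SingularDesignError):
            ft.fit_adaptation(design, 1.0, -1.0, cfg, start=(0.0, 1.0))


class TestFitIterative:
    @pytest.mark.parametrize("location", ["indoor", "outdoor"])
    def test_noiseless_recovery_temperature(self, temp_seasons, location):
        seasons, spec = temp_seasons
        design, cfg = design_for(seasons, spec, location)
        fit = ft.fit_iterative(design, cfg)
        assert fit.converged
        assert fit.iterations <= 10
        true = getattr(spec.params, location)
        for name in ("a", "l", "f", "g"):
            assert getattr(fit.params, name) == pytest.approx(
                getattr(true, name), rel=1e-4
            )

    def test_noiseless_recovery_core(self, core_data):
        seasons, spec = core_data
        design, cfg = design_for(seasons, spec, "indoor")
        fit = ft.fit_iterative(design, cfg)
        true = spec.params.indoor
        assert fit.params.a == pytest.approx(true.a, rel=1e-4)
        assert fit.params.f == pytest.approx(true.f, rel=1e-4)
        assert fit.params.g == pytest.approx(true.g, rel=1e-4)
        assert fit.params.l == -1.0

    def test_objective_trace_monotone(self, core_data):
        seasons, spec = core_data
        design, cfg = design_for(seasons, spec, "indoor")
        # make it work for its convergence: Poisson-noised counts
        rng = np.random.default_rng(0)
        noisy = design.assign(y=rng.poisson(np.maximum(design["y"], 0.0)))
        fit = ft.fit_iterative(noisy, cfg)
        trace = np.array(fit.objective_trace)
        assert (np.diff(trace) <= 1e-9 * trace[:-1] + 1e-9).all()

    def test_fixed_point_single_sweep(self, temp_seasons):
        # from the converged solution, one more sweep leaves it unchanged
        seasons, spec = temp_seasons
        design, cfg = design_for(seasons, spec, "indoor")
        fit = ft.fit_iterative(design, cfg)
        p = fit.params
        k = p.f * design["A"].to_numpy() + p.g
        a, l = ft.fit_scale_offset(design, k, cfg)
        f, g = ft.fit_adaptation(design, a, l, cfg, start=(p.f, p.g))
        assert a == pytest.approx(p.a, rel=1e-6)
        assert l == pytest.approx(p.l, rel=1e-6)
        assert f == pytest.approx(p.f, rel=1e-4)
        assert g == pytest.approx(p.g, rel=1e-6)

    def test_too_few_days(self, temp_seasons):
        seasons, spec = temp_seasons
        design, cfg = design_for(seasons, spec, "indoor")
        with pytest.raises(InsufficientHistoryError):
            ft.fit_iterative(design.iloc[:5], cfg)


class TestLoocvByYear:
    def test_identical_years_identical_params(self, core_data):
        seasons, spec = core_data
        # duplicate one season across 5 synthetic years (shifted dates)
        base = seasons[0]
        years = []
        for i in range(5):
            shift = pd.DateOffset(years=i)
            expo = base.exposure.assign(date=pd.to_datetime(base.exposure["date"]) + shift)
            counts = base.counts.assign(date=pd.to_datetime(base.counts["date"]) + shift)
            years.append(
                SeasonDataset(
                    year=2013 + i, exposure=expo, counts=counts,
                    population=base.population, age=base.age,
                )
            )
        cfg = ft.FitConfig.for_input("core_temperature_increase", "indoor", J=40)
        result = ft.loocv_by_year(years, cfg, "indoor")
        a_values = [f.params.a for f in result.folds]
        np.testing.assert_allclose(a_values, a_values[0], rtol=1e-9)
        true = spec.params.indoor
        assert result.averaged.a == pytest.approx(true.a, rel=1e-4)

    def test_fold_bookkeeping(self, temp_seasons):
        seasons, spec = temp_seasons
        cfg = ft.FitConfig.for_input("average_temperature", "indoor", J=40)
        result = ft.loocv_by_year(seasons, cfg, "indoor")
        assert len(result.folds) == len(seasons)
        assert sorted(f.year for f in result.folds) == [s.year for s in seasons]

    def test_noiseless_heldout_r2_is_one(self, temp_seasons):
        seasons, spec = temp_seasons
        cfg = ft.FitConfig.for_input("average_temperature", "outdoor", J=30)
        result = ft.loocv_by_year(seasons, cfg, "outdoor")
        for fold in result.folds:
            assert fold.r2 == pytest.approx(1.0, abs=1e-6)

    def test_averaged_is_mean(self, temp_seasons):
        seasons, spec = temp_seasons
        cfg = ft.FitConfig.for_input("average_temperature", "indoor", J=40)
        result = ft.loocv_by_year(seasons, cfg, "indoor")
        assert result.averaged.g == pytest.approx(
            np.mean([f.params.g for f in result.folds]), rel=1e-12
        )

    def test_needs_three_years(self, temp_seasons):
        seasons, spec = temp_seasons
        cfg = ft.FitConfig.for_input("average_temperature", "indoor", J=40)
        with pytest.raises(InsufficientHistoryError):
            ft.loocv_by_year(seasons[:2], cfg, "indoor")


class TestScanWindow:
    def test_table_bookkeeping(self, core_data):
        seasons, spec = core_data
        cfg = ft.FitConfig.for_input("core_temperature_increase", "indoor", J=10)
        table = ft.scan_adaptation_window(seasons, cfg, [10, 20, 30, 200], "indoor")
        assert len(table) <= 4
        assert list(table.columns) == ["J", "mean_r2"]
        assert 200 not in table["J"].to_numpy()

    def test_noiseless_argmax_at_true_J(self, core_data):
        seasons, spec = core_data
        cfg = ft.FitConfig.for_input("core_temperature_increase", "indoor", J=10)
        table = ft.scan_adaptation_window(seasons, cfg, [20, 40, 60], "indoor")
        assert table.loc[table["mean_r2"].idxmax(), "J"] == 40


class TestWarmStart:
    def test_reasonable_initialization(self, core_data):
        seasons, spec = core_data
        design, cfg = design_for(seasons, spec, "indoor")
        a, l, f, g = ft._warm_start(design, cfg)
        assert a > 0
        assert l == -1.0
        assert f == 0.0
        # g lands within an order of magnitude of truth
        assert 0.1 * spec.params.indoor.g < g < 10 * spec.params.indoor.g
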