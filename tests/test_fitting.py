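"""RMSE objective, evolutionary programming mechanics, case fitting."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oatkin.fitting import (
    CASE1_EP_SETTINGS,
    EPSettings,
    FitResult,
    TimeSeriesDataset,
    ep_optimize,
    fit_uptake_case,
    rank_cases,
    rmse,
    select_best_case,
    simulate_uptake_curve,
)
from oatkin.model import TransportParameters, UptakeCase


class TestRmse:
    def test_identical_series(self):
        assert rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        a = np.array([1.0, 5.0, 9.0])
        assert rmse(a, a + 0.7) == pytest.approx(0.7)

    def test_hand_computed_example(self):
        assert rmse([1.0, 2.0, 3.0], [2.0, 2.0, 5.0]) == pytest.approx(
            np.sqrt(5.0 / 3.0)
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0, 2.0, 3.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=20))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_nonnegative_and_zero_iff_identical(self, values):
        a = np.asarray(values)
        assert rmse(a, a) == 0.0
        perturbed = a + 1e-3
        assert rmse(a, perturbed) > 0.0


class TestTimeSeriesDataset:
    def _dataset(self):
        times = np.array([1.0, 2.0, 5.0])
        reps = np.array([[1.0, 1.2], [2.0, 2.2], [3.0, 3.2]])
        return TimeSeriesDataset(25.0, times, reps)

    def test_mean_values(self):
        np.testing.assert_allclose(self._dataset().mean_values, [1.1, 2.1, 3.1])

    def test_tidy_round_trip(self):
        ds = self._dataset()
        back = TimeSeriesDataset.from_frame(ds.to_frame())
        assert len(back) == 1
        np.testing.assert_allclose(back[0].replicate_values, ds.replicate_values)
        np.testing.assert_allclose(back[0].sample_times_min, ds.sample_times_min)
        assert back[0].initial_concentration == 25.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            TimeSeriesDataset(25.0, [2.0, 1.0], [[1.0], [1.0]])
        with pytest.raises(ValueError):
            TimeSeriesDataset(25.0, [1.0, 2.0], [[1.0], [-0.5]])


class TestEvolutionaryProgramming:
    def _bowl(self):
        return EPSettings(
            bounds={"a": (1e-2, 1e2), "b": (1e-1, 1e3)},
            initial_guess={"a": 1.0, "b": 1.0},
            generations=200,
            seed=3,
        )

    def test_recovers_quadratic_bowl_minimum(self):
        target = {"a": 10.0 ** 0.5, "b": 10.0 ** 1.2}

        def objective(p):
            return (np.log10(p["a"]) - 0.5) ** 2 + (np.log10(p["b"]) - 1.2) ** 2

        result = ep_optimize(objective, self._bowl())
        for name, expected in target.items():
            assert abs(result.parameters[name] - expected) / expected < 1e-3

    def test_same_seed_is_bitwise_deterministic(self):
        objective = lambda p: (np.log10(p["a"]) - 0.5) ** 2 + np.log10(p["b"]) ** 2
        settings_ = replace(self._bowl(), generations=30)
        r1 = ep_optimize(objective, settings_)
        r2 = ep_optimize(objective, settings_)
        assert r1.parameters == r2.parameters
        assert r1.objective == r2.objective
        np.testing.assert_array_equal(r1.trace, r2.trace)

    def test_never_evaluates_outside_bounds(self):
        seen = []

        def objective(p):
            seen.append(p)
            return (np.log10(p["a"]) - 0.5) ** 2

        settings_ = replace(self._bowl(), generations=25)
        ep_optimize(objective, settings_)
        for p in seen:
            assert 1e-2 <= p["a"] <= 1e2
            assert 1e-1 <= p["b"] <= 1e3

    def test_best_objective_non_increasing(self):
        objective = lambda p: (np.log10(p["a"]) + 1.0) ** 2 + (np.log10(p["b"]) - 2.0) ** 2
        result = ep_optimize(objective, replace(self._bowl(), generations=40))
        assert np.all(np.diff(result.trace) <= 0.0)

    def test_objective_failures_get_worst_fitness(self):
        def objective(p):
            if p["a"] > 1.0:  # half the box explodes
                raise RuntimeError("integration failed")
            return (np.log10(p["a"]) + 1.0) ** 2

        result = ep_optimize(objective, replace(self._bowl(), generations=30))
        assert result.fittable
        assert result.n_failed_evaluations > 0
        assert result.parameters["a"] <= 1.0

    def test_run_spread_across_repeated_runs(self):
        objective = lambda p: (np.log10(p["a"]) - 0.5) ** 2 + (np.log10(p["b"]) - 1.2) ** 2
        result = ep_optimize(objective, replace(self._bowl(), generations=120, runs=3))
        assert len(result.run_objectives) == 3
        assert result.objective == min(result.run_objectives)
        assert result.run_spread >= 0.0

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            EPSettings(bounds={"a": (1.0, 0.5)}, initial_guess={})
        with pytest.raises(ValueError):
            EPSettings(bounds={"a": (0.5, 2.0)}, initial_guess={"a": 10.0})
        with pytest.raises(ValueError):
            replace(CASE1_EP_SETTINGS, generations=0)


class TestFitUptakeCase:
    def test_objective_is_reproducible_from_parameters(
        self, noiseless_dataset_25, quick_ep
    ):
        fit = fit_uptake_case(UptakeCase.MASS_ACTION, noiseless_dataset_25, quick_ep)
        transport = TransportParameters(
            kf_uptake=fit.parameters["kf_uptake"],
            kf_dissociation=fit.parameters["kf_dissociation"],
            oat1_density_0=fit.parameters["oat1_density_0"],
        )
        sim = simulate_uptake_curve(
            transport, 25.0, noiseless_dataset_25.sample_times_min
        )
        assert rmse(noiseless_dataset_25.mean_values, sim) == pytest.approx(
            fit.objective, rel=1e-9
        )

    def test_mm_cases_free_only_vmax_km(self, noiseless_dataset_25, quick_ep):
        fit = fit_uptake_case(UptakeCase.MM_TIMES_OAT1, noiseless_dataset_25, quick_ep)
        assert set(fit.parameters) == {"vmax_case", "km_case"}
        assert fit.case is UptakeCase.MM_TIMES_OAT1


class TestSelectBestCase:
    def test_empty_fit_set_rejected(self, noiseless_dataset_25):
        with pytest.raises(ValueError):
            select_best_case({}, [noiseless_dataset_25])

    def test_unfittable_cases_excluded_from_ranking(self, noiseless_dataset_25):
        good = FitResult(
            parameters={"kf_uptake": 1.75e-5, "kf_dissociation": 4.18e-4,
                        "oat1_density_0": 1.15e7},
            objective=0.0, trace=np.zeros(1), run_objectives=[0.0],
            case=UptakeCase.MASS_ACTION,
        )
        bad = FitResult(
            parameters={}, objective=np.inf, trace=np.full(1, np.inf),
            run_objectives=[np.inf], fittable=False, case=UptakeCase.MICHAELIS_MENTEN,
        )
        selection = select_best_case(
            {UptakeCase.MASS_ACTION: good, UptakeCase.MICHAELIS_MENTEN: bad},
            [noiseless_dataset_25],
        )
        assert selection.ranking == [1]
        assert selection.best_case == 1

    def test_exact_tie_breaks_toward_simpler_kinetics(self):
        assert rank_cases({4: 0.5, 1: 0.5, 3: 0.5}) == [1, 3, 4]
        assert rank_cases({1: 0.9, 3: 0.5}) == [3, 1]

    def test_table_schema(self, noiseless_dataset_25):
        fit = FitResult(
            parameters={"kf_uptake": 1.75e-5, "kf_dissociation": 4.18e-4,
                        "oat1_density_0": 1.15e7},
            objective=0.0, trace=np.zeros(1), run_objectives=[0.0],
            case=UptakeCase.MASS_ACTION,
        )
        selection = select_best_case({1: fit}, [noiseless_dataset_25])
        assert isinstance(selection.table, pd.DataFrame)
        assert set(selection.table.columns) == {"case", "initial_conc_uM", "rmse_uM"}
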