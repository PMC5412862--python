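import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dasypop import (
    AccuracyReport,
    accuracy,
    aggregate_to_units,
    asr,
    compare,
    difference_map,
    unit_error_map,
)


class TestAccuracy:
    def test_perfect_prediction_scores_zero(self):
        s = pd.Series([10.0, 20.0], index=["a", "b"])
        rep = accuracy(s, s)
        assert rep.rmse == rep.mae == rep.pct_rmse == 0.0

    def test_hand_computed_example(self):
        obs = pd.Series([100.0, 200.0], index=["a", "b"])
        pred = pd.Series([110.0, 190.0], index=["a", "b"])
        rep = accuracy(pred, obs)
        assert rep.rmse == pytest.approx(10.0)
        assert rep.mae == pytest.approx(10.0)
        assert rep.pct_rmse == pytest.approx(100 * 10 / 150)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1e6, allow_nan=False),
                st.floats(1, 1e6, allow_nan=False),
            ),
            min_size=1,
            max_size=50,
        )
    )
    def test_rmse_dominates_mae(self, pairs):
        idx = [str(i) for i in range(len(pairs))]
        pred = pd.Series([p for p, _ in pairs], index=idx)
        obs = pd.Series([o for _, o in pairs], index=idx)
        rep = accuracy(pred, obs)
        assert rep.rmse >= rep.mae >= 0.0
        assert rep.pct_rmse == pytest.approx(100 * rep.rmse / rep.mean_obs)

    def test_matches_brute_force_recomputation(self, rng):
        idx = [f"u{i}" for i in range(500)]
        obs = pd.Series(rng.uniform(1, 1000, 500), index=idx)
        pred = obs + rng.normal(0, 50, 500)
        rep = accuracy(pred, obs)
        errs = [pred[i] - obs[i] for i in idx]
        assert rep.rmse == pytest.approx(
            np.sqrt(sum(e**2 for e in errs) / len(errs)), rel=1e-12
        )
        assert rep.mae == pytest.approx(
            sum(abs(e) for e in errs) / len(errs), rel=1e-12
        )

    def test_id_mismatch_lists_offenders(self):
        pred = pd.Series([1.0], index=["a"])
        obs = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="mismatch"):
            accuracy(pred, obs)


def _report(label, rmse, pct, mae):
    return AccuracyReport(
        label=label, rmse=rmse, pct_rmse=pct, mae=mae,
        n_units=79_618, mean_obs=100 * rmse / pct,
    )


class TestCompare:
    def test_published_difference_row_arithmetic(self):
        """Differencing two published per-model accuracy rows reproduces
        the published difference row to printed precision."""
        without = _report("without", 2284.14, 74.58, 1123.44)
        with_ = _report("with", 2213.99, 72.29, 1120.16)
        comp = compare(without, with_)
        assert comp.d_rmse == pytest.approx(70.15, abs=0.005)
        assert comp.d_pct_rmse == pytest.approx(2.29, abs=0.005)
        assert comp.d_mae == pytest.approx(3.28, abs=0.005)
        frame = comp.to_frame()
        assert list(frame["rmse"]) == [2284.14, 2213.99, 70.15]

    def test_identical_reports_difference_is_zero(self):
        rep = _report("m", 100.0, 50.0, 80.0)
        comp = compare(rep, rep)
        assert comp.d_rmse == comp.d_pct_rmse == comp.d_mae == 0.0


class TestAsr:
    def test_published_worked_examples(self):
        assert round(asr(3_364_560.063, 6_463), 1) == 22.8
        assert round(asr(3_362_579.043, 79_618), 2) == 6.50

    def test_unit_square(self):
        assert asr(100.0, 1) == 10.0

    @pytest.mark.parametrize("area,n", [(0, 1), (-5, 2), (10, 0)])
    def test_non_positive_inputs_rejected(self, area, n):
        with pytest.raises(ValueError):
            asr(area, n)


class TestAggregateToUnits:
    def test_truth_grid_reproduces_fine_census(self, truth):
        pred = aggregate_to_units(truth.true_population, truth.admin_fine)
        obs = pd.Series(
            truth.admin_fine.units["pop_count"].to_numpy(float),
            index=truth.admin_fine.units["unit_id"],
        )
        pd.testing.assert_series_equal(
            pred, obs, check_names=False, check_exact=True
        )

    def test_matches_brute_force_loop(self, truth, small_result):
        pop = small_result.with_events.population
        pred = aggregate_to_units(pop, truth.admin_fine)
        labels = truth.admin_fine.labels
        for lab, uid in enumerate(truth.admin_fine.units["unit_id"]):
            acc = 0.0
            for r in range(labels.shape[0]):
                for c in range(labels.shape[1]):
                    if labels[r, c] == lab:
                        acc += pop.data[r, c]
            assert pred[uid] == pytest.approx(acc, rel=1e-9)


class TestMaps:
    def test_difference_of_identical_maps_is_zero(self, small_result):
        pop = small_result.with_events.population
        out = difference_map(pop, pop)
        assert np.nanmax(np.abs(out.data)) == 0.0

    def test_antisymmetry(self, small_result):
        a = small_result.with_events.population
        b = small_result.without_events.population
        ab = difference_map(a, b)
        ba = difference_map(b, a)
        np.testing.assert_allclose(ab.data, -ba.data, equal_nan=True)

    def test_conserving_maps_difference_sums_to_zero(self, small_result):
        total = small_result.truth.config.pop_total
        s = np.nansum(small_result.pixel_difference.data)
        assert abs(s) <= 1e-6 * total

    def test_unit_error_map_matches_accuracy_residuals(self, truth, small_result):
        pred = small_result.with_events.predicted_fine
        obs = pd.Series(
            truth.admin_fine.units["pop_count"].to_numpy(float),
            index=truth.admin_fine.units["unit_id"],
        ).reindex(pred.index)
        err, raster = unit_error_map(pred, obs, truth.admin_fine)
        assert err.sum() == pytest.approx(pred.sum() - obs.sum(), abs=1e-6)
        # raster renders each unit's signed error over its pixels
        labels = truth.admin_fine.labels
        uid = truth.admin_fine.units["unit_id"].iloc[3]
        assert np.allclose(raster.data[labels == 3], err[uid])

    def test_perfect_prediction_error_map_is_zero(self, truth):
        obs = pd.Series(
            truth.admin_fine.units["pop_count"].to_numpy(float),
            index=truth.admin_fine.units["unit_id"],
        )
        err, raster = unit_error_map(obs, obs, truth.admin_fine)
        assert (err == 0).all()
        assert np.nanmax(np.abs(raster.data)) == 0.0
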