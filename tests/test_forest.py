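import dataclasses

import numpy as np
import pandas as pd
import pytest

from dasypop import (
    CovariateStack,
    RasterGrid,
    build_stacks,
    dasymetric_redistribute,
    fit_forest,
    predict_table,
    predict_weights,
    zonal_summarize,
)


def _toy_table(rng, n=200, noise=0.0):
    """Zonal-table stand-in where density is a known function of x1."""
    x1 = rng.uniform(0, 2, size=n)
    x2 = rng.normal(size=n)
    density = np.exp(x1) + noise * rng.normal(size=n)
    return pd.DataFrame(
        {
            "unit_id": [f"U{i}" for i in range(n)],
            "pop_count": (density * 10).astype(int),
            "area_km2": np.full(n, 10.0),
            "density": density,
            "x1": x1,
            "x2": x2,
        }
    )


class TestZonalSummarize:
    def test_uniform_layer_gives_constant_summary(self, truth):
        desc = truth.true_population
        stack = CovariateStack(desc, {"c": desc.copy_with(np.full(desc.shape, 3.5))})
        table = zonal_summarize(stack, truth.admin_coarse)
        assert (table["c"] == 3.5).all()
        assert (table["density"] >= 0).all()

    def test_matches_brute_force_loop(self, truth):
        stack, _ = build_stacks(truth, truth.config.cell_size)
        table = zonal_summarize(stack, truth.admin_coarse).set_index("unit_id")
        labels = truth.admin_coarse.labels
        ids = truth.admin_coarse.units["unit_id"]
        for name, layer in stack.layers.items():
            for lab, uid in enumerate(ids):
                acc, cnt = 0.0, 0
                for r in range(labels.shape[0]):
                    for c in range(labels.shape[1]):
                        v = layer.data[r, c]
                        if labels[r, c] == lab and np.isfinite(v):
                            acc += v
                            cnt += 1
                assert table.loc[uid, name] == pytest.approx(acc / cnt, rel=1e-12)

    def test_empty_admin_is_error(self, truth):
        stack, _ = build_stacks(truth, truth.config.cell_size)
        empty = dataclasses.replace(
            truth.admin_coarse,
            labels=np.full_like(truth.admin_coarse.labels, -1),
            units=truth.admin_coarse.units.iloc[:0],
        )
        with pytest.raises(ValueError):
            zonal_summarize(stack, empty)


class TestFitForest:
    def test_noise_free_signal_is_recovered(self, rng):
        fit = fit_forest(_toy_table(rng), n_trees=300, seed=0)
        assert fit.oob_var_explained > 0.9

    def test_deterministic_given_seed(self, rng):
        table = _toy_table(rng, n=80)
        a = fit_forest(table, n_trees=100, seed=5)
        b = fit_forest(table, n_trees=100, seed=5)
        pd.testing.assert_series_equal(a.importances, b.importances)
        assert a.oob_var_explained == b.oob_var_explained
        assert a.fingerprint == b.fingerprint

    def test_pure_noise_covariate_ranks_last(self):
        """A covariate with no relation to density should rank below every
        informative one in nearly all seeded fits."""
        wins = 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            table = _toy_table(r, n=150, noise=0.1)
            table["x2"] = np.exp(0.5 * table["x1"]) + 0.2 * r.normal(size=150)
            table["junk"] = r.normal(size=150)
            fit = fit_forest(table, n_trees=150, seed=seed)
            ranked = fit.importances.sort_values(ascending=False).index
            wins += ranked[-1] == "junk"
        assert wins >= 9

    def test_degenerate_tables_rejected(self, rng):
        table = _toy_table(rng, n=40)
        table["density"] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            fit_forest(table, n_trees=20, seed=0)
        with pytest.raises(ValueError, match="at least 10"):
            fit_forest(_toy_table(rng, n=5), n_trees=20, seed=0)

    def test_zero_density_units_excluded_from_log_fit(self, rng):
        table = _toy_table(rng, n=60)
        table.loc[:4, "density"] = 0.0
        fit = fit_forest(table, n_trees=50, seed=1)
        assert fit.n_units == 55


class TestPredictWeights:
    def test_constant_stack_gives_constant_weights(self, rng):
        table = _toy_table(rng, n=50)
        fit = fit_forest(table, n_trees=50, seed=2)
        desc = RasterGrid(np.zeros((5, 5)), 0.0, 1.0, 0.01)
        stack = CovariateStack(
            desc,
            {
                "x1": desc.copy_with(np.full((5, 5), 1.0)),
                "x2": desc.copy_with(np.full((5, 5), 0.0)),
            },
        )
        weights = predict_weights(fit, stack)
        assert np.unique(weights.data).size == 1
        assert (weights.data > 0).all()

    def test_nodata_pixel_propagates(self, rng):
        table = _toy_table(rng, n=50)
        fit = fit_forest(table, n_trees=50, seed=2)
        desc = RasterGrid(np.zeros((3, 3)), 0.0, 1.0, 0.01)
        x1 = np.ones((3, 3)); x1[1, 1] = np.nan
        stack = CovariateStack(
            desc,
            {"x1": desc.copy_with(x1), "x2": desc.copy_with(np.zeros((3, 3)))},
        )
        weights = predict_weights(fit, stack)
        assert np.isnan(weights.data[1, 1])
        assert np.isfinite(weights.data).sum() == 8

    def test_missing_layer_error_names_it(self, rng):
        fit = fit_forest(_toy_table(rng, n=50), n_trees=20, seed=2)
        desc = RasterGrid(np.zeros((3, 3)), 0.0, 1.0, 0.01)
        stack = CovariateStack(desc, {"x1": desc.copy_with(np.ones((3, 3)))})
        with pytest.raises(KeyError, match="x2"):
            predict_weights(fit, stack)

    def test_raster_and_tabular_paths_agree(self, rng):
        table = _toy_table(rng, n=50)
        fit = fit_forest(table, n_trees=50, seed=2)
        row = table.iloc[7]
        desc = RasterGrid(np.zeros((2, 2)), 0.0, 1.0, 0.01)
        stack = CovariateStack(
            desc,
            {
                "x1": desc.copy_with(np.full((2, 2), row["x1"])),
                "x2": desc.copy_with(np.full((2, 2), row["x2"])),
            },
        )
        raster_pred = predict_weights(fit, stack).data[0, 0]
        tab_pred = predict_table(fit, table.iloc[[7]])[0]
        assert raster_pred == pytest.approx(tab_pred, rel=1e-12)


class TestRedistribute:
    def test_uniform_weights_spread_uniformly(self, truth):
        admin = truth.admin_coarse
        weights = truth.true_population.copy_with(
            np.ones(truth.true_population.shape)
        )
        pop = dasymetric_redistribute(weights, admin)
        counts = admin.units["pop_count"].to_numpy(float)
        npix = admin.pixel_counts()
        for lab in range(admin.n_units):
            vals = pop.data[admin.labels == lab]
            assert np.allclose(vals, counts[lab] / npix[lab])

    def test_single_positive_pixel_takes_all(self):
        labels = np.zeros((2, 2), dtype=np.int32)
        units = pd.DataFrame(
            {"unit_id": ["A"], "parent_id": [""], "pop_count": [500],
             "area_km2": [1.0]}
        )
        from dasypop import AdminLayer

        admin = AdminLayer(labels, units, 0.0, 1.0, 0.01)
        w = np.zeros((2, 2)); w[0, 1] = 1.0
        pop = dasymetric_redistribute(RasterGrid(w, 0.0, 1.0, 0.01), admin)
        assert pop.data[0, 1] == 500
        assert pop.data.sum() == 500

    def test_conservation_on_fitted_weights(self, small_result):
        for arm in (small_result.with_events, small_result.without_events):
            sums = small_result.truth.admin_coarse.zonal_sum(arm.population)
            counts = small_result.truth.admin_coarse.units["pop_count"].to_numpy(float)
            assert (np.abs(sums - counts) <= 1e-6 * np.maximum(counts, 1)).all()

    def test_scale_equivariance_within_unit(self, truth, small_result):
        weights = small_result.with_events.weights
        admin = truth.admin_coarse
        scaled = weights.data.copy()
        scaled[admin.labels == 0] *= 7.3
        pop_a = dasymetric_redistribute(weights, admin)
        pop_b = dasymetric_redistribute(weights.copy_with(scaled), admin)
        np.testing.assert_allclose(pop_a.data, pop_b.data, rtol=1e-12)

    def test_zero_weight_unit_falls_back_to_uniform(self, truth):
        admin = truth.admin_coarse
        w = np.ones(truth.true_population.shape)
        w[admin.labels == 1] = 0.0
        pop = dasymetric_redistribute(truth.true_population.copy_with(w), admin)
        counts = admin.units["pop_count"].to_numpy(float)
        vals = pop.data[admin.labels == 1]
        assert np.allclose(vals, counts[1] / vals.size)
        assert pop.data[admin.labels >= 0].sum() == pytest.approx(counts.sum())
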