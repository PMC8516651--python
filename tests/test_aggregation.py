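"""Masking, population-weighted aggregation, counts, YLDs, burden classes."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from anemiamap.aggregation import (
    DisabilityWeights,
    aggregate_to_admin,
    apply_mask,
    classify_public_health_problem,
    compute_counts,
    compute_ylds,
    inequality_summaries,
    unit_population,
)
from anemiamap.grids import GridSpec

GRID = GridSpec(0.0, 0.0, 1.0, 2, 2, (2015,))


def _draws(values, n_draws=1):
    arr = np.broadcast_to(np.asarray(values, float), (n_draws, 1, 2, 2)).copy()
    return xr.Dataset(
        {"overall": (("draw", "year", "row", "col"), arr)},
        coords={"draw": np.arange(n_draws), "year": [2015],
                "row": [0, 1], "col": [0, 1]},
    )


class TestMask:
    def test_sparse_population_fully_masked(self):
        # 5 persons/km2 everywhere is below the 10-per-km2 threshold
        pop = np.full((2, 2), 5.0 * GRID.cell_area_km2)
        keep = apply_mask(pop, np.zeros((2, 2)), GRID)
        assert not keep.any()

    def test_dense_population_unmasked(self):
        pop = np.full((2, 2), 100.0 * GRID.cell_area_km2)
        keep = apply_mask(pop, np.zeros((2, 2)), GRID)
        assert keep.all()

    def test_barren_cells_masked(self):
        pop = np.full((2, 2), 100.0 * GRID.cell_area_km2)
        barren = np.zeros((2, 2), dtype=bool)
        barren[0, 0] = True
        keep = apply_mask(pop, barren, GRID)
        assert not keep[0, 0] and keep.sum() == 3

    def test_misaligned_raster_rejected(self):
        with pytest.raises(ValueError):
            apply_mask(np.ones((3, 3)), np.zeros((2, 2)), GRID)

    def test_masked_cells_excluded_from_aggregation(self):
        surf = _draws([[0.2, 0.9], [0.9, 0.9]])
        pop = np.full((2, 2), 100.0)
        keep = np.array([[True, False], [False, False]])
        agg = aggregate_to_admin(surf, pop, np.zeros((2, 2), int), keep)
        assert agg["overall"].values.item() == pytest.approx(0.2)


class TestAggregation:
    def test_weighted_mean_example(self):
        surf = _draws([[0.2, 0.4], [0.0, 0.0]])
        pop = np.array([[100.0, 300.0], [0.0, 0.0]])
        agg = aggregate_to_admin(surf, pop, np.zeros((2, 2), int))
        assert agg["overall"].values.item() == pytest.approx(0.35)

    def test_constant_surface(self):
        surf = _draws(0.3, n_draws=4)
        pop = np.array([[10.0, 20.0], [5.0, 100.0]])
        amap = np.array([[0, 0], [1, 1]])
        agg = aggregate_to_admin(surf, pop, amap)
        np.testing.assert_allclose(agg["overall"].values, 0.3)

    def test_hierarchy_consistency(self, rng):
        # aggregating admin2 results by population equals direct admin0
        surf = _draws(rng.uniform(0.1, 0.6, size=(2, 2)), n_draws=3)
        pop = rng.uniform(10, 100, size=(2, 2))
        admin2 = np.array([[0, 1], [2, 3]])
        admin0 = np.zeros((2, 2), int)
        a2 = aggregate_to_admin(surf, pop, admin2)
        a0 = aggregate_to_admin(surf, pop, admin0)
        pops = unit_population(pop, admin2)
        w = np.array([pops[u] for u in a2["unit"].values])
        recombined = (a2["overall"].values * w).sum(axis=-1) / w.sum()
        np.testing.assert_allclose(
            recombined, a0["overall"].values[..., 0], rtol=1e-12
        )

    def test_zero_population_unit_dropped(self):
        surf = _draws(0.3)
        pop = np.array([[10.0, 10.0], [0.0, 0.0]])
        amap = np.array([[0, 0], [1, 1]])
        agg = aggregate_to_admin(surf, pop, amap)
        assert list(agg["unit"].values) == [0]


class TestCountsAndYlds:
    def test_count_example(self):
        agg = xr.Dataset(
            {"overall": (("draw", "year", "unit"), np.full((1, 1, 1), 0.25))},
            coords={"draw": [0], "year": [2015], "unit": [0]},
        )
        counts = compute_counts(agg, pd.Series({0: 2000.0}))
        assert counts["overall"].values.item() == pytest.approx(500.0)

    def test_zero_prevalence_zero_count(self):
        agg = xr.Dataset(
            {"overall": (("draw", "year", "unit"), np.zeros((2, 1, 1)))},
            coords={"draw": [0, 1], "year": [2015], "unit": [0]},
        )
        counts = compute_counts(agg, pd.Series({0: 999.0}))
        assert float(counts["overall"].sum()) == 0.0

    def test_severity_counts_sum_to_overall(self, rng):
        p, pm, ps = rng.uniform(0.05, 0.9, size=(3, 4))
        mild, moderate, severe = p * pm, p * (1 - pm) * 0.6, p * (1 - pm) * 0.4
        data = {
            "overall": p, "mild": mild, "moderate": moderate, "severe": severe,
        }
        agg = xr.Dataset(
            {k: (("draw", "year", "unit"), v.reshape(4, 1, 1)) for k, v in data.items()},
            coords={"draw": range(4), "year": [2015], "unit": [0]},
        )
        counts = compute_counts(agg, pd.Series({0: 1234.0}))
        np.testing.assert_allclose(
            (counts["mild"] + counts["moderate"] + counts["severe"]).values,
            counts["overall"].values,
        )

    def test_yld_example_and_identity(self):
        dw = DisabilityWeights()
        counts = xr.Dataset(
            {
                "mild": (("draw",), [100.0]),
                "moderate": (("draw",), [200.0]),
                "severe": (("draw",), [500.0]),
            }
        )
        ylds = compute_ylds(counts, dw)
        assert ylds["severe"].values.item() == pytest.approx(500 * 0.149)
        assert ylds["total"].values.item() == pytest.approx(
            100 * 0.004 + 200 * 0.052 + 500 * 0.149
        )

    def test_dw_invariants(self):
        with pytest.raises(ValueError):
            DisabilityWeights(mild=0.1, moderate=0.05, severe=0.2)


class TestBurdenClass:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0, "none"), (0.04, "none"), (0.05, "low"), (0.19, "low"),
         (0.20, "medium"), (0.25, "medium"), (0.399, "medium"),
         (0.40, "high"), (0.9, "high")],
    )
    def test_bands(self, p, expected):
        assert classify_public_health_problem(p) == expected

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            classify_public_health_problem(1.2)


class TestInequality:
    def test_range_and_fold(self):
        a2 = pd.DataFrame(
            {"country": [0, 0], "unit": [0, 1], "mean": [0.1, 0.3]}
        )
        nat = pd.DataFrame({"country": [0], "mean": [0.2]})
        out = inequality_summaries(a2, nat)
        row = out.iloc[0]
        assert (row["min"], row["max"]) == (0.1, 0.3)
        assert row["fold_difference"] == pytest.approx(3.0)
        assert row["ratio_min"] == pytest.approx(0.5)
        assert row["ratio_max"] == pytest.approx(1.5)

    def test_all_equal(self):
        a2 = pd.DataFrame(
            {"country": [0, 0, 0], "unit": [0, 1, 2], "mean": [0.25] * 3}
        )
        nat = pd.DataFrame({"country": [0], "mean": [0.25]})
        row = inequality_summaries(a2, nat).iloc[0]
        assert row["fold_difference"] == pytest.approx(1.0)
        assert row["ratio_min"] == pytest.approx(1.0)

    def test_single_unit_country_skipped(self):
        a2 = pd.DataFrame({"country": [0], "unit": [0], "mean": [0.2]})
        nat = pd.DataFrame({"country": [0], "mean": [0.2]})
        assert inequality_summaries(a2, nat).empty
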