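"""Adjustment, WHO thresholding, cluster collapse and polygon resampling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from anemiamap.grids import GridSpec
from anemiamap.hemoglobin import (
    AdjustmentTables,
    PointsPerCellRule,
    SeverityThresholds,
    adjust_hemoglobin,
    classify_severity,
    collapse_to_clusters,
    resample_polygon,
)

TABLES = AdjustmentTables()
THR = SeverityThresholds()


class TestAdjustment:
    def test_sea_level_nonsmoker_identity(self):
        assert adjust_hemoglobin(12.3, 0.0, False, "raw", TABLES) == 12.3

    def test_elevation_decrement_1500m(self):
        # configured decrement at 1,500 m is 0.5 g/dl
        assert adjust_hemoglobin(13.0, 1500.0, False, "raw", TABLES) == pytest.approx(12.5)

    def test_smoking_decrement(self):
        assert adjust_hemoglobin(13.0, 0.0, True, "raw", TABLES) == pytest.approx(12.7)

    def test_fully_adjusted_passthrough(self):
        assert adjust_hemoglobin(9.9, 4000.0, True, "fully_adjusted", TABLES) == 9.9

    def test_partial_provenance_applies_missing_factor_only(self):
        # smoking already applied upstream: only elevation is subtracted
        out = adjust_hemoglobin(13.0, 1500.0, True, "smoking_adjusted", TABLES)
        assert out == pytest.approx(12.5)
        out = adjust_hemoglobin(13.0, 1500.0, True, "elevation_adjusted", TABLES)
        assert out == pytest.approx(12.7)

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError):
            adjust_hemoglobin(12.0, 0.0, False, "mystery", TABLES)

    def test_negative_result_clamped(self, caplog):
        out = adjust_hemoglobin(0.2, 4600.0, True, "raw", TABLES)
        assert out == pytest.approx(0.1)

    def test_table_invariants(self):
        with pytest.raises(ValueError):
            AdjustmentTables(elevation_bins=((100.0, 0.0), (1000.0, 0.2)))
        with pytest.raises(ValueError):
            AdjustmentTables(smoking_decrement=-0.1)


class TestClassification:
    @pytest.mark.parametrize(
        "hb,pregnant,expected",
        [
            # non-pregnant bands: severe <8.0, moderate 8.0-10.9,
            # mild 11.0-11.9, non-anemic >=12.0
            (7.9, False, "severe"),
            (8.0, False, "moderate"),
            (10.9, False, "moderate"),
            (11.0, False, "mild"),
            (11.5, False, "mild"),
            (11.9, False, "mild"),
            (12.0, False, "non_anemic"),
            (15.0, False, "non_anemic"),
            # pregnant bands shift down 1 g/dl
            (6.9, True, "severe"),
            (7.0, True, "moderate"),
            (9.9, True, "moderate"),
            (10.0, True, "mild"),
            (10.5, True, "mild"),
            (10.9, True, "mild"),
            (11.0, True, "non_anemic"),
        ],
    )
    def test_who_bands(self, hb, pregnant, expected):
        assert classify_severity(hb, pregnant, THR) == expected

    @given(st.floats(0.5, 20.0), st.booleans())
    def test_exactly_one_category(self, hb, pregnant):
        cat = classify_severity(hb, pregnant, THR)
        assert cat in ("non_anemic", "mild", "moderate", "severe")

    @given(st.lists(st.floats(0.5, 20.0), min_size=2, max_size=20), st.booleans())
    def test_severity_monotone_in_hemoglobin(self, hbs, pregnant):
        order = {"severe": 3, "moderate": 2, "mild": 1, "non_anemic": 0}
        hbs = np.sort(hbs)
        sev = [order[classify_severity(h, pregnant, THR)] for h in hbs]
        assert all(a >= b for a, b in zip(sev, sev[1:]))

    def test_threshold_invariants(self):
        with pytest.raises(ValueError):
            SeverityThresholds(non_pregnant=(11.0, 8.0, 12.0))


class TestCollapse:
    def _records(self, cats, year=2015, cluster="c1"):
        return pd.DataFrame(
            {
                "cluster_id": cluster,
                "lon": 1.0,
                "lat": 2.0,
                "year": year,
                "age": 30,
                "category": cats,
            }
        )

    def test_counts(self):
        df = self._records(
            ["mild"] * 3 + ["moderate"] * 2 + ["severe"] + ["non_anemic"] * 4
        )
        out = collapse_to_clusters(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["N"], row["anemic"], row["mild"], row["moderate"], row["severe"]) \
            == (10, 6, 3, 2, 1)
        assert row["weight"] == 1.0

    def test_empty_input(self):
        assert collapse_to_clusters(pd.DataFrame()).empty

    def test_two_years_two_observations(self):
        df = pd.concat(
            [self._records(["mild"] * 2, year=2015),
             self._records(["severe"] * 3, year=2016)]
        )
        out = collapse_to_clusters(df)
        assert len(out) == 2
        assert sorted(out["year"]) == [2015, 2016]

    def test_age_filter(self):
        df = self._records(["mild"] * 4)
        df.loc[:1, "age"] = 12  # under the 15-49 window
        out = collapse_to_clusters(df)
        assert out.iloc[0]["N"] == 2

    def test_roundtrip_recovers_generating_category(self, scenario, microdata):
        from anemiamap.hemoglobin import adjust_hemoglobin as adj
        from anemiamap.hemoglobin import classify_severity as cls

        adjusted = adj(
            microdata["raw_hb"], microdata["elevation"], microdata["smoker"],
            microdata["provenance"], scenario.adjustment_tables,
        )
        recovered = cls(adjusted, microdata["pregnant"], scenario.thresholds)
        assert (recovered == microdata["true_category"]).all()


class TestResample:
    GRID = GridSpec(0.0, 0.0, 1.0, 4, 4, (2010,))

    def _areal(self, pid=7, N=800):
        return {
            "polygon_id": pid, "year": 2010, "N": N,
            "anemic": 300, "mild": 150, "moderate": 120, "severe": 30,
        }

    def test_single_cell_polygon(self, rng):
        from shapely.geometry import box

        pop = np.ones((4, 4))
        out = resample_polygon(
            self._areal(), box(-0.5, -0.5, 0.5, 0.5), pop, self.GRID,
            PointsPerCellRule(), rng,
        )
        assert len(out) == 1
        assert out.iloc[0]["weight"] == 1.0
        assert (out.iloc[0]["lon"], out.iloc[0]["lat"]) == (0.0, 0.0)

    def test_weights_and_effective_sample_size(self, rng):
        from shapely.geometry import box

        pop = np.ones((4, 4))
        rule = PointsPerCellRule(cells_per_point=2)
        out = resample_polygon(
            self._areal(N=1000), box(-0.5, -0.5, 3.5, 3.5), pop, self.GRID, rule, rng
        )
        assert out["weight"].sum() == pytest.approx(1.0)
        assert (out["weight"] * out["N"]).sum() == pytest.approx(1000.0)

    def test_population_weighted_frequencies(self, rng):
        # two-cell polygon, populations 100/300: sampling probabilities .25/.75
        from shapely.geometry import box

        pop = np.zeros((4, 4))
        pop[0, 0], pop[0, 1] = 100.0, 300.0
        rule = PointsPerCellRule(cells_per_point=1, max_points=10000)
        draws = []
        for _ in range(5):
            out = resample_polygon(
                self._areal(), box(-0.5, -0.5, 1.5, 0.5), pop, self.GRID,
                PointsPerCellRule(cells_per_point=1, max_points=2000), rng,
            )
            draws.append(out)
        out = pd.concat(draws)
        frac = (out["lon"] == 1.0).mean()
        n = len(out)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(frac - 0.75) < 4 * se

    def test_uniform_population_frequencies(self, rng):
        from shapely.geometry import box

        pop = np.ones((4, 4))
        rule = PointsPerCellRule(cells_per_point=1, max_points=20000)
        out = resample_polygon(
            self._areal(), box(-0.5, -0.5, 3.5, 3.5), pop, self.GRID, rule, rng
        )
        # 16 equally likely cells; count per cell within 3 SE of uniform
        counts = out.groupby(["lon", "lat"]).size()
        k = len(out)
        expected = k / 16
        se = np.sqrt(k * (1 / 16) * (15 / 16))
        assert counts.sub(expected).abs().max() < 3 * se

    def test_zero_population_rejected(self, rng):
        from shapely.geometry import box

        with pytest.raises(ValueError):
            resample_polygon(
                self._areal(), box(-0.5, -0.5, 1.5, 1.5), np.zeros((4, 4)),
                self.GRID, PointsPerCellRule(), rng,
            )
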