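"""Path metrics and the permutation ANOVA / Dunn machinery."""

import numpy as np
import pandas as pd
import pytest

from trackiba.geo import AzimuthalEquidistant, great_circle_distance
from trackiba.metrics import (compare_metrics, dunn_test, individual_core_area,
                              max_distance, path_length_to_max, peranova)

PROJ = AzimuthalEquidistant(18.0, -33.5)
COLONY = (18.0, -33.5)


def _daily(lon, lat):
    n = len(lon)
    return pd.DataFrame({
        "timestamp": pd.date_range("2018-09-01T12:00", periods=n, freq="D",
                                   tz="UTC"),
        "lon": lon, "lat": lat, "gap": False})


class TestMaxDistance:
    def test_all_fixes_at_colony(self):
        d = max_distance(_daily([18.0] * 5, [-33.5] * 5), COLONY)
        assert d == 0.0

    def test_monotone_in_added_fixes(self):
        base = _daily([18.0, 18.5, 19.0], [-34.0, -34.0, -34.0])
        farther = _daily([18.0, 18.5, 19.0, 21.0], [-34.0] * 4)
        assert max_distance(farther, COLONY) >= max_distance(base, COLONY)

    def test_empty_track_errors(self):
        with pytest.raises(ValueError):
            max_distance(_daily([], []), COLONY)


class TestPathLength:
    def test_straight_outbound_equals_max_distance(self):
        lats = -33.5 - np.linspace(0.05, 1.0, 12)
        daily = _daily([18.0] * 12, lats)
        pl = path_length_to_max(daily, COLONY)
        md = max_distance(daily, COLONY)
        assert pl == pytest.approx(md, rel=1e-6)

    def test_zigzag_longer_than_displacement(self):
        lons = 18.0 + np.array([0.2, -0.2, 0.4, -0.4, 0.8])
        daily = _daily(lons, [-34.5] * 5)
        assert path_length_to_max(daily, COLONY) > max_distance(daily, COLONY)

    def test_matches_independent_segment_sum(self, rng):
        lon = 18.0 + np.cumsum(rng.normal(0, 0.05, 20))
        lat = -34.0 + np.cumsum(rng.normal(0, 0.05, 20))
        daily = _daily(lon, lat)
        # independent oracle: explicit loop over segments to the farthest fix
        d_all = [great_circle_distance(x, y, *COLONY) for x, y in zip(lon, lat)]
        k = int(np.argmax(d_all))
        expected = great_circle_distance(COLONY[0], COLONY[1], lon[0], lat[0])
        for i in range(k):
            expected += great_circle_distance(lon[i], lat[i],
                                              lon[i + 1], lat[i + 1])
        assert path_length_to_max(daily, COLONY) == pytest.approx(
            float(expected), rel=1e-9)


class TestCoreArea:
    def test_tight_cluster_matches_gaussian_closed_form(self):
        # coincident points: UD is the kernel itself, area(v) = -2*pi*h^2*ln(1-v)
        daily = _daily([18.0] * 30, [-34.5] * 30)
        area = individual_core_area(daily, PROJ, 54, h=7.0, cell=0.5)
        assert area == pytest.approx(-2 * np.pi * 49 * np.log(0.46), rel=0.02)

    def test_spread_increases_area(self, rng):
        lon1 = 18.0 + rng.normal(0, 0.1, 40)
        lat1 = -34.5 + rng.normal(0, 0.1, 40)
        a1 = individual_core_area(_daily(lon1, lat1), PROJ, 54)
        a2 = individual_core_area(
            _daily(18.0 + (lon1 - 18.0) * 2, -34.5 + (lat1 + 34.5) * 2),
            PROJ, 54)
        assert a2 > a1

    def test_core_smaller_than_distribution_range(self, rng):
        lon = 18.0 + rng.normal(0, 0.3, 50)
        lat = -34.5 + rng.normal(0, 0.3, 50)
        daily = _daily(lon, lat)
        assert (individual_core_area(daily, PROJ, 54)
                < individual_core_area(daily, PROJ, 90))

    def test_insufficient_positions(self):
        with pytest.raises(ValueError, match="at least 5"):
            individual_core_area(_daily([18.0] * 3, [-34.0] * 3), PROJ, 54)


class TestPeranova:
    def test_p_bounds(self, rng):
        vals = rng.normal(0, 1, 20)
        labels = ["a"] * 10 + ["b"] * 10
        _, p = peranova(vals, labels, n_perm=99, seed=0)
        assert 1.0 / 100 <= p <= 1.0

    def test_strong_shift_detected(self, rng):
        vals = np.concatenate([rng.normal(0, 1, 10), rng.normal(10, 1, 10)])
        labels = ["a"] * 10 + ["b"] * 10
        _, p = peranova(vals, labels, n_perm=5000, seed=0)
        assert p <= 0.001

    def test_null_calibration(self, rng):
        # under exchangeability the rejection rate stays near alpha
        rejections = 0
        n_rep = 200
        for r in range(n_rep):
            vals = rng.normal(0, 1, 16)
            labels = ["a"] * 8 + ["b"] * 8
            _, p = peranova(vals, labels, n_perm=99, seed=r)
            rejections += p <= 0.05
        assert 0.01 <= rejections / n_rep <= 0.10

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            peranova([1.0, 2.0], ["a", "a"], n_perm=10)


class TestDunn:
    def test_frozen_no_tie_example(self):
        # hand-derived: groups [1,2,3],[4,5,6],[7,8,9]; mean ranks 2,5,8;
        # pooled rank variance 7.5; z12 = -3/sqrt(5), z13 = -6/sqrt(5)
        vals = np.arange(1.0, 10.0)
        labels = np.repeat(["g1", "g2", "g3"], 3)
        out = dunn_test(vals, labels)
        r12 = out[(out.group1 == "g1") & (out.group2 == "g2")].iloc[0]
        r13 = out[(out.group1 == "g1") & (out.group2 == "g3")].iloc[0]
        assert r12["z"] == pytest.approx(-1.3416407, abs=1e-6)
        assert r12["p_raw"] == pytest.approx(0.1797125, abs=1e-6)
        assert r12["p_bonferroni"] == pytest.approx(0.5391375, abs=1e-6)
        assert r13["p_bonferroni"] == pytest.approx(0.0218711, abs=1e-6)

    def test_bonferroni_capped_at_one(self, rng):
        vals = rng.normal(0, 1, 15)
        labels = np.repeat(["a", "b", "c"], 5)
        out = dunn_test(vals, labels)
        assert (out["p_bonferroni"] <= 1.0).all()
        assert (out["p_bonferroni"] >= out["p_raw"]).all()

    def test_tie_correction_reduces_variance(self):
        vals = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 3.0, 4.0, 5.0])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        tied = dunn_test(vals, labels)
        untied = dunn_test(np.arange(8.0), labels)
        # same mean-rank difference direction, defined z in both cases
        assert np.isfinite(tied["z"]).all() and np.isfinite(untied["z"]).all()


class TestCompareMetrics:
    def _table(self, rng, shift=0.0):
        rows = []
        for g, mu in (("A", 0.0), ("B", shift)):
            for i in range(8):
                rows.append({"individual_id": f"{g}{i}", "colony": g,
                             "max_distance_km": rng.normal(100 + mu, 10),
                             "path_length_km": rng.normal(300 + 3 * mu, 30),
                             "core_area_km2": rng.normal(1000, 100)})
        return pd.DataFrame(rows)

    def test_shifted_groups_flagged_with_posthoc(self, rng):
        res = compare_metrics(self._table(rng, shift=100.0), "colony",
                              n_perm=500, seed=1)
        row = res.omnibus[res.omnibus.metric == "max_distance_km"].iloc[0]
        assert row["p"] <= 0.01
        assert (res.pairwise["metric"] == "max_distance_km").any()

    def test_small_group_excluded_with_warning(self, rng):
        table = self._table(rng)
        table = pd.concat([table, pd.DataFrame([{
            "individual_id": "solo", "colony": "C",
            "max_distance_km": 1.0, "path_length_km": 1.0,
            "core_area_km2": 1.0}])], ignore_index=True)
        with pytest.warns(UserWarning, match="< 2 individuals"):
            res = compare_metrics(table, "colony", n_perm=99, seed=0)
        assert set(res.omnibus["metric"]) == {"max_distance_km",
                                              "path_length_km",
                                              "core_area_km2"}
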