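"""IBA delineation: overlap surface, candidate sites, representativeness,
polygon aggregation and the final minimum convex polygon."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from trackiba.homerange import GridSpec
from trackiba.iba import (aggregate_polygons, candidate_site,
                          core_overlap_surface, delineate_iba, final_site,
                          individual_core_masks, representativeness)


def square(x0, y0, side):
    return box(x0, y0, x0 + side, y0 + side)


class TestOverlapSurface:
    def test_fractions(self):
        masks = np.zeros((10, 4, 4), dtype=bool)
        masks[:2, 1, 1] = True          # 2 of 10 cores cover cell (1,1)
        surface = core_overlap_surface(masks)
        assert surface[1, 1] == pytest.approx(0.2)
        assert surface[0, 0] == 0.0
        assert surface.max() <= 1.0

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            core_overlap_surface(np.zeros((1, 4, 4), dtype=bool))


class TestCandidateSite:
    grid = GridSpec(0.0, 0.0, 1.0, 6, 6)

    def test_identical_cores_return_common_core(self):
        masks = np.zeros((5, 6, 6), dtype=bool)
        masks[:, 2:4, 2:4] = True
        region, mask = candidate_site(core_overlap_surface(masks), self.grid)
        assert np.array_equal(mask, masks[0])
        assert region.area == pytest.approx(4.0)

    def test_eleven_disjoint_cores_empty(self):
        # max fraction 1/11 < 0.10 (strict threshold) -> empty site
        masks = np.zeros((11, 6, 6), dtype=bool)
        for i in range(11):
            masks[i, i % 6, i // 6] = True
        region, mask = candidate_site(core_overlap_surface(masks), self.grid)
        assert not mask.any() and region.is_empty

    def test_threshold_zero_is_union(self):
        masks = np.zeros((4, 6, 6), dtype=bool)
        masks[0, 0, 0] = masks[1, 5, 5] = True
        _, mask = candidate_site(core_overlap_surface(masks), self.grid,
                                 threshold=0.0)
        assert np.array_equal(mask, masks.any(axis=0))

    def test_lower_threshold_never_shrinks_region(self, rng):
        masks = rng.random((8, 6, 6)) < 0.3
        surface = core_overlap_surface(masks)
        _, m_low = candidate_site(surface, self.grid, threshold=0.05)
        _, m_high = candidate_site(surface, self.grid, threshold=0.25)
        assert np.all(m_low[m_high])


class TestRepresentativeness:
    def test_similar_individuals_high_score(self, rng):
        pts = [rng.normal((0, 0), 40, (30, 2)) for _ in range(15)]
        res = representativeness(pts, 54, n_boot=8, seed=0, cell=5.0,
                                 min_individuals=5)
        assert res.score > 70
        assert res.score <= 100.0

    def test_score_bounded_by_construction(self, rng):
        pts = [rng.normal((0, 0), 40, (20, 2)) for _ in range(12)]
        res = representativeness(pts, 54, n_boot=5, seed=1, cell=5.0,
                                 min_individuals=5,
                                 k_values=[1, 3, 5, 8, 11])
        assert 0.0 < res.score <= 100.0

    def test_too_few_individuals(self, rng):
        pts = [rng.normal((0, 0), 40, (20, 2)) for _ in range(5)]
        with pytest.raises(ValueError, match="requires"):
            representativeness(pts, 54, n_boot=5)


class TestAggregation:
    def test_small_component_dropped_larger_kept(self):
        big = square(0, 0, np.sqrt(90.0))      # 90% of total
        mid = square(50, 0, np.sqrt(6.0))      # 6% -> kept
        tiny = square(80, 0, 2.0)              # 4% -> dropped
        out = aggregate_polygons([big, mid, tiny])
        areas = sorted(p.area for p in out)
        assert len(out) == 2
        assert areas == pytest.approx([6.0, 90.0])

    def test_small_hole_filled_large_hole_kept(self):
        shell = square(0, 0, 10)               # area 100
        small_hole = Polygon([(1, 1), (3, 1), (3, 3), (1, 3)])   # 4%
        big_hole = Polygon([(5, 5), (8, 5), (8, 8), (5, 8)])     # 9%
        poly = Polygon(shell.exterior,
                       [small_hole.exterior, big_hole.exterior])
        out = aggregate_polygons([poly])
        assert len(out) == 1
        assert len(out[0].interiors) == 1
        assert out[0].area == pytest.approx(100.0 - 9.0)

    def test_single_polygon_unchanged(self):
        p = square(0, 0, 5)
        out = aggregate_polygons([p])
        assert len(out) == 1 and out[0].equals(p)

    def test_near_centroid_pair_merged(self):
        a = square(0, 0, 10)
        b = square(11, 0, 10)     # centroids 11 apart
        far = square(300, 0, 10)  # max centroid distance ~300 -> 5% = 15
        out = aggregate_polygons([a, b, far])
        assert len(out) == 2
        merged = max(out, key=lambda p: p.area)
        assert merged.contains(a.centroid) and merged.contains(b.centroid)

    def test_empty_input(self):
        assert aggregate_polygons([]) == []


class TestFinalSite:
    def test_hull_contains_all_polygons(self):
        polys = [square(0, 0, 5), square(20, 10, 5)]
        site = final_site(polys, 85.0, "A", "pre_moult", 12)
        for p in polys:
            assert site.polygon.contains(p.buffer(-1e-9))
        assert site.representative

    def test_two_squares_equal_joint_hull(self):
        a, b = square(0, 0, 4), square(10, 0, 4)
        site = final_site([a, b], 90.0, "A", "pre_moult", 12)
        from shapely.ops import unary_union
        assert site.polygon.equals(unary_union([a, b]).convex_hull)

    def test_convex_input_unchanged(self):
        p = square(0, 0, 8)
        site = final_site([p], 75.0, "A", "pre_moult", 12)
        assert site.polygon.equals(p)

    def test_low_representativeness_flagged_but_emitted(self):
        with pytest.warns(UserWarning, match="flagged"):
            site = final_site([square(0, 0, 5)], 60.0, "A", "pre_moult", 12)
        assert not site.representative
        assert not site.empty


class TestDelineate:
    def test_group_too_small_returns_none(self, rng):
        pts = [rng.normal((0, 0), 30, (20, 2)) for _ in range(10)]
        with pytest.warns(UserWarning, match="not estimated"):
            assert delineate_iba(pts, "A", "pre_moult", 54, n_boot=3) is None

    def test_full_delineation_site_properties(self, rng):
        pts = [rng.normal((0, 0), 40, (25, 2)) for _ in range(12)]
        site = delineate_iba(pts, "A", "pre_moult", 54, cell=5.0, n_boot=5,
                             seed=3, k_values=[1, 3, 5, 8, 11])
        assert site is not None and not site.empty
        assert site.n_individuals == 12
        # the MCP covers every aggregated component
        for p in site.component_polygons:
            assert site.polygon.contains(p.buffer(-1e-6))
        # final MCP area >= aggregated area
        assert site.polygon.area >= sum(p.area
                                        for p in site.component_polygons) - 1e-6
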