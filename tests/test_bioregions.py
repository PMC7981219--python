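"""Quadtree binning, bipartite network, label-propagation regions, summaries."""
import math

import numpy as np
import pytest

from sympatria.bioregions import (
    build_bipartite,
    detect_bioregions,
    quadtree_bin,
    richness_correlates,
    summarize_bioregions,
    BioregionSummary,
)
from sympatria.occurrence_io import RasterGrid
from sympatria.utils import EARTH_RADIUS_KM, ValidationError

from conftest import make_occurrences, random_clouds


def oracle_leaves(points, lon0, lat0, side, min_deg, max_cap, min_cap):
    """Independent recursive reference for the split-then-merge contract.

    Returns a list of (lon0, lat0, side, count) leaves for one root cell.
    """
    pts = [(x, y) for x, y in points if lon0 <= x < lon0 + side and lat0 <= y < lat0 + side]
    if len(pts) <= max_cap or side <= min_deg:
        return [(lon0, lat0, side, len(pts))]
    half = side / 2
    quads = []
    for dx in (0, 1):
        for dy in (0, 1):
            quads.append(oracle_leaves(pts, lon0 + dx * half, lat0 + dy * half, half,
                                       min_deg, max_cap, min_cap))
    for q in quads:
        if len(q) == 1 and q[0][2] == half and q[0][3] < min_cap:
            return [(lon0, lat0, side, len(pts))]
    return [leaf for q in quads for leaf in q]


class TestQuadtree:
    def test_below_capacity_single_leaf(self):
        rng = np.random.default_rng(0)
        occ = random_clouds(rng, 1, 50, box=(-100, 30, -96.01, 33.99))
        cells = quadtree_bin(occ)
        assert len(cells) == 1
        c = cells.cells[0]
        assert c.side == 4.0 and c.count == 50

    def test_uniform_overload_splits_once(self):
        rng = np.random.default_rng(1)
        occ = random_clouds(rng, 1, 400, box=(-100, 30, -96.01, 33.99))
        cells = quadtree_bin(occ)
        assert len(cells) == 4
        assert all(c.side == 2.0 for c in cells.cells)
        assert sum(c.count for c in cells.cells) == 400

    def test_corner_cluster_remerges_to_parent(self):
        # 101 points in one quadrant corner: three empty children force re-merge
        rng = np.random.default_rng(2)
        occ = random_clouds(rng, 1, 101, box=(-100, 30, -99.5, 30.5))
        cells = quadtree_bin(occ)
        assert len(cells) == 1
        assert cells.cells[0].side == 4.0 and cells.cells[0].count == 101

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 800))
        occ = random_clouds(rng, 2, n // 2, box=(-104, 28, -96.01, 35.99))
        cells = quadtree_bin(occ)
        pts = list(zip(occ.df["longitude"], occ.df["latitude"]))
        # occupied 4-degree root cells anchored at multiples of 4 from (-180, -90)
        roots = sorted({(math.floor((x + 180) / 4) * 4 - 180, math.floor((y + 90) / 4) * 4 - 90)
                        for x, y in pts})
        expected = []
        for gx, gy in roots:
            expected.extend(l for l in oracle_leaves(pts, gx, gy, 4.0, 2.0, 100, 10)
                            if l[3] > 0)
        got = sorted((c.lon0, c.lat0, c.side, c.count) for c in cells.cells)
        assert got == sorted(expected)

    def test_leaves_tile_without_overlap_and_cover_all_points(self):
        rng = np.random.default_rng(3)
        occ = random_clouds(rng, 3, 300, box=(-104, 28, -96.01, 35.99))
        cells = quadtree_bin(occ)
        # each occurrence in exactly one leaf
        counts = np.zeros(len(occ))
        for c in cells.cells:
            counts[c.point_idx] += 1
        assert (counts == 1).all()
        # capacity: an over-full large leaf is only legal when splitting it
        # would strand a quadrant below min_capacity (the re-merge rule)
        lon = occ.df["longitude"].to_numpy()
        lat = occ.df["latitude"].to_numpy()
        for c in cells.cells:
            if c.side > 2.0 and c.count > 100:
                half = c.side / 2
                quad_counts = [
                    np.sum((lon[c.point_idx] >= c.lon0 + dx * half)
                           & (lon[c.point_idx] < c.lon0 + (dx + 1) * half)
                           & (lat[c.point_idx] >= c.lat0 + dy * half)
                           & (lat[c.point_idx] < c.lat0 + (dy + 1) * half))
                    for dx in (0, 1) for dy in (0, 1)
                ]
                assert min(quad_counts) < 10

    def test_halving_capacity_never_coarsens(self):
        rng = np.random.default_rng(4)
        occ = random_clouds(rng, 2, 400, box=(-104, 28, -96.01, 35.99))
        coarse = quadtree_bin(occ, max_capacity=200, min_capacity=1)
        fine = quadtree_bin(occ, max_capacity=100, min_capacity=1)
        # map each point to its leaf side under both capacities
        side_of = {}
        for c in coarse.cells:
            for i in c.point_idx:
                side_of[i] = c.side
        for c in fine.cells:
            for i in c.point_idx:
                assert c.side <= side_of[i]

    def test_non_halving_geometry_rejected(self):
        occ = make_occurrences({"A": [(0, 0)]})
        with pytest.raises(ValidationError):
            quadtree_bin(occ, max_deg=4.0, min_deg=3.0)


class TestBipartite:
    def test_single_edge_weight(self):
        occ = make_occurrences({"A": [(-99, 31)] * 7})
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assert net.number_of_edges() == 1
        (_, _, w), = net.edges(data="weight")
        assert w == 7

    def test_weight_conservation(self):
        rng = np.random.default_rng(5)
        occ = random_clouds(rng, 4, 150, box=(-110, 20, -90.01, 39.99))
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assert sum(d["weight"] for _, _, d in net.edges(data=True)) == len(occ)


class TestDetectBioregions:
    def test_single_species_three_cells_one_region(self):
        occ = make_occurrences({"A": [(-99, 31)] * 20 + [(-95, 31)] * 20 + [(-91, 31)] * 20})
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assign = detect_bioregions(net, seed=1)
        assert assign.n_regions == 1
        assert len(assign.cell_region) == 3

    def test_disconnected_blocks_forced_apart(self):
        occ = make_occurrences({
            "A": [(-99, 31)] * 20 + [(-95, 31)] * 20,
            "B": [(-99, 31.5)] * 20 + [(-95, 31.5)] * 20,
            "C": [(-59, 11)] * 20 + [(-55, 11)] * 20,
            "D": [(-59, 11.5)] * 20 + [(-55, 11.5)] * 20,
        })
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assign = detect_bioregions(net, seed=1)
        assert assign.n_regions == 2
        blocks = {frozenset(v) for v in assign.region_species.values()}
        assert blocks == {frozenset("AB"), frozenset("CD")}

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        occ = random_clouds(rng, 5, 120, box=(-110, 20, -90.01, 39.99))
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        a = detect_bioregions(net, seed=9).cell_region
        b = detect_bioregions(net, seed=9).cell_region
        assert a == b

    @pytest.mark.parametrize("seed", range(20))
    def test_planted_two_blocks_recovered(self, seed):
        # two species x cell blocks with all weight inside blocks
        rng = np.random.default_rng(seed)
        west = random_clouds(rng, 3, 60, box=(-110, 20, -102.01, 27.99))
        east = random_clouds(rng, 3, 60, box=(-70, 20, -62.01, 27.99))
        east.df["species"] = east.df["species"] + "e"
        import pandas as pd

        occ = make_occurrences({})
        occ.df = pd.concat([west.df, east.df], ignore_index=True)
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assign = detect_bioregions(net, seed=seed)
        west_regions = {assign.cell_region[c.cell_id] for c in cells.cells if c.lon0 < -100}
        east_regions = {assign.cell_region[c.cell_id] for c in cells.cells if c.lon0 > -80}
        assert west_regions.isdisjoint(east_regions)


class TestSummaries:
    def test_equatorial_cell_area_closed_form(self):
        occ = make_occurrences({"A": [(0.5, 0.5)] * 5})
        cells = quadtree_bin(occ, max_deg=1.0, min_deg=1.0)
        expected = EARTH_RADIUS_KM**2 * math.radians(1.0) * math.sin(math.radians(1.0))
        assert cells.cells[0].area_km2() == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(12364, abs=2)

    def test_constant_elevation_sd_zero_single_biome_count_one(self):
        occ = make_occurrences({"A": [(-99, 31)] * 20})
        cells = quadtree_bin(occ)
        net = build_bipartite(cells, occ)
        assign = detect_bioregions(net, seed=1)
        elev = RasterGrid(-100, 30, 0.5, np.full((8, 8), 1234.0))
        biome = RasterGrid(-100, 30, 0.5, np.full((8, 8), 3.0))
        s, = summarize_bioregions(assign, cells, elev, biome)
        assert s.elevation_sd_m == 0.0
        assert s.n_biomes == 1
        assert s.richness == 1

    def test_absent_rasters_give_null_fields(self):
        occ = make_occurrences({"A": [(-99, 31)] * 20})
        cells = quadtree_bin(occ)
        assign = detect_bioregions(build_bipartite(cells, occ), seed=1)
        s, = summarize_bioregions(assign, cells)
        assert s.elevation_sd_m is None and s.n_biomes is None

    def test_region_area_conservation(self):
        rng = np.random.default_rng(7)
        occ = random_clouds(rng, 4, 200, box=(-110, 20, -90.01, 39.99))
        cells = quadtree_bin(occ)
        assign = detect_bioregions(build_bipartite(cells, occ), seed=1)
        summaries = summarize_bioregions(assign, cells)
        assert sum(s.area_km2 for s in summaries) == pytest.approx(
            sum(c.area_km2() for c in cells.cells), rel=1e-12)
        assert sum(len(v) for v in assign.region_cells.values()) == len(cells)


def summary(region, richness, area, northing, elev_sd, n_biomes):
    return BioregionSummary(region, richness, area, northing / 111.195, northing,
                            elev_sd, n_biomes)


class TestRichnessCorrelates:
    def test_perfectly_linear_biome_model(self):
        summaries = [summary(i, 2 * b + 1, 1000.0 + i, 100.0 * i, 10.0, b)
                     for i, b in enumerate([1, 2, 3, 4, 5])]
        res = {r.name: r for r in richness_correlates(summaries)}
        ols = res["ols:richness~n_biomes"]
        assert ols.r2 == pytest.approx(1.0)

    def test_constant_covariate_flagged_undefined(self):
        summaries = [summary(i, i + 1, 5000.0, 100.0 * i, 10.0, 3) for i in range(5)]
        res = {r.name: r for r in richness_correlates(summaries)}
        assert not res["pearson:richness~area_km2"].defined
        assert not res["ols:richness~n_biomes"].defined

    def test_null_pvalues_calibrated(self):
        # richness independent of a permuted covariate: two-sided p uniform
        rng = np.random.default_rng(8)
        n_regions, reps = 12, 1000
        rejections = 0
        for _ in range(reps):
            summaries = [summary(i, int(r), 1000.0 * a, 100.0 * i, 10.0, 3)
                         for i, (r, a) in enumerate(zip(rng.uniform(2, 40, n_regions),
                                                        rng.uniform(1, 9, n_regions)))]
            res = {r.name: r for r in richness_correlates(summaries)}
            if res["pearson:richness~area_km2"].p_value <= 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)
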