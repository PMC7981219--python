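"""Adaptive-grid binning, species-cell networks, bioregions, and richness correlates.

Occurrences are binned into an adaptive quadtree grid (cells from 4 deg down
to 2 deg by halving, split above a capacity, re-merged below a minimum),
linked to species in a weighted bipartite network, and partitioned into
bioregions by seeded two-mode label propagation. Per-region summaries (area,
centroid northing, elevation SD, biome count, size classes) feed the
richness-correlate statistics.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .occurrence_io import OccurrenceTable, RasterGrid
from .utils import EARTH_RADIUS_KM, KM_PER_DEG, StatResult, ValidationError


# ---------------------------------------------------------------------------
# adaptive quadtree grid
# ---------------------------------------------------------------------------
@dataclass
class GridCell:
    lon0: float
    lat0: float
    side: float
    point_idx: np.ndarray  # row indices into the occurrence table

    @property
    def cell_id(self) -> str:
        return f"{self.lon0:g}_{self.lat0:g}_{self.side:g}"

    @property
    def count(self) -> int:
        return len(self.point_idx)

    def contains(self, lon: float, lat: float) -> bool:
        return self.lon0 <= lon < self.lon0 + self.side and self.lat0 <= lat < self.lat0 + self.side

    def area_km2(self) -> float:
        phi1 = math.radians(self.lat0)
        phi2 = math.radians(self.lat0 + self.side)
        dlam = math.radians(self.side)
        return EARTH_RADIUS_KM**2 * dlam * (math.sin(phi2) - math.sin(phi1))

    def center(self) -> tuple[float, float]:
        return self.lon0 + self.side / 2, self.lat0 + self.side / 2


@dataclass
class GridCellSet:
    cells: list[GridCell]
    occ: OccurrenceTable
    max_deg: float
    min_deg: float

    def __post_init__(self):
        self._by_id = {c.cell_id: c for c in self.cells}

    def __len__(self) -> int:
        return len(self.cells)

    def cell(self, cell_id: str) -> GridCell:
        return self._by_id[cell_id]

    def species_in(self, cell: GridCell) -> dict[str, int]:
        sp = self.occ.df["species"].to_numpy()[cell.point_idx]
        uniq, counts = np.unique(sp, return_counts=True)
        return dict(zip(uniq.tolist(), counts.tolist()))

    def locate(self, lon: float, lat: float) -> GridCell | None:
        for c in self.cells:  # leaf count is small; linear scan is fine
            if c.contains(lon, lat):
                return c
        return None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"cell_id": c.cell_id, "lon0": c.lon0, "lat0": c.lat0, "side_deg": c.side,
                 "n_points": c.count, "n_species": len(self.species_in(c))}
                for c in self.cells
            ]
        )


def quadtree_bin(
    occ: OccurrenceTable,
    max_deg: float = 4.0,
    min_deg: float = 2.0,
    max_capacity: int = 100,
    min_capacity: int = 10,
) -> GridCellSet:
    """Adaptive-resolution binning of occurrence points.

    Starts from a max_deg lattice anchored at integer multiples of max_deg
    from (-180, -90). A cell with more than ``max_capacity`` points splits
    into quadrants while its side exceeds ``min_deg``; after a split, if any
    child ends as a leaf with fewer than ``min_capacity`` points the parent
    re-absorbs all quadrants and stays a single leaf. Empty cells are dropped.
    """
    ratio = max_deg / min_deg
    k = math.log2(ratio)
    if abs(k - round(k)) > 1e-9 or max_deg <= 0 or min_deg <= 0:
        raise ValidationError("max_deg must equal min_deg * 2^k for integer k >= 0")
    lon = occ.df["longitude"].to_numpy(float)
    lat = occ.df["latitude"].to_numpy(float)

    def build(lon0: float, lat0: float, side: float, idx: np.ndarray) -> list[GridCell]:
        if len(idx) <= max_capacity or side <= min_deg:
            return [GridCell(lon0, lat0, side, idx)]
        half = side / 2
        children = []
        for dx in (0, 1):
            for dy in (0, 1):
                cx, cy = lon0 + dx * half, lat0 + dy * half
                in_x = (lon[idx] >= cx) & ((lon[idx] < cx + half) | (dx == 1))
                in_y = (lat[idx] >= cy) & ((lat[idx] < cy + half) | (dy == 1))
                children.append(build(cx, cy, half, idx[in_x & in_y]))
        # merge rule: any direct child that stayed a single leaf of its own
        # extent with count below min_capacity pulls everything back
        for child in children:
            if len(child) == 1 and child[0].side == half and child[0].count < min_capacity:
                return [GridCell(lon0, lat0, side, idx)]
        return [c for sub in children for c in sub]

    ix = np.floor((lon + 180.0) / max_deg).astype(int)
    iy = np.floor((lat + 90.0) / max_deg).astype(int)
    leaves: list[GridCell] = []
    for gx, gy in sorted(set(zip(ix.tolist(), iy.tolist()))):
        idx = np.nonzero((ix == gx) & (iy == gy))[0]
        lon0 = -180.0 + gx * max_deg
        lat0 = -90.0 + gy * max_deg
        leaves.extend(c for c in build(lon0, lat0, max_deg, idx) if c.count > 0)
    return GridCellSet(leaves, occ, max_deg, min_deg)


# ---------------------------------------------------------------------------
# bipartite network and bioregion detection
# ---------------------------------------------------------------------------
def build_bipartite(cells: GridCellSet, occ: OccurrenceTable) -> nx.Graph:
    """Weighted species-cell graph; edge weight = that species' points in the cell."""
    covered = sum(c.count for c in cells.cells)
    if covered != len(occ):
        raise ValidationError(f"cells cover {covered} of {len(occ)} occurrences")
    g = nx.Graph()
    for cell in cells.cells:
        cid = ("cell", cell.cell_id)
        g.add_node(cid, bipartite="cell")
        for sp, w in cells.species_in(cell).items():
            g.add_node(("species", sp), bipartite="species")
            g.add_edge(("species", sp), cid, weight=w)
    return g


@dataclass
class BioregionAssignment:
    cell_region: dict[str, int]
    region_cells: dict[int, list[str]] = field(default_factory=dict)
    region_species: dict[int, set] = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return len(self.region_cells)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.cell_region.items()), columns=["cell_id", "region"]
        )


def detect_bioregions(net: nx.Graph, seed: int = 1) -> BioregionAssignment:
    """Partition grid cells into bioregions by species composition.

    Seeded asynchronous label propagation on the weighted bipartite graph:
    cells start with unique labels, species are unlabeled; each sweep updates
    species then cells to the weighted-majority label of their neighbors,
    lowest label winning ties, in an order shuffled by the seed. Iterated to
    a fixed point; the cell-side labels define the regions.
    """
    cell_nodes = sorted(n for n in net.nodes if n[0] == "cell")
    species_nodes = sorted(n for n in net.nodes if n[0] == "species")
    if not cell_nodes:
        raise ValidationError("empty network")
    label = {n: i for i, n in enumerate(cell_nodes)}
    rng = np.random.default_rng(seed)

    def majority(node) -> int | None:
        votes: dict[int, float] = {}
        for nb in net.neighbors(node):
            lab = label.get(nb)
            if lab is None:
                continue
            votes[lab] = votes.get(lab, 0.0) + net[node][nb]["weight"]
        if not votes:
            return None
        best = max(votes.values())
        return min(l for l, v in votes.items() if v >= best - 1e-12)

    for _ in range(200):
        changed = False
        for group in (species_nodes, cell_nodes):
            order = list(group)
            rng.shuffle(order)
            for node in order:
                new = majority(node)
                if new is not None and new != label.get(node):
                    label[node] = new
                    changed = True
        if not changed:
            break

    # renumber regions 1..R by first appearance over sorted cell ids
    region_of_label: dict[int, int] = {}
    cell_region: dict[str, int] = {}
    for node in cell_nodes:
        lab = label[node]
        if lab not in region_of_label:
            region_of_label[lab] = len(region_of_label) + 1
        cell_region[node[1]] = region_of_label[lab]
    region_cells: dict[int, list[str]] = {}
    region_species: dict[int, set] = {}
    for node in cell_nodes:
        r = cell_region[node[1]]
        region_cells.setdefault(r, []).append(node[1])
        region_species.setdefault(r, set()).update(nb[1] for nb in net.neighbors(node))
    return BioregionAssignment(cell_region, region_cells, region_species)


# ---------------------------------------------------------------------------
# summaries and correlates
# ---------------------------------------------------------------------------
@dataclass
class BioregionSummary:
    region: int
    richness: int
    area_km2: float
    centroid_lat_deg: float
    centroid_northing_km: float
    elevation_sd_m: float | None = None
    n_biomes: int | None = None
    size_class_counts: dict[str, int] | None = None

    def as_row(self) -> dict:
        row = {
            "region": self.region,
            "richness": self.richness,
            "area_km2": self.area_km2,
            "centroid_lat_deg": self.centroid_lat_deg,
            "centroid_northing_km": self.centroid_northing_km,
            "elevation_sd_m": self.elevation_sd_m,
            "n_biomes": self.n_biomes,
        }
        if self.size_class_counts:
            row.update({f"n_{k}": v for k, v in self.size_class_counts.items()})
        return row


def _raster_region_values(raster: RasterGrid, cells: GridCellSet, assign: BioregionAssignment):
    """Region id -> raster values whose cell centers fall inside a member grid cell."""
    lon, lat = raster.cell_centers()
    values: dict[int, list[float]] = {}
    flat = zip(lon.ravel(), lat.ravel(), raster.values.ravel())
    for x, y, v in flat:
        if v == raster.nodata:
            continue
        leaf = cells.locate(x, y)
        if leaf is None:
            continue
        r = assign.cell_region.get(leaf.cell_id)
        if r is not None:
            values.setdefault(r, []).append(float(v))
    return values


def summarize_bioregions(
    assign: BioregionAssignment,
    cells: GridCellSet,
    elevation: RasterGrid | None = None,
    biome: RasterGrid | None = None,
    cls=None,
) -> list[BioregionSummary]:
    """Per-region covariates: spherical area, area-weighted centroid, rasters, sizes."""
    elev_vals = _raster_region_values(elevation, cells, assign) if elevation is not None else None
    biome_vals = _raster_region_values(biome, cells, assign) if biome is not None else None
    out = []
    for region in sorted(assign.region_cells):
        member = [cells.cell(cid) for cid in assign.region_cells[region]]
        areas = np.array([c.area_km2() for c in member])
        lats = np.array([c.center()[1] for c in member])
        centroid_lat = float(np.average(lats, weights=areas))
        summary = BioregionSummary(
            region=region,
            richness=len(assign.region_species[region]),
            area_km2=float(areas.sum()),
            centroid_lat_deg=centroid_lat,
            centroid_northing_km=centroid_lat * KM_PER_DEG,
        )
        if elev_vals is not None:
            ev = elev_vals.get(region, [])
            summary.elevation_sd_m = float(np.std(ev)) if ev else None
        if biome_vals is not None:
            bv = biome_vals.get(region, [])
            summary.n_biomes = len(set(bv)) if bv else None
        if cls is not None:
            summary.size_class_counts = {
                c: sum(1 for sp in assign.region_species[region] if cls.classes.get(sp) == c)
                for c in cls.class_names
            }
        out.append(summary)
    return out


def richness_correlates(summaries: list[BioregionSummary]) -> list[StatResult]:
    """Richness vs area / centroid northing / elevation SD (Spearman and Pearson),
    plus OLS of richness on biome count (F, R^2)."""
    if len(summaries) < 3:
        raise ValidationError("need at least 3 regions with covariates")
    rich = np.array([s.richness for s in summaries], float)
    results: list[StatResult] = []

    def corr(name: str, x: np.ndarray, y: np.ndarray):
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = len(x)
        if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            results.append(StatResult(f"pearson:{name}", np.nan, max(n - 2, 0), np.nan, defined=False))
            results.append(StatResult(f"spearman:{name}", np.nan, max(n - 2, 0), np.nan, defined=False))
            return
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        results.append(StatResult(f"pearson:{name}", float(pr.statistic), n - 2, float(pr.pvalue)))
        results.append(StatResult(f"spearman:{name}", float(sr.statistic), n - 2, float(sr.pvalue)))

    covs = {
        "richness~area_km2": np.array([s.area_km2 for s in summaries], float),
        "richness~northing_km": np.array([s.centroid_northing_km for s in summaries], float),
        "richness~elevation_sd": np.array(
            [np.nan if s.elevation_sd_m is None else s.elevation_sd_m for s in summaries], float
        ),
    }
    for name, x in covs.items():
        corr(name, x, rich)

    nb = np.array([np.nan if s.n_biomes is None else s.n_biomes for s in summaries], float)
    keep = np.isfinite(nb)
    x, y = nb[keep], rich[keep]
    if len(x) >= 3 and np.ptp(x) > 0:
        res = stats.linregress(x, y)
        n = len(x)
        r2 = res.rvalue**2
        f = (r2 / (1 - r2)) * (n - 2) if r2 < 1 else np.inf
        results.append(StatResult("ols:richness~n_biomes", float(f), n - 2, float(res.pvalue), r2=float(r2)))
    else:
        results.append(StatResult("ols:richness~n_biomes", np.nan, 0, np.nan, defined=False))
    return results
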