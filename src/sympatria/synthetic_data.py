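"""Synthetic phylogenies, traits, ranges, occurrences, and rasters.

The generator reproduces the statistical structure the downstream analysis
assumes: a Yule (pure-birth) tree, Brownian-motion body size, circular
species ranges with a controllable co-occurrence design (which pairs
overlap, and by how much), uniform occurrence sampling within ranges, and
smooth elevation / categorical biome rasters. Every output is a pure
function of the configuration plus a root seed; per-stage child seeds are
derived from the stage name so stages are individually reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import ndimage, optimize
from shapely.geometry import Polygon

from .occurrence_io import OccurrenceTable, RasterGrid, SpeciesRanges, TraitTable
from .trees import Phylogeny
from .utils import KM_PER_DEG, PackingError, ValidationError, child_seed

import pandas as pd


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults mirror a desk-scale version of a species-rich lizard clade:
    a few dozen species, SVL diffusing from a ~76 mm root with rate
    sigma2 = 8 mm^2 per unit branch length, ranges of order 100 km across
    a subtropical domain.
    """

    n_species: int = 40
    birth_rate: float = 1.0
    root_svl: float = 76.0
    sigma2: float = 8.0
    domain_bbox: tuple[float, float, float, float] = (-120.0, 10.0, -80.0, 40.0)
    range_radius_km: float = 100.0
    n_points_per_species: int = 200
    cooccurrence_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    raster_resolution_deg: float = 0.5
    n_biomes: int = 5
    elevation_relief_m: float = 500.0  # amplitude of the random field; 0 -> flat
    seed: int = 1

    def __post_init__(self):
        if self.n_species < 2:
            raise ValidationError("n_species must be >= 2")
        if self.sigma2 < 0:
            raise ValidationError("sigma2 must be >= 0")
        lo_x, lo_y, hi_x, hi_y = self.domain_bbox
        if not (lo_x < hi_x and lo_y < hi_y):
            raise ValidationError("domain_bbox must satisfy min < max")
        for a, b, f in self.cooccurrence_pairs:
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"overlap fraction for ({a},{b}) outside [0,1]: {f}")

    def species_names(self) -> list[str]:
        return [f"sp{i + 1:03d}" for i in range(self.n_species)]


# ---------------------------------------------------------------------------
# tree and traits
# ---------------------------------------------------------------------------
def simulate_yule_tree(n_tips: int, birth_rate: float, seed: int) -> Phylogeny:
    """Pure-birth tree with exponential waiting times.

    Starting from two lineages, with k extant lineages the next speciation
    waits Exp(k * birth_rate); a uniformly chosen lineage splits. A final
    waiting period is drawn at n_tips lineages, so the expected root-to-tip
    depth is sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_tips < 2:
        raise ValidationError("n_tips must be >= 2")
    if birth_rate <= 0:
        raise ValidationError("birth_rate must be > 0")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    left, right = root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)
    active = [left, right]
    for k in range(2, n_tips + 1):
        dt = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            node.edge.length += dt
        if k < n_tips:
            split = active.pop(rng.integers(len(active)))
            active.append(split.new_child(edge_length=0.0))
            active.append(split.new_child(edge_length=0.0))
    ns = dendropy.TaxonNamespace()
    tree.taxon_namespace = ns
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(f"sp{i + 1:03d}")
    return Phylogeny(tree)


def simulate_bm_trait(tree: Phylogeny, root_state: float, sigma2: float, seed: int) -> TraitTable:
    """Brownian motion along the tree: independent N(0, sigma2 * branch) increments."""
    if sigma2 < 0:
        raise ValidationError("sigma2 must be >= 0")
    rng = np.random.default_rng(seed)
    dt = tree.dendropy_tree
    states = {id(dt.seed_node): float(root_state)}
    values: dict[str, float] = {}
    for node in dt.preorder_node_iter():
        if node is dt.seed_node:
            continue
        bl = node.edge.length or 0.0
        x = states[id(node.parent_node)] + rng.normal(0.0, math.sqrt(sigma2 * bl))
        states[id(node)] = x
        if node.is_leaf():
            values[node.taxon.label] = x
    return TraitTable(values)


# ---------------------------------------------------------------------------
# ranges and occurrences
# ---------------------------------------------------------------------------
def _lens_fraction(d: float, r: float) -> float:
    """Intersection area of two radius-r discs at center distance d, as a disc fraction."""
    if d >= 2 * r:
        return 0.0
    area = 2 * r * r * math.acos(d / (2 * r)) - (d / 2) * math.sqrt(4 * r * r - d * d)
    return area / (math.pi * r * r)


def _separation_for_overlap(f: float, r: float) -> float:
    """Center separation giving disc-overlap fraction f (inverted numerically)."""
    if f >= 1.0:
        return 0.0
    if f <= 0.0:
        return 2.0 * r
    return optimize.brentq(lambda d: _lens_fraction(d, r) - f, 0.0, 2.0 * r, xtol=1e-10 * r)


def _disc_polygon(cx: float, cy: float, r_km: float, km_per_deg_lon: float, n_vertices: int = 64) -> Polygon:
    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    lon = cx + (r_km / km_per_deg_lon) * np.cos(theta)
    lat = cy + (r_km / KM_PER_DEG) * np.sin(theta)
    return Polygon(zip(lon, lat))


def generate_ranges(config: SimConfig) -> SpeciesRanges:
    """Place one circular (64-gon) range per species on a regular lattice.

    Species named in ``cooccurrence_pairs`` are placed as a unit, the second
    disc offset east of the first by the separation that yields the requested
    overlap fraction; all other disc pairs are disjoint by construction.
    Placement uses a local equirectangular projection at the domain center.
    """
    names = config.species_names()
    r = config.range_radius_km
    lo_x, lo_y, hi_x, hi_y = config.domain_bbox
    lat_c = 0.5 * (lo_y + hi_y)
    km_lon = KM_PER_DEG * math.cos(math.radians(lat_c))

    in_pair: dict[str, tuple] = {}
    for a, b, f in config.cooccurrence_pairs:
        if a not in names or b not in names:
            raise ValidationError(f"cooccurrence pair names unknown: ({a}, {b})")
        if a in in_pair or b in in_pair or a == b:
            raise ValidationError("each species may appear in at most one cooccurrence pair")
        in_pair[a] = in_pair[b] = (a, b, f)

    units: list[tuple] = []
    seen = set()
    for sp in names:
        if sp in seen:
            continue
        if sp in in_pair:
            a, b, f = in_pair[sp]
            units.append((a, b, _separation_for_overlap(f, r)))
            seen.update((a, b))
        else:
            units.append((sp,))
            seen.add(sp)

    max_offset = max((u[2] for u in units if len(u) == 3), default=0.0)
    n_units = len(units)
    cols = math.ceil(math.sqrt(n_units))
    rows = math.ceil(n_units / cols)
    # margin keeps discs (and the eastward pair offset) inside the bbox
    margin_x = (r + max_offset) / km_lon
    margin_y = r / KM_PER_DEG
    span_x = (hi_x - lo_x) - 2 * margin_x
    span_y = (hi_y - lo_y) - 2 * margin_y
    if span_x <= 0 or span_y <= 0:
        raise PackingError("domain_bbox too small for range_radius_km")
    step_x = span_x / cols
    step_y = span_y / rows
    min_step_km = min(step_x * km_lon, step_y * KM_PER_DEG)
    if n_units > 1 and min_step_km <= 2 * r + max_offset:
        raise PackingError(
            f"cannot pack {n_units} range units of radius {r} km with lattice step "
            f"{min_step_km:.1f} km; enlarge domain_bbox or shrink range_radius_km"
        )
    polys: dict[str, Polygon] = {}
    for i, unit in enumerate(units):
        cx = lo_x + margin_x + (i % cols + 0.5) * step_x
        cy = lo_y + margin_y + (i // cols + 0.5) * step_y
        if len(unit) == 1:
            polys[unit[0]] = _disc_polygon(cx, cy, r, km_lon)
        else:
            a, b, d = unit
            polys[a] = _disc_polygon(cx - d / (2 * km_lon), cy, r, km_lon)
            polys[b] = _disc_polygon(cx + d / (2 * km_lon), cy, r, km_lon)
    return SpeciesRanges(polys)


def sample_occurrences(ranges: SpeciesRanges, n_points_per_species: int, seed: int) -> OccurrenceTable:
    """Uniform points within each species polygon (rejection sampling, boundary-inclusive)."""
    if n_points_per_species < 1:
        raise ValidationError("n_points_per_species must be >= 1")
    import shapely

    rows = []
    for sp in sorted(ranges.polygons):
        poly = ranges.polygons[sp]
        if poly.is_empty:
            raise ValidationError(f"empty polygon for {sp!r}")
        rng = np.random.default_rng(child_seed(seed, f"occ:{sp}"))
        lo_x, lo_y, hi_x, hi_y = poly.bounds
        got = 0
        if hi_x - lo_x < 1e-12 and hi_y - lo_y < 1e-12:
            # degenerate (near-point) support: all mass at the centroid
            c = poly.centroid
            rows.extend((sp, c.x, c.y) for _ in range(n_points_per_species))
            continue
        while got < n_points_per_species:
            m = max(4 * (n_points_per_species - got), 64)
            xs = rng.uniform(lo_x, hi_x, m)
            ys = rng.uniform(lo_y, hi_y, m)
            ok = shapely.covers(poly, shapely.points(xs, ys))
            for x, y in zip(xs[ok], ys[ok]):
                if got == n_points_per_species:
                    break
                rows.append((sp, float(x), float(y)))
                got += 1
    return OccurrenceTable(pd.DataFrame(rows, columns=["species", "longitude", "latitude"]))


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------
def _smooth_field(shape: tuple[int, int], rng: np.random.Generator, smooth_cells: float = 4.0) -> np.ndarray:
    field_ = ndimage.gaussian_filter(rng.normal(size=shape), smooth_cells, mode="nearest")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_rasters(config: SimConfig) -> tuple[RasterGrid, RasterGrid]:
    """(elevation, biome) rasters over the domain.

    Elevation is a smoothed Gaussian random field: 1000 m base plus
    ``elevation_relief_m`` times a unit-variance field (relief 0 gives a
    constant grid). Biomes are quantile bands of an independent smooth field,
    so exactly ``n_biomes`` labels are present.
    """
    if config.n_biomes < 1:
        raise ValidationError("n_biomes must be >= 1")
    lo_x, lo_y, hi_x, hi_y = config.domain_bbox
    res = config.raster_resolution_deg
    nx = (hi_x - lo_x) / res
    ny = (hi_y - lo_y) / res
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ValidationError("raster_resolution_deg must divide the bbox extents")
    shape = (int(round(ny)), int(round(nx)))
    if shape[0] * shape[1] < config.n_biomes:
        raise ValidationError("raster too coarse to host n_biomes distinct labels")

    rng_e = np.random.default_rng(child_seed(config.seed, "raster:elevation"))
    elev = 1000.0 + config.elevation_relief_m * _smooth_field(shape, rng_e)
    elevation = RasterGrid(lo_x, lo_y, res, elev)

    rng_b = np.random.default_rng(child_seed(config.seed, "raster:biome"))
    f = _smooth_field(shape, rng_b)
    # tiny jitter breaks exact ties so every quantile band is non-empty
    f = f + rng_b.uniform(-1e-9, 1e-9, size=shape)
    qs = np.quantile(f, np.linspace(0, 1, config.n_biomes + 1)[1:-1])
    biome = np.digitize(f, qs) + 1.0  # labels 1..n_biomes
    return elevation, RasterGrid(lo_x, lo_y, res, biome)


# ---------------------------------------------------------------------------
# co-occurrence designs
# ---------------------------------------------------------------------------
def design_cooccurrence_pairs(
    svl: dict[str, float], mode: str, overlap: float = 0.6
) -> list[tuple[str, str, float]]:
    """Build a co-occurrence design from body sizes.

    ``divergent`` pairs each of the smallest third of species with one of the
    largest third; ``assorted`` pairs similarly sized species (adjacent
    ranks); ``size_structured`` overlays both patterns — half the large
    species overlap each other (convergent large sympatry) while the rest
    overlap small species (divergent small sympatry).
    """
    order = sorted(svl, key=lambda s: (svl[s], s))
    n = len(order)
    third = n // 3
    if mode == "divergent":
        small, large = order[:third], order[-third:]
        return [(s, large[i % len(large)], overlap) for i, s in enumerate(small)]
    if mode == "assorted":
        return [(order[i], order[i + 1], overlap) for i in range(0, 2 * (n // 2), 2)]
    if mode == "size_structured":
        small, large = order[:third], order[-third:]
        n_ll = (len(large) // 2) & ~1  # even count reserved for large-large pairs
        pairs = [(large[i], large[i + 1], overlap) for i in range(0, n_ll, 2)]
        free_large = large[n_ll:]
        pairs += [(s, l, overlap) for s, l in zip(small, free_large)]
        return pairs
    raise ValidationError(f"unknown design mode {mode!r}")


def with_design(config: SimConfig, mode: str, overlap: float = 0.6) -> SimConfig:
    """Return a copy of ``config`` whose co-occurrence pairs follow a size design.

    Regenerates the tree and traits deterministically from the config seed
    (the same draws ``generate_all`` will make) and pairs species by size.
    """
    import dataclasses

    tree = simulate_yule_tree(config.n_species, config.birth_rate, child_seed(config.seed, "tree"))
    traits = simulate_bm_trait(tree, config.root_svl, config.sigma2, child_seed(config.seed, "traits"))
    pairs = design_cooccurrence_pairs(traits.svl_mm, mode, overlap)
    return dataclasses.replace(config, cooccurrence_pairs=pairs)


def generate_all(config: SimConfig):
    """Convenience: tree, traits, ranges, occurrences, rasters from one config."""
    tree = simulate_yule_tree(config.n_species, config.birth_rate, child_seed(config.seed, "tree"))
    traits = simulate_bm_trait(tree, config.root_svl, config.sigma2, child_seed(config.seed, "traits"))
    ranges = generate_ranges(config)
    occ = sample_occurrences(ranges, config.n_points_per_species, child_seed(config.seed, "occurrences"))
    elevation, biome = generate_rasters(config)
    return tree, traits, ranges, occ, elevation, biome
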