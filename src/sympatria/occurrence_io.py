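"""Readers, writers, validation, and cleaning for the pipeline's input data.

Formats: occurrence CSV/TSV (``species,longitude,latitude``; column names
remappable), GeoJSON range polygons, Newick trees, trait CSV
(``species,svl_mm``), and ESRI ASCII grid rasters. Coordinates are WGS84
decimal degrees throughout; no datum transforms are applied.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

from .trees import Phylogeny
from .utils import SchemaError, ValidationError

DEFAULT_DIALECT = {"species": "species", "longitude": "longitude", "latitude": "latitude"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------
@dataclass
class OccurrenceTable:
    """Point occurrence records: one row per (species, longitude, latitude)."""

    df: pd.DataFrame  # columns: species, longitude, latitude

    def __post_init__(self):
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())

    def coords_of(self, sp: str) -> np.ndarray:
        sub = self.df[self.df["species"] == sp]
        return sub[["longitude", "latitude"]].to_numpy(float)

    def write(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class SpeciesRanges:
    """Species id -> simple polygon (lon/lat ring)."""

    polygons: dict[str, Polygon]

    def __post_init__(self):
        for sp, poly in self.polygons.items():
            if poly.is_empty or len(poly.exterior.coords) < 4:
                raise ValidationError(f"range polygon for {sp!r} has fewer than 3 distinct vertices")
            if not poly.is_valid:
                raise ValidationError(f"range polygon for {sp!r} is not simple")

    def write(self, path: str | Path) -> None:
        features = [
            {"type": "Feature", "properties": {"species": sp}, "geometry": mapping(poly)}
            for sp, poly in sorted(self.polygons.items())
        ]
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


@dataclass
class TraitTable:
    """Species id -> adult male snout-to-vent length (mm)."""

    svl_mm: dict[str, float]

    def __post_init__(self):
        for sp, v in self.svl_mm.items():
            if not np.isfinite(v) or v <= 0:
                raise ValidationError(f"non-positive SVL for {sp!r}: {v}")

    def __len__(self) -> int:
        return len(self.svl_mm)

    @property
    def species(self) -> list[str]:
        return sorted(self.svl_mm)

    def write(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species": self.species, "svl_mm": [self.svl_mm[s] for s in self.species]}
        ).to_csv(path, index=False)


@dataclass
class RasterGrid:
    """Regular lon/lat grid in the ESRI ASCII dialect.

    ``values`` is (n_rows, n_cols) with row 0 the NORTHERN edge (ASCII grid
    convention); (xllcorner, yllcorner) is the lower-left corner.
    """

    xllcorner: float
    yllcorner: float
    cellsize: float
    values: np.ndarray
    nodata: float = -9999.0

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (n_rows, n_cols) for cell centers."""
        lon = self.xllcorner + (np.arange(self.n_cols) + 0.5) * self.cellsize
        lat_top = self.yllcorner + self.n_rows * self.cellsize
        lat = lat_top - (np.arange(self.n_rows) + 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def write(self, path: str | Path) -> None:
        header = (
            f"ncols {self.n_cols}\nnrows {self.n_rows}\n"
            f"xllcorner {self.xllcorner!r}\nyllcorner {self.yllcorner!r}\n"
            f"cellsize {self.cellsize!r}\nNODATA_value {self.nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in self.values:
                fh.write(" ".join(repr(float(v)) for v in row) + "\n")


@dataclass
class RemovalReport:
    """Per-species bookkeeping for range-based cleaning."""

    retained: dict[str, int] = field(default_factory=dict)
    removed: dict[str, int] = field(default_factory=dict)
    unfilterable: dict[str, int] = field(default_factory=dict)

    def total(self, sp: str) -> int:
        return self.retained.get(sp, 0) + self.removed.get(sp, 0) + self.unfilterable.get(sp, 0)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------
def _sniff_sep(path: str | Path) -> str:
    first = Path(path).open().readline()
    return "\t" if first.count("\t") > first.count(",") else ","


def read_occurrences(path: str | Path, dialect: dict | None = None) -> OccurrenceTable:
    """Read and validate an occurrence table.

    ``dialect`` maps canonical names (species/longitude/latitude) to the
    file's column names. Unmapped columns are ignored; row order is kept.
    """
    dialect = {**DEFAULT_DIALECT, **(dialect or {})}
    df = pd.read_csv(path, sep=_sniff_sep(path))
    missing = [c for c in dialect.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    out = pd.DataFrame(
        {
            "species": df[dialect["species"]].astype(str),
            "longitude": pd.to_numeric(df[dialect["longitude"]], errors="coerce"),
            "latitude": pd.to_numeric(df[dialect["latitude"]], errors="coerce"),
        }
    )
    bad = out.index[out["species"].str.len() == 0].tolist()
    bad += out.index[~np.isfinite(out["longitude"]) | ~np.isfinite(out["latitude"])].tolist()
    bad += out.index[(out["longitude"] < -180) | (out["longitude"] > 180)].tolist()
    bad += out.index[(out["latitude"] < -90) | (out["latitude"] > 90)].tolist()
    if bad:
        rows = sorted(set(int(b) + 2 for b in bad))  # 1-based file rows incl. header
        raise ValidationError(f"{path}: invalid coordinate/species at file row(s) {rows[:20]}")
    return OccurrenceTable(out)


def read_ranges(path: str | Path) -> SpeciesRanges:
    """Read a GeoJSON FeatureCollection with one polygon Feature per species."""
    gj = json.loads(Path(path).read_text())
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    polys: dict[str, Polygon] = {}
    for feat in gj["features"]:
        sp = feat.get("properties", {}).get("species")
        if not sp:
            raise SchemaError(f"{path}: Feature missing 'species' property")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise SchemaError(f"{path}: geometry for {sp!r} is {geom.geom_type}, want Polygon")
        polys[sp] = geom
    return SpeciesRanges(polys)


def read_tree(path: str | Path) -> Phylogeny:
    return Phylogeny.from_newick(Path(path))


def read_traits(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep=_sniff_sep(path))
    for col in ("species", "svl_mm"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    species = df["species"].astype(str)
    if species.duplicated().any():
        raise ValidationError(f"{path}: duplicate species ids")
    return TraitTable(dict(zip(species, pd.to_numeric(df["svl_mm"]))))


def read_raster(path: str | Path) -> RasterGrid:
    lines = Path(path).read_text().split("\n")
    header: dict[str, float] = {}
    for line in lines[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = np.loadtxt(lines[6:], max_rows=nrows)
    values = np.atleast_2d(values).reshape(nrows, ncols)
    return RasterGrid(
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        values=values,
        nodata=header.get("nodata_value", -9999.0),
    )


# ---------------------------------------------------------------------------
# cleaning and summaries
# ---------------------------------------------------------------------------
def filter_by_range(occ: OccurrenceTable, ranges: SpeciesRanges) -> tuple[OccurrenceTable, RemovalReport]:
    """Drop records outside their species' range polygon (boundary-inclusive).

    Records for species without a polygon are routed to the report as
    "unfilterable" and dropped from the retained table, never silently kept.
    """
    report = RemovalReport()
    keep = np.zeros(len(occ), dtype=bool)
    for sp, sub in occ.df.groupby("species", sort=True):
        poly = ranges.polygons.get(sp)
        if poly is None:
            report.unfilterable[sp] = len(sub)
            continue
        pts = shapely.points(sub["longitude"].to_numpy(), sub["latitude"].to_numpy())
        inside = shapely.covers(poly, pts)  # covers = boundary-inclusive
        keep[sub.index.to_numpy()] = inside
        report.retained[sp] = int(inside.sum())
        report.removed[sp] = int((~inside).sum())
    return OccurrenceTable(occ.df[keep]), report


def species_centroids(occ: OccurrenceTable) -> dict[str, tuple[float, float]]:
    """Arithmetic mean (longitude, latitude) per species.

    Plain coordinate means — no antimeridian unwrapping; adequate for a
    single-hemisphere study domain but wrong for ranges spanning ±180°.
    """
    g = occ.df.groupby("species")[["longitude", "latitude"]].mean()
    return {sp: (float(r["longitude"]), float(r["latitude"])) for sp, r in g.iterrows()}


def reconcile_names(**name_sets) -> dict:
    """Set-algebra reconciliation across named species-id collections.

    Returns the shared intersection plus each collection's orphans, e.g.
    ``reconcile_names(tree={...}, traits={...})``.
    """
    sets = {k: set(v) for k, v in name_sets.items()}
    shared = set.intersection(*sets.values()) if sets else set()
    report = {"shared": sorted(shared)}
    for k, s in sets.items():
        report[f"{k}_only"] = sorted(s - set.union(*(o for n, o in sets.items() if n != k)))
    return report
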