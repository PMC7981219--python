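"""Great-circle distances and the directed congeneric-sympatry rule.

Species *a* is called sympatric with species *b* when at least ``min_points``
of *a*'s occurrence points lie within ``threshold_km`` (inclusive) of at
least one point of *b*. The rule is directional: the supporting count is a
property of the focal species' own points, so S[a->b] and S[b->a] can differ.

Two implementations are provided: an O(n^2) brute-force path and an indexed
path (k-d tree on unit-sphere coordinates used only to propose candidate
pairs, each then re-checked with the same haversine formula), which are
exactly count-equivalent.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .occurrence_io import OccurrenceTable
from .utils import EARTH_RADIUS_KM, ValidationError


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance (km) on a sphere of mean radius 6371.0088 km. Vectorized."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float)) for v in (lon1, lat1, lon2, lat2))
    a = np.sin((lat2 - lat1) / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_distance_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine distance between two (lon, lat) points with bounds checking."""
    for lon, lat in (p1, p2):
        if not (-180 <= lon <= 180 and -90 <= lat <= 90):
            raise ValidationError(f"coordinate out of range: ({lon}, {lat})")
    return float(haversine_km(p1[0], p1[1], p2[0], p2[1]))


@dataclass
class SympatryMatrix:
    """Directed sympatry calls with supporting point counts.

    N[a, b] = number of a's occurrence points within threshold_km of any b
    point; S[a, b] = (N[a, b] >= min_points). Diagonal is excluded
    (self-sympatry undefined; stored as 0/False).
    """

    species: list[str]
    N: np.ndarray  # int, (s, s)
    threshold_km: float
    min_points: int
    symmetrized: bool = False

    @property
    def S(self) -> np.ndarray:
        S = self.N >= self.min_points
        np.fill_diagonal(S, False)
        if self.symmetrized:
            S = S | S.T
        return S

    def index(self, sp: str) -> int:
        try:
            return self.species.index(sp)
        except ValueError:
            raise ValidationError(f"species {sp!r} not in sympatry matrix") from None

    def congeners_of(self, focal: str) -> list[tuple[str, int]]:
        i = self.index(focal)
        S = self.S
        return [(self.species[j], int(self.N[i, j])) for j in range(len(self.species)) if S[i, j]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        S = self.S
        for i, a in enumerate(self.species):
            for j, b in enumerate(self.species):
                if i == j:
                    continue
                rows.append((a, b, int(self.N[i, j]), bool(S[i, j])))
        return pd.DataFrame(rows, columns=["focal", "other", "supporting_points", "sympatric"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, threshold_km: float, min_points: int) -> "SympatryMatrix":
        species = sorted(set(df["focal"]) | set(df["other"]))
        idx = {s: i for i, s in enumerate(species)}
        N = np.zeros((len(species), len(species)), dtype=int)
        for _, row in df.iterrows():
            N[idx[row["focal"]], idx[row["other"]]] = int(row["supporting_points"])
        return cls(species, N, threshold_km, min_points)


def _species_arrays(occ: OccurrenceTable):
    species = occ.species
    coords = {sp: occ.coords_of(sp) for sp in species}
    return species, coords


def _counts_bruteforce(occ: OccurrenceTable, threshold_km: float) -> tuple[list[str], np.ndarray]:
    """All-pairs haversine counts; the oracle the indexed path must match exactly."""
    species, coords = _species_arrays(occ)
    s = len(species)
    N = np.zeros((s, s), dtype=int)
    for i, a in enumerate(species):
        pa = coords[a]
        for j, b in enumerate(species):
            if i == j:
                continue
            pb = coords[b]
            d = haversine_km(pa[:, 0:1], pa[:, 1:2], pb[None, :, 0], pb[None, :, 1])
            N[i, j] = int(np.any(d <= threshold_km, axis=1).sum())
    return species, N


def _counts_indexed(occ: OccurrenceTable, threshold_km: float) -> tuple[list[str], np.ndarray]:
    """Candidate pairs from a 3-D k-d tree, re-checked with exact haversine."""
    species = occ.species
    sp_index = {sp: i for i, sp in enumerate(species)}
    lon = occ.df["longitude"].to_numpy(float)
    lat = occ.df["latitude"].to_numpy(float)
    sp_of = occ.df["species"].map(sp_index).to_numpy()
    lam, phi = np.radians(lon), np.radians(lat)
    xyz = np.column_stack(
        [np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)]
    )
    # chord length corresponding to the arc threshold, inflated so no true
    # neighbor is ever missed; candidates are confirmed with haversine below
    chord = 2.0 * np.sin(min(threshold_km / (2.0 * EARTH_RADIUS_KM), np.pi / 2))
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(chord * (1 + 1e-9) + 1e-12, output_type="ndarray")
    s = len(species)
    N = np.zeros((s, s), dtype=int)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        ok = haversine_km(lon[i], lat[i], lon[j], lat[j]) <= threshold_km
        i, j = i[ok], j[ok]
        cross = sp_of[i] != sp_of[j]
        i, j = i[cross], j[cross]
        # each focal point supports a (focal -> other species) call at most
        # once, however many neighbor points and whichever pair orientation
        fwd = np.column_stack([i, sp_of[j]])
        rev = np.column_stack([j, sp_of[i]])
        for pt, other in np.unique(np.vstack([fwd, rev]), axis=0):
            N[sp_of[pt], other] += 1
    return species, N


def sympatry_matrix(
    occ: OccurrenceTable,
    threshold_km: float = 5.0,
    min_points: int = 10,
    method: str = "indexed",
    symmetrize: bool = False,
) -> SympatryMatrix:
    """Directed sympatry matrix over every species pair in the table."""
    if len(occ.species) < 2:
        raise ValidationError("sympatry requires at least 2 species")
    if threshold_km < 0 or min_points < 1:
        raise ValidationError("threshold_km must be >= 0 and min_points >= 1")
    counts = _counts_indexed if method == "indexed" else _counts_bruteforce
    species, N = counts(occ, threshold_km)
    return SympatryMatrix(species, N, threshold_km, min_points, symmetrized=symmetrize)


def sympatric_congeners(
    occ: OccurrenceTable, focal: str, threshold_km: float = 5.0, min_points: int = 10
) -> list[tuple[str, int]]:
    """Species sympatric with ``focal`` under the directed rule, with supporting counts."""
    if focal not in occ.species:
        raise ValidationError(f"focal species {focal!r} absent from occurrences")
    symp = sympatry_matrix(occ, threshold_km, min_points)
    return symp.congeners_of(focal)
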