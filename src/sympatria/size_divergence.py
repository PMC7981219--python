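"""Body-size classes and the signed divergent-sympatry statistic.

Sizes are split into k classes (default small/medium/large) by Fisher–Jenks
optimal 1-D classification — the partition minimizing total within-class sum
of squared deviations. For each focal species, the signed statistic compares
the size-class counts of its sympatric congeners with the counts expected
from the genus-wide size-class frequencies:

    chi2 = sum_c (O_c - E_c)^2 / E_c        over classes with E_c > 0

and the sign is -1 when the focal's own class is over-represented among its
sympatric congeners (convergent sympatry) and +1 otherwise (divergent).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .occurrence_io import TraitTable
from .sympatry import SympatryMatrix
from .utils import ValidationError

CLASS_NAMES_3 = ("small", "medium", "large")


# ---------------------------------------------------------------------------
# Fisher–Jenks natural breaks
# ---------------------------------------------------------------------------
def jenks_class_bounds(values: np.ndarray, k: int) -> list[float]:
    """Upper bound of each of the k optimal classes (Fisher–Jenks dynamic program).

    O(k n^2); within-class cost is the sum of squared deviations from the
    class mean. Returns k strictly increasing class maxima.
    """
    x = np.sort(np.asarray(values, float))
    n = len(x)
    # prefix sums give O(1) within-class SS for any contiguous run
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:  # SS of x[i..j-1], 0-based half-open
        m = j - i
        s = cs[j] - cs[i]
        return max((cs2[j] - cs2[i]) - s * s / m, 0.0)

    best = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for m in range(1, k + 1):
        for j in range(m, n + 1):
            for i in range(m - 1, j):
                c = best[m - 1, i] + cost(i, j)
                if c < best[m, j]:
                    best[m, j] = c
                    back[m, j] = i
    bounds = []
    j = n
    for m in range(k, 0, -1):
        bounds.append(x[j - 1])
        j = back[m, j]
    return bounds[::-1]


@dataclass
class SizeClassification:
    """k-class size partition with explicit break thresholds.

    ``breaks`` holds k-1 thresholds: values <= breaks[0] fall in the first
    class, <= breaks[1] in the second, etc. (boundary values go to the lower
    class).
    """

    breaks: tuple[float, ...]
    classes: dict[str, str]
    class_names: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {c: sum(1 for v in self.classes.values() if v == c) for c in self.class_names}

    def proportions(self, exclude: str | None = None) -> np.ndarray:
        pool = [sp for sp in self.classes if sp != exclude]
        return np.array(
            [sum(1 for sp in pool if self.classes[sp] == c) for c in self.class_names], float
        ) / len(pool)

    def of(self, sp: str) -> str:
        if sp not in self.classes:
            raise ValidationError(f"species {sp!r} not classified")
        return self.classes[sp]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"species": sorted(self.classes), "size_class": [self.classes[s] for s in sorted(self.classes)]}
        )


def classify_sizes(
    traits: TraitTable, k: int = 3, breaks: tuple[float, ...] | None = None
) -> SizeClassification:
    """Fisher–Jenks k-class body-size classification (or user-supplied breaks).

    Explicit ``breaks`` (k-1 thresholds) override the optimization, matching
    workflows where class limits were chosen by eye from a histogram.
    """
    values = np.array([traits.svl_mm[s] for s in traits.species])
    if breaks is None:
        if len(np.unique(values)) < k:
            raise ValidationError(f"need at least {k} distinct trait values for {k} classes")
        bounds = jenks_class_bounds(values, k)
        breaks = tuple(bounds[:-1])
    else:
        breaks = tuple(sorted(float(b) for b in breaks))
        if len(breaks) != k - 1:
            raise ValidationError(f"expected {k - 1} breaks, got {len(breaks)}")
    names = CLASS_NAMES_3 if k == 3 else tuple(f"class{i + 1}" for i in range(k))
    classes = {
        sp: names[int(np.searchsorted(np.array(breaks), traits.svl_mm[sp], side="left"))]
        for sp in traits.species
    }
    return SizeClassification(breaks, classes, names)


# ---------------------------------------------------------------------------
# divergent sympatry
# ---------------------------------------------------------------------------
@dataclass
class DivergentSympatryResult:
    focal: str
    focal_class: str
    observed: np.ndarray  # per-class counts of sympatric congeners
    expected: np.ndarray  # genus-frequency expectation, sums to n_sympatric
    chi2: float
    sign: int
    signed_score: float
    n_sympatric: int
    defined: bool = True

    def as_row(self) -> dict:
        row = {"focal": self.focal, "class": self.focal_class, "n_sympatric": self.n_sympatric}
        for name, o, e in zip(CLASS_NAMES_3, self.observed, self.expected):
            row[f"O_{name}"] = int(o)
            row[f"E_{name}"] = float(e)
        row.update(chi2=self.chi2, sign=self.sign, signed_score=self.signed_score, defined=self.defined)
        return row


def divergent_sympatry(
    focal: str,
    symp: SympatryMatrix,
    cls: SizeClassification,
    include_focal_in_pool: bool = False,
) -> DivergentSympatryResult:
    """Signed chi-squared divergence of a focal species' sympatric size spectrum.

    The expectation pool is every classified species except the focal (set
    ``include_focal_in_pool`` to keep it). A species with zero sympatric
    congeners yields a result flagged undefined, excluded downstream.
    """
    focal_class = cls.of(focal)
    congeners = [(b, n) for b, n in symp.congeners_of(focal) if b in cls.classes]
    names = cls.class_names
    observed = np.array([sum(1 for b, _ in congeners if cls.classes[b] == c) for c in names], float)
    n_symp = int(observed.sum())
    if n_symp == 0:
        return DivergentSympatryResult(
            focal, focal_class, observed, np.zeros(len(names)), np.nan, 1, np.nan, 0, defined=False
        )
    props = cls.proportions(exclude=None if include_focal_in_pool else focal)
    expected = n_symp * props
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    own = names.index(focal_class)
    sign = -1 if observed[own] > expected[own] else 1
    return DivergentSympatryResult(
        focal, focal_class, observed, expected, chi2, sign, sign * chi2, n_symp
    )


def all_divergent_sympatry(
    symp: SympatryMatrix, cls: SizeClassification, include_focal_in_pool: bool = False
) -> list[DivergentSympatryResult]:
    return [
        divergent_sympatry(sp, symp, cls, include_focal_in_pool)
        for sp in symp.species
        if sp in cls.classes
    ]


# ---------------------------------------------------------------------------
# composition tests
# ---------------------------------------------------------------------------
@dataclass
class CompositionTest:
    """Pearson goodness-of-fit of observed category counts against an expectation."""

    unit: str
    categories: tuple[str, ...]
    observed: np.ndarray
    expected: np.ndarray
    chi2: float
    df: int
    p_value: float
    tested: bool = True

    def as_row(self) -> dict:
        row = {"unit": self.unit, "chi2": self.chi2, "df": self.df, "p_value": self.p_value,
               "tested": self.tested}
        for c, o, e in zip(self.categories, self.observed, self.expected):
            row[f"O_{c}"] = float(o)
            row[f"E_{c}"] = float(e)
        return row


def _pearson_gof(observed: np.ndarray, expected: np.ndarray) -> tuple[float, int, float]:
    mask = expected > 0
    chi2 = float(np.sum((observed[mask] - expected[mask]) ** 2 / expected[mask]))
    df = int(mask.sum()) - 1
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else np.nan
    return chi2, df, p


def sign_category_test(
    results: list[DivergentSympatryResult], size_class: str, neutral_band: float = 0.0
) -> CompositionTest:
    """Uniform goodness-of-fit over divergent / near-neutral / convergent counts.

    Species of ``size_class`` (with a defined score) are partitioned by
    signed score: > +neutral_band, |score| <= neutral_band, < -neutral_band.
    With the default band of 0 every nonzero score is divergent or
    convergent; a positive band carves out the middle category.
    """
    scores = [r.signed_score for r in results if r.defined and r.focal_class == size_class]
    if not scores:
        raise ValidationError(f"no defined divergence results in class {size_class!r}")
    s = np.array(scores)
    observed = np.array(
        [np.sum(s > neutral_band), np.sum(np.abs(s) <= neutral_band), np.sum(s < -neutral_band)],
        float,
    )
    expected = np.full(3, len(s) / 3.0)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, 2))
    return CompositionTest(
        f"class:{size_class}", ("divergent", "neutral", "convergent"), observed, expected, chi2, 2, p
    )


def bioregion_size_composition(assignment, cls: SizeClassification) -> list[CompositionTest]:
    """Per-bioregion size-class composition vs genus-wide class frequencies.

    ``assignment`` is any object with a ``region_species`` mapping
    (region id -> species set). Regions with fewer than 2 classified species
    are flagged untested.
    """
    props = cls.proportions()
    names = cls.class_names
    tests = []
    for region in sorted(assignment.region_species):
        members = [sp for sp in assignment.region_species[region] if sp in cls.classes]
        observed = np.array([sum(1 for sp in members if cls.classes[sp] == c) for c in names], float)
        if len(members) < 2:
            tests.append(
                CompositionTest(f"region:{region}", names, observed, len(members) * props,
                                np.nan, 0, np.nan, tested=False)
            )
            continue
        expected = len(members) * props
        chi2, df, p = _pearson_gof(observed, expected)
        tests.append(CompositionTest(f"region:{region}", names, observed, expected, chi2, df, p))
    return tests
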