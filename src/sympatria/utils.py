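"""Shared constants, error types, and seed derivation."""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

#: Mean Earth radius (km), used for every great-circle quantity in the package.
EARTH_RADIUS_KM = 6371.0088
#: Length of one degree of a great circle on that sphere (km/deg).
KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


class ValidationError(ValueError):
    """Input data violates a documented bound or invariant."""


class SchemaError(ValueError):
    """A file is missing a required column/field."""


class PackingError(RuntimeError):
    """Synthetic range placement cannot satisfy the disjointness contract."""


def child_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived from a root seed and a stage name."""
    h = hashlib.sha256(f"{int(root_seed)}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


@dataclass
class StatResult:
    """One correlation/regression result (Spearman rho, Pearson rho, or OLS F)."""

    name: str
    estimate: float
    df: int
    p_value: float
    r2: float | None = None
    defined: bool = True

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "estimate": self.estimate,
            "df": self.df,
            "p_value": self.p_value,
            "r2": self.r2,
            "defined": self.defined,
        }
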