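"""Protein co-sedimentation across gradient fractions.

Immunoblot densitometry of gradient fractions gives, per protein and
sample, an intensity per fraction.  Because exposure differs between blots,
all comparisons are made on per-lane normalized shares (each protein-sample
lane sums to 1).  The association index is the share of signal found in a
target region (e.g. POLYSOMES, or {80S, POLYSOMES}); a shift between two
conditions is summarised as the change in association index and the change
in the signal's center of mass in fraction units (negative = toward lighter
fractions, as seen when EDTA dissociates ribosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COSED_COLUMNS = ("protein", "sample", "fraction_index", "intensity")


@dataclass
class CosedTable:
    """Long-format densitometry table plus a fraction -> region map."""

    data: pd.DataFrame
    fraction_regions: dict  # fraction_index -> region name

    def __post_init__(self) -> None:
        missing = [c for c in COSED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"co-sedimentation table missing columns {missing}")
        if (self.data["intensity"] < 0).any():
            raise ValueError("intensities must be >= 0")
        unmapped = set(self.data["fraction_index"]) - set(self.fraction_regions)
        if unmapped:
            raise ValueError(f"fractions without a region assignment: {sorted(unmapped)}")


def normalize_distribution(table: CosedTable, protein: str, sample: str) -> pd.Series:
    """Per-fraction signal shares for one protein-sample lane (sum to 1)."""
    sub = table.data[(table.data["protein"] == protein) & (table.data["sample"] == sample)]
    if sub.empty:
        raise ValueError(f"no rows for protein={protein!r}, sample={sample!r}")
    lane = sub.groupby("fraction_index")["intensity"].sum().sort_index()
    total = lane.sum()
    if total == 0:
        raise ValueError(f"all-zero lane for protein={protein!r}, sample={sample!r}")
    return lane / total


def _target_fractions(fraction_regions: Mapping, target) -> list:
    targets = {target} if isinstance(target, str) else set(target)
    unknown = targets - set(fraction_regions.values())
    if unknown:
        raise ValueError(f"target region(s) {sorted(unknown)} not present in the fraction map")
    return [f for f, r in fraction_regions.items() if r in targets]


def association_index(shares: pd.Series, fraction_regions: Mapping,
                      target="POLYSOMES") -> float:
    """Share of a protein's signal in the target region(s); in [0, 1]."""
    fracs = _target_fractions(fraction_regions, target)
    return float(shares.reindex(fracs).fillna(0.0).sum())


@dataclass
class SedimentationShift:
    delta_association: float      # index(b) - index(a)
    delta_center_of_mass: float   # in fraction units; negative = lighter
    center_of_mass_a: float
    center_of_mass_b: float


def center_of_mass(shares: pd.Series) -> float:
    """Signal-weighted mean fraction index."""
    return float((shares.index.to_numpy(dtype=float) * shares.to_numpy()).sum())


def sedimentation_shift(shares_a: pd.Series, shares_b: pd.Series,
                        fraction_regions: Mapping | None = None,
                        target="POLYSOMES") -> SedimentationShift:
    """Signed shift statistics of condition b relative to condition a."""
    if not shares_a.index.equals(shares_b.index):
        raise ValueError("fraction grids of the two distributions do not match")
    com_a, com_b = center_of_mass(shares_a), center_of_mass(shares_b)
    if fraction_regions is not None:
        d_assoc = (association_index(shares_b, fraction_regions, target)
                   - association_index(shares_a, fraction_regions, target))
    else:
        d_assoc = float("nan")
    return SedimentationShift(delta_association=d_assoc,
                              delta_center_of_mass=com_b - com_a,
                              center_of_mass_a=com_a, center_of_mass_b=com_b)


def default_fraction_regions(fraction_count: int = 12) -> dict:
    """Region map for a gradient collected in `fraction_count` fractions.

    Light-to-heavy assignment mirroring a typical 12-fraction gradient:
    RNP in the first two fractions, one fraction each for 40S and 60S, two
    for the 80S monosome, the rest polysomal.
    """
    if fraction_count < 6:
        raise ValueError("need at least 6 fractions to represent all regions")
    regions = {}
    plan = [("RNP", 2), ("40S", 1), ("60S", 1), ("80S", 2)]
    f = 1
    for name, count in plan:
        for _ in range(count):
            regions[f] = name
            f += 1
    while f <= fraction_count:
        regions[f] = "POLYSOMES"
        f += 1
    return regions
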