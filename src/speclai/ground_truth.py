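"""Destructive ground-truth LAI from leaf-subsample measurements.

Field protocol: all leaves from a known ground area (a 1 m^2 quadrat) are
collected and weighed (``w1``); five leaves are cut to a fixed segment
length, their area ``s1`` measured, and weighed (``w2``).  Total leaf area
scales the measured segment area by the fresh-weight ratio, and LAI is total
one-sided leaf area per unit ground area.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LeafSubsample", "total_leaf_area", "lai_from_area", "compute_lai",
           "read_subsamples", "CM2_PER_M2"]

CM2_PER_M2 = 1.0e4

#: weight-proportional scale-up S = s1 * w1 / w2 (default), plus two audit
#: variants for alternative readings of ambiguous protocol write-ups
FORMULA_VARIANTS = ("w1_over_w2", "sum_over_w1", "sum_over_w2")


@dataclass(frozen=True)
class LeafSubsample:
    """One quadrat's destructive measurements.

    s1_cm2 : area of the five cut leaf segments (cm^2)
    w1_g   : fresh weight of all leaves from the quadrat (g)
    w2_g   : fresh weight of the five cut leaves (g)
    ground_area_m2 : sampled ground area (m^2), default 1
    """

    s1_cm2: float
    w1_g: float
    w2_g: float
    ground_area_m2: float = 1.0

    def __post_init__(self) -> None:
        if self.s1_cm2 <= 0 or self.w1_g <= 0 or self.w2_g <= 0:
            raise ValueError("areas and weights must be positive")
        if self.w2_g > self.w1_g:
            raise ValueError("cut-leaf weight w2 cannot exceed total weight w1")
        if self.ground_area_m2 <= 0:
            raise ValueError("ground area must be positive")


def total_leaf_area(sub: LeafSubsample, variant: str = "w1_over_w2") -> float:
    """Total one-sided leaf area S (cm^2) of the quadrat.

    Default: S = s1 * w1 / w2, the weight-proportional scale-up of the cut
    segment area.  ``variant`` selects alternative readings for audit:
    ``sum_over_w1`` -> s1 * (w1 + w2) / w1; ``sum_over_w2`` ->
    s1 * (w1 + w2) / w2.
    """
    if variant == "w1_over_w2":
        return sub.s1_cm2 * sub.w1_g / sub.w2_g
    if variant == "sum_over_w1":
        return sub.s1_cm2 * (sub.w1_g + sub.w2_g) / sub.w1_g
    if variant == "sum_over_w2":
        return sub.s1_cm2 * (sub.w1_g + sub.w2_g) / sub.w2_g
    raise ValueError(f"unknown formula variant {variant!r}; choose from {FORMULA_VARIANTS}")


def lai_from_area(total_area: float, ground_area_m2: float, area_units: str = "cm2") -> float:
    """LAI = total leaf area / ground area (dimensionless).

    ``area_units`` names the units of ``total_area`` ("cm2" or "m2"); the
    ground area is always in m^2.
    """
    if ground_area_m2 <= 0:
        raise ValueError("ground area must be positive")
    if total_area <= 0:
        raise ValueError("leaf area must be positive")
    if area_units == "cm2":
        total_m2 = total_area / CM2_PER_M2
    elif area_units == "m2":
        total_m2 = total_area
    else:
        raise ValueError("area_units must be 'cm2' or 'm2'")
    return total_m2 / ground_area_m2


def compute_lai(sub: LeafSubsample, variant: str = "w1_over_w2") -> float:
    """Ground-truth LAI for one quadrat."""
    s_cm2 = total_leaf_area(sub, variant=variant)
    return lai_from_area(s_cm2, sub.ground_area_m2, area_units="cm2")


def read_subsamples(path, variant: str = "w1_over_w2") -> pd.DataFrame:
    """Read a per-sample CSV (sample_id,s1_cm2,w1_g,w2_g,ground_area_m2)
    and append the computed ``lai`` column."""
    df = pd.read_csv(path)
    required = {"sample_id", "s1_cm2", "w1_g", "w2_g"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"subsample table missing columns: {sorted(missing)}")
    if "ground_area_m2" not in df.columns:
        df["ground_area_m2"] = 1.0
    df["lai"] = [
        compute_lai(
            LeafSubsample(r.s1_cm2, r.w1_g, r.w2_g, r.ground_area_m2), variant=variant
        )
        for r in df.itertuples()
    ]
    return df
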