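"""Calibration/validation splitting and model-quality metrics.

Models are judged by the coefficient of determination (R^2), root mean
squared error (RMSE) and the ratio of performance to deviation (RPD =
SD(observed) / RMSE), with the conventional RPD classes: > 2 good,
1.4-2 (inclusive) moderate, < 1.4 poor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalValSplit",
    "ModelReport",
    "split_cal_val",
    "rmse",
    "r_squared",
    "rpd",
    "rpd_class",
    "evaluate_predictions",
    "write_report_table",
]

RPD_GOOD = 2.0
RPD_MODERATE = 1.4


@dataclass(frozen=True)
class CalValSplit:
    """Disjoint calibration/validation sample-id lists."""

    calibration_ids: tuple
    validation_ids: tuple
    seed: int

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation ids overlap")
        if not self.calibration_ids or not self.validation_ids:
            raise ValueError("both sides of the split must be non-empty")


def split_cal_val(sample_ids, ratio: float = 2 / 3, seed: int = 0) -> CalValSplit:
    """Uniform random split without replacement.

    The calibration side receives ``round(ratio * n)`` samples, which
    reproduces the conventional 2:1 splits 93 -> (62, 31) and 84 -> (56, 28).
    Deterministic under a fixed seed.
    """
    ids = list(sample_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0 < ratio < 1):
        raise ValueError("ratio must be in (0, 1)")
    n_cal = int(round(ratio * n))
    if n_cal < 1 or n_cal >= n:
        raise ValueError(f"split ratio {ratio} leaves an empty side for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cal = tuple(ids[i] for i in sorted(perm[:n_cal]))
    val = tuple(ids[i] for i in sorted(perm[n_cal:]))
    return CalValSplit(calibration_ids=cal, validation_ids=val, seed=seed)


# ---------------------------------------------------------------------------
# metrics


def rmse(observed, predicted) -> float:
    """Root mean squared error, same units as the observations."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size == 0:
        raise ValueError("observed and predicted must be equal-length, non-empty")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def r_squared(observed, predicted, method: str = "pearson") -> float:
    """Coefficient of determination.

    Default is the squared Pearson correlation between observed and
    predicted (the convention behind 1:1 scatter evaluation);
    ``method='deviation'`` gives 1 - SSE/SST instead.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need at least 3 equal-length pairs")
    if np.std(obs) == 0:
        raise ValueError("observed values have zero variance")
    if method == "pearson":
        if np.std(pred) == 0:
            raise ValueError("predicted values have zero variance")
        r = np.corrcoef(obs, pred)[0, 1]
        return float(r**2)
    if method == "deviation":
        sse = float(np.sum((obs - pred) ** 2))
        sst = float(np.sum((obs - obs.mean()) ** 2))
        return 1.0 - sse / sst
    raise ValueError("method must be 'pearson' or 'deviation'")


def rpd(observed, rmse_value: float) -> float:
    """Ratio of performance to deviation: SD(observed, n-1) / RMSE."""
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 observed values")
    sd = float(np.std(obs, ddof=1))
    if sd == 0:
        raise ValueError("observed values have zero variance; RPD undefined")
    if rmse_value <= 0:
        raise ValueError("degenerate-perfect fit (RMSE = 0); RPD undefined")
    return sd / rmse_value


def rpd_class(rpd_value: float) -> str:
    """good: RPD > 2; moderate: 1.4 <= RPD <= 2 (closed); poor: RPD < 1.4."""
    if rpd_value <= 0:
        raise ValueError("RPD must be positive")
    if rpd_value > RPD_GOOD:
        return "good"
    if rpd_value >= RPD_MODERATE:
        return "moderate"
    return "poor"


# ---------------------------------------------------------------------------
# model reports


@dataclass
class ModelReport:
    """R^2/RMSE/RPD summary of one model on one data split, with the
    (observed, predicted) pairs for 1:1 plotting."""

    split: str
    r_squared: float
    rmse: float
    rpd: float
    rpd_class: str
    n: int
    predictions: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.split not in ("calibration", "validation"):
            raise ValueError("split must be 'calibration' or 'validation'")
        if self.rmse < 0 or self.rpd <= 0:
            raise ValueError("rmse must be >= 0 and rpd > 0")
        if self.rpd_class != rpd_class(self.rpd):
            raise ValueError("rpd_class inconsistent with thresholds")
        if self.n != len(self.predictions):
            raise ValueError("n must equal the number of prediction pairs")

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "rpd": self.rpd,
            "rpd_class": self.rpd_class,
            "n": self.n,
            "predictions": [[float(o), float(p)] for o, p in self.predictions],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelReport":
        return cls(
            split=d["split"], r_squared=d["r_squared"], rmse=d["rmse"],
            rpd=d["rpd"], rpd_class=d["rpd_class"], n=d["n"],
            predictions=[tuple(p) for p in d["predictions"]],
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ModelReport":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def evaluate_predictions(observed, predicted, split: str) -> ModelReport:
    """Build a ModelReport from observed/predicted vectors."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    e_rmse = rmse(obs, pred)
    e_r2 = r_squared(obs, pred)
    e_rpd = rpd(obs, e_rmse)
    return ModelReport(
        split=split, r_squared=e_r2, rmse=e_rmse, rpd=e_rpd,
        rpd_class=rpd_class(e_rpd), n=obs.size,
        predictions=list(zip(obs.tolist(), pred.tolist())),
    )


def write_report_table(reports: dict, path) -> pd.DataFrame:
    """Model-comparison table: method,field_type,split,r2,rmse,rpd,rpd_class,n_variables.

    ``reports`` maps (method, field_type, split) -> (ModelReport, n_variables).
    """
    rows = []
    for (method, field_type, split), (rep, n_vars) in reports.items():
        rows.append(
            {"method": method, "field_type": field_type, "split": split,
             "r2": rep.r_squared, "rmse": rep.rmse, "rpd": rep.rpd,
             "rpd_class": rep.rpd_class, "n_variables": n_vars}
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
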