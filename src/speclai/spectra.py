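"""Containers for canopy reflectance spectra and their wide-CSV dialect.

A :class:`SpectraSet` holds one replicate-averaged spectrum per sample on a
common wavelength grid, together with per-sample metadata (field type, growth
stage, measured LAI).  A :class:`ReplicateSpectra` holds the raw replicate
scans before averaging.  Both round-trip through plain CSV so that simulated
and user-supplied data flow through the same pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIELD_TYPES = ("irrigated", "rainfed")

#: metadata columns stored alongside the reflectance matrix, in CSV order
META_COLUMNS = ("sample_id", "field_type", "stage", "lai")


def _validate_grid(wavelengths: np.ndarray) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size == 0:
        raise ValueError("wavelength grid must be a non-empty 1-D vector")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    return wl


@dataclass
class SpectraSet:
    """Relative reflectance matrix (samples x bands) with sample metadata.

    Parameters
    ----------
    wavelengths : (p,) array, nm, strictly increasing.
    reflectance : (n, p) array, dimensionless relative reflectance, finite
        and non-negative.
    metadata : DataFrame with at least ``sample_id``; ``field_type``,
        ``stage`` and ``lai`` are carried when present.  ``lai`` may be
        absent for prediction-only sets.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.wavelengths = _validate_grid(self.wavelengths)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        n, p = self.reflectance.shape
        if p != self.wavelengths.size:
            raise ValueError(
                f"reflectance has {p} columns but grid has {self.wavelengths.size} bands"
            )
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance must be finite")
        if np.any(self.reflectance < 0):
            raise ValueError("reflectance must be non-negative")
        if self.metadata is None:
            self.metadata = pd.DataFrame(
                {"sample_id": [f"s{i:04d}" for i in range(n)]}
            )
        self.metadata = self.metadata.reset_index(drop=True)
        if len(self.metadata) != n:
            raise ValueError("metadata row count must match sample count")
        ids = self.metadata["sample_id"]
        if ids.duplicated().any():
            raise ValueError("sample_ids must be unique")

    # -- basic accessors ---------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_bands(self) -> int:
        return self.reflectance.shape[1]

    @property
    def sample_ids(self) -> np.ndarray:
        return self.metadata["sample_id"].to_numpy()

    @property
    def lai(self) -> np.ndarray | None:
        if "lai" not in self.metadata:
            return None
        return self.metadata["lai"].to_numpy(dtype=float)

    def band_index(self, nm: float) -> int:
        """Index of the grid point closest to ``nm``."""
        return int(np.argmin(np.abs(self.wavelengths - nm)))

    def select_samples(self, sample_ids) -> "SpectraSet":
        """Subset by sample id, preserving the requested order."""
        pos = pd.Index(self.metadata["sample_id"]).get_indexer(list(sample_ids))
        if np.any(pos < 0):
            missing = [s for s, p_ in zip(sample_ids, pos) if p_ < 0]
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return SpectraSet(
            self.wavelengths.copy(),
            self.reflectance[pos].copy(),
            self.metadata.iloc[pos].reset_index(drop=True),
        )

    # -- wide-CSV dialect --------------------------------------------------
    # header: sample_id,field_type,stage,lai,R400,R401,...  UTF-8, '.' decimal.

    def to_wide_csv(self, path) -> None:
        df = self.to_frame()
        df.to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        cols = [c for c in META_COLUMNS if c in self.metadata.columns]
        band_cols = [f"R{wl:g}" for wl in self.wavelengths]
        bands = pd.DataFrame(self.reflectance, columns=band_cols)
        return pd.concat([self.metadata[cols].reset_index(drop=True), bands], axis=1)

    @classmethod
    def from_wide_csv(cls, path) -> "SpectraSet":
        # round_trip parsing keeps write->read bit-exact for reproducibility
        df = pd.read_csv(path, float_precision="round_trip")
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SpectraSet":
        band_cols = [c for c in df.columns if c.startswith("R") and c[1:].replace(".", "", 1).isdigit()]
        if not band_cols:
            raise ValueError("no reflectance columns (R<nm>) found")
        wavelengths = np.array([float(c[1:]) for c in band_cols])
        order = np.argsort(wavelengths)
        wavelengths = wavelengths[order]
        reflectance = df[band_cols].to_numpy(dtype=float)[:, order]
        meta_cols = [c for c in df.columns if c not in band_cols]
        return cls(wavelengths, reflectance, df[meta_cols].copy())


@dataclass
class ReplicateSpectra:
    """Raw replicate scans: shape (samples, replicates, bands)."""

    wavelengths: np.ndarray
    reflectance: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = _validate_grid(self.wavelengths)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 3:
            raise ValueError("replicate reflectance must be (samples, replicates, bands)")
        if self.reflectance.shape[2] != self.wavelengths.size:
            raise ValueError("band axis must match wavelength grid")
        if self.reflectance.shape[1] < 1:
            raise ValueError("at least one replicate scan is required")
        if len(self.metadata) != self.reflectance.shape[0]:
            raise ValueError("metadata row count must match sample count")

    @property
    def n_replicates(self) -> int:
        return self.reflectance.shape[1]

    def to_long_csv(self, path) -> None:
        """Long-format replicate file: one row per (sample, replicate)."""
        rows = []
        band_cols = [f"R{wl:g}" for wl in self.wavelengths]
        for i in range(self.reflectance.shape[0]):
            for r in range(self.n_replicates):
                row = {c: self.metadata.iloc[i][c] for c in self.metadata.columns}
                row["replicate"] = r + 1
                row.update(dict(zip(band_cols, self.reflectance[i, r])))
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
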