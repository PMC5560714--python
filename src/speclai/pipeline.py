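"""End-to-end orchestration: spectra -> preprocessing -> split -> correlation
analysis -> SPA-MLR and full-spectrum PLSR -> evaluation tables.

Each field type (irrigated, rainfed) is analysed as a fully independent run
sharing only the code path; one global seed drives an explicit per-stage
seed sequence so any stage can be reproduced in isolation.  All artifacts
are plain CSV/JSON under the output directory, listed in a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import (
    evaluate_predictions,
    split_cal_val,
    write_report_table,
)
from .models import correlation_curve, fit_mlr, fit_plsr, loo_select_factors, vip_scores
from .preprocess import average_replicates, savgol_smooth, subset_band_range
from .spa import spa_select, write_band_table
from .spectra import FIELD_TYPES, SpectraSet
from .synthetic import (
    SimulationConfig,
    irrigated_defaults,
    rainfed_defaults,
    simulate_canopy,
)

logger = logging.getLogger("speclai")

__all__ = ["PipelineConfig", "FieldResult", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    ``mode`` is ``simulate`` (generate synthetic populations) or ``files``
    (read wide-CSV spectra).  In simulate mode the per-field simulation
    seeds are derived from the pipeline ``seed``, so one integer reproduces
    the whole run.
    """

    mode: str = "simulate"
    seed: int = 0
    fields: dict = dc_field(default_factory=dict)   # field_type -> SimulationConfig
    files: dict = dc_field(default_factory=dict)    # field_type -> csv path
    window_points: int = 9
    polyorder: int = 2
    band_low_nm: float = 400.0
    band_high_nm: float = 1400.0
    split_ratio: float = 2 / 3
    spa_m_min: int = 10
    spa_m_max: int = 10
    plsr_max_factors: int = 12

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if self.band_low_nm >= self.band_high_nm:
            raise ValueError(
                f"invalid band range [{self.band_low_nm:g}, {self.band_high_nm:g}]: "
                "band range low must be below high"
            )
        if not (0 < self.split_ratio < 1):
            raise ValueError("split ratio must be in (0, 1)")
        if not (1 <= self.spa_m_min <= self.spa_m_max):
            raise ValueError("spa m_min/m_max must satisfy 1 <= m_min <= m_max")
        if self.plsr_max_factors < 1:
            raise ValueError("plsr max_factors must be >= 1")
        if self.mode == "simulate" and not self.fields:
            self.fields = {
                "irrigated": irrigated_defaults(),
                "rainfed": rainfed_defaults(),
            }
        if self.mode == "files" and not self.files:
            raise ValueError("files mode requires a 'files' mapping field_type -> csv")

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        pre = d.pop("preprocess", {})
        split = d.pop("split", {})
        spa = d.pop("spa", {})
        plsr = d.pop("plsr", {})
        fields = {}
        for name, overrides in (d.pop("fields", None) or {}).items():
            if name not in FIELD_TYPES:
                raise ValueError(f"unknown field type {name!r} in 'fields'")
            base = irrigated_defaults() if name == "irrigated" else rainfed_defaults()
            fields[name] = base.with_(**(overrides or {}))
        m = spa.pop("m", None)
        kwargs = dict(
            mode=d.pop("mode", "simulate"),
            seed=int(d.pop("seed", 0)),
            files=d.pop("files", None) or {},
            window_points=int(pre.get("window_points", 9)),
            polyorder=int(pre.get("polyorder", 2)),
            band_low_nm=float(pre.get("band_low_nm", 400.0)),
            band_high_nm=float(pre.get("band_high_nm", 1400.0)),
            split_ratio=float(split.get("ratio", 2 / 3)),
            spa_m_min=int(spa.get("m_min", m if m is not None else 10)),
            spa_m_max=int(spa.get("m_max", m if m is not None else 10)),
            plsr_max_factors=int(plsr.get("max_factors", 12)),
        )
        if fields:
            kwargs["fields"] = fields
        d.pop("out_dir", None)
        if d:
            raise ValueError(f"unknown config keys: {sorted(d)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "seed": self.seed,
            "fields": {
                name: {k: getattr(cfg, k) for k in cfg.__dataclass_fields__}
                for name, cfg in self.fields.items()
            },
            "files": {k: str(v) for k, v in self.files.items()},
            "preprocess": {
                "window_points": self.window_points,
                "polyorder": self.polyorder,
                "band_low_nm": self.band_low_nm,
                "band_high_nm": self.band_high_nm,
            },
            "split": {"ratio": self.split_ratio},
            "spa": {"m_min": self.spa_m_min, "m_max": self.spa_m_max},
            "plsr": {"max_factors": self.plsr_max_factors},
        }


def _stage_seeds(seed: int, field_type: str) -> dict[str, int]:
    """Per-stage integer seeds (< 2^31), stable in the field name."""
    base = int(np.random.SeedSequence(
        [seed, FIELD_TYPES.index(field_type)]
    ).generate_state(1)[0])
    ss = np.random.SeedSequence(base).spawn(2)
    return {
        "simulate": int(ss[0].generate_state(1)[0] % (2**31)),
        "split": int(ss[1].generate_state(1)[0] % (2**31)),
    }


@dataclass
class FieldResult:
    """All per-field outputs of one pipeline run."""

    field_type: str
    spectra: SpectraSet
    split: object
    correlation: object
    spa_result: object
    mlr_model: object
    plsr_model: object
    plsr_factors: int
    vip: np.ndarray
    reports: dict  # (method, split) -> ModelReport


@dataclass
class PipelineResult:
    config: PipelineConfig
    fields: dict[str, FieldResult]
    out_dir: Path | None
    artifacts: list[str]


def _descriptives(lai: np.ndarray) -> dict:
    return {
        "n": int(lai.size),
        "range": float(lai.max() - lai.min()),
        "minimum": float(lai.min()),
        "maximum": float(lai.max()),
        "mean": float(lai.mean()),
        "sd": float(np.std(lai, ddof=1)),
    }


def _prepare_field_spectra(config: PipelineConfig, field_type: str,
                           out_dir: Path | None, artifacts: list[str]) -> SpectraSet:
    if config.mode == "simulate":
        sim_cfg: SimulationConfig = config.fields[field_type]
        sim_cfg = sim_cfg.with_(seed=_stage_seeds(config.seed, field_type)["simulate"])
        reps = simulate_canopy(sim_cfg)
        logger.info("%s: simulated %d samples x %d replicates x %d bands",
                    field_type, *reps.reflectance.shape)
        averaged = average_replicates(reps)
        if out_dir is not None:
            path = out_dir / f"spectra_{field_type}.csv"
            averaged.to_wide_csv(path)
            artifacts.append(path.name)
    else:
        averaged = SpectraSet.from_wide_csv(config.files[field_type])
        logger.info("%s: read %d samples x %d bands from %s",
                    field_type, averaged.n_samples, averaged.n_bands,
                    config.files[field_type])
    smoothed = savgol_smooth(averaged, config.window_points, config.polyorder)
    return subset_band_range(smoothed, config.band_low_nm, config.band_high_nm)


def _run_field(config: PipelineConfig, field_type: str,
               out_dir: Path | None, artifacts: list[str]) -> FieldResult:
    spectra = _prepare_field_spectra(config, field_type, out_dir, artifacts)
    if spectra.lai is None:
        raise ValueError(f"{field_type}: spectra have no 'lai' column; cannot model")

    split = split_cal_val(spectra.sample_ids, config.split_ratio,
                          _stage_seeds(config.seed, field_type)["split"])
    cal = spectra.select_samples(split.calibration_ids)
    val = spectra.select_samples(split.validation_ids)
    logger.info("%s: split %d calibration / %d validation",
                field_type, cal.n_samples, val.n_samples)

    corr = correlation_curve(cal.reflectance, cal.lai, cal.wavelengths)

    spa_res = spa_select(
        cal.reflectance, cal.lai, val.reflectance, val.lai,
        config.spa_m_min, config.spa_m_max, wavelengths=spectra.wavelengths,
    )
    logger.info("%s: SPA selected %d bands (start %d): %s nm",
                field_type, spa_res.n_selected, spa_res.start_index_chosen,
                np.sort(spa_res.selected_wavelengths_nm).astype(int).tolist())
    idx = spa_res.selected_indices
    mlr = fit_mlr(cal.reflectance[:, idx], cal.lai, band_indices=idx)

    n_factors, rmsecv = loo_select_factors(cal.reflectance, cal.lai,
                                           config.plsr_max_factors)
    plsr = fit_plsr(cal.reflectance, cal.lai, n_factors)
    plsr.rmsecv_curve = rmsecv
    vip = vip_scores(plsr)
    logger.info("%s: PLSR kept %d factors (RMSECV %.3f)",
                field_type, n_factors, rmsecv[n_factors])

    reports = {}
    for method, model, bands in (
        ("SPA-MLR", mlr, idx),
        ("PLSR", plsr, slice(None)),
    ):
        for split_name, subset in (("calibration", cal), ("validation", val)):
            pred = model.predict(subset.reflectance[:, bands])
            reports[(method, split_name)] = evaluate_predictions(
                subset.lai, pred, split_name
            )

    result = FieldResult(
        field_type=field_type, spectra=spectra, split=split, correlation=corr,
        spa_result=spa_res, mlr_model=mlr, plsr_model=plsr,
        plsr_factors=n_factors, vip=vip, reports=reports,
    )
    if out_dir is not None:
        _write_field_artifacts(result, rmsecv, out_dir, artifacts)
    return result


def _write_field_artifacts(res: FieldResult, rmsecv: dict,
                           out_dir: Path, artifacts: list[str]) -> None:
    ft = res.field_type
    res.correlation.to_frame().to_csv(out_dir / f"correlation_{ft}.csv", index=False)
    pd.DataFrame(
        {"n_factors": list(rmsecv), "rmsecv": list(rmsecv.values())}
    ).to_csv(out_dir / f"rmsecv_{ft}.csv", index=False)
    pd.DataFrame(
        {"wavelength_nm": res.spectra.wavelengths, "vip": res.vip,
         "b_coefficient": res.plsr_model.b_coefficients}
    ).to_csv(out_dir / f"vip_b_{ft}.csv", index=False)
    for (method, split_name), rep in res.reports.items():
        name = f"predictions_{method.lower().replace('-', '_')}_{split_name}_{ft}.csv"
        pd.DataFrame(rep.predictions, columns=["observed", "predicted"]).to_csv(
            out_dir / name, index=False
        )
        artifacts.append(name)
    res.plsr_model.to_json(out_dir / f"plsr_model_{ft}.json")
    with open(out_dir / f"mlr_model_{ft}.json", "w", encoding="utf-8") as fh:
        json.dump(res.mlr_model.to_dict(), fh, indent=1)
    artifacts.extend(
        [f"correlation_{ft}.csv", f"rmsecv_{ft}.csv", f"vip_b_{ft}.csv",
         f"plsr_model_{ft}.json", f"mlr_model_{ft}.json"]
    )


def run_pipeline(config: PipelineConfig, out_dir=None,
                 field: str = "both") -> PipelineResult:
    """Execute the full per-field workflow and (optionally) write artifacts.

    ``field`` restricts the run to one field type; default analyses both
    independently.  Identical config + seed produce identical outputs.
    """
    if field not in FIELD_TYPES + ("both",):
        raise ValueError(f"field must be one of {FIELD_TYPES + ('both',)}")
    targets = list(FIELD_TYPES) if field == "both" else [field]
    available = config.fields if config.mode == "simulate" else config.files
    targets = [t for t in targets if t in available]
    if not targets:
        raise ValueError("no requested field type is present in the config")

    out_path = None
    artifacts: list[str] = []
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)

    results: dict[str, FieldResult] = {}
    for ft in targets:
        try:
            results[ft] = _run_field(config, ft, out_path, artifacts)
        except Exception as err:
            raise RuntimeError(f"pipeline failed for field {ft!r}: {err}") from err

    if out_path is not None:
        _write_summary_artifacts(config, results, out_path, artifacts)
    return PipelineResult(config=config, fields=results, out_dir=out_path,
                          artifacts=artifacts)


def _write_summary_artifacts(config: PipelineConfig, results: dict,
                             out_path: Path, artifacts: list[str]) -> None:
    # Table-1-style descriptives
    rows = []
    for ft, res in results.items():
        lai = res.spectra.lai
        ids = pd.Index(res.spectra.metadata["sample_id"])
        for split_name, id_list in (
            ("calibration", res.split.calibration_ids),
            ("validation", res.split.validation_ids),
        ):
            stats = _descriptives(lai[ids.get_indexer(list(id_list))])
            rows.append({"field_type": ft, "set": split_name, **stats})
    pd.DataFrame(rows).to_csv(out_path / "descriptives.csv", index=False)

    write_band_table({ft: r.spa_result for ft, r in results.items()},
                     out_path / "selected_bands.csv")

    reports = {}
    for ft, res in results.items():
        for (method, split_name), rep in res.reports.items():
            n_vars = (res.spa_result.n_selected if method == "SPA-MLR"
                      else res.plsr_factors)
            reports[(method, ft, split_name)] = (rep, n_vars)
    write_report_table(reports, out_path / "model_performance.csv")

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    artifacts.extend(["descriptives.csv", "selected_bands.csv",
                      "model_performance.csv", "manifest.json"])
    manifest = {
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "speclai_version": __version__,
        "numpy_version": np.__version__,
        "artifacts": sorted(set(artifacts)),
    }
    with open(out_path / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
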