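"""End-to-end orchestration of the radiomics survival analysis.

Stages (each toggleable, each persisting its artifacts so any stage can be
re-run from files):

    simulate -> standardize -> [sweep] -> extract -> harmonize ->
    filter -> select -> model

A :class:`PipelineConfig` is a plain, YAML-serializable record of every
parameter; ``run_pipeline`` executes the enabled stages in order inside a
run directory and writes a ``run.json`` log with the config hash, seeds
and stage outcomes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .combat import combat_fit_transform
from .coxsuite import build_four_models
from .cvselect import (
    event_matched_folds,
    redundancy_filter,
    run_selection_comparison,
    volume_filter,
)
from .imgprep import nyul_apply, nyul_train, resample_isotropic
from .robustsel import quantization_sweep
from .synthcohort import CohortConfig, cohort_frame, generate_cohort, read_cohort, write_cohort
from .texturefeat import FEATURE_CLASSES, WAVELET_SUBBANDS, extract_all

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: str = "radsurv_run"
    seed: int = 0
    # stage toggles
    simulate: bool = True
    standardize: bool = True
    sweep: bool = False
    extract: bool = True
    harmonize: bool = True
    select: bool = True
    model: bool = True
    # synthetic cohort parameters (passed to CohortConfig)
    cohort: dict = field(default_factory=dict)
    input_cohort_dir: str | None = None
    # standardization
    nyul_percentiles: list = field(
        default_factory=lambda: [1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99]
    )
    mask_histograms: bool = True
    # extraction
    bin_number: int = 32
    voxel_mm: float = 1.0
    filters: list = field(
        default_factory=lambda: ["original"]
        + [f"wavelet-{s}" for s in WAVELET_SUBBANDS]
    )
    classes: list = field(default_factory=lambda: list(FEATURE_CLASSES))
    # robustness sweep
    sweep_bins: list = field(default_factory=lambda: [8, 32, 128])
    sweep_voxels: list = field(default_factory=lambda: [1.0, 2.0])
    icc_threshold: float = 0.8
    # unsupervised filters
    volume_rho_threshold: float = 0.5
    redundancy_r_threshold: float = 0.5
    # cross-validated selection
    cv_k: int = 5
    cv_repeats: int = 40
    selection_alpha: float = 0.05
    mrmr_max_k: int = 10
    max_candidate_features: int | None = None
    # modelling
    bootstrap_B: int = 0

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(log: dict, name: str):
    log["stages"].append(name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the enabled stages; returns the run directory.

    Every intermediate is persisted (cohort files, standardized feature
    matrices, selection summary, model report).  A stage failure raises
    :class:`PipelineError` naming the stage; artifacts written before the
    failure are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": [],
    }
    config.to_yaml(out / "config.yaml")

    # --- simulate / load -------------------------------------------------
    try:
        if config.simulate:
            ccfg = CohortConfig(seed=config.seed, **config.cohort)
            patients = generate_cohort(ccfg)
            write_cohort(patients, out / "cohort", config=ccfg)
            _stage(log, "simulate")
        elif config.input_cohort_dir:
            patients = read_cohort(config.input_cohort_dir)
        else:
            patients = read_cohort(out / "cohort")
    except Exception as exc:
        raise PipelineError(f"stage 'simulate': {exc}") from exc
    table = cohort_frame(patients)
    table.to_csv(out / "cohort_table.csv")

    # --- standardize ------------------------------------------------------
    images = [p.image.data for p in patients]
    masks = [p.mask for p in patients]
    spacings = [p.image.spacing for p in patients]
    try:
        if config.standardize:
            hist_masks = masks if config.mask_histograms else None
            model = nyul_train(images, hist_masks,
                               percentiles=config.nyul_percentiles)
            model.to_json(out / "nyul_model.json")
            images = [
                nyul_apply(img, model, msk if config.mask_histograms else None)
                for img, msk in zip(images, masks)
            ]
            _stage(log, "standardize")
    except Exception as exc:
        raise PipelineError(f"stage 'standardize': {exc}") from exc

    # --- robustness sweep -------------------------------------------------
    bin_number, voxel_mm = config.bin_number, config.voxel_mm
    robust_features = None
    try:
        if config.sweep:
            report = quantization_sweep(
                images, masks, spacings,
                bin_numbers=config.sweep_bins,
                voxel_sizes=config.sweep_voxels,
                icc_threshold=config.icc_threshold,
                patient_ids=list(table.index),
                filters=tuple(config.filters),
                classes=tuple(config.classes),
            )
            bin_number, voxel_mm = report.winning_setting
            robust_features = report.robust_features
            report.to_frame().to_csv(out / "icc.csv")
            with open(out / "sweep.json", "w") as fh:
                json.dump(
                    {"winning_setting": list(report.winning_setting),
                     "n_robust": len(robust_features)}, fh, indent=1)
            _stage(log, "sweep")
    except Exception as exc:
        raise PipelineError(f"stage 'sweep': {exc}") from exc

    # --- extract ----------------------------------------------------------
    features = None
    try:
        if config.extract:
            rows = {}
            for pid, img, msk, sp in zip(table.index, images, masks, spacings):
                r_img, r_msk, r_sp = resample_isotropic(img, msk, sp, voxel_mm,
                                                        patient_id=pid)
                rows[pid] = extract_all(
                    r_img, r_msk, bin_number=bin_number, voxel_spacing=r_sp,
                    filters=tuple(config.filters),
                    classes=tuple(config.classes), patient_id=pid,
                )
            features = pd.DataFrame.from_dict(rows, orient="index")
            if robust_features is not None:
                features = features[robust_features]
            features.to_csv(out / "features_raw.csv")
            schema = {
                "bin_number": bin_number, "voxel_mm": voxel_mm,
                "filters": list(config.filters),
                "classes": list(config.classes),
                "columns": list(features.columns),
            }
            with open(out / "features_schema.json", "w") as fh:
                json.dump(schema, fh, indent=1)
            _stage(log, "extract")
    except Exception as exc:
        raise PipelineError(f"stage 'extract': {exc}") from exc

    # --- harmonize --------------------------------------------------------
    try:
        if config.harmonize and features is not None:
            usable = features.loc[:, features.notna().all()]
            harmonized, _model = combat_fit_transform(
                usable, table["scanner_id"].to_numpy()
            )
            features = harmonized
            features.to_csv(out / "features_harmonized.csv")
            _stage(log, "harmonize")
    except Exception as exc:
        raise PipelineError(f"stage 'harmonize': {exc}") from exc

    # --- select -----------------------------------------------------------
    final_features: list[str] = []
    try:
        if config.select and features is not None:
            cand = features.loc[:, features.notna().all()]
            cand = cand.loc[:, cand.std() > 0]
            cand = cand.drop(
                columns=[c for c in cand.columns if c.startswith("shape_")],
                errors="ignore",
            )
            kept = volume_filter(cand, table["tumour_volume_ml"],
                                 rho_threshold=config.volume_rho_threshold)
            kept = redundancy_filter(cand[kept],
                                     r_threshold=config.redundancy_r_threshold)
            cand = cand[kept]
            if config.max_candidate_features:
                cand = cand[sorted(cand.columns)[: config.max_candidate_features]]
            parts = event_matched_folds(table["event"], k=config.cv_k,
                                        repeats=config.cv_repeats,
                                        seed=config.seed + 1)
            _results, summary = run_selection_comparison(
                cand, table, parts, alpha=config.selection_alpha,
                mrmr_max_k=config.mrmr_max_k,
            )
            final_features = summary.final_features
            pd.DataFrame(summary.frequencies).to_csv(out / "selection_frequencies.csv")
            with open(out / "selection.json", "w") as fh:
                json.dump(
                    {
                        "chosen_method": summary.chosen_method,
                        "final_features": final_features,
                        "median_counts": summary.median_counts,
                        "c_train_median": summary.c_train_median,
                        "c_test_median": summary.c_test_median,
                        "n_failed": summary.n_failed,
                    },
                    fh, indent=1)
            _stage(log, "select")
    except Exception as exc:
        raise PipelineError(f"stage 'select': {exc}") from exc

    # --- model ------------------------------------------------------------
    try:
        if config.model:
            rad = None
            if config.select and final_features and features is not None:
                rad = features[final_features]
            report = build_four_models(
                table, rad, bootstrap_B=config.bootstrap_B, seed=config.seed + 2
            )
            report.to_frame().to_csv(out / "model_report.csv", index=False)
            payload = {
                "models": {
                    name: {
                        "aic": fit.aic,
                        "loglik": fit.loglik,
                        "covariates": fit.names,
                    }
                    for name, fit in report.fits.items()
                },
                "comparisons": {
                    name: {"lr": c.lr_stat, "df": c.delta_k, "p": c.p_value}
                    for name, c in report.comparisons.items()
                },
                "bootstrap": {
                    name: {"median_c": b.median, "ci": list(b.ci)}
                    for name, b in report.bootstrap.items()
                },
                "notes": report.notes,
            }
            with open(out / "model_report.json", "w") as fh:
                json.dump(payload, fh, indent=1)
            _stage(log, "model")
    except Exception as exc:
        raise PipelineError(f"stage 'model': {exc}") from exc

    with open(out / "run.json", "w") as fh:
        json.dump(log, fh, indent=1)
    return out
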