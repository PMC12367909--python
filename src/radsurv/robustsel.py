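"""Robust quantization selection via the intraclass correlation screen.

Texture features depend on how the image is resampled and how grey levels
are binned.  This module sweeps a grid of (bin number, isotropic voxel
size) settings, treats the settings as "raters" of each feature on each
patient, and keeps features whose agreement across settings — measured by
the two-way random-effects absolute-agreement single-measurement ICC(2,1)
— exceeds a threshold.  The winning setting is the one whose extracted,
ICC-passing feature set is largest.

The choice of raters (extraction settings, rather than repeat scans or
repeat delineations) is this package's convention and is documented in
the methods note; ICC(3,1) is available by switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgprep import resample_isotropic
from .texturefeat import extract_all

__all__ = ["RobustnessReport", "icc21", "quantization_sweep",
            "DEFAULT_BIN_NUMBERS", "DEFAULT_VOXEL_SIZES"]

DEFAULT_BIN_NUMBERS = (8, 16, 32, 64, 128, 256)
DEFAULT_VOXEL_SIZES = (1.0, 2.0, 3.0)


def icc21(measurements, model: str = "ICC2") -> float:
    """Intraclass correlation of a subjects x raters matrix.

    ``model="ICC2"`` (default) is the two-way random-effects,
    absolute-agreement, single-measurement coefficient
    ``(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)``;
    ``model="ICC3"`` drops the rater-variance term (consistency).
    Estimates below 0 are reported as computed.

    Raises
    ------
    ValueError
        Fewer than 2 subjects/raters, missing cells, or zero total
        variance (ICC undefined).
    """
    Y = np.asarray(measurements, dtype=float)
    if Y.ndim != 2:
        raise ValueError("expected a subjects x raters matrix")
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("ICC requires >= 2 subjects and >= 2 raters")
    if np.isnan(Y).any():
        raise ValueError("missing cells are not supported")
    gm = Y.mean()
    row_m = Y.mean(axis=1)
    col_m = Y.mean(axis=0)
    ss_total = ((Y - gm) ** 2).sum()
    if ss_total == 0:
        raise ValueError("zero total variance: ICC undefined")
    ss_rows = k * ((row_m - gm) ** 2).sum()
    ss_cols = n * ((col_m - gm) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    elif model == "ICC3":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom == 0:
        raise ValueError("zero denominator: ICC undefined")
    return float((msr - mse) / denom)


@dataclass
class RobustnessReport:
    """Outcome of the quantization sweep."""

    settings: list[tuple[int, float]]                 # (bin_number, voxel_mm)
    icc: pd.Series                                     # per feature
    robust_by_setting: dict[tuple[int, float], list[str]]
    winning_setting: tuple[int, float]
    icc_threshold: float
    undefined_features: list[str] = field(default_factory=list)

    @property
    def robust_features(self) -> list[str]:
        return self.robust_by_setting[self.winning_setting]

    def to_frame(self) -> pd.DataFrame:
        return self.icc.rename("icc").to_frame()


def quantization_sweep(
    images,
    masks,
    spacings,
    bin_numbers=DEFAULT_BIN_NUMBERS,
    voxel_sizes=DEFAULT_VOXEL_SIZES,
    icc_threshold: float = 0.8,
    icc_model: str = "ICC2",
    patient_ids=None,
    **extract_kwargs,
) -> RobustnessReport:
    """Sweep discretization settings and screen features by ICC.

    For every candidate (bin number, voxel size), features are extracted
    for all patients; each feature's ICC is then computed over the full
    grid of settings treated as raters (subjects = patients).  A feature
    is robust when ICC > threshold.  Each setting's robust set is the
    robust features it extracted to a finite value; the winner is the
    largest such set, ties broken toward larger bin number then smaller
    voxel size.
    """
    settings = [(int(b), float(v)) for b in bin_numbers for v in voxel_sizes]
    if len(settings) < 2:
        raise ValueError("at least 2 settings are required (>= 2 raters)")
    images = list(images)
    masks = list(masks)
    spacings = list(spacings)
    if patient_ids is None:
        patient_ids = [f"p{i}" for i in range(len(images))]
    if len(images) < 2:
        raise ValueError("at least 2 patients are required (>= 2 subjects)")

    per_setting: dict[tuple[int, float], pd.DataFrame] = {}
    for bins, vox in settings:
        rows = {}
        for pid, img, msk, sp in zip(patient_ids, images, masks, spacings):
            try:
                r_img, r_msk, r_sp = resample_isotropic(img, msk, sp, vox,
                                                        patient_id=pid)
                rows[pid] = extract_all(
                    r_img, r_msk, bin_number=bins, voxel_spacing=r_sp,
                    patient_id=pid, **extract_kwargs,
                )
            except Exception as exc:
                raise RuntimeError(
                    f"extraction failed for patient {pid} at setting "
                    f"(bins={bins}, voxel={vox} mm): {exc}"
                ) from exc
        per_setting[(bins, vox)] = pd.DataFrame.from_dict(rows, orient="index")

    feature_names = list(per_setting[settings[0]].columns)
    icc_vals = {}
    undefined = []
    for feat in feature_names:
        Y = np.column_stack([per_setting[s][feat].to_numpy() for s in settings])
        if np.isnan(Y).any():
            icc_vals[feat] = np.nan
            undefined.append(feat)
            continue
        try:
            icc_vals[feat] = icc21(Y, model=icc_model)
        except ValueError:
            icc_vals[feat] = np.nan
            undefined.append(feat)
    icc_series = pd.Series(icc_vals)

    robust_by_setting = {}
    for s in settings:
        ok = []
        for feat in feature_names:
            v = icc_series[feat]
            if np.isfinite(v) and v > icc_threshold and \
                    np.isfinite(per_setting[s][feat]).all():
                ok.append(feat)
        robust_by_setting[s] = ok
    # largest robust set; ties -> larger bin number, then smaller voxel
    winner = max(
        settings,
        key=lambda s: (len(robust_by_setting[s]), s[0], -s[1]),
    )
    return RobustnessReport(
        settings=settings,
        icc=icc_series,
        robust_by_setting=robust_by_setting,
        winning_setting=winner,
        icc_threshold=icc_threshold,
        undefined_features=undefined,
    )
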