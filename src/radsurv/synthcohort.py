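"""Synthetic prostate-radiotherapy cohorts with planted image texture signal.

The generator emulates the statistical shape of a high-risk prostate
radiotherapy cohort: clinical marginals (age, PSA, ISUP grade, T-stage,
treatment, tumour volume), correlated hypoxia gene-signature scores,
multi-scanner intensity batch effects, and a biochemical-recurrence
outcome whose hazard depends on the clinical covariates and on a scalar
image-texture "dial" — the correlation length of a stationary Gaussian
random field inside an ellipsoidal prostate mask.  Downstream texture
features (wavelet/GLCM and friends) demonstrably track that correlation
length, so the planted log-hazard per SD of standardized log correlation
length (``texture_effect``) is recoverable end to end.

Survival model: exponential baseline hazard ``h0`` (proportional hazards
hold exactly), hazard ``h0 * exp(beta' (z - mu_z) + gamma * s)`` with
``s`` the standardized log correlation length; independent uniform
censoring on ``censor_window`` plus an administrative cap.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` spawns (scanner effects, patients,
outcomes), so cohorts are bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage, stats

__all__ = [
    "CohortConfig",
    "ImageVolume",
    "SyntheticPatient",
    "generate_cohort",
    "cohort_frame",
    "write_cohort",
    "read_cohort",
]

ISUP_PROBS = (0.028, 0.37, 0.20, 0.090, 0.312)
TSTAGE_PROBS = {"T1": 0.022, "T2": 0.19, "T3": 0.78, "T4": 0.008}


@dataclass
class CohortConfig:
    """Free parameters of the synthetic cohort generator.

    Defaults are calibrated to the study conditions: a 178-patient
    high-risk cohort with ~32% biochemical recurrence, median follow-up
    ~84 months, 80% EBRT-alone, and Table-1-like clinical marginals.
    """

    n_patients: int = 178
    seed: int = 0
    # scanners / batch effects (intensity map x -> a_b * x + c_b)
    n_scanners: int = 3
    scanner_gain_range: tuple[float, float] = (0.8, 1.25)
    scanner_offset_range: tuple[float, float] = (-20.0, 20.0)
    # planted texture effect: log-hazard per SD of standardized log
    # correlation length
    texture_effect: float = 0.8
    # log-hazard per unit of each (centered) clinical covariate
    clinical_coefficients: dict = field(
        default_factory=lambda: {
            "age": -0.051,
            "psa": 0.00995,
            "isup": 0.285,
            "tstage_t3": 1.058,
            "tumour_volume": 0.0,
            "treat_ebrt": 0.438,
        }
    )
    baseline_hazard: float = 0.0037      # events/month; calibrated to ~32% events
    censor_window: tuple[float, float] = (28.0, 140.0)   # months; median 84
    admin_cap: float = 140.0             # months
    # imaging
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask_semiaxes_frac: tuple[float, float, float] = (0.38, 0.34, 0.30)
    intensity_base: float = 300.0
    intensity_contrast: float = 100.0
    # texture dial: correlation length (mm), log-normal across patients
    texture_scale_median_mm: float = 2.0
    texture_scale_sigma_log: float = 0.35
    # clinical marginals
    age_mean: float = 70.0
    age_sd: float = 5.0
    age_range: tuple[float, float] = (52.0, 80.0)
    psa_median: float = 20.0
    psa_sigma_log: float = 0.85
    isup_probs: tuple = ISUP_PROBS
    tstage_probs: dict = field(default_factory=lambda: dict(TSTAGE_PROBS))
    ebrt_prob: float = 0.803
    volume_median_ml: float = 5.0
    volume_sigma_log: float = 1.0
    # hypoxia scores
    ragnum_mean: float = 0.30
    ragnum_sd: float = 0.215
    west_mean: float = 1.40
    west_sd: float = 1.03
    hypoxia_corr: float = 0.5

    def __post_init__(self):
        if self.n_patients < 10:
            raise ValueError("n_patients must be >= 10")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        c_min, c_max = self.censor_window
        if not (c_min < c_max <= self.admin_cap):
            raise ValueError("require c_min < c_max <= admin_cap")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacings must be positive")
        if min(self.grid_shape) < 8:
            raise ValueError("grid too small to contain an ellipsoidal mask")

    # theoretical covariate means used to center the linear predictor
    def covariate_means(self) -> dict[str, float]:
        lo, hi = self.age_range
        a = (lo - self.age_mean) / self.age_sd
        b = (hi - self.age_mean) / self.age_sd
        age_mu = float(stats.truncnorm.mean(a, b, loc=self.age_mean,
                                            scale=self.age_sd))
        psa_mu = float(self.psa_median * np.exp(self.psa_sigma_log**2 / 2))
        p = np.asarray(self.isup_probs, float)
        p = p / p.sum()
        isup_mu = float((np.arange(1, 6) * p).sum())
        tp = self.tstage_probs
        tot = sum(tp.values())
        t3_mu = (tp.get("T3", 0.0) + tp.get("T4", 0.0)) / tot
        vol_mu = float(self.volume_median_ml * np.exp(self.volume_sigma_log**2 / 2))
        return {
            "age": age_mu,
            "psa": psa_mu,
            "isup": isup_mu,
            "tstage_t3": t3_mu,
            "tumour_volume": vol_mu,
            "treat_ebrt": self.ebrt_prob,
        }

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ImageVolume:
    """A 3D scalar intensity grid with physical voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    scanner: int = 0


@dataclass
class SyntheticPatient:
    patient_id: str
    image: ImageVolume
    mask: np.ndarray
    texture_scale: float            # correlation length, mm
    texture_s: float                # standardized log correlation length
    age: float
    psa: float
    isup: int
    tstage: str
    treatment: str
    tumour_volume_ml: float
    ragnum32: float
    west28: float
    time_months: float
    event: int
    scanner_id: int


def _ellipsoid_mask(shape, semiaxes_frac) -> np.ndarray:
    shape = np.asarray(shape)
    center = (shape - 1) / 2.0
    semi = np.asarray(semiaxes_frac) * shape
    if np.any(semi < 1):
        raise ValueError("grid too small to contain the ellipsoidal mask")
    grids = np.ogrid[[slice(0, s) for s in shape]]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    mask = r2 <= 1.0
    if not mask.any():  # pragma: no cover - excluded by the semiaxis check
        raise ValueError("empty mask")
    return mask


def _random_field(rng, shape, corr_len_mm, spacing) -> np.ndarray:
    """Stationary Gaussian field: white noise smoothed with a Gaussian
    kernel of width corr_len (per axis, in voxels), rescaled to unit SD."""
    noise = rng.standard_normal(shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    field_ = ndimage.gaussian_filter(noise, sigma=sigma_vox, mode="reflect")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    return field_


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a complete synthetic cohort (images, masks, clinical,
    hypoxia, outcomes), deterministic given ``config.seed``."""
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    scanner_ss, patient_ss, outcome_ss = ss.spawn(3)
    scanner_rng = np.random.default_rng(scanner_ss)
    patient_rng = np.random.default_rng(patient_ss)
    outcome_rng = np.random.default_rng(outcome_ss)

    gains = scanner_rng.uniform(*cfg.scanner_gain_range, size=cfg.n_scanners)
    offsets = scanner_rng.uniform(*cfg.scanner_offset_range, size=cfg.n_scanners)

    n = cfg.n_patients
    lo, hi = cfg.age_range
    a = (lo - cfg.age_mean) / cfg.age_sd
    b = (hi - cfg.age_mean) / cfg.age_sd
    age = stats.truncnorm.rvs(a, b, loc=cfg.age_mean, scale=cfg.age_sd,
                              size=n, random_state=patient_rng)
    psa = cfg.psa_median * np.exp(
        cfg.psa_sigma_log * patient_rng.standard_normal(n)
    )
    p_isup = np.asarray(cfg.isup_probs, float)
    p_isup = p_isup / p_isup.sum()
    isup = patient_rng.choice(np.arange(1, 6), size=n, p=p_isup)
    t_names = list(cfg.tstage_probs)
    p_t = np.asarray([cfg.tstage_probs[k] for k in t_names], float)
    p_t = p_t / p_t.sum()
    tstage = patient_rng.choice(t_names, size=n, p=p_t)
    treat = np.where(patient_rng.random(n) < cfg.ebrt_prob, "EBRT", "HDR+EBRT")
    volume = cfg.volume_median_ml * np.exp(
        cfg.volume_sigma_log * patient_rng.standard_normal(n)
    )
    # correlated bivariate-normal hypoxia scores
    z1 = patient_rng.standard_normal(n)
    z2 = cfg.hypoxia_corr * z1 + np.sqrt(1 - cfg.hypoxia_corr**2) * \
        patient_rng.standard_normal(n)
    ragnum = cfg.ragnum_mean + cfg.ragnum_sd * z1
    west = cfg.west_mean + cfg.west_sd * z2
    # texture dial
    log_ell = np.log(cfg.texture_scale_median_mm) + \
        cfg.texture_scale_sigma_log * patient_rng.standard_normal(n)
    ell = np.exp(log_ell)
    s = (log_ell - np.log(cfg.texture_scale_median_mm)) / cfg.texture_scale_sigma_log
    scanner_id = patient_rng.integers(0, cfg.n_scanners, size=n)

    mu = cfg.covariate_means()
    beta = cfg.clinical_coefficients
    t3 = np.isin(tstage, ["T3", "T4"]).astype(float)
    ebrt = (treat == "EBRT").astype(float)
    eta = (
        beta.get("age", 0.0) * (age - mu["age"])
        + beta.get("psa", 0.0) * (psa - mu["psa"])
        + beta.get("isup", 0.0) * (isup - mu["isup"])
        + beta.get("tstage_t3", 0.0) * (t3 - mu["tstage_t3"])
        + beta.get("tumour_volume", 0.0) * (volume - mu["tumour_volume"])
        + beta.get("treat_ebrt", 0.0) * (ebrt - mu["treat_ebrt"])
        + cfg.texture_effect * s
    )
    lam = cfg.baseline_hazard * np.exp(eta)
    t_event = outcome_rng.exponential(1.0 / lam)
    c_min, c_max = cfg.censor_window
    t_cens = np.minimum(outcome_rng.uniform(c_min, c_max, size=n), cfg.admin_cap)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    mask = _ellipsoid_mask(cfg.grid_shape, cfg.mask_semiaxes_frac)
    patients = []
    for i in range(n):
        field_ = _random_field(patient_rng, cfg.grid_shape, ell[i],
                               cfg.voxel_spacing)
        img = cfg.intensity_base + cfg.intensity_contrast * field_
        b_id = int(scanner_id[i])
        img = gains[b_id] * img + offsets[b_id]
        patients.append(
            SyntheticPatient(
                patient_id=f"pt{i:04d}",
                image=ImageVolume(img, tuple(cfg.voxel_spacing), b_id),
                mask=mask.copy(),
                texture_scale=float(ell[i]),
                texture_s=float(s[i]),
                age=float(age[i]),
                psa=float(psa[i]),
                isup=int(isup[i]),
                tstage=str(tstage[i]),
                treatment=str(treat[i]),
                tumour_volume_ml=float(volume[i]),
                ragnum32=float(ragnum[i]),
                west28=float(west[i]),
                time_months=float(time[i]),
                event=int(event[i]),
                scanner_id=b_id,
            )
        )
    return patients


def cohort_frame(patients) -> pd.DataFrame:
    """Tabular view of a cohort (clinical + hypoxia + outcome + batch)."""
    rows = [
        {
            "patient_id": p.patient_id,
            "age": p.age,
            "psa": p.psa,
            "isup": p.isup,
            "tstage": p.tstage,
            "treatment": p.treatment,
            "tumour_volume_ml": p.tumour_volume_ml,
            "ragnum32": p.ragnum32,
            "west28": p.west28,
            "time_months": p.time_months,
            "event": p.event,
            "scanner_id": p.scanner_id,
            "texture_scale_mm": p.texture_scale,
            "texture_s": p.texture_s,
        }
        for p in patients
    ]
    return pd.DataFrame(rows).set_index("patient_id")


def write_cohort(patients, directory, config: CohortConfig | None = None) -> dict:
    """Write NIfTI image/mask pairs, the cohort CSV and a JSON manifest.

    Returns the manifest (also saved as ``manifest.json``); the layout
    round-trips losslessly through :func:`read_cohort`.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {directory}: {exc}") from exc
    images, masks = [], []
    for p in patients:
        affine = np.diag(list(p.image.spacing) + [1.0])
        img_path = directory / f"{p.patient_id}_image.nii.gz"
        msk_path = directory / f"{p.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(p.image.data.astype(np.float64), affine), img_path)
        nib.save(nib.Nifti1Image(p.mask.astype(np.uint8), affine), msk_path)
        images.append(img_path.name)
        masks.append(msk_path.name)
    table = cohort_frame(patients) if patients else pd.DataFrame()
    table.to_csv(directory / "cohort.csv")
    manifest = {
        "n_patients": len(patients),
        "images": images,
        "masks": masks,
        "table": "cohort.csv",
        "config": config.to_dict() if config is not None else None,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory) -> list[SyntheticPatient]:
    """Reload a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    if manifest["n_patients"] == 0:
        return []
    table = pd.read_csv(directory / manifest["table"], index_col="patient_id")
    patients = []
    for pid, row in table.iterrows():
        img = nib.load(directory / f"{pid}_image.nii.gz")
        msk = nib.load(directory / f"{pid}_mask.nii.gz")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        patients.append(
            SyntheticPatient(
                patient_id=str(pid),
                image=ImageVolume(np.asarray(img.dataobj, dtype=np.float64),
                                  spacing, int(row["scanner_id"])),
                mask=np.asarray(msk.dataobj).astype(bool),
                texture_scale=float(row["texture_scale_mm"]),
                texture_s=float(row["texture_s"]),
                age=float(row["age"]),
                psa=float(row["psa"]),
                isup=int(row["isup"]),
                tstage=str(row["tstage"]),
                treatment=str(row["treatment"]),
                tumour_volume_ml=float(row["tumour_volume_ml"]),
                ragnum32=float(row["ragnum32"]),
                west28=float(row["west28"]),
                time_months=float(row["time_months"]),
                event=int(row["event"]),
                scanner_id=int(row["scanner_id"]),
            )
        )
    return patients
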