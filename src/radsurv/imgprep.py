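"""Intensity standardization and grey-level preparation of MR volumes.

MR signal intensity is scanner- and protocol-dependent with no physical
unit, so histograms must be aligned to a common scale before texture
features become comparable across patients.  This module provides the
piecewise-linear landmark standardization of Nyúl & Udupa, isotropic
resampling, and fixed-bin-number grey-level discretization of ROI values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "StandardizationModel",
    "DEFAULT_LANDMARKS",
    "nyul_train",
    "nyul_apply",
    "resample_isotropic",
    "discretize",
]

#: Decile landmarks plus near-extreme percentiles; the canonical choice.
DEFAULT_LANDMARKS = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)

#: Range the clipped intensity window [p_low, p_high] is mapped onto
#: before averaging landmark locations across training images.
_STANDARD_RANGE = (0.0, 100.0)


@dataclass
class StandardizationModel:
    """Learned landmark positions on the common intensity scale."""

    landmark_percentiles: np.ndarray
    standard_scale: np.ndarray
    clip_percentiles: tuple[float, float] = (1.0, 99.0)
    n_training_images: int = 0

    def __post_init__(self):
        self.landmark_percentiles = np.asarray(self.landmark_percentiles, float)
        self.standard_scale = np.asarray(self.standard_scale, float)
        if np.any(np.diff(self.landmark_percentiles) <= 0):
            raise ValueError("landmark percentiles must be strictly increasing")
        if np.any(np.diff(self.standard_scale) <= 0):
            raise ValueError("standard scale values must be strictly increasing")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "landmark_percentiles": self.landmark_percentiles.tolist(),
                    "standard_scale": self.standard_scale.tolist(),
                    "clip_percentiles": list(self.clip_percentiles),
                    "n_training_images": self.n_training_images,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "StandardizationModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            landmark_percentiles=d["landmark_percentiles"],
            standard_scale=d["standard_scale"],
            clip_percentiles=tuple(d["clip_percentiles"]),
            n_training_images=d.get("n_training_images", 0),
        )


def _masked_values(image, mask) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if mask is None:
        return arr.ravel()
    m = np.asarray(mask).astype(bool)
    if m.shape != arr.shape:
        raise ValueError("mask shape does not match image shape")
    return arr[m]


def _rescaled_landmarks(values, percentiles, clip) -> np.ndarray:
    """Landmark percentiles after mapping [p_low, p_high] linearly onto
    the fixed standard range."""
    p_low, p_high = clip
    lo, hi = np.percentile(values, [p_low, p_high])
    if hi <= lo:
        raise ValueError("degenerate histogram: intensity range is constant")
    lmk = np.percentile(values, percentiles)
    s0, s1 = _STANDARD_RANGE
    return s0 + (lmk - lo) * (s1 - s0) / (hi - lo)


def nyul_train(
    images,
    masks=None,
    percentiles=DEFAULT_LANDMARKS,
    clip_percentiles: tuple[float, float] = (1.0, 99.0),
) -> StandardizationModel:
    """Learn a standard intensity scale from training images.

    Each image's histogram (optionally restricted to its mask) is linearly
    rescaled so its [clip_low, clip_high] percentile window spans a fixed
    range; the standard scale is the per-landmark mean of the rescaled
    landmark locations over the training images.
    """
    images = list(images)
    if len(images) < 1:
        raise ValueError("at least one training image is required")
    if masks is None:
        masks = [None] * len(images)
    percentiles = np.asarray(percentiles, float)
    if np.any(percentiles <= 0) or np.any(percentiles >= 100):
        raise ValueError("landmark percentiles must lie strictly inside (0, 100)")
    all_lmk = []
    for img, msk in zip(images, masks):
        vals = _masked_values(img, msk)
        all_lmk.append(_rescaled_landmarks(vals, percentiles, clip_percentiles))
    scale = np.mean(all_lmk, axis=0)
    # enforce strict monotonicity against ties from discrete histograms
    eps = 1e-9 * max(1.0, np.ptp(scale))
    for i in range(1, len(scale)):
        if scale[i] <= scale[i - 1]:
            scale[i] = scale[i - 1] + eps
    return StandardizationModel(
        landmark_percentiles=percentiles,
        standard_scale=scale,
        clip_percentiles=tuple(clip_percentiles),
        n_training_images=len(images),
    )


def nyul_apply(image, model: StandardizationModel, mask=None) -> np.ndarray:
    """Map an image onto the standard scale.

    The image's own landmark percentiles (within ``mask`` if given) are
    paired with the model's standard-scale values and intensities are
    transformed by piecewise-linear interpolation through those pairs,
    with linear extension beyond the outermost landmarks.
    """
    if model.n_training_images < 1:
        raise ValueError("standardization model has not been trained")
    arr = np.asarray(image, dtype=float)
    vals = _masked_values(arr, mask)
    src = np.percentile(vals, model.landmark_percentiles)
    dst = model.standard_scale
    # collapse exactly tied source landmarks to keep the map well defined
    keep = np.concatenate([[True], np.diff(src) > 0])
    src_k, dst_k = src[keep], dst[keep]
    if len(src_k) < 2:
        raise ValueError("degenerate histogram: too few distinct landmarks")
    out = np.interp(arr, src_k, dst_k)
    lo_slope = (dst_k[1] - dst_k[0]) / (src_k[1] - src_k[0])
    hi_slope = (dst_k[-1] - dst_k[-2]) / (src_k[-1] - src_k[-2])
    below = arr < src_k[0]
    above = arr > src_k[-1]
    out[below] = dst_k[0] + (arr[below] - src_k[0]) * lo_slope
    out[above] = dst_k[-1] + (arr[above] - src_k[-1]) * hi_slope
    return out


def resample_isotropic(
    image,
    mask,
    spacing,
    target_mm: float,
    method: str = "linear",
    patient_id: str | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample an image/mask pair to isotropic voxels of ``target_mm``.

    Image intensities are interpolated (linear by default), the mask with
    nearest-neighbour so it stays binary.  Returns (image, mask, spacing).
    """
    if target_mm <= 0:
        raise ValueError("target spacing must be positive")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("voxel spacings must be positive")
    arr = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask).astype(np.uint8)
    if spacing == (target_mm,) * 3:
        return arr.copy(), msk.astype(bool), spacing

    interp = {"linear": sitk.sitkLinear, "bspline": sitk.sitkBSpline,
              "nearest": sitk.sitkNearestNeighbor}[method]
    # SimpleITK uses (x, y, z) index order = reversed numpy axes
    img_itk = sitk.GetImageFromArray(arr)
    img_itk.SetSpacing(spacing[::-1])
    msk_itk = sitk.GetImageFromArray(msk)
    msk_itk.SetSpacing(spacing[::-1])
    new_size = [
        max(1, int(round(arr.shape[2 - i] * spacing[::-1][i] / target_mm)))
        for i in range(3)
    ]
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_mm,) * 3)
    res.SetSize(new_size)
    res.SetOutputOrigin(img_itk.GetOrigin())
    res.SetOutputDirection(img_itk.GetDirection())
    res.SetUseNearestNeighborExtrapolator(True)
    res.SetInterpolator(interp)
    out_img = sitk.GetArrayFromImage(res.Execute(img_itk))
    res.SetInterpolator(sitk.sitkNearestNeighbor)
    out_msk = sitk.GetArrayFromImage(res.Execute(msk_itk)).astype(bool)
    if not out_msk.any():
        who = f" for patient {patient_id}" if patient_id else ""
        raise ValueError(f"mask is empty after resampling to {target_mm} mm{who}")
    return out_img, out_msk, (target_mm,) * 3


def discretize(roi_values, bin_number: int) -> np.ndarray:
    """Discretize ROI intensities into 1..bin_number equal-width grey levels.

    Bins span [min, max] of the ROI with half-open edges except the last
    bin, which is closed; a constant ROI maps every voxel to level 1.  A
    fixed bin *number* (not width) is used because MR intensity units are
    arbitrary even after standardization.
    """
    if bin_number < 2:
        raise ValueError("bin_number must be >= 2")
    v = np.asarray(roi_values, dtype=float)
    if v.size == 0:
        raise ValueError("ROI is empty")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.ones(v.shape, dtype=np.int64)
    width = (hi - lo) / bin_number
    levels = np.floor((v - lo) / width).astype(np.int64) + 1
    return np.clip(levels, 1, bin_number)
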