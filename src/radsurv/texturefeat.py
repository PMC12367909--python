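"""Radiomic feature extraction from discretized ROIs.

Feature classes follow the standard texture-matrix definitions used in
radiomics (first order, GLCM, GLRLM, GLSZM, GLDM, NGTDM, shape), computed
on fixed-bin-number discretized grey levels inside a binary mask, for the
original image and for each of the eight sub-bands of a single-level
undecimated 3D wavelet transform.

Conventions that matter for reproducibility:

* wavelet sub-band names ``LLL`` .. ``HHH`` denote the low/high-pass
  filter applied along axes (0, 1, 2) in that fixed order;
* grey levels are re-discretized per filtered sub-band (each sub-band has
  its own intensity range, wavelet outputs are signed);
* GLCM/GLRLM use the 13 unique 3D direction offsets and per-direction
  values are averaged into one scalar per feature;
* kurtosis is uncorrected (a normal sample gives ~3, not ~0);
* degenerate matrices yield NaN ("undefined"), never a silent 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .imgprep import discretize

__all__ = [
    "WAVELET_SUBBANDS",
    "DIRECTIONS_13",
    "FEATURE_CLASSES",
    "wavelet_decompose",
    "first_order_features",
    "glcm_build",
    "glcm_features",
    "glrlm_build",
    "glrlm_features",
    "glszm_build",
    "glszm_features",
    "gldm_build",
    "gldm_features",
    "ngtdm_build",
    "ngtdm_features",
    "shape_features",
    "extract_all",
    "feature_names",
]

WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

#: The 13 unique 3D neighbour offsets (one of each +/- pair).
DIRECTIONS_13 = tuple(
    (a, b, c)
    for a in (-1, 0, 1)
    for b in (-1, 0, 1)
    for c in (-1, 0, 1)
    if (a, b, c) > (0, 0, 0)
)

FEATURE_CLASSES = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


# ---------------------------------------------------------------------------
# wavelet filtering


def wavelet_decompose(image, wavelet: str = "coif1", mode: str = "reflect"):
    """Single-level undecimated separable 3D wavelet transform.

    Applies the decomposition low-pass (L) or high-pass (H) filter along
    each axis in turn; the eight L/H combinations give sub-bands the same
    shape as the input.  High-pass filters have zero DC gain, so every
    sub-band containing an H is identically zero on a constant image.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    w = pywt.Wavelet(wavelet)
    lo = np.asarray(w.dec_lo, float)
    hi = np.asarray(w.dec_hi, float)
    if min(arr.shape) < len(lo):
        raise ValueError(
            f"volume dimensions {arr.shape} shorter than the {wavelet} "
            f"filter length {len(lo)}"
        )
    out = {}
    for name in WAVELET_SUBBANDS:
        sub = arr
        for axis, letter in enumerate(name):
            filt = lo if letter == "L" else hi
            sub = ndimage.convolve1d(sub, filt, axis=axis, mode=mode)
        out[name] = sub
    return out


# ---------------------------------------------------------------------------
# first order


def first_order_features(roi_values, n_bins: int = 64) -> dict[str, float]:
    """Intensity-distribution statistics of the raw (continuous) ROI values.

    Entropy and uniformity are computed on an equal-width ``n_bins``
    histogram of the ROI.  Kurtosis is the uncorrected fourth standardized
    moment (normal data -> ~3).
    """
    v = np.asarray(roi_values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("ROI is empty")
    mean = v.mean()
    var = v.var()
    sd = np.sqrt(var)
    if sd > 0:
        z = (v - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0
    if v.max() > v.min():
        counts, _ = np.histogram(v, bins=n_bins)
    else:
        counts = np.array([v.size])
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    p10, p90 = np.percentile(v, [10, 90])
    return {
        "mean": float(mean),
        "median": float(np.median(v)),
        "variance": float(var),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((v**2).sum()),
        "entropy": entropy,
        "minimum": float(v.min()),
        "maximum": float(v.max()),
        "p10": float(p10),
        "p90": float(p90),
        "range": float(v.max() - v.min()),
        "rms": float(np.sqrt(np.mean(v**2))),
        "mad": float(np.mean(np.abs(v - mean))),
        "uniformity": float((p**2).sum()),
    }


# ---------------------------------------------------------------------------
# shared helpers for level grids


def _level_grid(levels_roi, mask) -> np.ndarray:
    """Full-grid int array with grey levels inside the mask, 0 outside."""
    m = np.asarray(mask).astype(bool)
    L = np.zeros(m.shape, dtype=np.int64)
    L[m] = np.asarray(levels_roi, dtype=np.int64)
    return L


def _shifted(L, offset):
    """L sampled at x+offset, 0-filled at the boundary."""
    out = np.zeros_like(L)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        n = L.shape[ax]
        if d > 0:
            dst[ax], src[ax] = slice(0, n - d), slice(d, n)
        elif d < 0:
            dst[ax], src[ax] = slice(-d, n), slice(0, n + d)
    out[tuple(dst)] = L[tuple(src)]
    return out


# ---------------------------------------------------------------------------
# GLCM


@dataclass
class GLCM:
    """Per-direction symmetric normalized co-occurrence matrices."""

    matrices: np.ndarray  # (n_directions, Ng, Ng), rows may be all-NaN
    n_levels: int
    distance: int
    directions: tuple

    @property
    def valid(self) -> np.ndarray:
        return ~np.isnan(self.matrices[:, 0, 0])


def glcm_build(
    levels_roi,
    mask,
    n_levels: int | None = None,
    distance: int = 1,
    directions=DIRECTIONS_13,
    symmetric: bool = True,
) -> GLCM:
    """Grey-level co-occurrence matrices over the 3D direction set.

    Pairs with either voxel outside the mask are ignored; directions with
    no in-mask pair yield an all-NaN (undefined) matrix.
    """
    L = _level_grid(levels_roi, mask)
    Ng = int(n_levels if n_levels is not None else max(L.max(), 1))
    mats = np.full((len(directions), Ng, Ng), np.nan)
    for k, d in enumerate(directions):
        off = tuple(distance * c for c in d)
        Ls = _shifted(L, off)
        sel = (L > 0) & (Ls > 0)
        if not sel.any():
            continue
        C = np.zeros((Ng, Ng))
        np.add.at(C, (L[sel] - 1, Ls[sel] - 1), 1.0)
        if symmetric:
            C = C + C.T
        mats[k] = C / C.sum()
    return GLCM(mats, Ng, distance, tuple(directions))


def _glcm_features_single(P: np.ndarray) -> dict[str, float]:
    Ng = P.shape[0]
    i = np.arange(1, Ng + 1)[:, None] * np.ones((1, Ng))
    j = i.T
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    lv = np.arange(1, Ng + 1)
    mx = float((lv * px).sum())
    my = float((lv * py).sum())
    vx = float(((lv - mx) ** 2 * px).sum())
    vy = float(((lv - my) ** 2 * py).sum())
    nz = P > 0
    out = {
        "contrast": float(((i - j) ** 2 * P).sum()),
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "homogeneity": float((P / (1.0 + (i - j) ** 2)).sum()),
        "inverse_difference": float((P / (1.0 + np.abs(i - j))).sum()),
        "joint_energy": float((P**2).sum()),
        "joint_entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
        "joint_average": mx,
        "autocorrelation": float((i * j * P).sum()),
        "cluster_tendency": float(((i + j - mx - my) ** 2 * P).sum()),
        "cluster_shade": float(((i + j - mx - my) ** 3 * P).sum()),
        "cluster_prominence": float(((i + j - mx - my) ** 4 * P).sum()),
        "maximum_probability": float(P.max()),
    }
    if vx > 0 and vy > 0:
        out["correlation"] = float(
            (((i - mx) * (j - my) * P).sum()) / np.sqrt(vx * vy)
        )
    else:
        out["correlation"] = np.nan
    return out


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """Direction-averaged GLCM features; NaN if every direction is empty."""
    per_dir = [
        _glcm_features_single(glcm.matrices[k])
        for k in range(len(glcm.directions))
        if glcm.valid[k]
    ]
    if not per_dir:
        keys = _glcm_features_single(np.array([[1.0]])).keys()
        return {k: np.nan for k in keys}
    return {k: float(np.nanmean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLRLM


@dataclass
class GLRLM:
    matrices: np.ndarray  # (n_directions, Ng, max_run)
    n_levels: int
    n_voxels: int
    directions: tuple


def glrlm_build(levels_roi, mask, n_levels=None, directions=DIRECTIONS_13) -> GLRLM:
    """Run-length matrices: maximal runs of equal grey level per direction."""
    L = _level_grid(levels_roi, mask)
    Ng = int(n_levels if n_levels is not None else max(L.max(), 1))
    max_run = int(max(L.shape))
    mats = np.zeros((len(directions), Ng, max_run))
    inside = L > 0
    for k, d in enumerate(directions):
        nxt = _shifted(L, d)
        prv = _shifted(L, tuple(-c for c in d))
        cont = inside & (nxt == L) & (nxt > 0)  # run continues at x -> x+d
        starts = inside & ~((prv == L) & (prv > 0))
        pos = np.argwhere(starts)
        lengths = np.ones(len(pos), dtype=np.int64)
        act = np.arange(len(pos))
        cur = pos.copy()
        while act.size:
            c = cont[tuple(cur[act].T)]
            act = act[c]
            cur[act] += d
            lengths[act] += 1
        lvl = L[tuple(pos.T)]
        np.add.at(mats[k], (lvl - 1, lengths - 1), 1.0)
    return GLRLM(mats, Ng, int(inside.sum()), tuple(directions))


def _rlm_style_features(M, n_voxels, prefix_short="run") -> dict[str, float]:
    """Shared emphasis-style statistics for run/zone/dependence matrices.

    ``M[i-1, j-1]`` counts structures of grey level i and size/length j.
    """
    Nr = M.sum()
    if Nr == 0:
        keys = [
            "short_emphasis", "long_emphasis", "gl_nonuniformity",
            "size_nonuniformity", "percentage", "low_gl_emphasis",
            "high_gl_emphasis", "short_low_gl_emphasis", "short_high_gl_emphasis",
            "long_low_gl_emphasis", "long_high_gl_emphasis", "gl_variance",
            "size_variance", "entropy",
        ]
        return {k: np.nan for k in keys}
    i = np.arange(1, M.shape[0] + 1)[:, None].astype(float)
    j = np.arange(1, M.shape[1] + 1)[None, :].astype(float)
    p = M / Nr
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    nz = p > 0
    return {
        "short_emphasis": float((M / j**2).sum() / Nr),
        "long_emphasis": float((M * j**2).sum() / Nr),
        "gl_nonuniformity": float((M.sum(axis=1) ** 2).sum() / Nr),
        "size_nonuniformity": float((M.sum(axis=0) ** 2).sum() / Nr),
        "percentage": float(Nr / n_voxels) if n_voxels else np.nan,
        "low_gl_emphasis": float((M / i**2).sum() / Nr),
        "high_gl_emphasis": float((M * i**2).sum() / Nr),
        "short_low_gl_emphasis": float((M / (i**2 * j**2)).sum() / Nr),
        "short_high_gl_emphasis": float((M * i**2 / j**2).sum() / Nr),
        "long_low_gl_emphasis": float((M * j**2 / i**2).sum() / Nr),
        "long_high_gl_emphasis": float((M * i**2 * j**2).sum() / Nr),
        "gl_variance": float(((i - mu_i) ** 2 * p).sum()),
        "size_variance": float(((j - mu_j) ** 2 * p).sum()),
        "entropy": float(-(p[nz] * np.log2(p[nz])).sum()),
    }


def glrlm_features(glrlm: GLRLM) -> dict[str, float]:
    """Direction-averaged run-length features."""
    per_dir = []
    for k in range(len(glrlm.directions)):
        M = glrlm.matrices[k]
        if M.sum() > 0:
            per_dir.append(_rlm_style_features(M, glrlm.n_voxels))
    if not per_dir:
        return _rlm_style_features(np.zeros((1, 1)), 0)
    return {k: float(np.nanmean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# GLSZM


@dataclass
class GLSZM:
    matrix: np.ndarray  # (Ng, max_zone_size)
    n_levels: int
    n_voxels: int


_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_build(levels_roi, mask, n_levels=None) -> GLSZM:
    """Size-zone matrix: 26-connected zones of equal grey level."""
    L = _level_grid(levels_roi, mask)
    Ng = int(n_levels if n_levels is not None else max(L.max(), 1))
    n_vox = int((L > 0).sum())
    zones: list[tuple[int, int]] = []
    for lvl in np.unique(L[L > 0]):
        lab, n_lab = ndimage.label(L == lvl, structure=_STRUCT_26)
        if n_lab:
            sizes = np.bincount(lab.ravel())[1:]
            zones.extend((int(lvl), int(s)) for s in sizes)
    max_size = max((s for _, s in zones), default=1)
    M = np.zeros((Ng, max_size))
    for lvl, s in zones:
        M[lvl - 1, s - 1] += 1
    return GLSZM(M, Ng, n_vox)


def glszm_features(glszm: GLSZM) -> dict[str, float]:
    """Zone-size features; ``long_high_gl_emphasis`` is the Large Area
    High Gray Level Emphasis  sum s(i,j) i^2 j^2 / Nz."""
    return _rlm_style_features(glszm.matrix, glszm.n_voxels)


# ---------------------------------------------------------------------------
# GLDM


@dataclass
class GLDM:
    matrix: np.ndarray  # (Ng, max_dependence)
    n_levels: int
    n_voxels: int
    alpha: int


def gldm_build(levels_roi, mask, n_levels=None, alpha: int = 0) -> GLDM:
    """Dependence matrix: for each voxel, the count of 26-neighbours whose
    grey level differs by at most ``alpha`` (the centre counts, so the
    dependence of an isolated voxel is 1)."""
    L = _level_grid(levels_roi, mask)
    Ng = int(n_levels if n_levels is not None else max(L.max(), 1))
    inside = L > 0
    dep = np.ones(L.shape, dtype=np.int64)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            Ls = _shifted(L, off)
            dep += (inside & (Ls > 0) & (np.abs(Ls - L) <= alpha)).astype(np.int64)
    M = np.zeros((Ng, 27))
    sel = inside
    np.add.at(M, (L[sel] - 1, dep[sel] - 1), 1.0)
    M = M[:, : max(1, int(dep[sel].max()) if sel.any() else 1)]
    return GLDM(M, Ng, int(inside.sum()), alpha)


def gldm_features(gldm: GLDM) -> dict[str, float]:
    return _rlm_style_features(gldm.matrix, gldm.n_voxels)


# ---------------------------------------------------------------------------
# NGTDM


@dataclass
class NGTDM:
    s: np.ndarray  # per-level summed absolute difference from neighbourhood mean
    n: np.ndarray  # per-level voxel counts
    n_levels: int


def ngtdm_build(levels_roi, mask, n_levels=None) -> NGTDM:
    """Neighbourhood grey-tone difference: per grey level, the summed
    absolute difference between voxel level and the mean level of its
    in-mask 26-neighbourhood."""
    L = _level_grid(levels_roi, mask).astype(float)
    inside = L > 0
    Ng = int(n_levels if n_levels is not None else max(int(L.max()), 1))
    nb_sum = np.zeros(L.shape)
    nb_cnt = np.zeros(L.shape)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-c for c in d)):
            Ls = _shifted(L, off)
            has = Ls > 0
            nb_sum += np.where(has, Ls, 0.0)
            nb_cnt += has
    s = np.zeros(Ng)
    n = np.zeros(Ng, dtype=np.int64)
    valid = inside & (nb_cnt > 0)
    diffs = np.abs(L - np.divide(nb_sum, nb_cnt, out=np.zeros_like(nb_sum),
                                 where=nb_cnt > 0))
    lv = L[valid].astype(int)
    np.add.at(s, lv - 1, diffs[valid])
    np.add.at(n, lv - 1, 1)
    return NGTDM(s, n, Ng)


def ngtdm_features(ngtdm: NGTDM) -> dict[str, float]:
    n = ngtdm.n.astype(float)
    N = n.sum()
    if N == 0:
        return {k: np.nan for k in
                ("coarseness", "contrast", "busyness", "complexity", "strength")}
    p = n / N
    s = ngtdm.s
    lv = np.arange(1, ngtdm.n_levels + 1, dtype=float)
    present = p > 0
    Ngp = int(present.sum())
    ps = float((p * s).sum())
    out = {}
    out["coarseness"] = float(1.0 / ps) if ps > 0 else 1e6
    if Ngp > 1:
        ii, jj = np.meshgrid(lv[present], lv[present], indexing="ij")
        pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
        out["contrast"] = float(
            (pi * pj * (ii - jj) ** 2).sum() / (Ngp * (Ngp - 1)) * s.sum() / N
        )
        denom = float(np.abs(lv[present][:, None] * p[present][:, None]
                             - lv[present][None, :] * p[present][None, :]).sum())
        out["busyness"] = float(ps / denom) if denom > 0 else np.nan
        si, sj = np.meshgrid(s[present], s[present], indexing="ij")
        out["complexity"] = float(
            (np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum() / N
        )
        out["strength"] = (
            float(((pi + pj) * (ii - jj) ** 2).sum() / s.sum())
            if s.sum() > 0 else np.nan
        )
    else:
        out["contrast"] = 0.0
        out["busyness"] = np.nan
        out["complexity"] = 0.0
        out["strength"] = np.nan
    return out


# ---------------------------------------------------------------------------
# shape


def shape_features(mask, spacing) -> dict[str, float]:
    """Mask-only morphology: volume (mL), surface area, sphericity and
    maximum 3D diameter (mm), computed in physical coordinates."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("mask is empty")
    spacing = np.asarray(spacing, dtype=float)
    vox_mm3 = float(np.prod(spacing))
    n_vox = int(m.sum())
    volume_mm3 = n_vox * vox_mm3

    from skimage.measure import marching_cubes, mesh_surface_area

    padded = np.pad(m.astype(float), 1)
    try:
        verts, faces, *_ = marching_cubes(padded, level=0.5, spacing=tuple(spacing))
        surface = float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):  # pragma: no cover - degenerate mask
        surface = np.nan
    sphericity = (
        float(np.pi ** (1 / 3) * (6.0 * volume_mm3) ** (2 / 3) / surface)
        if surface and np.isfinite(surface) and surface > 0
        else np.nan
    )
    coords = np.argwhere(m) * spacing
    if len(coords) == 1:
        diam = 0.0
    else:
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except QhullError:
            pts = coords
        diam = float(pdist(pts).max()) if len(pts) > 1 else 0.0
    return {
        "voxel_count": float(n_vox),
        "volume_ml": volume_mm3 / 1000.0,
        "surface_area_mm2": surface,
        "sphericity": sphericity,
        "max_3d_diameter_mm": diam,
    }


# ---------------------------------------------------------------------------
# orchestration


def _texture_features_for_roi(volume, mask, bin_number, glcm_distance, gldm_alpha,
                              classes) -> dict[str, float]:
    roi = volume[mask]
    out = {}
    if "firstorder" in classes:
        for k, v in first_order_features(roi).items():
            out[f"firstorder_{k}"] = v
    need_levels = any(c in classes for c in ("glcm", "glrlm", "glszm", "gldm", "ngtdm"))
    if need_levels:
        levels = discretize(roi, bin_number)
        Ng = bin_number
        if "glcm" in classes:
            for k, v in glcm_features(
                glcm_build(levels, mask, Ng, distance=glcm_distance)
            ).items():
                out[f"glcm_{k}"] = v
        if "glrlm" in classes:
            for k, v in glrlm_features(glrlm_build(levels, mask, Ng)).items():
                out[f"glrlm_{k}"] = v
        if "glszm" in classes:
            for k, v in glszm_features(glszm_build(levels, mask, Ng)).items():
                out[f"glszm_{k}"] = v
        if "gldm" in classes:
            for k, v in gldm_features(
                gldm_build(levels, mask, Ng, alpha=gldm_alpha)
            ).items():
                out[f"gldm_{k}"] = v
        if "ngtdm" in classes:
            for k, v in ngtdm_features(ngtdm_build(levels, mask, Ng)).items():
                out[f"ngtdm_{k}"] = v
    return out


def extract_all(
    image,
    mask,
    bin_number: int = 32,
    voxel_spacing=(1.0, 1.0, 1.0),
    filters=("original",) + tuple(f"wavelet-{s}" for s in WAVELET_SUBBANDS),
    classes=FEATURE_CLASSES,
    include_shape: bool = True,
    glcm_distance: int = 1,
    gldm_alpha: int = 0,
    wavelet: str = "coif1",
    patient_id: str | None = None,
) -> dict[str, float]:
    """Full per-patient feature vector: ``<filter>_<class>_<feature>``.

    Shape is computed once from the mask alone; each filtered volume is
    re-discretized on its own ROI range before texture matrices are built.
    The name set is a pure function of the configuration, identical across
    patients.
    """
    try:
        arr = np.asarray(image, dtype=float)
        m = np.asarray(mask).astype(bool)
        if arr.shape != m.shape:
            raise ValueError("image and mask shapes differ")
        if not m.any():
            raise ValueError("mask is empty")
        out: dict[str, float] = {}
        if include_shape:
            for k, v in shape_features(m, voxel_spacing).items():
                out[f"shape_{k}"] = v
        volumes = {}
        if "original" in filters:
            volumes["original"] = arr
        wanted_subbands = [f.split("-", 1)[1] for f in filters if f.startswith("wavelet-")]
        if wanted_subbands:
            bands = wavelet_decompose(arr, wavelet=wavelet)
            for s in wanted_subbands:
                volumes[f"wavelet-{s}"] = bands[s]
        for filt in filters:
            vol = volumes[filt]
            feats = _texture_features_for_roi(
                vol, m, bin_number, glcm_distance, gldm_alpha, classes
            )
            for k, v in feats.items():
                out[f"{filt}_{k}"] = v
        return out
    except Exception as exc:
        if patient_id is not None:
            raise RuntimeError(f"feature extraction failed for patient "
                               f"{patient_id}: {exc}") from exc
        raise


def feature_names(**kwargs) -> list[str]:
    """The deterministic feature schema for a configuration (data-free)."""
    img = np.zeros((8, 8, 8))
    img[2:6, 2:6, 2:6] = np.arange(64).reshape(4, 4, 4)
    msk = np.zeros((8, 8, 8), bool)
    msk[2:6, 2:6, 2:6] = True
    return list(extract_all(img, msk, **kwargs).keys())
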