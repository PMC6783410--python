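"""Texture and shape feature extraction over VOIs.

All texture operators are fully 3-D. Gray-level matrices (GLCM, GLRLM) are
built on an equal-width re-binning of the 256-level normalized image
inside the VOI (default 32 bins — 256-level matrices are nearly empty on
small VOIs). Pair and run constructions never cross invalid (deleted)
voxels or leave the VOI, and each of the 13 unique direction offsets of
the 26-neighbourhood is evaluated separately; per-statistic mean and SD
across directions are reported.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from scipy import ndimage
from skimage import measure

from .catalog import (
    CATALOG,
    FIRST_ORDER_STATS,
    GLCM_STATS,
    GLRLM_STATS,
    SERIES_ORDER,
    VOI_ORDER,
)
from .preproc import NormalizedImage
from .voi import VOI

# the 13 unique offsets of the 26-neighbourhood (first nonzero positive)
DIRECTIONS_13 = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class TextureConfig:
    n_gray_bins: int = 32
    distance: int = 1
    directions: tuple = DIRECTIONS_13
    min_voi_voxels: int = 8

    def __post_init__(self) -> None:
        if self.n_gray_bins < 2:
            raise ValueError("need at least 2 gray bins")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


# ---------------------------------------------------------------------------
# Quantization


def quantize_levels(norm_img: NormalizedImage, voi: VOI, n_bins: int = 32):
    """Assign bins 1..n_bins to valid in-VOI voxels; 0 elsewhere.

    Equal-width binning of the [min, max] of valid in-VOI levels; a
    constant VOI maps entirely to bin 1. Returns None when the VOI holds
    no valid voxels.
    """
    sel = voi.mask & norm_img.validity
    if not sel.any():
        return None
    vals = norm_img.levels[sel].astype(float)
    lo, hi = vals.min(), vals.max()
    labels = np.zeros(norm_img.shape, dtype=np.int32)
    if hi == lo:
        labels[sel] = 1
        return labels
    frac = (norm_img.levels[sel] - lo) / (hi - lo)
    b = np.minimum(np.floor(frac * n_bins).astype(np.int32), n_bins - 1) + 1
    labels[sel] = b
    return labels


# ---------------------------------------------------------------------------
# First-order statistics


def first_order_features(norm_img: NormalizedImage, voi: VOI,
                         min_voxels: int = 8) -> dict:
    """14 histogram statistics of valid in-VOI gray levels.

    Variance is the population variance; skewness and excess kurtosis are
    the biased moment estimators (0 for a constant VOI); energy is the
    mean squared level; entropy is base-2 over the 256-level histogram.
    """
    sel = voi.mask & norm_img.validity
    v = norm_img.levels[sel].astype(float)
    if v.size < min_voxels:
        return {s: np.nan for s in FIRST_ORDER_STATS}
    mean = v.mean()
    var = v.var()
    if var > 0:
        sd = np.sqrt(var)
        skew = np.mean((v - mean) ** 3) / sd**3
        kurt = np.mean((v - mean) ** 4) / var**2 - 3.0
    else:
        skew = kurt = 0.0
    counts = np.bincount(v.astype(int), minlength=256)
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "Mean": float(mean),
        "Median": float(np.median(v)),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Variance": float(var),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Energy": float(np.mean(v**2)),
        "Entropy": entropy,
        "P10": float(np.percentile(v, 10)),
        "P90": float(np.percentile(v, 90)),
        "IQR": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "RMS": float(np.sqrt(np.mean(v**2))),
    }


# ---------------------------------------------------------------------------
# GLCM


def _offset_slices(shape, offset):
    """Slices (src, dst) so that a[src] and a[dst] are voxel pairs p, p+d."""
    src, dst = [], []
    for n, d in zip(shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def glcm_matrix(labels: np.ndarray, offset, n_bins: int):
    """Symmetric, normalized co-occurrence matrix for one offset.

    Counts each in-VOI voxel pair (p, p+d) in both orders. Returns None
    when no valid pair exists for this offset.
    """
    src, dst = _offset_slices(labels.shape, offset)
    a = labels[src]
    b = labels[dst]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        return None
    ai = a[ok] - 1
    bi = b[ok] - 1
    mat = np.zeros((n_bins, n_bins))
    np.add.at(mat, (ai, bi), 1.0)
    np.add.at(mat, (bi, ai), 1.0)
    return mat / mat.sum()


def glcm_statistics(p: np.ndarray) -> dict:
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    autocorr = float((ii * jj * p).sum())
    corr = float((autocorr - mu * mu) / sigma2) if sigma2 > 1e-12 else 1.0
    nz = p[p > 0]
    return {
        "Contrast": contrast,
        "Correlation": corr,
        "Energy": float((p**2).sum()),
        "Entropy": float(-(nz * np.log2(nz)).sum()),
        "Homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "Autocorrelation": autocorr,
        "ClusterShade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "ClusterProminence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "SumAverage": float(((ii + jj) * p).sum()),
        "MaxProbability": float(p.max()),
    }


def glcm_features(labels, config: TextureConfig) -> dict:
    """Per-direction GLCM statistics aggregated as Mean/SD over directions."""
    if labels is None or (labels > 0).sum() < config.min_voi_voxels:
        return {f"{s}_{a}": np.nan for s in GLCM_STATS for a in ("Mean", "SD")}
    per_dir = []
    for d in config.directions:
        off = tuple(config.distance * c for c in d)
        mat = glcm_matrix(labels, off, config.n_gray_bins)
        if mat is not None:
            per_dir.append(glcm_statistics(mat))
    if not per_dir:
        return {f"{s}_{a}": np.nan for s in GLCM_STATS for a in ("Mean", "SD")}
    out = {}
    for s in GLCM_STATS:
        vals = np.array([d[s] for d in per_dir])
        out[f"{s}_Mean"] = float(vals.mean())
        out[f"{s}_SD"] = float(vals.std())
    return out


# ---------------------------------------------------------------------------
# GLRLM


def run_list(labels: np.ndarray, offset) -> tuple:
    """All maximal same-bin runs along one direction.

    Returns (gray_levels, run_lengths) arrays. Runs are broken by voxels
    outside the VOI (bin 0), so deleted voxels never join two runs.
    """
    d = np.asarray(offset)
    in_voi = labels > 0

    def shifted(arr, dd, fill):
        out = np.full_like(arr, fill)
        src, dst = _offset_slices(arr.shape, tuple(dd))
        out[dst] = arr[src]
        return out

    prev_lab = shifted(labels, d, 0)        # value at p - d
    prev_in = shifted(in_voi, d, False)
    starts = in_voi & ~(prev_in & (prev_lab == labels))
    next_lab = shifted(labels, -d, 0)       # value at p + d
    next_in = shifted(in_voi, -d, False)
    ends = in_voi & ~(next_in & (next_lab == labels))

    idx = np.indices(labels.shape)
    ax = int(np.nonzero(d)[0][0])
    t = idx[ax] * int(np.sign(d[ax]))
    # two voxels share a line iff p - t*d is equal
    key_parts = [idx[k] - t * d[k] for k in range(3)]
    base = 4 * (max(labels.shape) + 1)
    key = ((key_parts[0] + base) * base + (key_parts[1] + base)) * base + (
        key_parts[2] + base
    )

    ks, ts = key[starts], t[starts]
    ke, te = key[ends], t[ends]
    so = np.lexsort((ts, ks))
    eo = np.lexsort((te, ke))
    lengths = te[eo] - ts[so] + 1
    grays = labels[starts][so]
    return grays, lengths


def glrlm_statistics(grays, lengths, n_voxels: int) -> dict:
    g = np.asarray(grays, dtype=float)
    l = np.asarray(lengths, dtype=float)
    r = float(len(l))
    _, gcounts = np.unique(g, return_counts=True)
    _, lcounts = np.unique(l, return_counts=True)
    return {
        "ShortRun": float(np.sum(1.0 / l**2) / r),
        "Lrge": float(np.sum(l**2) / r),
        "GrayNonUnif": float(np.sum(gcounts.astype(float) ** 2) / r),
        "RunNonUnif": float(np.sum(lcounts.astype(float) ** 2) / r),
        "RunPct": float(r / n_voxels),
        "LowGrayRun": float(np.sum(1.0 / g**2) / r),
    }


def glrlm_features(labels, config: TextureConfig) -> dict:
    """Per-direction run-length statistics aggregated as Mean/SD."""
    if labels is None or (labels > 0).sum() < config.min_voi_voxels:
        return {f"{s}_{a}": np.nan for s in GLRLM_STATS for a in ("Mean", "SD")}
    n_vox = int((labels > 0).sum())
    per_dir = []
    for d in config.directions:
        off = tuple(config.distance * c for c in d)
        grays, lengths = run_list(labels, off)
        if len(lengths) == 0:
            continue
        assert int(lengths.sum()) == n_vox, "run-length mass must equal VOI size"
        per_dir.append(glrlm_statistics(grays, lengths, n_vox))
    if not per_dir:
        return {f"{s}_{a}": np.nan for s in GLRLM_STATS for a in ("Mean", "SD")}
    out = {}
    for s in GLRLM_STATS:
        vals = np.array([d[s] for d in per_dir])
        out[f"{s}_Mean"] = float(vals.mean())
        out[f"{s}_SD"] = float(vals.std())
    return out


# ---------------------------------------------------------------------------
# Shape


def _surface_area(mask: np.ndarray, spacing) -> float:
    """Mesh surface area of the mask isosurface.

    The binary mask is lightly smoothed before meshing so the staircase
    artifact does not inflate the area (a raw binary ball reads ~9 %
    high); structures too thin to survive smoothing fall back to the
    raw binary mesh.
    """
    padded = np.pad(mask, 1).astype(float)
    smoothed = ndimage.gaussian_filter(padded, 0.8)
    surf = smoothed if smoothed.max() > 0.5 else padded
    verts, faces, _, _ = measure.marching_cubes(surf, level=0.5, spacing=tuple(spacing))
    return float(measure.mesh_surface_area(verts, faces))


def _max_diameter(mask: np.ndarray, spacing) -> float:
    """Maximum pairwise distance between surface voxel centres (mm)."""
    surf = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(surf) * np.asarray(spacing)
    if len(pts) < 2:
        return 0.0
    if len(pts) > 4:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # degenerate (coplanar) point sets
            pass
    return float(pdist(pts).max())


def shape_features(core: VOI, edema: VOI | None, spacing) -> dict:
    """Volume, mesh surface area, sphericity and maximum 3-D diameter for
    both VOIs, plus the edema/core volume ratio.

    Sphericity = pi^(1/3) (6V)^(2/3) / A, 1 for a perfect ball.
    """
    out = {name: np.nan for name in (
        "Shape_core_Volume", "Shape_core_SurfaceArea", "Shape_core_Sphericity",
        "Shape_core_MaxDiameter", "Shape_edema_Volume", "Shape_edema_SurfaceArea",
        "Shape_edema_Sphericity", "Shape_edema_MaxDiameter",
        "Shape_edema_CoreVolumeRatio",
    )}
    if core is None or core.is_empty:
        return out
    spacing = np.asarray(spacing, dtype=float)
    voxvol = float(np.prod(spacing))
    cv = core.voxel_count * voxvol
    ca = _surface_area(core.mask, spacing)
    out["Shape_core_Volume"] = cv
    out["Shape_core_SurfaceArea"] = ca
    out["Shape_core_Sphericity"] = float(np.pi ** (1 / 3) * (6 * cv) ** (2 / 3) / ca)
    out["Shape_core_MaxDiameter"] = _max_diameter(core.mask, spacing)
    if edema is not None and not edema.is_empty:
        ev = edema.voxel_count * voxvol
        ea = _surface_area(edema.mask, spacing)
        out["Shape_edema_Volume"] = ev
        out["Shape_edema_SurfaceArea"] = ea
        out["Shape_edema_Sphericity"] = float(np.pi ** (1 / 3) * (6 * ev) ** (2 / 3) / ea)
        out["Shape_edema_MaxDiameter"] = _max_diameter(edema.mask, spacing)
        out["Shape_edema_CoreVolumeRatio"] = float(ev / cv)
    return out


# ---------------------------------------------------------------------------
# Full-case extraction


def extract_case_features(series: dict, core: VOI, edema: VOI,
                          config: TextureConfig | None = None) -> pd.Series:
    """The full 489-value feature vector of one case, in catalog order.

    ``series`` maps sequence tags (T1, T2, T1Gd, T2Edge, Gdzscore) to
    :class:`NormalizedImage` objects on the Gd-T1 grid. Absent series or
    too-small VOIs yield NaN for the affected features; the vector always
    carries all 489 catalog keys. Extraction is deterministic.
    """
    config = config or TextureConfig()
    values: dict = {}
    vois = {"core": core, "edema": edema}
    for tag in SERIES_ORDER:
        img = series.get(tag)
        for voi_name in VOI_ORDER:
            voi = vois[voi_name]
            prefix = f"{tag}_{voi_name}_"
            if img is None or voi is None or voi.is_empty:
                fo = {s: np.nan for s in FIRST_ORDER_STATS}
                labels = None
            else:
                fo = first_order_features(img, voi, config.min_voi_voxels)
                labels = quantize_levels(img, voi, config.n_gray_bins)
            for s, v in fo.items():
                values[prefix + "Hist" + s] = v
            for k, v in glcm_features(labels, config).items():
                values[prefix + "GLCM" + k] = v
            for k, v in glrlm_features(labels, config).items():
                values[prefix + "GLRLM" + k] = v
    spacing = core.spacing_mm if core is not None else np.ones(3)
    values.update(shape_features(core, edema, spacing))
    vec = pd.Series(values, dtype=float).reindex(CATALOG)
    assert len(vec) == len(CATALOG)
    return vec
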