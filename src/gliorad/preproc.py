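"""Volume handling and intensity preprocessing.

Multi-scanner MR intensities are not quantitative, so every series is
reduced to 256 integer gray levels before texture analysis:

* T1-like series (non-contrast T1 and Gd-enhanced T1): the top 0.1 % of
  in-brain intensities is treated as high-signal noise and marked invalid;
  the remaining 99.9 % of the range is mapped onto levels 0-255.
* T2: the full in-brain range is mapped onto levels 0-255.

Two derived series are constructed from the normalized inputs: ``T2Edge``
(the 3-D Prewitt gradient magnitude of the normalized T2) and ``Gdzscore``
(the voxel-wise z-score of the Gd-T1 minus T1 level difference, a simple
contrast-enhancement map).

"Deleted" voxels are never removed from the rectangular grid; they are
carried in a validity mask and excluded from all downstream statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

SequenceTag = Literal["T1", "T2", "T1Gd", "T2Edge", "Gdzscore"]

N_LEVELS = 256
TOP_CUT_PERCENTILE = 99.9


class LoadError(RuntimeError):
    """A study file failed to load or validate."""


class GridMismatchError(ValueError):
    """Operands live on different voxel grids; resample first."""


@dataclass
class Image3D:
    """A 3-D voxel grid with physical geometry.

    Parameters
    ----------
    voxels : float array, shape (nx, ny, nz)
    spacing_mm : voxel edge lengths in mm
    grid_to_world : 4x4 affine taking voxel indices to world mm
    sequence_tag : which MR series this is
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray
    grid_to_world: np.ndarray
    sequence_tag: str = "T1"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.grid_to_world = np.asarray(self.grid_to_world, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive")
        if self.grid_to_world.shape != (4, 4):
            raise ValueError("grid_to_world must be 4x4")
        if abs(np.linalg.det(self.grid_to_world)) < 1e-12:
            raise ValueError("grid_to_world affine is singular")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def same_grid(self, other: "Image3D") -> bool:
        return self.shape == other.shape and np.allclose(
            self.grid_to_world, other.grid_to_world
        )


@dataclass
class NormalizedImage:
    """Integer 0-255 gray levels plus a validity mask.

    ``validity`` marks voxels usable for statistics: inside the brain mask
    and, for T1-like series, not in the deleted top-0.1 % tail.
    ``normalization_params`` records (cut percentile used, observed cutoff
    intensity, in-mask minimum).
    """

    levels: np.ndarray
    validity: np.ndarray
    source_tag: str
    normalization_params: tuple
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    grid_to_world: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.levels.shape != self.validity.shape:
            raise ValueError("levels and validity shapes differ")
        if self.levels.min() < 0 or self.levels.max() > 255:
            raise ValueError("levels must lie in [0, 255]")

    @property
    def shape(self) -> tuple:
        return self.levels.shape


@dataclass
class AffineTransform:
    """A 4x4 world-to-world affine between two named grids."""

    matrix: np.ndarray
    source_grid: str = "source"
    target_grid: str = "target"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if not np.allclose(self.matrix[3], [0, 0, 0, 1]):
            raise ValueError("last affine row must be (0,0,0,1)")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, source: str = "source", target: str = "target"):
        return cls(np.eye(4), source, target)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(
            np.linalg.inv(self.matrix), self.target_grid, self.source_grid
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_nifti(path, sequence_tag: str = "T1") -> Image3D:
    """Load a single-volume NIfTI file as an :class:`Image3D`."""
    path = Path(path)
    if not path.exists():
        raise LoadError(f"file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise LoadError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    data = np.asarray(data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise LoadError(f"{path}: volume contains non-finite voxels")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    return Image3D(data, spacing, np.asarray(img.affine), sequence_tag)


def write_nifti(img: Image3D, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(img.voxels, img.grid_to_world), str(path))
    return path


def read_affine_text(path, source: str = "source", target: str = "target") -> AffineTransform:
    """Read a whitespace-delimited 4x4 world-coordinate affine."""
    mat = np.loadtxt(path)
    return AffineTransform(mat, source, target)


@dataclass
class StudyBundle:
    """One case's loaded volumes and masks, all on their native grids."""

    case_id: str
    t1: Image3D
    t2: Image3D
    t1gd: Image3D
    core_mask: np.ndarray
    t2_mask: np.ndarray
    brain_mask: np.ndarray | None = None


def load_study(
    case_id: str,
    t1_path,
    t2_path,
    t1gd_path,
    core_mask_path,
    t2_mask_path,
    brain_mask_path=None,
) -> StudyBundle:
    """Load the three sequences and the two lesion masks for one case.

    Masks are binarized (>0). The core mask must match the Gd-T1 grid and
    the T2 lesion mask the T2 grid (they are drawn on those sequences).
    """
    t1 = read_nifti(t1_path, "T1")
    t2 = read_nifti(t2_path, "T2")
    t1gd = read_nifti(t1gd_path, "T1Gd")
    core = read_nifti(core_mask_path, "T1Gd").voxels > 0
    t2les = read_nifti(t2_mask_path, "T2").voxels > 0
    if core.shape != t1gd.shape:
        raise LoadError(
            f"core mask shape {core.shape} does not match Gd-T1 grid {t1gd.shape}"
        )
    if t2les.shape != t2.shape:
        raise LoadError(
            f"T2 lesion mask shape {t2les.shape} does not match T2 grid {t2.shape}"
        )
    brain = None
    if brain_mask_path is not None:
        brain = read_nifti(brain_mask_path, "T1").voxels > 0
    return StudyBundle(case_id, t1, t2, t1gd, core, t2les, brain)


# ---------------------------------------------------------------------------
# Normalization

def _resolve_brain_mask(img: Image3D, brain_mask) -> np.ndarray:
    if brain_mask is None:
        mask = img.voxels != 0
    else:
        mask = np.asarray(brain_mask) > 0
    if mask.shape != img.shape:
        raise GridMismatchError("brain mask shape does not match image")
    if not mask.any():
        raise ValueError("brain mask is empty")
    return mask


def _levels_from_range(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Equal-width 256-bin quantization of [lo, hi]; degenerate range -> 0."""
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int16)
    frac = (values - lo) / (hi - lo)
    lv = np.floor(frac * N_LEVELS).astype(np.int16)
    return np.clip(lv, 0, 255)


def normalize_t1_like(img: Image3D, brain_mask=None) -> NormalizedImage:
    """Normalize a T1-like series to 256 gray levels, deleting the top 0.1 %.

    The cutoff is the 99.9th percentile of in-mask intensities; voxels
    strictly above it are marked invalid (high-signal noise). The remaining
    in-mask range [min, cutoff] is mapped to integer levels 0-255.
    """
    mask = _resolve_brain_mask(img, brain_mask)
    vals = img.voxels[mask]
    cutoff = float(np.percentile(vals, TOP_CUT_PERCENTILE))
    lo = float(vals.min())
    validity = mask & (img.voxels <= cutoff)
    levels = np.zeros(img.shape, dtype=np.int16)
    levels[validity] = _levels_from_range(img.voxels[validity], lo, cutoff)
    return NormalizedImage(
        levels, validity, img.sequence_tag,
        (TOP_CUT_PERCENTILE, cutoff, lo),
        img.spacing_mm, img.grid_to_world,
    )


def normalize_t2(img: Image3D, brain_mask=None) -> NormalizedImage:
    """Normalize a T2 series: full in-mask range to 256 gray levels."""
    mask = _resolve_brain_mask(img, brain_mask)
    vals = img.voxels[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(img.shape, dtype=np.int16)
    levels[mask] = _levels_from_range(img.voxels[mask], lo, hi)
    return NormalizedImage(
        levels, mask, img.sequence_tag, (100.0, hi, lo),
        img.spacing_mm, img.grid_to_world,
    )


# ---------------------------------------------------------------------------
# Derived series


def compute_t2edge(norm_t2: NormalizedImage) -> NormalizedImage:
    """Prewitt gradient-magnitude series from a normalized T2.

    Each gradient component is a separable 3x3x3 Prewitt kernel
    (derivative [-1,0,1] along one axis, smoothing [1,1,1] along the other
    two); the magnitude is the Euclidean norm of the three components,
    re-mapped to 0-255 over the valid voxels. Validity is the input
    validity eroded by one voxel (26-connectivity) because the kernel
    support of a border voxel leaves the valid set.
    """
    if not norm_t2.validity.any():
        raise ValueError("input has no valid voxels")
    lv = norm_t2.levels.astype(float)
    mag = np.zeros_like(lv)
    for axis in range(3):
        g = ndimage.prewitt(lv, axis=axis, mode="nearest")
        mag += g * g
    mag = np.sqrt(mag)
    validity = ndimage.binary_erosion(
        norm_t2.validity, structure=np.ones((3, 3, 3), bool)
    )
    levels = np.zeros(norm_t2.shape, dtype=np.int16)
    if validity.any():
        vals = mag[validity]
        levels[validity] = _levels_from_range(vals, float(vals.min()), float(vals.max()))
    return NormalizedImage(
        levels, validity, "T2Edge", (100.0, float(mag.max()), 0.0),
        norm_t2.spacing_mm, norm_t2.grid_to_world,
    )


def compute_gdzscore(
    norm_t1: NormalizedImage, norm_t1gd: NormalizedImage, brain_mask=None
) -> NormalizedImage:
    """Contrast-enhancement series: z-scored Gd-T1 minus T1 level difference.

    D = level(T1Gd) - level(T1) on jointly valid voxels; D is standardized
    to zero mean / unit population SD over those voxels and the z values
    are re-mapped to 0-255 over their full range. A zero-spread difference
    (no enhancement anywhere) yields all-zero levels.
    """
    if norm_t1.shape != norm_t1gd.shape:
        raise GridMismatchError(
            "T1 and Gd-T1 are on different grids; resample one onto the other first"
        )
    validity = norm_t1.validity & norm_t1gd.validity
    if brain_mask is not None:
        validity = validity & (np.asarray(brain_mask) > 0)
    if not validity.any():
        raise ValueError("no jointly valid voxels")
    d = norm_t1gd.levels.astype(float) - norm_t1.levels.astype(float)
    dv = d[validity]
    sd = float(dv.std())  # population SD
    z = np.zeros(norm_t1.shape)
    if sd > 0:
        z[validity] = (dv - dv.mean()) / sd
    levels = np.zeros(norm_t1.shape, dtype=np.int16)
    zv = z[validity]
    levels[validity] = _levels_from_range(zv, float(zv.min()), float(zv.max()))
    return NormalizedImage(
        levels, validity, "Gdzscore", (100.0, float(zv.max()), float(zv.min())),
        norm_t1.spacing_mm, norm_t1.grid_to_world,
    )


# ---------------------------------------------------------------------------
# Affine resampling


@dataclass
class GridSpec:
    """Target grid geometry for resampling."""

    shape: tuple
    grid_to_world: np.ndarray

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.grid_to_world)[:3, :3], axis=0)


def resample_affine(
    img: Image3D,
    transform: AffineTransform,
    target: GridSpec,
    interpolation: str = "trilinear",
) -> Image3D:
    """Resample a volume through a world-to-world affine onto a target grid.

    ``transform.matrix`` maps source-world coordinates to target-world
    coordinates. Intensities use trilinear interpolation; masks should use
    nearest-neighbour. Target voxels that map outside the source grid are
    set to 0.
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation mode: {interpolation}")
    order = 1 if interpolation == "trilinear" else 0
    # target index -> target world -> source world -> source index
    tgt2world = np.asarray(target.grid_to_world, dtype=float)
    world2src_world = np.linalg.inv(transform.matrix)
    src_world2idx = np.linalg.inv(img.grid_to_world)
    full = src_world2idx @ world2src_world @ tgt2world
    out = ndimage.affine_transform(
        img.voxels,
        full[:3, :3],
        offset=full[:3, 3],
        output_shape=tuple(target.shape),
        order=order,
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    return Image3D(out, target.spacing_mm, tgt2world, img.sequence_tag)


def resample_mask(mask: np.ndarray, source_grid_to_world, transform: AffineTransform,
                  target: GridSpec) -> np.ndarray:
    """Nearest-neighbour resample of a binary mask onto a target grid."""
    img = Image3D(np.asarray(mask, dtype=float), np.ones(3), source_grid_to_world)
    out = resample_affine(img, transform, target, interpolation="nearest")
    return out.voxels > 0.5
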