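"""Volumes of interest: mask algebra, atlas mapping, and location analysis.

Two VOIs drive the whole feature pipeline: the contrast-enhancing tumour
core delineated on Gd-T1 (``core``) and the peritumoral edema, obtained by
subtracting the core from the T2 high-intensity lesion (``edema``). They
are disjoint by construction. Texture features are computed on the native
Gd-T1 grid; only location analysis moves masks to a 1 mm isotropic
MNI152-space atlas grid.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preproc import AffineTransform, GridSpec, resample_mask


class EmptyVOIError(ValueError):
    """A location/feature query on an empty VOI."""


# 1 mm isotropic MNI152 grid geometry (shape and world origin of the
# standard 182x218x182 template); only the geometry is needed here, never
# the template volume itself.
def mni152_grid() -> GridSpec:
    affine = np.array([
        [1.0, 0.0, 0.0, -90.0],
        [0.0, 1.0, 0.0, -126.0],
        [0.0, 0.0, 1.0, -72.0],
        [0.0, 0.0, 0.0, 1.0],
    ])
    return GridSpec(shape=(182, 218, 182), grid_to_world=affine)


@dataclass
class VOI:
    mask: np.ndarray
    role: str                      # "core" | "edema"
    grid_id: str
    spacing_mm: np.ndarray
    grid_to_world: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.grid_to_world = np.asarray(self.grid_to_world, dtype=float)
        if self.role not in ("core", "edema"):
            raise ValueError(f"unknown VOI role: {self.role}")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


def build_voi_core(gd_lesion_mask, spacing_mm, grid_to_world, grid_id="gd") -> VOI:
    """Core VOI from the enhancing-lesion mask drawn on Gd-T1."""
    mask = np.asarray(gd_lesion_mask) > 0
    return VOI(mask, "core", grid_id, spacing_mm, grid_to_world)


def build_voi_edema(t2_lesion_mask, core: VOI) -> VOI:
    """Edema VOI: T2 lesion (already on the Gd grid) minus the core."""
    mask = np.asarray(t2_lesion_mask) > 0
    if mask.shape != core.mask.shape:
        raise ValueError(
            f"T2 lesion mask shape {mask.shape} does not match core grid "
            f"{core.mask.shape}; resample onto the Gd-T1 grid first"
        )
    edema = mask & ~core.mask
    return VOI(edema, "edema", core.grid_id, core.spacing_mm, core.grid_to_world)


def map_voi_to_atlas(voi: VOI, subject_to_atlas: AffineTransform,
                     atlas: GridSpec | None = None) -> VOI:
    """Nearest-neighbour resampling of a VOI onto the atlas grid."""
    if atlas is None:
        atlas = mni152_grid()
    mask = resample_mask(voi.mask, voi.grid_to_world, subject_to_atlas, atlas)
    return VOI(mask, voi.role, "atlas", atlas.spacing_mm, atlas.grid_to_world)


def dice_index(mask_a, mask_b) -> float:
    """Dice overlap between two segmentations (interobserver utility).

    2|A∩B| / (|A|+|B|); defined as 1.0 when both masks are empty.
    """
    a = np.asarray(mask_a) > 0
    b = np.asarray(mask_b) > 0
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


@dataclass
class FrequencyMap:
    counts: np.ndarray
    n_cases: int


def lesion_frequency_map(atlas_vois) -> FrequencyMap:
    """Voxelwise count of overlapping VOIs on a shared atlas grid."""
    vois = list(atlas_vois)
    if not vois:
        raise ValueError("no VOIs supplied")
    shape = vois[0].mask.shape
    counts = np.zeros(shape, dtype=np.int32)
    for v in vois:
        if v.mask.shape != shape:
            raise ValueError("frequency map requires VOIs on one grid")
        counts += v.mask
    return FrequencyMap(counts, len(vois))


@dataclass
class LocationFeatures:
    centroid_atlas_mm: tuple
    volume_atlas_mm3: float
    left_fraction: float
    right_fraction: float


def location_features(atlas_voi: VOI) -> LocationFeatures:
    """Centroid (atlas mm), volume, and laterality of an atlas-grid VOI.

    Laterality splits at the atlas midline x = 0; by the sign convention
    of the atlas affine used here, x > 0 is the right side. Voxels exactly
    on the midline count half to each side.
    """
    if atlas_voi.is_empty:
        raise EmptyVOIError("location features are undefined for an empty VOI")
    idx = np.argwhere(atlas_voi.mask)
    hom = np.c_[idx, np.ones(len(idx))]
    world = hom @ atlas_voi.grid_to_world.T
    xyz = world[:, :3]
    centroid = xyz.mean(axis=0)
    vol = atlas_voi.voxel_count * atlas_voi.voxel_volume_mm3
    x = xyz[:, 0]
    right = float(np.sum(x > 0) + 0.5 * np.sum(x == 0)) / len(x)
    return LocationFeatures(tuple(centroid), float(vol), 1.0 - right, right)
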