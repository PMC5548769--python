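"""Per-ossicle bone morphometry: BV, BS, TV and their ratios.

Definitions
-----------
BV  : volume of voxels carrying the label (voxel count x voxel volume).
BS  : area of the triangulated 0.5-isosurface of the binary label mask.
TV  : volume of the label after filling enclosed cavities; background
      components are taken 26-connected, so surface concavities open to the
      image border are *not* holes and do not inflate TV.

All outputs use millimetre units (mm^3, mm^2, mm^-1); voxel sizes are given
in micrometres throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import MorphometryError

UM_TO_MM = 1.0e-3
UM3_TO_MM3 = UM_TO_MM**3
UM2_TO_MM2 = UM_TO_MM**2

#: 26-connected structuring element used for the hole-filling complement.
_BACKGROUND_STRUCTURE = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class MorphometryResult:
    """Morphometric parameters of a single labelled object."""

    label: int
    BV: float  # mm^3
    BS: float  # mm^2
    TV: float  # mm^3
    BV_TV: float = field(init=False)
    BS_BV: float = field(init=False)  # mm^-1
    BS_TV: float = field(init=False)  # mm^-1

    def __post_init__(self) -> None:
        object.__setattr__(self, "BV_TV", self.BV / self.TV)
        object.__setattr__(self, "BS_BV", self.BS / self.BV)
        object.__setattr__(self, "BS_TV", self.BS / self.TV)

    def as_dict(self) -> dict:
        return asdict(self)


def _coerce(lv, voxel_size_um: float | None) -> tuple[np.ndarray, float]:
    """Accept either a labelled-volume object or a bare integer array."""
    if hasattr(lv, "labels") and hasattr(lv, "voxel_size_um"):
        return np.asarray(lv.labels), float(lv.voxel_size_um)
    if voxel_size_um is None:
        raise MorphometryError("voxel_size_um required when passing a bare array")
    return np.asarray(lv), float(voxel_size_um)


def _label_mask(labels: np.ndarray, label: int) -> np.ndarray:
    if label <= 0:
        raise MorphometryError(f"label must be positive, got {label}")
    mask = labels == label
    if not mask.any():
        raise MorphometryError(f"label {label} not present in volume")
    return mask


def bone_volume(lv, label: int, voxel_size_um: float | None = None) -> float:
    """Bone volume of ``label`` in mm^3 (exact voxel count)."""
    labels, vs = _coerce(lv, voxel_size_um)
    mask = _label_mask(labels, label)
    return float(mask.sum()) * vs**3 * UM3_TO_MM3


def bone_surface(lv, label: int, voxel_size_um: float | None = None,
                 smoothing_sigma: float = 1.0) -> float:
    """Surface area of ``label`` in mm^2 by marching-cubes triangulation.

    The 0/1 mask is anti-aliased with a ``smoothing_sigma``-voxel Gaussian
    before triangulating the 0.5 isosurface: triangulating the raw binary
    mask carries a systematic staircase overestimate (~9% for a sphere of 25
    voxel radius), while the one-voxel pre-filter removes it without moving
    the interface. Pass ``smoothing_sigma=0`` for the raw staircase surface.

    The label must not touch the volume boundary: the isosurface would be
    clipped open and the triangle-area sum would under-report the surface.
    """
    labels, vs = _coerce(lv, voxel_size_um)
    mask = _label_mask(labels, label)
    if _touches_boundary(mask):
        raise MorphometryError(
            f"label {label} touches the volume boundary; surface would be open"
        )
    field_ = mask.astype(np.float32)
    if smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(field_, smoothing_sigma)
        # tiny objects can be smoothed entirely below the isolevel
        if smoothed.max() > 0.5:
            field_ = smoothed
    verts, faces, _, _ = measure.marching_cubes(field_, level=0.5)
    area_vox = measure.mesh_surface_area(verts, faces)
    return float(area_vox) * vs**2 * UM2_TO_MM2


def total_volume(lv, label: int, voxel_size_um: float | None = None) -> float:
    """Total volume of ``label`` in mm^3 after filling enclosed cavities."""
    labels, vs = _coerce(lv, voxel_size_um)
    mask = _label_mask(labels, label)
    filled = fill_holes(mask)
    return float(filled.sum()) * vs**3 * UM3_TO_MM3


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background cavities not 26-connected to the image border."""
    return ndimage.binary_fill_holes(mask, structure=_BACKGROUND_STRUCTURE)


def compute_morphometry(lv, voxel_size_um: float | None = None) -> list[MorphometryResult]:
    """One :class:`MorphometryResult` per positive label, ascending label order."""
    labels, vs = _coerce(lv, voxel_size_um)
    present = np.unique(labels)
    present = present[present > 0]
    if present.size == 0:
        raise MorphometryError("no labelled objects in volume")
    results = []
    for lab in present:
        lab = int(lab)
        results.append(
            MorphometryResult(
                label=lab,
                BV=bone_volume(labels, lab, vs),
                BS=bone_surface(labels, lab, vs),
                TV=total_volume(labels, lab, vs),
            )
        )
    return results


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(
        mask[0].any() or mask[-1].any()
        or mask[:, 0].any() or mask[:, -1].any()
        or mask[:, :, 0].any() or mask[:, :, -1].any()
    )
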