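"""Ossicle phantom generation and stochastic surface erosion.

Phantoms are binary voxel objects with analytically known reference
morphometry ("truth"): the truth table is computed with the same operators
the :mod:`ossimetry.morphometry` module exposes, so truth is self-consistent
with the measurement path by construction. Spheres additionally carry the
closed-form volume and surface so the voxelization itself is checkable.

Shape vocabulary: ``sphere`` (calibration object), ``pyramid`` (anterior-type
ossicle) and ``lunula`` (crescent, posterior-type ossicle).

A note on porosity: total volume is defined by hole filling, so eroding the
*outer* surface of a fully solid body reduces BV and TV by the same voxels
and leaves BV/TV at 1. A programmed BV/TV drop is therefore only reachable
for objects with enclosed internal porosity; ``make_ossicle`` accepts a
``cavity_fraction`` that carves a sealed spherical cavity at the object's
deepest interior point. Erosion then shrinks the envelope around a constant
cavity and BV/TV falls.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage

from . import morphometry as mm
from .errors import ErosionTargetError, PhantomError

ShapeKind = Literal["sphere", "pyramid", "lunula"]

#: 6-connectivity structuring element (face neighbours only).
STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class Phantom:
    """Binary ossicle object with ground-truth morphometry."""

    volume: np.ndarray            # bool, True = bone
    voxel_size_um: float
    labels: np.ndarray            # integer id per ossicle, 0 = background
    truth: dict[int, mm.MorphometryResult]
    seed: int
    analytic: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def voxel_size(self) -> float:  # µm, alias
        return self.voxel_size_um

    def label_ids(self) -> list[int]:
        return sorted(self.truth)

    def copy(self) -> "Phantom":
        return Phantom(
            volume=self.volume.copy(),
            voxel_size_um=self.voxel_size_um,
            labels=self.labels.copy(),
            truth=dict(self.truth),
            seed=self.seed,
            analytic=dict(self.analytic),
            meta=copy.deepcopy(self.meta),
        )


@dataclass(frozen=True)
class ErosionSpec:
    """Programmed erosion effect: relative BV/TV drop via surface removal."""

    target_bvtv_drop: float = 0.11
    removal_prob: float = 0.2
    max_iters: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_bvtv_drop < 1.0:
            raise PhantomError(
                f"target_bvtv_drop must be in [0, 1), got {self.target_bvtv_drop}"
            )
        if not 0.0 < self.removal_prob <= 1.0:
            raise PhantomError(
                f"removal_prob must be in (0, 1], got {self.removal_prob}"
            )
        if self.max_iters < 1:
            raise PhantomError("max_iters must be >= 1")


# ---------------------------------------------------------------------------
# shape rasterizers
# ---------------------------------------------------------------------------

def _grids(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    nz, ny, nx = shape
    cz, cy, cx = (nz - 1) / 2.0, (ny - 1) / 2.0, (nx - 1) / 2.0
    z, y, x = np.ogrid[:nz, :ny, :nx]
    return z - cz, y - cy, x - cx


def _sphere_mask(shape, r_vox: float) -> np.ndarray:
    z, y, x = _grids(shape)
    return z * z + y * y + x * x <= r_vox * r_vox


def _pyramid_mask(shape, base_vox: float, height_vox: float) -> np.ndarray:
    # Square-base pyramid, apex up (+z), base centred.
    z, y, x = _grids(shape)
    zz = z + height_vox / 2.0  # 0 at base plane, height_vox at apex
    half = (base_vox / 2.0) * (1.0 - zz / height_vox)
    inside_z = (zz >= 0) & (zz <= height_vox)
    return inside_z & (np.abs(y) <= half) & (np.abs(x) <= half)


def _lunula_mask(shape, r_vox: float, offset_vox: float, cut_r_vox: float) -> np.ndarray:
    # Crescent: inside the primary sphere, outside a second sphere offset
    # along +x. The remainder is a single connected cap.
    z, y, x = _grids(shape)
    inner = z * z + y * y + x * x <= r_vox * r_vox
    cut = z * z + y * y + (x - offset_vox) ** 2 <= cut_r_vox * cut_r_vox
    return inner & ~cut


def _carve_cavity(mask: np.ndarray, cavity_fraction: float) -> np.ndarray:
    """Remove a sealed sphere of ``cavity_fraction`` of the bone volume.

    The cavity is centred at the interior point farthest from the surface and
    must keep a >=2-voxel bone wall, otherwise the porosity request fails.
    """
    if cavity_fraction <= 0:
        return mask
    if cavity_fraction >= 1:
        raise PhantomError("cavity_fraction must be < 1")
    n_bone = int(mask.sum())
    rc = (cavity_fraction * n_bone * 3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    dist = ndimage.distance_transform_edt(mask)
    center = np.unravel_index(int(np.argmax(dist)), mask.shape)
    if rc > dist[center] - 2.0:
        raise PhantomError(
            f"cavity_fraction {cavity_fraction} too large: cavity radius "
            f"{rc:.1f} vox does not fit inside the object "
            f"(max interior depth {dist[center]:.1f} vox)"
        )
    z, y, x = np.ogrid[: mask.shape[0], : mask.shape[1], : mask.shape[2]]
    cav = (
        (z - center[0]) ** 2 + (y - center[1]) ** 2 + (x - center[2]) ** 2
        <= rc * rc
    )
    out = mask & ~cav
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def make_ossicle(
    shape_kind: ShapeKind,
    size_params: dict[str, float],
    voxel_size_um: float = 2.0,
    seed: int = 0,
    cavity_fraction: float = 0.0,
    margin_vox: int = 4,
    grid_shape: tuple[int, int, int] | None = None,
) -> Phantom:
    """Rasterize one ossicle-like object with self-consistent truth.

    Parameters
    ----------
    shape_kind:
        ``sphere`` (``radius_um``), ``pyramid`` (``base_um``, ``height_um``)
        or ``lunula`` (``radius_um``, optional ``offset_um``, ``cut_radius_um``).
    size_params:
        Physical lengths in micrometres.
    cavity_fraction:
        Fraction of the bone volume carved out as a sealed internal cavity
        (0 = solid). Required if the phantom is to be eroded to a lower BV/TV.
    margin_vox:
        Background margin on every face; must be >= 2.
    """
    if margin_vox < 2:
        raise PhantomError("margin_vox must be >= 2")
    vs = float(voxel_size_um)
    if vs <= 0:
        raise PhantomError("voxel_size_um must be positive")

    if shape_kind == "sphere":
        r = size_params["radius_um"] / vs
        n = int(np.ceil(2 * r)) + 2 * margin_vox + 1
        shape = grid_shape or (n, n, n)
        mask = _sphere_mask(shape, r)
    elif shape_kind == "pyramid":
        b = size_params["base_um"] / vs
        h = size_params["height_um"] / vs
        nz = int(np.ceil(h)) + 2 * margin_vox + 1
        nxy = int(np.ceil(b)) + 2 * margin_vox + 1
        shape = grid_shape or (nz, nxy, nxy)
        mask = _pyramid_mask(shape, b, h)
    elif shape_kind == "lunula":
        r = size_params["radius_um"] / vs
        offset = size_params.get("offset_um", 0.7 * size_params["radius_um"]) / vs
        cut_r = size_params.get("cut_radius_um", size_params["radius_um"]) / vs
        n = int(np.ceil(2 * r)) + 2 * margin_vox + 1
        shape = grid_shape or (n, n, n)
        mask = _lunula_mask(shape, r, offset, cut_r)
    else:
        raise PhantomError(f"unknown shape_kind {shape_kind!r}")

    if not mask.any():
        raise PhantomError("size_params produced an empty object")
    if mm._touches_boundary(mask):
        raise PhantomError("object touches the grid boundary; increase margin")

    mask = _carve_cavity(mask, cavity_fraction)

    # single 6-connected component required
    lab, n_comp = ndimage.label(mask, structure=STRUCT_6)
    if n_comp != 1:
        raise PhantomError(
            f"{shape_kind} rasterized into {n_comp} 6-connected components"
        )

    labels = mask.astype(np.uint8)
    truth = {1: mm.compute_morphometry(labels, vs)[0]}

    analytic: dict[str, float] = {}
    if shape_kind == "sphere":
        r_mm = size_params["radius_um"] * mm.UM_TO_MM
        analytic = {
            "BV_mm3": 4.0 / 3.0 * np.pi * r_mm**3,
            "BS_mm2": 4.0 * np.pi * r_mm**2,
            "BS_BV_mm-1": 3.0 / r_mm,
        }

    return Phantom(
        volume=mask,
        voxel_size_um=vs,
        labels=labels,
        truth=truth,
        seed=seed,
        analytic=analytic,
        meta={
            "shape_kind": shape_kind,
            "size_params": dict(size_params),
            "cavity_fraction": cavity_fraction,
        },
    )


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of bone voxels with >=1 of 6 face-neighbours background."""
    eroded = ndimage.binary_erosion(mask, structure=STRUCT_6, border_value=1)
    return mask & ~eroded


def _is_simple_6(mask: np.ndarray, idx: tuple[int, int, int]) -> bool:
    """True if removing ``idx`` cannot split its label (local 6-connectivity).

    Conservative articulation test on the 3x3x3 neighbourhood: every bone
    face-neighbour of the voxel must lie in a single 6-connected component of
    the neighbourhood with the voxel itself removed.
    """
    z, y, x = idx
    nb = mask[z - 1 : z + 2, y - 1 : y + 2, x - 1 : x + 2].copy()
    nb[1, 1, 1] = False
    faces = [nb[0, 1, 1], nb[2, 1, 1], nb[1, 0, 1], nb[1, 2, 1], nb[1, 1, 0], nb[1, 1, 2]]
    n_faces = int(np.sum(faces))
    if n_faces == 0:
        return False  # isolated voxel: removal deletes the component
    if n_faces == 1:
        return True  # end voxel, cannot disconnect anything
    lab, _ = ndimage.label(nb, structure=STRUCT_6)
    face_labels = {
        lab[0, 1, 1], lab[2, 1, 1], lab[1, 0, 1],
        lab[1, 2, 1], lab[1, 1, 0], lab[1, 1, 2],
    }
    face_labels.discard(0)
    return len(face_labels) == 1


def erode_phantom(p: Phantom, spec: ErosionSpec) -> Phantom:
    """Stochastically remove exposed surface voxels until BV/TV has dropped.

    Removal candidates are drawn per iteration with probability
    ``spec.removal_prob`` from the current surface-voxel set; candidates whose
    removal would locally disconnect their label are skipped, so every label
    stays a single 6-connected body. Interior voxels are never touched.

    Stops once the label-1 relative BV/TV drop is within +-0.01 of
    ``spec.target_bvtv_drop``; raises :class:`ErosionTargetError` (naming the
    achieved drop) if ``max_iters`` is exhausted first.
    """
    if not p.truth:
        raise PhantomError("phantom has no labelled ossicle")
    if spec.target_bvtv_drop == 0.0:
        return p.copy()

    rng = np.random.default_rng(spec.seed)
    mask = p.volume.copy()

    filled0 = mm.fill_holes(mask)
    enclosed = filled0 & ~mask  # sealed cavities; must never be breached
    # hole filling treats background as 26-connected, so removals must keep a
    # full 26-neighbourhood clearance from any enclosed cavity; the extra
    # iterations keep the cavity wall thick enough to survive the imaging
    # chain (a 1-voxel wall perforates under partial volume + noise)
    protected = ndimage.binary_dilation(
        enclosed, structure=np.ones((3, 3, 3)), iterations=3
    )
    bv0 = int(mask.sum())
    tv0 = int(filled0.sum())
    cavity = tv0 - bv0  # constant under pure surface erosion
    rho0 = bv0 / tv0
    rho_target = rho0 * (1.0 - spec.target_bvtv_drop)

    bv = bv0
    tv = tv0

    def drop() -> float:
        return 1.0 - (bv / tv) / rho0

    achieved = drop()
    for _ in range(spec.max_iters):
        # exact number of removals still needed: rho = 1 - cavity/tv
        if cavity == 0:
            needed = tv  # unreachable; keep eroding until max_iters trips
        else:
            tv_target = cavity / (1.0 - rho_target)
            needed = int(round(tv - tv_target))
        if needed <= 0:
            break
        surf = np.argwhere(surface_voxels(mask))
        if surf.shape[0] == 0:
            break
        pick = rng.random(surf.shape[0]) < spec.removal_prob
        candidates = surf[pick]
        rng.shuffle(candidates, axis=0)
        removed = 0
        for idx in candidates:
            if removed >= needed:
                break
            t = (int(idx[0]), int(idx[1]), int(idx[2]))
            if protected[t]:
                continue  # removal would open a sealed cavity to the exterior
            if not _is_simple_6(mask, t):
                continue
            mask[t] = False
            removed += 1
        bv -= removed
        tv -= removed
        achieved = drop()

    if abs(achieved - spec.target_bvtv_drop) > 0.01:
        raise ErosionTargetError(spec.target_bvtv_drop, achieved, spec.max_iters)

    labels = mask.astype(p.labels.dtype)
    out = p.copy()
    out.volume = mask
    out.labels = labels
    out.truth = {1: mm.compute_morphometry(labels, p.voxel_size_um)[0]}
    out.analytic = {}
    out.meta = {**p.meta, "erosion": {
        "target_bvtv_drop": spec.target_bvtv_drop,
        "achieved_drop": achieved,
        "seed": spec.seed,
    }}
    return out


def make_cohort(
    n_per_group: int,
    effect: ErosionSpec,
    between_animal_cv: float = 0.05,
    seed: int = 0,
    shape_kind: ShapeKind = "pyramid",
    size_params: dict[str, float] | None = None,
    voxel_size_um: float = 2.0,
    cavity_fraction: float | None = None,
    ossicle_class: str | None = None,
    grid_shape: tuple[int, int, int] | None = None,
) -> list[tuple[Phantom, str]]:
    """Paired control/arthritis cohort of ossicle phantoms.

    Per animal, one base phantom is built with isotropic size jitter at the
    stated coefficient of variation; the control group keeps it untouched and
    the arthritis group is the same base passed through :func:`erode_phantom`
    (contralateral-joint pairing). Per-phantom erosion seeds derive from
    ``effect.seed`` by fixed offsets, so the cohort is fully reproducible.
    """
    if n_per_group < 2:
        raise PhantomError("n_per_group must be >= 2")
    if between_animal_cv < 0:
        raise PhantomError("between_animal_cv must be >= 0")
    if size_params is None:
        size_params = _default_size_params(shape_kind)
    if ossicle_class is None:
        ossicle_class = "posterior" if shape_kind == "lunula" else "anterior"
    if cavity_fraction is None:
        # the thin lunula crescent only accommodates a small sealed cavity
        cavity_fraction = 0.05 if shape_kind == "lunula" else 0.25

    rng = np.random.default_rng(seed)
    cohort: list[tuple[Phantom, str]] = []
    for i in range(n_per_group):
        scale = 1.0 + between_animal_cv * float(rng.standard_normal())
        scale = max(scale, 0.5)
        sized = {k: v * scale for k, v in size_params.items()}
        base = make_ossicle(
            shape_kind, sized, voxel_size_um,
            seed=seed + 1000 + i, cavity_fraction=cavity_fraction,
            grid_shape=grid_shape,
        )
        base.meta.update(sample_id=f"{ossicle_class}_ctrl_{i}",
                         ossicle_class=ossicle_class, animal=i)
        cohort.append((base, "control"))

        if effect.target_bvtv_drop == 0.0:
            arth = base.copy()
        else:
            per_spec = ErosionSpec(
                target_bvtv_drop=effect.target_bvtv_drop,
                removal_prob=effect.removal_prob,
                max_iters=effect.max_iters,
                seed=effect.seed + 7919 * (i + 1),
            )
            arth = erode_phantom(base, per_spec)
        arth.meta.update(sample_id=f"{ossicle_class}_arth_{i}",
                         ossicle_class=ossicle_class, animal=i)
        cohort.append((arth, "arthritis"))
    return cohort


def _default_size_params(shape_kind: ShapeKind) -> dict[str, float]:
    if shape_kind == "sphere":
        return {"radius_um": 80.0}
    if shape_kind == "pyramid":
        return {"base_um": 140.0, "height_um": 140.0}
    if shape_kind == "lunula":
        return {"radius_um": 80.0}
    raise PhantomError(f"unknown shape_kind {shape_kind!r}")
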