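"""Parallel-beam acquisition simulator.

Monochromatic Beer-Lambert projections of a two-material phantom, free-space
propagation contrast, Poisson counting noise, and offset-detector (extended
field of view) splitting of a 360-degree scan.

The propagation step is deliberately the exact algebraic inverse of the
single-distance retrieval filter in :mod:`ossimetry.recon`: both operate on
the same symmetric-padded Fourier grid, so ``phase_retrieve(propagate(x))``
reproduces ``-log(x)`` to machine precision in the noise-free case. This
makes retrieval correctness testable exactly, which a physical Fresnel
propagator would not allow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse

from .errors import GeometryError
from .morphometry import UM_TO_MM

# hc in keV * Angstrom
_HC_KEV_ANGSTROM = 12.398


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry.

    Defaults follow the synchrotron protocol this pipeline models:
    2 um detector pixels, 15 cm propagation distance, 25 keV mean energy,
    2400 projections over 360 degrees.
    """

    pixel_size_um: float = 2.0
    distance_cm: float = 15.0
    energy_keV: float = 25.0
    n_projections: int = 2400
    angular_range_deg: int = 360
    fov_offset_px: int = 0
    detector_width_px: int | None = None
    exposure_ms: float = 600.0  # provenance only; no computational effect

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.energy_keV <= 0:
            raise GeometryError("pixel_size_um and energy_keV must be positive")
        if self.distance_cm < 0:
            raise GeometryError("distance_cm must be >= 0")
        if self.n_projections < 1:
            raise GeometryError("n_projections must be >= 1")
        if self.angular_range_deg not in (180, 360):
            raise GeometryError("angular_range_deg must be 180 or 360")

    @property
    def wavelength_angstrom(self) -> float:
        """lambda = hc / E, in Angstrom (12.398 / E[keV])."""
        return _HC_KEV_ANGSTROM / self.energy_keV

    @property
    def wavelength_um(self) -> float:
        return self.wavelength_angstrom * 1.0e-4

    @property
    def distance_um(self) -> float:
        return self.distance_cm * 1.0e4

    def angles_deg(self) -> np.ndarray:
        """Projection angles: k * range / n for k = 0 .. n-1."""
        k = np.arange(self.n_projections)
        return k * (self.angular_range_deg / self.n_projections)


@dataclass
class ProjectionSet:
    """Angular intensity projections with flats, darks and geometry."""

    projections: np.ndarray          # (n_angles, n_rows, n_cols)
    angles_deg: np.ndarray           # strictly increasing
    flats: np.ndarray                # (n_flats, n_rows, n_cols)
    darks: np.ndarray                # (n_darks, n_rows, n_cols)
    geometry: Geometry
    delta_beta: float | None = None  # ratio applied at propagation/retrieval
    is_log: bool = False             # True once converted to line integrals
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.projections.ndim != 3:
            raise GeometryError("projections must be a 3D stack (angle, row, col)")
        if len(self.angles_deg) != self.projections.shape[0]:
            raise GeometryError("angle count must equal projection count")
        if np.any(np.diff(self.angles_deg) <= 0):
            raise GeometryError("angles must be strictly increasing")
        for name, stack in (("flats", self.flats), ("darks", self.darks)):
            stack = np.asarray(stack, dtype=np.float64)
            if stack.shape[1:] != self.projections.shape[1:]:
                raise GeometryError(f"{name} shape differs from projections")
            setattr(self, name, stack)
        # propagation fringes may undershoot zero; every other pre-log stage
        # must be physically nonnegative
        if (not self.is_log and not self.meta.get("propagated")
                and np.any(self.projections < 0)):
            raise GeometryError("intensities must be nonnegative")

    @property
    def n_angles(self) -> int:
        return self.projections.shape[0]

    @property
    def detector_shape(self) -> tuple[int, int]:
        return self.projections.shape[1:]

    def replace(self, **kw) -> "ProjectionSet":
        data = dict(
            projections=self.projections, angles_deg=self.angles_deg,
            flats=self.flats, darks=self.darks, geometry=self.geometry,
            delta_beta=self.delta_beta, is_log=self.is_log, meta=dict(self.meta),
        )
        data.update(kw)
        return ProjectionSet(**data)


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def _splat_matrix(ny: int, nx: int, ndet: int, theta_rad: float) -> sparse.csr_matrix:
    """Sparse operator mapping an image plane to one detector row.

    Each voxel deposits its value into the two detector bins bracketing
    s = (x - cx) cos(t) + (y - cy) sin(t), with linear weights (adjoint of
    linear-interpolation backprojection). Total deposited weight per voxel is
    exactly 1, so the sinogram mass is conserved at every angle.
    """
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    cdet = (ndet - 1) / 2.0
    y, x = np.mgrid[:ny, :nx]
    s = (x - cx) * np.cos(theta_rad) + (y - cy) * np.sin(theta_rad) + cdet
    i0 = np.floor(s).astype(np.int64)
    w1 = s - i0
    w0 = 1.0 - w1
    rows = np.repeat(np.arange(ny * nx), 2)
    cols = np.stack([i0.ravel(), i0.ravel() + 1], axis=1).ravel()
    data = np.stack([w0.ravel(), w1.ravel()], axis=1).ravel()
    ok = (cols >= 0) & (cols < ndet)
    return sparse.csr_matrix(
        (data[ok], (rows[ok], cols[ok])), shape=(ny * nx, ndet)
    )


def required_detector_width(p) -> int:
    """Detector columns needed to cover the bone at every rotation angle."""
    coords = np.argwhere(p.volume)
    if coords.size == 0:
        return 1
    ny, nx = p.volume.shape[1:]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.sqrt((coords[:, 1] - cy) ** 2 + (coords[:, 2] - cx) ** 2).max()
    return int(2 * np.ceil(r) + 3)


def project(
    p,
    mu_bone: float,
    mu_background: float,
    g: Geometry,
    flat_value: float = 1.0,
    n_flats: int = 1,
    n_darks: int = 1,
) -> ProjectionSet:
    """Noise-free Beer-Lambert projections of a phantom.

    ``mu_bone`` / ``mu_background`` are linear attenuation coefficients in
    mm^-1; line integrals through the voxel grid are converted to optical
    depth with the voxel size and exponentiated to transmitted intensity,
    scaled by a uniform flat field.
    """
    if abs(g.pixel_size_um - p.voxel_size_um) > 1e-9:
        raise GeometryError(
            f"phantom voxel size {p.voxel_size_um} um does not match "
            f"detector pixel size {g.pixel_size_um} um"
        )
    vol = np.where(p.volume, mu_bone, mu_background).astype(np.float64)
    nz, ny, nx = vol.shape
    ndet = nx if g.detector_width_px is None else g.detector_width_px
    if ndet < nx and g.fov_offset_px == 0:
        need = required_detector_width(p)
        if ndet < need:
            raise GeometryError(
                f"phantom needs {need} detector columns but only {ndet} are "
                "available; acquire in extended field of view mode "
                "(360 degrees with fov_offset_px > 0) or widen the detector"
            )
    angles = g.angles_deg()
    vol2 = vol.reshape(nz, ny * nx)
    depth_scale = p.voxel_size_um * UM_TO_MM  # voxel path length in mm
    projections = np.empty((len(angles), nz, ndet), dtype=np.float64)
    for i, a in enumerate(angles):
        A = _splat_matrix(ny, nx, ndet, np.deg2rad(a))
        line = vol2 @ A  # (nz, ndet) line integrals in mm^-1 * voxel
        projections[i] = flat_value * np.exp(-line * depth_scale)
    shape2 = (nz, ndet)
    flats = np.full((n_flats, *shape2), flat_value, dtype=np.float64)
    darks = np.zeros((n_darks, *shape2), dtype=np.float64)
    return ProjectionSet(
        projections=projections, angles_deg=angles, flats=flats, darks=darks,
        geometry=g, meta={"mu_bone": mu_bone, "mu_background": mu_background},
    )


# ---------------------------------------------------------------------------
# propagation contrast (exact inverse of the retrieval filter)
# ---------------------------------------------------------------------------

def paganin_coefficient_um2(g: Geometry, delta_beta: float) -> float:
    """alpha = lambda * D * (delta/beta) / (4 pi), in um^2."""
    return g.wavelength_um * g.distance_um * delta_beta / (4.0 * np.pi)


def _padded_filter(shape: tuple[int, int], pixel_um: float, alpha_um2: float) -> np.ndarray:
    """Retrieval low-pass H(u, v) on the symmetric-padded rFFT grid."""
    pr, pc = 2 * shape[0], 2 * shape[1]
    ky = 2.0 * np.pi * np.fft.fftfreq(pr, d=pixel_um)
    kx = 2.0 * np.pi * np.fft.rfftfreq(pc, d=pixel_um)
    return 1.0 / (1.0 + alpha_um2 * (ky[:, None] ** 2 + kx[None, :] ** 2))


def apply_fourier_filter(image: np.ndarray, filt: np.ndarray) -> np.ndarray:
    """Filter one image on a doubled symmetric-padded grid, then crop.

    Symmetric padding makes the padded signal even about the pad boundaries;
    a real even Fourier filter preserves that symmetry, so pad -> filter ->
    crop composes exactly with its reciprocal filter.
    """
    r, c = image.shape
    padded = np.pad(image, ((0, r), (0, c)), mode="symmetric")
    out = np.fft.irfft2(np.fft.rfft2(padded) * filt, s=padded.shape)
    return out[:r, :c]


def propagate(ps: ProjectionSet, delta_beta: float = 300.0) -> ProjectionSet:
    """Apply edge-enhancing propagation contrast to every projection.

    Multiplies each projection, in 2D Fourier space, by the reciprocal of the
    retrieval filter H so that :func:`ossimetry.recon.phase_retrieve` at the
    same delta/beta is an exact inverse on noise-free data.
    """
    if delta_beta < 0:
        raise GeometryError("delta_beta must be >= 0")
    alpha = paganin_coefficient_um2(ps.geometry, delta_beta)
    if alpha == 0.0:
        return ps.replace(delta_beta=delta_beta)
    inv_h = 1.0 / _padded_filter(
        ps.detector_shape, ps.geometry.pixel_size_um, alpha
    )
    out = np.empty_like(ps.projections)
    for i in range(ps.n_angles):
        out[i] = apply_fourier_filter(ps.projections[i], inv_h)
    return ps.replace(projections=out, delta_beta=delta_beta,
                      meta={**ps.meta, "propagated": True})


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def add_noise(
    ps: ProjectionSet,
    mean_counts: float,
    seed: int,
    read_noise_counts: float = 1.0,
) -> ProjectionSet:
    """Poisson counting noise on projections and flats; read noise on darks.

    Intensities are interpreted as fractions of ``mean_counts`` photons per
    pixel: each pixel becomes Poisson(I * N) / N, so the noise-free limit is
    recovered as N grows. Darks receive zero-mean Gaussian read noise of
    ``read_noise_counts`` (in counts). Propagation fringes may undershoot
    zero; they are clipped at zero before sampling, as a real detector would.
    """
    if mean_counts <= 0:
        raise GeometryError("mean_counts must be positive")
    rng = np.random.default_rng(seed)
    n = float(mean_counts)
    proj = rng.poisson(np.clip(ps.projections, 0.0, None) * n) / n
    flats = rng.poisson(np.clip(ps.flats, 0.0, None) * n) / n
    darks = ps.darks + rng.normal(0.0, read_noise_counts, ps.darks.shape) / n
    return ps.replace(projections=proj, flats=flats, darks=darks,
                      meta={**ps.meta, "mean_counts": mean_counts,
                            "noise_seed": seed})


# ---------------------------------------------------------------------------
# extended field of view
# ---------------------------------------------------------------------------

def split_extended_fov(ps: ProjectionSet, offset: int) -> ProjectionSet:
    """Emulate an offset-detector 360-degree acquisition.

    Keeps the right half of every detector row plus ``offset`` extra columns
    across the rotation axis, so the axis sits ``offset`` columns from the
    left edge of the reduced detector. Output width = input_width/2 + offset.
    """
    g = ps.geometry
    if g.angular_range_deg != 360:
        raise GeometryError("extended field of view requires a 360 degree scan")
    ncols = ps.projections.shape[2]
    if offset < 0 or offset >= ncols // 2:
        raise GeometryError(f"offset must be in [0, {ncols // 2}), got {offset}")
    start = ncols - (ncols // 2 + offset)
    sl = np.s_[..., start:]
    g_out = replace(g, fov_offset_px=offset,
                    detector_width_px=ncols - start)
    return ps.replace(
        projections=ps.projections[sl].copy(),
        flats=ps.flats[sl].copy(),
        darks=ps.darks[sl].copy(),
        geometry=g_out,
    )
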