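"""Preprocessing and tomographic reconstruction.

Flat/dark normalization, 360-degree extended-field-of-view stitching,
single-distance phase retrieval, and filtered back projection (Ram-Lak ramp,
optional cosine apodization, linear-interpolation backprojection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import FlatFieldError, GeometryError, StitchError
from .forward_model import (
    ProjectionSet,
    apply_fourier_filter,
    paganin_coefficient_um2,
    _padded_filter,
)
from .morphometry import UM_TO_MM


@dataclass
class ReconVolume:
    """Reconstructed floating-point volume with provenance."""

    volume: np.ndarray       # (nz, ny, nx), attenuation in mm^-1
    voxel_size_um: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=np.float64)
        if not np.isfinite(self.volume).all():
            raise GeometryError("reconstructed volume contains NaN/Inf")

    @property
    def voxel_size(self) -> float:
        return self.voxel_size_um

    def replace_volume(self, volume: np.ndarray, **prov) -> "ReconVolume":
        return ReconVolume(
            volume=volume, voxel_size_um=self.voxel_size_um,
            provenance={**self.provenance, **prov},
        )


# ---------------------------------------------------------------------------
# flat/dark correction
# ---------------------------------------------------------------------------

def flat_correct(ps: ProjectionSet, epsilon: float = 1.0e-6) -> ProjectionSet:
    """(raw - mean dark) / (mean flat - mean dark), floored at ``epsilon``."""
    if ps.flats.shape[0] < 1 or ps.darks.shape[0] < 1:
        raise FlatFieldError("need at least one flat and one dark image")
    mean_flat = ps.flats.mean(axis=0)
    mean_dark = ps.darks.mean(axis=0)
    denom = mean_flat - mean_dark
    bad = int(np.sum(denom <= 0))
    if bad:
        raise FlatFieldError(
            f"mean flat <= mean dark at {bad} pixel(s); cannot normalize"
        )
    corrected = np.clip((ps.projections - mean_dark) / denom, epsilon, None)
    return ps.replace(
        projections=corrected,
        flats=np.ones_like(ps.flats[:1]),
        darks=np.zeros_like(ps.darks[:1]),
        meta={**ps.meta, "flat_corrected": True, "epsilon": epsilon},
    )


# ---------------------------------------------------------------------------
# extended-FOV stitching
# ---------------------------------------------------------------------------

def _stitch_rows(a: np.ndarray, b: np.ndarray, overlap: int) -> np.ndarray:
    """Merge one offset-detector projection pair into a full-width row.

    ``a`` is the projection at angle theta, ``b`` its partner at theta+180;
    ``b`` is mirrored so both sample the same detector coordinate, and the
    ``overlap`` central columns are blended with linear weights.
    """
    bf = b[..., ::-1]
    w = a.shape[-1]
    if overlap == 0:
        return np.concatenate([bf, a], axis=-1)
    left = bf[..., : w - overlap]
    right = a[..., overlap:]
    wa = (np.arange(1, overlap + 1) / (overlap + 1.0))
    blend = (1.0 - wa) * bf[..., w - overlap:] + wa * a[..., :overlap]
    return np.concatenate([left, blend, right], axis=-1)


def stitch_360(ps: ProjectionSet, overlap: int | None = None,
               angle_tol_deg: float = 1.0e-3) -> ProjectionSet:
    """Stitch a 360-degree offset-detector scan into 180-degree full width.

    Pairs the projection at theta with the horizontally mirrored projection
    at theta+180 and blends the ``overlap`` columns spanning the rotation
    axis (default 2 x fov_offset). Output width =
    2 x (input width - overlap) + overlap and the angle count halves.
    """
    g = ps.geometry
    if g.angular_range_deg != 360:
        raise StitchError("stitching requires a 360 degree scan")
    n = ps.n_angles
    if n % 2:
        raise StitchError("stitching requires an even number of projections")
    if overlap is None:
        overlap = 2 * g.fov_offset_px
    ncols = ps.projections.shape[2]
    if not 0 <= overlap < ncols:
        raise StitchError(f"overlap {overlap} out of range for width {ncols}")
    half = n // 2
    d = ps.angles_deg[half:] - ps.angles_deg[:half]
    if np.any(np.abs(d - 180.0) > angle_tol_deg):
        worst = float(np.abs(d - 180.0).max())
        raise StitchError(
            f"no theta+180 partner within {angle_tol_deg} deg "
            f"(worst mismatch {worst:.2e} deg)"
        )
    proj = np.stack([
        _stitch_rows(ps.projections[i], ps.projections[i + half], overlap)
        for i in range(half)
    ])
    flats = np.stack([_stitch_rows(f, f, overlap) for f in ps.flats])
    darks = np.stack([_stitch_rows(d_, d_, overlap) for d_ in ps.darks])
    g_out = replace(g, angular_range_deg=180, n_projections=half,
                    fov_offset_px=0, detector_width_px=proj.shape[2])
    return ps.replace(
        projections=proj, angles_deg=ps.angles_deg[:half],
        flats=flats, darks=darks, geometry=g_out,
        meta={**ps.meta, "stitched_overlap": overlap},
    )


# ---------------------------------------------------------------------------
# phase retrieval
# ---------------------------------------------------------------------------

def phase_retrieve(ps: ProjectionSet, delta_beta: float = 300.0) -> ProjectionSet:
    """Single-distance retrieval: Fourier low-pass then -log.

    Per projection: mirror-pad to double size, multiply the 2D spectrum by
    H(u, v) = 1 / (1 + lambda D (delta/beta) / (4 pi) * (u^2 + v^2)), inverse
    transform, crop, and take -log to obtain a thickness-proportional map.
    With delta/beta = 0 this reduces exactly to -log(I).
    """
    if delta_beta < 0:
        raise GeometryError("delta_beta must be >= 0")
    if ps.is_log:
        raise GeometryError("projections are already line integrals")
    if np.min(ps.projections) <= 0:
        raise FlatFieldError(
            "nonpositive intensities; apply flat_correct (with a positive "
            "epsilon floor) before phase retrieval"
        )
    alpha = paganin_coefficient_um2(ps.geometry, delta_beta)
    if alpha == 0.0:
        out = -np.log(ps.projections)
    else:
        h = _padded_filter(ps.detector_shape, ps.geometry.pixel_size_um, alpha)
        out = np.empty_like(ps.projections)
        for i in range(ps.n_angles):
            filtered = apply_fourier_filter(ps.projections[i], h)
            if np.min(filtered) <= 0:
                raise FlatFieldError(
                    "nonpositive intensity after padded filtering; check "
                    "flat correction"
                )
            out[i] = -np.log(filtered)
    return ps.replace(projections=out, delta_beta=delta_beta, is_log=True,
                      meta={**ps.meta, "phase_retrieved": True})


# ---------------------------------------------------------------------------
# filtered back projection
# ---------------------------------------------------------------------------

def _ramp_filter(n_pad: int, apodization: str | None) -> np.ndarray:
    """Ram-Lak frequency response from the band-limited spatial kernel.

    Sampling the ideal |f| ramp directly under-weights the DC/low-frequency
    band of a finite sinogram and produces a few-percent cupping; the
    discrete kernel (1/4 at 0, -1/(pi n)^2 at odd lags) avoids that.
    """
    n = np.concatenate([np.arange(0, n_pad // 2 + 1), np.arange(-(n_pad - n_pad // 2 - 1), 0)])
    kernel = np.zeros(n_pad)
    kernel[0] = 0.25
    odd = n % 2 == 1
    kernel[odd] = -1.0 / (np.pi * n[odd]) ** 2
    filt = 2.0 * np.real(np.fft.fft(kernel))
    if apodization == "cosine":
        f = np.fft.fftfreq(n_pad)
        filt = filt * np.cos(np.pi * np.abs(f))
    elif apodization is not None:
        raise GeometryError(f"unknown apodization {apodization!r}")
    return filt


def fbp_reconstruct(ps: ProjectionSet,
                    apodization: str | None = None) -> ReconVolume:
    """Slice-by-slice filtered back projection of post-log projections.

    Ram-Lak ramp filtering in Fourier space (rows zero-padded to the next
    power of two past twice the width), linear-interpolation backprojection,
    and scaling such that a phantom of attenuation mu (mm^-1) reconstructs
    to mu.
    """
    if ps.n_angles < 2:
        raise GeometryError("filtered back projection needs >= 2 angles")
    if not ps.is_log:
        raise GeometryError(
            "projections must be line integrals; run phase_retrieve first"
        )
    n_angles, nz, ncols = ps.projections.shape
    n_pad = 2 ** int(np.ceil(np.log2(2 * ncols)))
    filt = _ramp_filter(n_pad, apodization)

    spectra = np.fft.fft(ps.projections, n=n_pad, axis=2)
    filtered = np.real(np.fft.ifft(spectra * filt, axis=2))[..., :ncols]

    ny = nx = ncols
    cy = cx = cdet = (ncols - 1) / 2.0
    y, x = np.mgrid[:ny, :nx]
    out = np.zeros((nz, ny, nx), dtype=np.float64)
    theta = np.deg2rad(ps.angles_deg)
    for i in range(n_angles):
        s = (x - cx) * np.cos(theta[i]) + (y - cy) * np.sin(theta[i]) + cdet
        i0 = np.floor(s).astype(np.int64)
        w1 = s - i0
        inside = (i0 >= 0) & (i0 < ncols - 1)
        i0c = np.clip(i0, 0, ncols - 2)
        rows = filtered[i]  # (nz, ncols)
        vals = rows[:, i0c] * (1.0 - w1) + rows[:, i0c + 1] * w1
        vals *= inside
        out += vals

    # filter peaks at 2 x Nyquist, so pi / 2N for N uniform angles over
    # either 180 or 360 degrees (over 360 every ray is covered twice)
    out *= np.pi / (2.0 * n_angles)
    # sinogram samples are optical depth per detector pixel -> mm^-1
    out /= ps.geometry.pixel_size_um * UM_TO_MM

    prov = {
        "geometry": ps.geometry,
        "delta_beta": ps.delta_beta,
        "filter": "ram-lak" if apodization is None else f"ram-lak+{apodization}",
        "n_angles": n_angles,
    }
    return ReconVolume(volume=out, voxel_size_um=ps.geometry.pixel_size_um,
                       provenance=prov)
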