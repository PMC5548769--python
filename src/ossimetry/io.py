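"""TIFF-stack and YAML-sidecar I/O shared by all pipeline stages."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .errors import ConfigError

logger = logging.getLogger("ossimetry")

_SUPPORTED_DTYPES = (np.uint8, np.uint16, np.float32)


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".yaml")


def write_tiff_stack(field: np.ndarray, path, sidecar: dict | None = None) -> None:
    """Write a 3D array as a multi-page TIFF plus an optional YAML sidecar.

    Round-trips 8/16-bit integer and 32-bit float stacks losslessly.
    """
    arr = np.asarray(field)
    if arr.ndim != 3:
        raise ConfigError(f"expected a 3D stack, got shape {arr.shape}")
    if arr.dtype not in [np.dtype(d) for d in _SUPPORTED_DTYPES]:
        raise ConfigError(
            f"unsupported dtype {arr.dtype}; use uint8, uint16 or float32"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, arr, photometric="minisblack")
    if sidecar is not None:
        with open(sidecar_path(path), "w") as fh:
            yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_tiff_stack(path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF and its YAML sidecar (if present).

    A missing sidecar yields ``{}`` with a logged warning; a truncated or
    otherwise corrupt file raises rather than returning a partial volume.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ConfigError(f"{path} is not a 2D/3D TIFF (shape {arr.shape})")
    sc = sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            meta = yaml.safe_load(fh) or {}
    else:
        logger.warning("no sidecar %s; proceeding with defaults", sc)
        meta = {}
    return arr, meta


def geometry_sidecar(geometry, delta_beta: float | None = None) -> dict:
    """Fixed-name geometry fields used by all persisted projection sets."""
    d = {
        "pixel_size_um": geometry.pixel_size_um,
        "distance_cm": geometry.distance_cm,
        "energy_keV": geometry.energy_keV,
        "n_projections": geometry.n_projections,
        "angular_range_deg": geometry.angular_range_deg,
        "fov_offset_px": geometry.fov_offset_px,
    }
    if delta_beta is not None:
        d["delta_beta"] = delta_beta
    return d


def truth_table(phantom) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for lab, res in sorted(phantom.truth.items()):
        rows.append({
            "label": lab,
            "BV_mm3": res.BV, "BS_mm2": res.BS, "TV_mm3": res.TV,
            "BV_TV": res.BV_TV, "BS_BV_mm-1": res.BS_BV,
            "BS_TV_mm-1": res.BS_TV,
        })
    return pd.DataFrame(rows)


def write_phantom(phantom, path) -> None:
    """Persist a phantom as 8-bit label TIFF + YAML sidecar + truth CSV."""
    path = Path(path)
    sidecar = {
        "voxel_size_um": phantom.voxel_size_um,
        "seed": phantom.seed,
        "meta": _plain(phantom.meta),
        "truth": {int(k): _plain(v.as_dict()) for k, v in phantom.truth.items()},
    }
    write_tiff_stack(phantom.labels.astype(np.uint8), path, sidecar)
    truth_table(phantom).to_csv(path.with_suffix(".truth.csv"), index=False)


def _plain(obj):
    """Recursively convert numpy scalars/containers to YAML-safe types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
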