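"""Segmentation: median filtering, Otsu thresholding, labelling, VOI matching.

Conventions: 6-connectivity for labelled objects, 26-connectivity for the
background complement (the standard topological pairing used by the
hole-filling step in morphometry). Volume-of-interest selection replaces
manual region drawing with overlap matching against a reference label field,
removing any operator dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .errors import AmbiguousOverlapError, SegmentationError
from .phantom import STRUCT_6
from .recon import ReconVolume


@dataclass
class LabeledVolume:
    """Integer label field (0 = background) with segmentation provenance."""

    labels: np.ndarray
    voxel_size_um: float
    threshold_used: float | None = None
    filter_radius: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise SegmentationError("labels must be nonnegative")

    @property
    def voxel_size(self) -> float:
        return self.voxel_size_um

    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i > 0]


def median_filter_3d(v: ReconVolume, radius: int = 1) -> ReconVolume:
    """Cubic median filter of half-width ``radius`` (edge-replicated borders)."""
    if radius < 0:
        raise SegmentationError("radius must be >= 0")
    if radius == 0:
        return v.replace_volume(v.volume.copy(), median_radius=0)
    size = 2 * radius + 1
    out = ndimage.median_filter(v.volume, size=size, mode="nearest")
    return v.replace_volume(out, median_radius=radius)


def otsu_threshold(v, n_bins: int = 256) -> float:
    """Histogram threshold maximizing the between-class variance.

    Evaluates sigma_b^2(t) = w0(t) w1(t) (mu0(t) - mu1(t))^2 at every
    interior bin edge of an ``n_bins`` histogram and returns the lowest
    maximizing edge. Raises on constant input.
    """
    data = v.volume if isinstance(v, ReconVolume) else np.asarray(v)
    data = data.ravel().astype(np.float64)
    lo, hi = float(data.min()), float(data.max())
    if lo == hi:
        raise SegmentationError("cannot threshold a constant volume")
    if n_bins < 2:
        raise SegmentationError("n_bins must be >= 2")
    counts, edges = np.histogram(data, bins=n_bins, range=(lo, hi))
    counts = counts.astype(np.float64)
    total = counts.sum()
    # class 0 = bins strictly below edge t
    centers = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)[:-1] / total
    w1 = 1.0 - w0
    csum = np.cumsum(counts * centers)
    mu0 = np.divide(csum[:-1], np.cumsum(counts)[:-1],
                    out=np.zeros(n_bins - 1), where=np.cumsum(counts)[:-1] > 0)
    mu1 = np.divide(csum[-1] - csum[:-1], total - np.cumsum(counts)[:-1],
                    out=np.zeros(n_bins - 1),
                    where=(total - np.cumsum(counts)[:-1]) > 0)
    sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(sigma_b))  # argmax returns the first (lowest) edge
    return float(edges[best + 1])


def label_components(binary: np.ndarray, min_voxels: int = 1,
                     voxel_size_um: float = 1.0,
                     threshold_used: float | None = None) -> LabeledVolume:
    """6-connected components, labelled 1..K in decreasing size order.

    Components smaller than ``min_voxels`` are dropped; an empty result is
    allowed.
    """
    binary = np.asarray(binary, dtype=bool)
    raw, n = ndimage.label(binary, structure=STRUCT_6)
    out = np.zeros_like(raw, dtype=np.int32)
    if n:
        sizes = np.bincount(raw.ravel())[1:]
        # decreasing size; ties broken by original (scan-order) label id
        order = np.lexsort((np.arange(1, n + 1), -sizes))
        new_id = 1
        lut = np.zeros(n + 1, dtype=np.int32)
        for old in order + 1:
            if sizes[old - 1] >= max(min_voxels, 1):
                lut[old] = new_id
                new_id += 1
        out = lut[raw]
    return LabeledVolume(labels=out, voxel_size_um=voxel_size_um,
                         threshold_used=threshold_used)


@dataclass
class VoiMatch:
    """Overlap-based matching of segmented labels to reference labels."""

    mapping: dict[int, int]              # segmented label -> reference label
    overlap_fraction: dict[int, float]   # of the reference object covered
    unmatched_segmented: list[int]
    unmatched_reference: list[int]


def select_voi(lv: LabeledVolume, reference_labels: np.ndarray) -> VoiMatch:
    """Match each segmented label to the reference object it overlaps most.

    An exact tie between two reference objects is an error (the match would
    be arbitrary); reference objects hit by no segmented label are reported
    as unmatched.
    """
    ref = np.asarray(reference_labels)
    seg = lv.labels
    if ref.shape != seg.shape:
        raise SegmentationError("segmented and reference fields differ in shape")
    n_seg = int(seg.max())
    n_ref = int(ref.max())
    pair = sparse.coo_matrix(
        (np.ones(seg.size, dtype=np.int64),
         (seg.ravel().astype(np.int64), ref.ravel().astype(np.int64))),
        shape=(n_seg + 1, n_ref + 1),
    ).tocsr().toarray()

    mapping: dict[int, int] = {}
    unmatched_seg: list[int] = []
    for s in range(1, n_seg + 1):
        overlaps = pair[s, 1:]
        if overlaps.sum() == 0:
            unmatched_seg.append(s)
            continue
        best = int(np.argmax(overlaps)) + 1
        ties = np.flatnonzero(overlaps == overlaps[best - 1]) + 1
        if len(ties) > 1:
            raise AmbiguousOverlapError(
                f"segmented label {s} overlaps reference labels "
                f"{ties.tolist()} equally ({int(overlaps[best - 1])} voxels)"
            )
        mapping[s] = best

    matched_ref = set(mapping.values())
    unmatched_ref = [r for r in range(1, n_ref + 1)
                     if (ref == r).any() and r not in matched_ref]
    ref_sizes = np.bincount(ref.ravel(), minlength=n_ref + 1)
    overlap_fraction = {
        s: float(pair[s, r] / ref_sizes[r]) for s, r in mapping.items()
    }
    return VoiMatch(mapping=mapping, overlap_fraction=overlap_fraction,
                    unmatched_segmented=unmatched_seg,
                    unmatched_reference=unmatched_ref)


def segment_volume(v: ReconVolume, median_radius: int = 1, n_bins: int = 256,
                   min_voxels: int = 27) -> LabeledVolume:
    """Full segmentation chain: median filter, Otsu, connected components."""
    filtered = median_filter_3d(v, median_radius)
    thr = otsu_threshold(filtered, n_bins)
    lv = label_components(filtered.volume > thr, min_voxels=min_voxels,
                          voxel_size_um=v.voxel_size_um, threshold_used=thr)
    lv.filter_radius = median_radius
    return lv
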