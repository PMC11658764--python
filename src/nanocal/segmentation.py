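"""Segmentation: nanocluster masks with a physical size gate, cell masks,
and the cluster-negative compartment by mask subtraction.

The nanocluster channel is automatically thresholded (Otsu by default),
connected components are labeled with 8-connectivity, and components whose
physical area falls below the configured minimum (default 0.15 um^2, i.e.
2 pixels at 0.284 um/px) are discarded.  Centroids are unweighted means of
pixel centers, reported in micrometres.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import filters, measure

from nanocal.core_io import BinaryMask, ClusterRecord, ClusterSet

__all__ = [
    "auto_threshold",
    "extract_nanoclusters",
    "segment_cell",
    "subtract_masks",
]

_THRESHOLD_METHODS = {
    "otsu": filters.threshold_otsu,
    "li": filters.threshold_li,
    "triangle": filters.threshold_triangle,
    "yen": filters.threshold_yen,
}


def auto_threshold(
    frame: np.ndarray, pixel_size_um: float, method: str = "otsu"
) -> BinaryMask:
    """Automatic global threshold; mask = pixels strictly above threshold.

    A constant frame has no foreground and yields an empty mask with a
    warning rather than an exception, so movie loops never abort on a
    blank frame.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be 2-D")
    try:
        thresh_fn = _THRESHOLD_METHODS[method]
    except KeyError:
        raise ValueError(
            f"unknown threshold method {method!r}; have {sorted(_THRESHOLD_METHODS)}"
        )
    if np.ptp(frame) == 0:
        warnings.warn("constant frame: empty threshold mask", stacklevel=2)
        return BinaryMask(np.zeros(frame.shape, dtype=bool), pixel_size_um)
    thresh = thresh_fn(frame)
    return BinaryMask(frame > thresh, pixel_size_um)


def extract_nanoclusters(
    mask: BinaryMask,
    min_area_um2: float = 0.15,
    channels: dict[str, np.ndarray] | None = None,
    frame_index: int = 0,
) -> ClusterSet:
    """Label connected components and apply the physical size gate.

    A component survives iff ``pixel_count * pixel_size_um**2 >=
    min_area_um2`` (at 0.284 um/px the 0.15 um^2 gate is a 2-pixel
    minimum).  8-connectivity is used.  Per cluster, the centroid is the
    unweighted mean of pixel centers in um (x = col, y = row) and the mean
    intensity of each supplied channel is recorded.
    """
    if min_area_um2 <= 0:
        raise ValueError("min_area_um2 must be > 0")
    channels = channels or {}
    for name, ch in channels.items():
        if np.asarray(ch).shape != mask.pixels.shape:
            raise ValueError(f"channel {name!r} shape differs from mask")
    px2 = mask.pixel_size_um**2
    labels = measure.label(mask.pixels, connectivity=2)
    records = []
    cluster_id = 0
    for region in measure.regionprops(labels):
        area_um2 = region.num_pixels * px2
        if area_um2 < min_area_um2:
            continue
        cluster_id += 1
        row_c, col_c = region.centroid  # unweighted pixel-index mean
        means = {}
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        for name, ch in channels.items():
            means[name] = float(np.asarray(ch, dtype=float)[rr, cc].mean())
        records.append(
            ClusterRecord(
                cluster_id=cluster_id,
                centroid_xy_um=(
                    float(col_c) * mask.pixel_size_um,
                    float(row_c) * mask.pixel_size_um,
                ),
                area_um2=float(area_um2),
                pixel_count=int(region.num_pixels),
                mean_intensity=means,
            )
        )
    return ClusterSet(
        frame_index=frame_index,
        records=tuple(records),
        pixel_size_um=mask.pixel_size_um,
    )


def cluster_mask(cluster_set_or_mask: BinaryMask, min_area_um2: float) -> BinaryMask:
    """Binary mask of the size-gated components of a thresholded mask."""
    mask = cluster_set_or_mask
    labels = measure.label(mask.pixels, connectivity=2)
    min_px = int(np.ceil(min_area_um2 / mask.pixel_size_um**2 - 1e-9))
    counts = np.bincount(labels.ravel())
    keep = np.zeros_like(counts, dtype=bool)
    keep[1:] = counts[1:] >= min_px
    return BinaryMask(keep[labels], mask.pixel_size_um)


def segment_cell(cyto_frame: np.ndarray, pixel_size_um: float,
                 method: str = "otsu") -> BinaryMask:
    """Cell mask from the cytosolic reporter channel.

    Auto-threshold, keep the largest connected component, fill holes.  An
    empty threshold result yields an empty mask with a warning.
    """
    rough = auto_threshold(cyto_frame, pixel_size_um, method=method)
    if rough.n_pixels == 0:
        warnings.warn("cell segmentation produced an empty mask", stacklevel=2)
        return rough
    labels, n = ndimage.label(rough.pixels)
    sizes = ndimage.sum_labels(rough.pixels, labels, index=np.arange(1, n + 1))
    largest = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask(ndimage.binary_fill_holes(largest), pixel_size_um)


def subtract_masks(cell_mask: BinaryMask, cluster_mask: BinaryMask) -> BinaryMask:
    """The cluster-negative compartment: cell AND NOT cluster.

    Together with (cluster AND cell) this partitions the cell mask exactly.
    """
    if cell_mask.pixels.shape != cluster_mask.pixels.shape:
        raise ValueError("cell and cluster masks must share shape")
    return BinaryMask(
        cell_mask.pixels & ~cluster_mask.pixels, cell_mask.pixel_size_um
    )
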