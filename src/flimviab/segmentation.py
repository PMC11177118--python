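"""Voronoi single-cell segmentation and per-cell aggregation.

Cell regions are a plain Voronoi partition of the fragment mask: each
in-mask pixel is assigned to its nearest nucleus centroid (Euclidean
distance between pixel centers, ties to the lowest centroid index).
Regions larger than 1000 pixels are excluded as containing noncellular
space; per retained cell, the mean NMS and the total summed PI intensity
are tabulated, and a cell is marked PI-dead when its summed PI counts
strictly exceed 1000.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .config import SegmentationConfig
from .metrics import MetricImage

__all__ = ["voronoi_labels", "filter_large_regions", "cell_stats",
           "CELL_TABLE_COLUMNS"]

CELL_TABLE_COLUMNS = ["cell_id", "row", "col", "n_pixels", "mean_nms",
                      "total_pi_counts", "pi_dead", "nms_class",
                      "fragment_id", "timepoint"]


def voronoi_labels(centroids: np.ndarray, mask: np.ndarray,
                   bound_by_mask: bool = True) -> np.ndarray:
    """Nearest-centroid label image (1-based; 0 = background).

    ``bound_by_mask=False`` labels the whole frame instead of only the
    fragment support.  Ties go to the lowest centroid index: candidate
    neighbors from a KD-tree are re-compared with exact integer squared
    distances so the tie-break is bit-reproducible.
    """
    from scipy.spatial import cKDTree

    centroids = np.asarray(centroids)
    mask = np.asarray(mask, dtype=bool)
    if centroids.ndim != 2 or centroids.shape[1] != 2 or len(centroids) == 0:
        raise ValueError("need at least one (row, col) centroid")
    cent = centroids.astype(np.int64)
    if bound_by_mask and not mask[cent[:, 0], cent[:, 1]].all():
        raise ValueError("all centroids must lie inside the mask")
    support = mask if bound_by_mask else np.ones_like(mask)
    coords = np.argwhere(support).astype(np.int64)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if len(coords) == 0:
        return labels
    k = min(6, len(cent))
    _, cand = cKDTree(cent).query(coords, k=k)
    cand = np.atleast_2d(cand.reshape(len(coords), k))
    cand.sort(axis=1)  # index order => first minimum is the lowest index
    diff = coords[:, None, :] - cent[cand]
    d2 = (diff * diff).sum(axis=2)
    nearest = np.take_along_axis(cand, np.argmin(d2, axis=1)[:, None],
                                 axis=1)[:, 0]
    labels[tuple(coords.T)] = nearest + 1
    return labels


def filter_large_regions(labels: np.ndarray, max_region_px: int = 1000
                         ) -> Tuple[np.ndarray, np.ndarray]:
    """Drop regions with strictly more than ``max_region_px`` pixels.

    Returns ``(filtered_labels, excluded_ids)``; excluded regions are set
    to background in the filtered image but reported for the record.
    """
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    excluded = ids[counts > max_region_px]
    if excluded.size:
        filtered = np.where(np.isin(labels, excluded), 0, labels)
    else:
        filtered = labels.copy()
    return filtered, excluded


def cell_stats(labels: np.ndarray, nms_image: MetricImage,
               pi_image: np.ndarray,
               config: Optional[SegmentationConfig] = None,
               centroids: Optional[np.ndarray] = None,
               fragment_id: str = "", timepoint: str = "") -> pd.DataFrame:
    """Per-cell statistics table.

    For each retained cell: mean NMS over in-mask, valid-metric pixels;
    total PI counts over ALL region pixels; ``pi_dead`` when the PI total
    strictly exceeds the configured threshold.  Cells with zero valid
    metric pixels are dropped with a warning.  ``nms_class`` is left empty
    here and filled by the classification stage.
    """
    config = config or SegmentationConfig()
    labels = np.asarray(labels)
    if labels.shape != nms_image.values.shape or labels.shape != np.shape(pi_image):
        raise ValueError("labels, NMS and PI images must be aligned")
    labels, excluded = filter_large_regions(labels, config.max_region_px)
    pi_image = np.asarray(pi_image)
    valid = nms_image.mask & np.isfinite(nms_image.values)

    rows = []
    dropped = 0
    for cid in np.unique(labels[labels > 0]):
        region = labels == cid
        metric_px = region & valid
        n_metric = int(metric_px.sum())
        total_pi = float(pi_image[region].sum())
        if n_metric == 0:
            dropped += 1
            continue
        if centroids is not None:
            r, c = centroids[cid - 1]
        else:
            rr, cc = np.nonzero(region)
            r, c = float(rr.mean()), float(cc.mean())
        rows.append({
            "cell_id": int(cid), "row": r, "col": c,
            "n_pixels": int(region.sum()),
            "mean_nms": float(nms_image.values[metric_px].mean()),
            "total_pi_counts": total_pi,
            "pi_dead": bool(total_pi > config.pi_dead_counts),
            "nms_class": "", "fragment_id": fragment_id,
            "timepoint": timepoint,
        })
    if dropped:
        warnings.warn(f"{dropped} cells had no valid metric pixels and were dropped")
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
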