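"""Regional aggregation of voxelwise maps.

Per-region medians are computed over the intersection of the grey-matter
mask and each cortical label, after discarding free-water-dominated voxels
(f_iso >= threshold, default 0.5, strict inequality for inclusion) to
minimise cerebrospinal-fluid partial-volume contamination.  The median is
used throughout for robustness to residual partial-volume outliers.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["build_region_mask", "regional_medians", "CORTICAL_LABEL_MAX"]

logger = logging.getLogger(__name__)

# Labels above this are treated as sub-cortical / cerebellar and rejected:
# the regional analysis covers an 82-region cortical scheme only.
CORTICAL_LABEL_MAX = 82


def _check_grids(*volumes: np.ndarray) -> None:
    shapes = {np.shape(v) for v in volumes}
    if len(shapes) > 1:
        raise ValueError(f"volumes are not on a shared grid: shapes {sorted(shapes)}")


def build_region_mask(
    gm_mask: np.ndarray,
    region_labels: np.ndarray,
    fiso_map: np.ndarray,
    fiso_threshold: float = 0.5,
) -> dict[int, np.ndarray]:
    """Per-region boolean voxel masks under the free-water exclusion.

    A voxel belongs to region ``r`` iff it is grey matter, carries label
    ``r`` and has f_iso strictly below the threshold (a voxel at exactly the
    threshold is excluded).  Regions whose voxels are all excluded map to an
    all-False mask.  Labels outside the cortical range are dropped with a
    warning.
    """
    gm_mask = np.asarray(gm_mask).astype(bool)
    region_labels = np.asarray(region_labels)
    fiso_map = np.asarray(fiso_map, dtype=float)
    _check_grids(gm_mask, region_labels, fiso_map)
    keep = gm_mask & (fiso_map < fiso_threshold)
    out: dict[int, np.ndarray] = {}
    for r in np.unique(region_labels):
        r = int(r)
        if r == 0:
            continue
        if r > CORTICAL_LABEL_MAX:
            logger.warning("label %d is outside the cortical scheme; ignored", r)
            continue
        out[r] = keep & (region_labels == r)
    return out


def regional_medians(
    metric_maps: dict[str, np.ndarray],
    region_masks: dict[int, np.ndarray],
    acquisition_id: str = "",
) -> pd.DataFrame:
    """Median of each metric over each region's voxel set.

    Returns one row per (acquisition, region, metric) with the voxel count;
    a pooled whole-cortex row (region 0 = union of all regional voxel sets)
    is emitted as well.  Empty regions are omitted and logged.  NaN voxels
    (e.g., failed fits) are ignored within a region.
    """
    shapes = [np.shape(m) for m in metric_maps.values()]
    _check_grids(*shapes_to_arrays(metric_maps), *region_masks.values())
    rows = []
    union = None
    for r, mask in sorted(region_masks.items()):
        union = mask.copy() if union is None else (union | mask)
    entries = list(sorted(region_masks.items()))
    if union is not None:
        entries.append((0, union))
    for r, mask in entries:
        n_vox = int(mask.sum())
        if n_vox == 0:
            logger.info("region %d has no voxels after exclusion; omitted", r)
            continue
        for metric, vol in metric_maps.items():
            vals = np.asarray(vol, dtype=float)[mask]
            vals = vals[~np.isnan(vals)]
            if vals.size == 0:
                logger.info("region %d metric %s has no finite voxels; omitted", r, metric)
                continue
            rows.append({
                "acq_id": acquisition_id,
                "region": r,
                "metric": metric,
                "median": float(np.median(vals)),
                "n_voxels": int(vals.size),
            })
    return pd.DataFrame(rows, columns=["acq_id", "region", "metric", "median", "n_voxels"])


def shapes_to_arrays(metric_maps: dict[str, np.ndarray]) -> list[np.ndarray]:
    return [np.asarray(v) for v in metric_maps.values()]
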