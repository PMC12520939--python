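"""Single-cell segmentation and 5-feature phenotype extraction.

Cells are segmented on the summed chemical maps (total unmixed signal, the
highest-SNR image available), thresholded by Otsu or a fixed value, holes
filled, 8-connected components labeled, small components dropped, and labels
renumbered in raster order of the component centroids.  Each cell's
phenotype is the fixed 5-feature vector the classifier consumes: cellular
area plus integrated (summed-over-mask) protein, nucleic-acid,
saturated-lipid and unsaturated-lipid coefficients.  Integrated totals are
the default so that composition and cell size jointly inform the phenotype;
per-pixel means are available via ``aggregate="mean"``.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .spectral_library import COMPONENTS
from .unmixing import ChemicalMaps

__all__ = [
    "FEATURE_COLUMNS",
    "FEATURE_TABLE_COLUMNS",
    "segment_cells",
    "extract_features",
    "match_cells_to_truth",
]

#: The five phenotyping features, in the fixed order used downstream.
FEATURE_COLUMNS = ["area", "protein", "nucleic_acid", "saturated_lipid", "unsaturated_lipid"]
FEATURE_TABLE_COLUMNS = ["cell_id", "source_image", "class"] + FEATURE_COLUMNS


def segment_cells(
    maps: ChemicalMaps,
    min_area: int = 30,
    threshold: Literal["otsu"] | float = "otsu",
) -> np.ndarray:
    """Label mask (H×W int32; 0 = background, 1..K = cells).

    A constant total-signal image under Otsu yields an empty mask (K = 0)
    rather than an error.
    """
    total = maps.total_signal
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError("threshold must be 'otsu' or a numeric value")
        if np.ptp(total) == 0:
            return np.zeros(total.shape, dtype=np.int32)
        thr = threshold_otsu(total)
    else:
        thr = float(threshold)
    fg = ndimage.binary_fill_holes(total > thr)
    labels = measure.label(fg, connectivity=2)
    out = np.zeros_like(labels, dtype=np.int32)
    props = [p for p in measure.regionprops(labels) if p.area >= min_area]
    props.sort(key=lambda p: (p.centroid[0], p.centroid[1]))
    for new_id, p in enumerate(props, start=1):
        out[labels == p.label] = new_id
    return out


def extract_features(
    mask: np.ndarray,
    maps: ChemicalMaps,
    pixel_size: float | None = None,
    aggregate: Literal["sum", "mean"] = "sum",
    class_labels: dict[int, str] | None = None,
    source_image: str = "",
) -> pd.DataFrame:
    """Per-cell feature table from a label mask and chemical maps.

    ``area`` is the pixel count (×``pixel_size``² in µm² when given); each
    content feature is the sum (default) or mean of that component's
    coefficients over the cell mask.  One row per label, ordered by label id.
    """
    mask = np.asarray(mask)
    if mask.shape != maps.residual.shape:
        raise ValueError("mask and maps dimensions differ")
    ids = np.unique(mask)
    ids = ids[ids > 0]
    rows = []
    for cid in ids:
        sel = mask == cid
        n_px = int(sel.sum())
        area = n_px * (pixel_size**2) if pixel_size else n_px
        contents = {
            comp: float(maps.component_map(comp)[sel].sum()) for comp in COMPONENTS
        }
        if aggregate == "mean":
            contents = {k: v / n_px for k, v in contents.items()}
        elif aggregate != "sum":
            raise ValueError("aggregate must be 'sum' or 'mean'")
        rows.append(
            {
                "cell_id": int(cid),
                "source_image": source_image,
                "class": (class_labels or {}).get(int(cid), ""),
                "area": area,
                **{k: contents[k] for k in FEATURE_COLUMNS[1:]},
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def match_cells_to_truth(mask: np.ndarray, truth: np.ndarray) -> pd.DataFrame:
    """Greedy max-IoU matching of segmented cells to ground-truth cells.

    Returns a frame with columns ``cell_id, truth_id, iou``; segmented cells
    with no overlapping truth cell get ``truth_id`` 0 and ``iou`` 0.  Each
    truth cell is matched at most once (greedy, best IoU first).
    """
    mask = np.asarray(mask)
    truth = np.asarray(truth)
    if mask.shape != truth.shape:
        raise ValueError("mask and truth dimensions differ")
    m_ids = np.unique(mask)
    m_ids = m_ids[m_ids > 0]
    areas_m = {int(i): int((mask == i).sum()) for i in m_ids}
    areas_t = {int(i): int(n) for i, n in zip(*np.unique(truth[truth > 0], return_counts=True))}
    # joint overlap counts
    both = (mask > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([mask[both], truth[both]]).astype(np.int64), axis=1, return_counts=True
    )
    candidates = []
    for (mi, ti), inter in zip(pairs.T, counts):
        union = areas_m[int(mi)] + areas_t[int(ti)] - int(inter)
        candidates.append((int(inter) / union, int(mi), int(ti)))
    candidates.sort(reverse=True)
    used_m, used_t = set(), set()
    matches = {}
    for iou, mi, ti in candidates:
        if mi in used_m or ti in used_t:
            continue
        matches[mi] = (ti, iou)
        used_m.add(mi)
        used_t.add(ti)
    rows = [
        {"cell_id": int(mi), "truth_id": matches.get(int(mi), (0, 0.0))[0], "iou": matches.get(int(mi), (0, 0.0))[1]}
        for mi in m_ids
    ]
    return pd.DataFrame(rows, columns=["cell_id", "truth_id", "iou"])
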