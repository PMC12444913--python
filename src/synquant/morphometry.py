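"""Per-object geometry: areas, centroids, fitted-ellipse aspect ratios,
orientation classification, nearest-neighbour distances and areal density."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .core import LabelMap, ParameterError

__all__ = [
    "FieldSummary",
    "region_properties",
    "classify_view",
    "nearest_neighbor_distances",
    "mean_nnd",
    "field_density",
    "AR_SIDE_VIEW_THRESHOLD",
]

#: Empirical aspect-ratio boundary separating side-view (>=) from en-face (<)
#: synapse orientations in thin sections.
AR_SIDE_VIEW_THRESHOLD = 2.7


@dataclass
class FieldSummary:
    """Per-field synapse abundance summary."""

    field_id: str
    analyzable_area_um2: float
    synapse_count: int
    density_per_um2: float
    mean_nnd_um: float | None = None


def region_properties(labels: LabelMap) -> pd.DataFrame:
    """Geometry table for every label.

    Columns: ``label``, ``area_um2``, ``centroid_row``/``centroid_col`` (px),
    ``centroid_x_um``/``centroid_y_um`` (x = column direction), ``aspect_ratio``
    (major/minor axis of the moment-matched ellipse, axis length =
    4*sqrt(eigenvalue) of the second central moments), ``touches_border``.
    """
    px_um = labels.pixel_size_nm / 1000.0
    rows = []
    for rp in regionprops(labels.labels):
        minor = rp.axis_minor_length
        major = rp.axis_major_length
        if minor > 0:
            ar = major / minor
        else:
            ar = 1.0 if major == 0 else np.inf
        r0, c0 = rp.centroid
        rows.append(
            {
                "label": int(rp.label),
                "area_um2": float(rp.area) * px_um**2,
                "centroid_row": float(r0),
                "centroid_col": float(c0),
                "centroid_x_um": float(c0) * px_um,
                "centroid_y_um": float(r0) * px_um,
                "aspect_ratio": float(max(ar, 1.0)),
                "touches_border": int(rp.label) in labels.border_labels,
            }
        )
    cols = [
        "label",
        "area_um2",
        "centroid_row",
        "centroid_col",
        "centroid_x_um",
        "centroid_y_um",
        "aspect_ratio",
        "touches_border",
    ]
    return pd.DataFrame(rows, columns=cols)


def classify_view(aspect_ratio: float, threshold: float = AR_SIDE_VIEW_THRESHOLD) -> str:
    """``"side_view"`` iff AR >= threshold, else ``"en_face"``."""
    if aspect_ratio < 1:
        raise ParameterError("aspect ratio must be >= 1")
    return "side_view" if aspect_ratio >= threshold else "en_face"


def nearest_neighbor_distances(points_um: np.ndarray) -> np.ndarray:
    """Per-point Euclidean distance to its closest other point (µm).

    Returns an empty array with a warning for fewer than two points.
    """
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or (len(pts) and pts.shape[1] != 2):
        raise ParameterError("points must be an (n, 2) array")
    if len(pts) < 2:
        warnings.warn("fewer than 2 points; no nearest-neighbour distances")
        return np.empty(0)
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def mean_nnd(
    points_um: np.ndarray,
    field_size_um: tuple[float, float] | None = None,
    border_correction: bool = True,
) -> float:
    """Mean nearest-neighbour distance, optionally border corrected.

    With correction, points lying closer to the field border than to their
    nearest neighbour are dropped from the mean (their true nearest neighbour
    may be outside the field).  ``field_size_um`` is (width, height) with
    points as (x, y); required when correcting.
    """
    pts = np.asarray(points_um, dtype=float)
    nnd = nearest_neighbor_distances(pts)
    if nnd.size == 0:
        return float("nan")
    if border_correction:
        if field_size_um is None:
            raise ParameterError("field_size_um is required for border correction")
        w, h = field_size_um
        d_border = np.minimum.reduce(
            [pts[:, 0], pts[:, 1], w - pts[:, 0], h - pts[:, 1]]
        )
        keep = d_border >= nnd
        if keep.any():
            nnd = nnd[keep]
    return float(nnd.mean())


def field_density(
    labels: LabelMap,
    analyzable_mask: np.ndarray | None = None,
    field_id: str = "",
    points_um: np.ndarray | None = None,
) -> FieldSummary:
    """Synapse count per analyzable area (µm^-2), plus the mean NND if
    centroids are supplied.

    The analyzable area defaults to the full imaged area; pass a mask to
    exclude cell bodies, fractures or vessels from the denominator.
    """
    total_px = labels.labels.size if analyzable_mask is None else int(
        np.count_nonzero(analyzable_mask)
    )
    area = total_px * labels.pixel_area_um2
    if area <= 0:
        raise ParameterError("zero analyzable area")
    count = labels.n_labels
    nnd = None
    if points_um is not None and len(points_um) >= 2:
        px_um = labels.pixel_size_nm / 1000.0
        h, w = labels.labels.shape
        nnd = mean_nnd(points_um, field_size_um=(w * px_um, h * px_um))
    return FieldSummary(
        field_id=field_id,
        analyzable_area_um2=float(area),
        synapse_count=int(count),
        density_per_um2=count / area,
        mean_nnd_um=nnd,
    )
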