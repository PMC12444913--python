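"""Object masks: synaptic label maps, PV somata, neuropil background, dendrites.

Synaptic puncta are segmented by combining a histogram threshold (Otsu) on the
Gaussian-blurred channel with prominence-based maxima splitting, so that
nearby synapses merged by the threshold are separated -- each final label
contains exactly one accepted maximum.  Somata use the triangle threshold
with an area filter plus an optional exclusion list standing in for manual
revision.  Dendrites are polyline annotations (manual outlines replayed from
CSV, or generator ground truth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    DegenerateInputError,
    ImagePlane,
    LabelMap,
    ParameterError,
    as_bool_mask,
    border_touching_labels,
    relabel_sequential_2d,
)
from .imageops import (
    find_maxima,
    gaussian_blur,
    rolling_ball_background,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
)

__all__ = [
    "DendriteAnnotation",
    "psd95_synapse_labels",
    "soma_labels",
    "neuropil_background_mask",
    "summed_channel_labels",
    "filter_by_psd95_integral",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class DendriteAnnotation:
    """One outlined dendrite: polyline in µm plus its pixel mask.

    ``is_myelinated_axon`` marks thick myelinated PV+ axons (identified by
    myelin counterstain in the original workflow) which are excluded from all
    dendrite metrics.
    """

    dendrite_id: str
    polyline_um: np.ndarray  # (n, 2) of (x, y) in µm
    mask: np.ndarray
    pv_positive: bool = True
    is_myelinated_axon: bool = False
    subject_id: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        pl = np.asarray(self.polyline_um, dtype=float)
        if pl.ndim != 2 or pl.shape[1] != 2 or len(pl) == 0:
            raise ParameterError("polyline_um must be a non-empty (n, 2) array")
        self.polyline_um = pl
        self.mask = as_bool_mask(self.mask)

    @property
    def length_um(self) -> float:
        """Polyline arc length in µm."""
        d = np.diff(self.polyline_um, axis=0)
        return float(np.sqrt((d**2).sum(axis=1)).sum())


def psd95_synapse_labels(
    psd95: ImagePlane,
    maxima_prominence: float,
    blur_radius_px: float = 2.0,
) -> LabelMap:
    """Segment synaptic puncta from a PSD-95 channel.

    A Gaussian blur (sigma ``blur_radius_px``) is followed by Otsu
    thresholding; above-threshold support is then flooded from
    prominence-accepted maxima so that merged neighbouring puncta are split
    (one maximum per label).  Constant images yield an empty map with a
    warning.
    """
    blurred = gaussian_blur(psd95, blur_radius_px)
    try:
        thr = threshold_otsu(blurred)
    except DegenerateInputError:
        warnings.warn("degenerate (constant) image; returning empty label map")
        return LabelMap(
            np.zeros(psd95.shape, dtype=np.int32), psd95.pixel_size_nm, "synapse"
        )
    res = find_maxima(blurred, maxima_prominence, mode="segmented", floor=thr)
    labels = relabel_sequential_2d(res.segments)
    return LabelMap(
        labels,
        psd95.pixel_size_nm,
        "synapse",
        border_labels=border_touching_labels(labels),
    )


def soma_labels(
    pv: ImagePlane,
    min_area_um2: float = 50.0,
    exclusions: list[int] | None = None,
    blur_radius_px: float = 2.0,
    refine_erosion_px: int = 2,
) -> LabelMap:
    """Segment PV+ cell bodies: blur, triangle threshold, area filter.

    The raw threshold mask is refined deterministically (hole filling plus an
    erosion of ``refine_erosion_px``, trimming the blurred soma rim) -- the
    scriptable replacement for manual mask revision, as is the ``exclusions``
    list of label ids (as produced by this function with no exclusions) to
    drop.
    """
    blurred = gaussian_blur(pv, blur_radius_px)
    try:
        thr = threshold_triangle(blurred)
    except DegenerateInputError:
        return LabelMap(np.zeros(pv.shape, dtype=np.int32), pv.pixel_size_nm, "soma")
    mask = blurred.pixels > thr
    mask = ndimage.binary_fill_holes(mask)
    if refine_erosion_px > 0:
        mask = ndimage.binary_erosion(
            mask, structure=_STRUCT8, iterations=int(refine_erosion_px)
        )
    lab, _ = ndimage.label(mask, structure=_STRUCT8)
    lab = relabel_sequential_2d(lab)
    n = int(lab.max())
    if n:
        areas = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        min_px = min_area_um2 / pv.pixel_area_um2
        drop = set(np.flatnonzero(areas < min_px) + 1)
        if exclusions:
            drop |= {int(e) for e in exclusions}
        if drop:
            lab[np.isin(lab, list(drop))] = 0
            lab = relabel_sequential_2d(lab)
    return LabelMap(
        lab, pv.pixel_size_nm, "soma", border_labels=border_touching_labels(lab)
    )


def neuropil_background_mask(pv: ImagePlane) -> np.ndarray:
    """Mask of neuropil lacking PV fluorescence: pixels at or below the mean threshold.

    The complement (strictly above the mean threshold of the unfiltered image)
    is the PV-positive mask, so the two are disjoint by construction.
    """
    thr = threshold_mean(pv)
    return pv.pixels <= thr


def summed_channel_labels(
    psd95: ImagePlane,
    ampar: ImagePlane,
    glun1: ImagePlane,
    maxima_prominence: float,
    blur_radius_px: float = 2.0,
) -> LabelMap:
    """Synapse labels from the pixelwise sum of PSD-95, AMPAR and GluN1.

    Synapses on PV+ dendrites carry weak PSD-95; summing the three channels
    makes their detection reliable.  The segmentation procedure is identical
    to :func:`psd95_synapse_labels` applied to the summed plane.
    """
    if not (psd95.shape == ampar.shape == glun1.shape):
        raise ParameterError("channel shapes differ; register the field first")
    summed = psd95.with_pixels(psd95.pixels + ampar.pixels + glun1.pixels)
    return psd95_synapse_labels(summed, maxima_prominence, blur_radius_px)


def filter_by_psd95_integral(
    labels: LabelMap,
    psd95: ImagePlane,
    min_integral: float = 10.0,
    background: ImagePlane | None = None,
    background_radius_px: float = 7.0,
) -> LabelMap:
    """Retain labels whose background-subtracted PSD-95 integral exceeds ``min_integral``.

    The background defaults to the rolling-ball estimate of the PSD-95
    channel.  Surviving labels are relabelled contiguously.
    """
    if labels.labels.shape != psd95.shape:
        raise ParameterError("label map and PSD-95 plane shapes differ")
    if background is None:
        background = rolling_ball_background(psd95, background_radius_px)
    diff = np.clip(psd95.pixels - background.pixels, 0, None)
    n = labels.n_labels
    lab = labels.labels.copy()
    if n:
        integrals = ndimage.sum_labels(diff, lab, index=np.arange(1, n + 1))
        drop = np.flatnonzero(integrals <= min_integral) + 1
        if len(drop):
            lab[np.isin(lab, drop)] = 0
        lab = relabel_sequential_2d(lab)
    return LabelMap(
        lab,
        labels.pixel_size_nm,
        labels.kind,
        border_labels=border_touching_labels(lab),
    )
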