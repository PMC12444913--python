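"""Core raster containers shared by every pipeline stage.

The currency of the pipeline is the :class:`ImagePlane` -- one 2-D fluorescence
channel with a physical pixel size -- plus boolean masks and integer label maps
derived from it.  Tabular results (synapse records, subject summaries, ground
truth) are plain :class:`pandas.DataFrame` objects with documented columns; see
:mod:`synquant.morphometry` and :mod:`synquant.quantify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "ImagePlane",
    "LabelMap",
    "MaximaResult",
    "ParameterError",
    "DegenerateInputError",
]


class ParameterError(ValueError):
    """An operator was called with an out-of-range parameter."""


class DegenerateInputError(ValueError):
    """The input is degenerate for the requested operation (e.g. constant image)."""


@dataclass
class ImagePlane:
    """One 2-D intensity channel with physical scale and provenance.

    Parameters
    ----------
    pixels
        Rectangular, non-empty array of finite, non-negative intensities
        (arbitrary units).  Stored as float64.
    pixel_size_nm
        Physical edge length of one pixel, in nanometres (> 0).
    channel
        Channel label, e.g. ``"PSD95"`` or ``"Munc13-1"``.
    field_id, subject_id, condition
        Provenance strings; free-form.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    channel: str = ""
    field_id: str = ""
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.size == 0:
            raise ParameterError("pixels must be a non-empty 2-D array")
        if not np.all(np.isfinite(px)):
            raise ParameterError("pixel intensities must be finite")
        if px.min() < 0:
            raise ParameterError("pixel intensities must be >= 0")
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be > 0")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm²."""
        return (self.pixel_size_nm / 1000.0) ** 2

    def with_pixels(self, pixels: np.ndarray) -> "ImagePlane":
        """Copy of this plane with new pixel data, same scale and provenance."""
        return replace(self, pixels=pixels)


@dataclass
class LabelMap:
    """Integer-labelled segmentation of one field.

    ``labels`` is a non-negative integer grid where 0 is background and the
    positive labels are contiguous ``1..K``, each one 8-connected component.
    ``border_labels`` flags objects touching the field border (truncated
    objects, excluded from area/NND statistics downstream).
    """

    labels: np.ndarray
    pixel_size_nm: float
    kind: Literal["synapse", "soma", "dendrite"] = "synapse"
    border_labels: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or lab.size == 0:
            raise ParameterError("labels must be a non-empty 2-D array")
        if not np.issubdtype(lab.dtype, np.integer):
            lab = lab.astype(np.int32)
        if lab.min() < 0:
            raise ParameterError("labels must be non-negative")
        self.labels = lab
        if not self.pixel_size_nm > 0:
            raise ParameterError("pixel_size_nm must be > 0")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def pixel_area_um2(self) -> float:
        return (self.pixel_size_nm / 1000.0) ** 2


@dataclass
class MaximaResult:
    """Output of :func:`synquant.imageops.find_maxima`.

    ``points`` are (row, col) coordinates of accepted maxima; ``segments`` is
    the optional label grid from segmented-particles mode, where segment ``i+1``
    contains ``points[i]``.  ``prominence`` echoes the noise tolerance used.
    """

    points: np.ndarray  # (n, 2) int array of (row, col)
    prominence: float
    segments: np.ndarray | None = None

    @property
    def n_maxima(self) -> int:
        return len(self.points)


def as_bool_mask(mask: np.ndarray, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Validate and return ``mask`` as a boolean array, optionally shape-checked."""
    m = np.asarray(mask)
    if m.dtype != bool:
        m = m.astype(bool)
    if shape is not None and m.shape != shape:
        raise ParameterError(f"mask shape {m.shape} does not match plane shape {shape}")
    return m


def relabel_sequential_2d(labels: np.ndarray) -> np.ndarray:
    """Relabel a non-negative integer grid so positive labels are 1..K, row-major order."""
    labels = np.asarray(labels)
    out = np.zeros_like(labels, dtype=np.int32)
    # order of first appearance (row-major) keeps results deterministic
    flat = labels.ravel()
    pos = flat > 0
    uniq, first = np.unique(flat[pos], return_index=True)
    order = np.argsort(first)
    mapping = np.zeros(int(flat.max()) + 1 if flat.size and flat.max() > 0 else 1, dtype=np.int32)
    for newid, old in enumerate(uniq[order], start=1):
        mapping[old] = newid
    out.ravel()[pos] = mapping[flat[pos]]
    return out


def border_touching_labels(labels: np.ndarray) -> frozenset[int]:
    """Set of labels that touch the image border."""
    edge = np.concatenate(
        [labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]
    )
    return frozenset(int(v) for v in np.unique(edge) if v > 0)
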