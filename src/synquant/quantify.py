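"""Intensity-derived measurements.

Background-subtracted per-synapse intensities, PSD-95-normalized protein
levels, Munc13-1 nanocluster counts inside dilated synaptic masks,
peak-aligned lateral intensity profiles across the synaptic cleft, somatic PV
intensities, and receptor/PSD-95 density ratios of synapses on PV+ dendrites.

All intensity measurements operate on background-subtracted images, clipped
at zero (negative fluorescence is unphysical); masks are built on the raw
blurred channels upstream in :mod:`synquant.segmentation`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DegenerateInputError,
    ImagePlane,
    LabelMap,
    ParameterError,
    as_bool_mask,
)
from .imageops import dilate_mask, find_maxima
from .segmentation import DendriteAnnotation

__all__ = [
    "ProfileResult",
    "per_synapse_intensity",
    "normalize_to_psd95",
    "count_nanoclusters",
    "nanocluster_area_correlation",
    "peak_aligned_profile",
    "pv_dendrite_metrics",
    "somatic_pv_metrics",
]


@dataclass
class ProfileResult:
    """Peak-normalized 1-D lateral intensity trace of one channel.

    ``offset_nm`` is the signed distance of this channel's profile peak from
    the reference (PSD-95) peak along the box's long axis; it is an integer
    multiple of the pixel size because profiles are sampled on the pixel
    pitch.
    """

    channel: str
    offset_nm: float
    positions_nm: np.ndarray
    profile: np.ndarray


def per_synapse_intensity(
    labels: LabelMap, channel: ImagePlane, background: ImagePlane
) -> pd.DataFrame:
    """Mean and integral of (channel - background), clipped at 0, per label.

    Columns: ``label``, ``mean``, ``integral``.
    """
    if labels.labels.shape != channel.shape or channel.shape != background.shape:
        raise ParameterError("labels, channel and background shapes differ")
    diff = np.clip(channel.pixels - background.pixels, 0, None)
    n = labels.n_labels
    idx = np.arange(1, n + 1)
    if n:
        sums = ndimage.sum_labels(diff, labels.labels, index=idx)
        counts = ndimage.sum_labels(np.ones_like(diff), labels.labels, index=idx)
        means = sums / counts
    else:
        sums = means = np.empty(0)
    return pd.DataFrame({"label": idx, "mean": means, "integral": sums})


def normalize_to_psd95(
    records: pd.DataFrame,
    value_col: str = "paired_mean",
    psd95_col: str = "psd95_mean",
    reaction_col: str = "reaction",
) -> pd.Series:
    """Normalized mean intensity: paired-channel mean over the population mean
    of PSD-95 within the same reaction.

    Normalizing to the reaction-wise PSD-95 population mean absorbs labeling
    efficiency differences between reactions.
    """
    out = np.empty(len(records))
    for _, idx in records.groupby(reaction_col).indices.items():
        pop = records[psd95_col].iloc[idx].mean()
        if pop == 0:
            raise ParameterError("zero PSD-95 population mean in a reaction")
        out[idx] = records[value_col].iloc[idx] / pop
    return pd.Series(out, index=records.index, name="normalized_mean_intensity")


def count_nanoclusters(
    munc: ImagePlane,
    labels: LabelMap,
    prominence: float,
    dilate_px: int = 3,
) -> pd.DataFrame:
    """Count Munc13-1 intensity peaks per synapse inside dilated synaptic masks.

    Masks are dilated by ``dilate_px`` (disc) so that presynaptic active
    zones of side-view synapses are included.  One shared ``prominence``
    value is used for all subjects of an experiment.  Where dilated masks
    overlap, a peak is assigned to the label with the nearest non-dilated
    boundary.

    Columns: ``label``, ``nanocluster_count``.
    """
    if munc.shape != labels.labels.shape:
        raise ParameterError("channel and label map shapes differ")
    n = labels.n_labels
    counts = np.zeros(n, dtype=int)
    if n:
        res = find_maxima(munc, prominence, mode="points")
        if len(res.points):
            # nearest labelled pixel (and its distance) for every pixel
            dist, (ir, ic) = ndimage.distance_transform_edt(
                labels.labels == 0, return_indices=True
            )
            pr, pc = res.points[:, 0], res.points[:, 1]
            d = dist[pr, pc]
            lab = labels.labels[ir[pr, pc], ic[pr, pc]]
            ok = d <= dilate_px
            np.add.at(counts, lab[ok] - 1, 1)
    return pd.DataFrame(
        {"label": np.arange(1, n + 1), "nanocluster_count": counts}
    )


def nanocluster_area_correlation(records: pd.DataFrame):
    """Spearman rank correlation of nanocluster count against synaptic area."""
    from .stats import spearman

    if len(records) < 3:
        raise ParameterError("need at least 3 synapses for a correlation")
    return spearman(
        records["area_um2"].to_numpy(), records["nanocluster_count"].to_numpy()
    )


def peak_aligned_profile(
    planes: dict[str, ImagePlane],
    center_px: tuple[float, float],
    axis: tuple[float, float],
    reference: str = "PSD95",
    box_length_nm: float = 860.0,
    box_width_nm: float = 175.0,
) -> dict[str, ProfileResult]:
    """Peak-normalized lateral intensity profiles across the synaptic cleft.

    A ``box_length_nm`` x ``box_width_nm`` box is centred at ``center_px``
    (row, col) with its long axis along ``axis`` (row, col direction,
    perpendicular to the postsynaptic bar).  Each profile is the mean
    intensity across the short axis at every long-axis position (pixel
    pitch), normalized to its own peak; offsets are signed distances of each
    channel's peak from the reference channel's peak.
    """
    if reference not in planes:
        raise ParameterError(f"reference channel {reference!r} missing")
    ref_plane = planes[reference]
    px_nm = ref_plane.pixel_size_nm
    ax = np.asarray(axis, dtype=float)
    norm = np.hypot(*ax)
    if norm == 0:
        raise ParameterError("axis vector must be nonzero")
    ax = ax / norm
    perp = np.array([-ax[1], ax[0]])

    n_long = int(round(box_length_nm / px_nm)) + 1
    n_short = max(int(round(box_width_nm / px_nm)) + 1, 1)
    s = (np.arange(n_long) - (n_long - 1) / 2.0) * 1.0
    t = (np.arange(n_short) - (n_short - 1) / 2.0) * 1.0
    c = np.asarray(center_px, dtype=float)
    # sample grid: rows x cols coordinates, shape (n_long, n_short, 2)
    coords = (
        c[None, None, :]
        + s[:, None, None] * ax[None, None, :]
        + t[None, :, None] * perp[None, None, :]
    )
    h, w = ref_plane.shape
    if (
        coords[..., 0].min() < 0
        or coords[..., 1].min() < 0
        or coords[..., 0].max() > h - 1
        or coords[..., 1].max() > w - 1
    ):
        raise ParameterError("profile box exceeds image bounds")

    def trace(plane: ImagePlane) -> np.ndarray:
        vals = ndimage.map_coordinates(
            plane.pixels, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1
        ).reshape(n_long, n_short)
        return vals.mean(axis=1)

    ref_trace = trace(ref_plane)
    if ref_trace.max() == ref_trace.min():
        raise DegenerateInputError("flat reference profile; peak undefined")
    ref_peak = int(np.argmax(ref_trace))
    positions_nm = (s - s[ref_peak]) * px_nm

    out: dict[str, ProfileResult] = {}
    for name, plane in planes.items():
        if plane.shape != ref_plane.shape:
            raise ParameterError("all planes must share one registered shape")
        tr = trace(plane)
        if tr.max() == tr.min():
            warnings.warn(f"flat profile for channel {name!r}; peak undefined")
            continue
        peak = int(np.argmax(tr))
        out[name] = ProfileResult(
            channel=name,
            offset_nm=float((peak - ref_peak) * px_nm),
            positions_nm=positions_nm,
            profile=tr / tr.max(),
        )
    return out


def pv_dendrite_metrics(
    labels: LabelMap,
    dendrites: list[DendriteAnnotation],
    channels: dict[str, pd.DataFrame],
    psd95: pd.DataFrame,
    normalization: str = "mean_of_ratios",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Receptor/PSD-95 density ratios of synapses on PV+ dendrites.

    Parameters
    ----------
    labels
        Synapse label map (summed-channel segmentation, PSD-95 filtered).
    dendrites
        Dendrite annotations; myelinated-axon entries are excluded.
    channels
        Mapping of channel name to its :func:`per_synapse_intensity` table.
    psd95
        :func:`per_synapse_intensity` table of the PSD-95 channel.
    normalization
        ``"mean_of_ratios"`` (default) divides each PV-synapse ratio by the
        mean per-synapse ratio of the non-PV population; ``"ratio_of_means"``
        uses the ratio of population-mean integrals instead.

    Returns
    -------
    synapses, dendrite_table
        ``synapses`` has one row per synapse with ``on_pv_dendrite``,
        per-channel ``<ch>_ratio`` (integral/PSD-95 integral) and
        ``<ch>_normalized`` (PV ratios over the non-PV population level);
        ``dendrite_table`` has one row per valid dendrite with
        ``length_um``, ``synapse_count`` and ``synapses_per_um``.
    """
    if normalization not in ("mean_of_ratios", "ratio_of_means"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    n = labels.n_labels
    lab = labels.labels
    valid = [d for d in dendrites if not d.is_myelinated_axon and d.pv_positive]
    on_pv = np.zeros(n, dtype=bool)
    dend_rows = []
    for d in valid:
        if d.length_um <= 0:
            warnings.warn(f"dendrite {d.dendrite_id} has zero length; skipped")
            continue
        mask = as_bool_mask(d.mask, lab.shape)
        overlapping = np.unique(lab[mask])
        overlapping = overlapping[overlapping > 0]
        on_pv[overlapping - 1] = True
        dend_rows.append(
            {
                "dendrite_id": d.dendrite_id,
                "length_um": d.length_um,
                "synapse_count": int(len(overlapping)),
                "synapses_per_um": len(overlapping) / d.length_um,
            }
        )
    dend_table = pd.DataFrame(
        dend_rows, columns=["dendrite_id", "length_um", "synapse_count", "synapses_per_um"]
    )

    syn = pd.DataFrame(
        {
            "label": np.arange(1, n + 1),
            "psd95_integral": psd95["integral"].to_numpy(),
            "on_pv_dendrite": on_pv,
        }
    )
    pos = syn["psd95_integral"] > 0
    for ch, tab in channels.items():
        ratio = np.full(n, np.nan)
        ratio[pos.to_numpy()] = (
            tab["integral"].to_numpy()[pos] / syn["psd95_integral"].to_numpy()[pos]
        )
        syn[f"{ch}_ratio"] = ratio
        non_pv = syn.loc[~syn["on_pv_dendrite"] & pos, f"{ch}_ratio"]
        if normalization == "mean_of_ratios":
            ref = non_pv.mean()
        else:
            npv = syn.loc[~syn["on_pv_dendrite"] & pos]
            ref = (
                tab["integral"].to_numpy()[npv.index].sum()
                / npv["psd95_integral"].sum()
            )
        syn[f"{ch}_normalized"] = syn[f"{ch}_ratio"] / ref if ref else np.nan
    return syn, dend_table


def somatic_pv_metrics(
    pv: ImagePlane, somata: LabelMap, background_mask: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Background-subtracted somatic PV intensities plus somata per area.

    The scalar mean over ``background_mask`` (PV-negative neuropil) is
    subtracted from each soma's raw mean intensity in the unfiltered image.
    Returns the per-soma table and the somatic density (count per µm^2 of
    imaged area).
    """
    bg = as_bool_mask(background_mask, pv.shape)
    if not bg.any():
        raise ParameterError("empty background mask")
    bg_mean = float(pv.pixels[bg].mean())
    n = somata.n_labels
    idx = np.arange(1, n + 1)
    if n:
        means = ndimage.mean(pv.pixels, somata.labels, index=idx)
        areas = (
            ndimage.sum_labels(np.ones(pv.shape), somata.labels, index=idx)
            * somata.pixel_area_um2
        )
    else:
        means = areas = np.empty(0)
    table = pd.DataFrame(
        {
            "soma_id": idx,
            "mean_intensity_bgsub": np.asarray(means) - bg_mean,
            "area_um2": areas,
            "background_au": bg_mean,
        }
    )
    density = n / (pv.pixels.size * pv.pixel_area_um2)
    return table, density
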