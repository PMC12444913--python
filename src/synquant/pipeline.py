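"""Pipeline orchestration: per-field analyses, subject aggregation, group tests.

Ties the stages into the workflow's four analyses: the Layer-2 synapse
population (density, NND, areas, normalized paired-protein intensities), STED
nanocluster counting, receptor densities of synapses on PV+ dendrites, and
somatic PV intensities.  Channels of one field are registered to the
reference channel by translation before measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ImagePlane, LabelMap
from .imageops import register_translation, rolling_ball_background
from .morphometry import (
    AR_SIDE_VIEW_THRESHOLD,
    classify_view,
    field_density,
    region_properties,
)
from .quantify import (
    count_nanoclusters,
    normalize_to_psd95,
    per_synapse_intensity,
    pv_dendrite_metrics,
    somatic_pv_metrics,
)
from .segmentation import (
    DendriteAnnotation,
    filter_by_psd95_integral,
    neuropil_background_mask,
    psd95_synapse_labels,
    soma_labels,
    summed_channel_labels,
)
from .stats import holm_bonferroni, percent_reduction, t_unpaired

__all__ = [
    "PipelineParams",
    "register_channels",
    "analyze_layer2_field",
    "analyze_sted_field",
    "analyze_pv_dendrite_field",
    "analyze_pv_soma_field",
    "run_cohort",
    "subject_summary",
    "group_stats",
    "stats_report",
    "DEFAULT_HOLM_FAMILIES",
]


@dataclass
class PipelineParams:
    """All tunable stage parameters with their working defaults.

    Prominences are in the intensity units of the images being analyzed; one
    shared value is used for every subject of an experiment.
    """

    blur_radius_px: float = 2.0
    confocal_prominence: float = 5.0
    sted_prominence: float = 5.0
    munc_prominence: float = 50.0
    rolling_ball_radius_px: float = 7.0
    rolling_ball_presmooth_px: int = 1
    nanocluster_dilate_px: int = 3
    ar_threshold: float = AR_SIDE_VIEW_THRESHOLD
    psd95_min_integral: float = 10.0
    soma_min_area_um2: float = 50.0
    dendrite_width_um: float = 1.2
    normalization: str = "mean_of_ratios"
    exclude_border: bool = True


#: Comparisons adjusted together (the sets reported side by side).
DEFAULT_HOLM_FAMILIES: dict[str, tuple[str, ...]] = {
    "pv_soma": ("somatic_pv_intensity", "pv_cell_density"),
    "pv_dendrite": (
        "AMPAR_pv_normalized",
        "GluN1_pv_normalized",
        "GluN2B_pv_normalized",
    ),
    "layer2_paired": ("paired_normalized_intensity",),
}


def register_channels(
    planes: dict[str, ImagePlane], reference: str = "PSD95"
) -> dict[str, ImagePlane]:
    """Translation-align all channels to the reference channel.

    Residual shifts are corrected by integer rolls (reflective wrap pixels at
    the border are harmless at the shifts this stage sees).
    """
    if reference not in planes:
        return planes
    ref = planes[reference]
    out = {}
    for name, plane in planes.items():
        if name == reference:
            out[name] = plane
            continue
        dy, dx = register_translation(ref, plane)
        if (dy, dx) != (0, 0):
            rolled = np.roll(np.roll(plane.pixels, -dy, axis=0), -dx, axis=1)
            plane = plane.with_pixels(rolled)
        out[name] = plane
    return out


def _background(plane: ImagePlane, params: PipelineParams) -> ImagePlane:
    return rolling_ball_background(
        plane,
        params.rolling_ball_radius_px,
        presmooth_px=params.rolling_ball_presmooth_px,
    )


def _records_from_labels(
    labels: LabelMap, planes: dict[str, ImagePlane], params: PipelineParams
) -> pd.DataFrame:
    """Geometry plus per-channel background-subtracted intensities per label."""
    props = region_properties(labels)
    rec = props.rename(columns={"label": "synapse_id"})
    rec["view"] = [
        classify_view(min(a, 1e6), params.ar_threshold) for a in rec["aspect_ratio"]
    ]
    for name, plane in planes.items():
        tab = per_synapse_intensity(labels, plane, _background(plane, params))
        rec[f"{name}_mean"] = tab["mean"].to_numpy()
        rec[f"{name}_integral"] = tab["integral"].to_numpy()
    return rec


def _annotate(rec: pd.DataFrame, plane: ImagePlane, reaction: int = 0) -> pd.DataFrame:
    rec.insert(0, "subject_id", plane.subject_id)
    rec.insert(1, "condition", plane.condition)
    rec.insert(2, "field_id", plane.field_id)
    rec["reaction"] = reaction
    return rec


def analyze_layer2_field(
    planes: dict[str, ImagePlane],
    params: PipelineParams | None = None,
    reaction: int = 0,
):
    """Layer-2 confocal analysis of one field.

    Returns (synapse records, field summary).  Records carry per-channel
    means/integrals; the summary carries synapse count, density and the
    border-corrected mean NND.
    """
    params = params or PipelineParams()
    planes = register_channels(planes)
    psd = planes["PSD95"]
    labels = psd95_synapse_labels(
        psd, params.confocal_prominence, params.blur_radius_px
    )
    rec = _records_from_labels(labels, planes, params)
    rec = _annotate(rec, psd, reaction)
    pts = rec.loc[~rec["touches_border"], ["centroid_x_um", "centroid_y_um"]].to_numpy()
    summary = field_density(labels, field_id=psd.field_id, points_um=pts)
    return rec, summary


def analyze_sted_field(
    planes: dict[str, ImagePlane],
    params: PipelineParams | None = None,
    munc_channel: str = "Munc13-1",
):
    """STED analysis: synapse morphometry plus nanocluster counts per synapse."""
    params = params or PipelineParams()
    planes = register_channels(planes)
    psd = planes["PSD95"]
    labels = psd95_synapse_labels(psd, params.sted_prominence, params.blur_radius_px)
    rec = _records_from_labels(labels, planes, params)
    counts = count_nanoclusters(
        planes[munc_channel],
        labels,
        prominence=params.munc_prominence,
        dilate_px=params.nanocluster_dilate_px,
    )
    rec["nanocluster_count"] = counts["nanocluster_count"].to_numpy()
    return _annotate(rec, psd)


def analyze_pv_dendrite_field(
    planes: dict[str, ImagePlane],
    dendrites: list[DendriteAnnotation],
    params: PipelineParams | None = None,
    receptor_channels: tuple[str, ...] = ("AMPAR", "GluN1", "GluN2B"),
):
    """Deep-layer analysis: summed-channel masks, PSD-95 filter, PV ratios.

    Returns (synapse table with on_pv_dendrite flags and normalized ratios,
    per-dendrite table).
    """
    params = params or PipelineParams()
    planes = register_channels(planes)
    psd = planes["PSD95"]
    labels = summed_channel_labels(
        psd,
        planes["AMPAR"],
        planes["GluN1"],
        maxima_prominence=params.confocal_prominence,
        blur_radius_px=params.blur_radius_px,
    )
    bg_psd = _background(psd, params)
    labels = filter_by_psd95_integral(
        labels, psd, params.psd95_min_integral, background=bg_psd
    )
    psd_tab = per_synapse_intensity(labels, psd, bg_psd)
    chans = {
        ch: per_synapse_intensity(labels, planes[ch], _background(planes[ch], params))
        for ch in receptor_channels
        if ch in planes
    }
    syn, dend = pv_dendrite_metrics(
        labels, dendrites, chans, psd_tab, normalization=params.normalization
    )
    props = region_properties(labels)
    syn = syn.merge(
        props[["label", "area_um2", "centroid_x_um", "centroid_y_um", "touches_border"]],
        on="label",
    )
    syn = _annotate(syn, psd)
    dend.insert(0, "subject_id", psd.subject_id)
    dend.insert(1, "condition", psd.condition)
    dend.insert(2, "field_id", psd.field_id)
    return syn, dend


def analyze_pv_soma_field(pv: ImagePlane, params: PipelineParams | None = None):
    """Somatic PV analysis: soma label map, neuropil background, intensities."""
    params = params or PipelineParams()
    somata = soma_labels(
        pv, min_area_um2=params.soma_min_area_um2, blur_radius_px=params.blur_radius_px
    )
    table, density = somatic_pv_metrics(pv, somata, neuropil_background_mask(pv))
    table = _annotate(table, pv)
    table["soma_density_per_um2"] = density
    return table


# ---------------------------------------------------------------------------
# cohort driver
# ---------------------------------------------------------------------------

def run_cohort(
    cohort_dir: str | Path,
    out_dir: str | Path,
    params: PipelineParams | None = None,
    kinds: tuple[str, ...] | None = None,
) -> dict[str, pd.DataFrame]:
    """Quantify every field of a cohort on disk; write tidy CSV tables.

    Outputs ``synapses.csv``, ``field_summaries.csv``, ``somata.csv``,
    ``dendrite_table.csv`` and ``subject_summary.csv`` under ``out_dir``.
    """
    from .io import load_field_planes, read_dendrite_annotations

    params = params or PipelineParams()
    cohort_dir = Path(cohort_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = pd.read_csv(cohort_dir / "metadata.csv")
    if kinds is not None:
        meta = meta[meta["kind"].isin(kinds)]
    dend_path = cohort_dir / "truth" / "dendrites.csv"

    syn_all, fsum_all, soma_all, dend_all = [], [], [], []
    for (field_id, kind), grp in meta.groupby(["field_id", "kind"], sort=True):
        planes = load_field_planes(cohort_dir, grp)
        reaction = int(grp["reaction"].iloc[0])
        if kind == "layer2":
            rec, summary = analyze_layer2_field(planes, params, reaction)
            rec["kind"] = kind
            syn_all.append(rec)
            fsum_all.append(
                {
                    "field_id": summary.field_id,
                    "kind": kind,
                    "subject_id": rec["subject_id"].iloc[0] if len(rec) else "",
                    "condition": rec["condition"].iloc[0] if len(rec) else "",
                    "analyzable_area_um2": summary.analyzable_area_um2,
                    "synapse_count": summary.synapse_count,
                    "density_per_um2": summary.density_per_um2,
                    "mean_nnd_um": summary.mean_nnd_um,
                }
            )
        elif kind == "sted":
            rec = analyze_sted_field(planes, params)
            rec["kind"] = kind
            syn_all.append(rec)
        elif kind == "pv_dendrite":
            shape = planes["PSD95"].shape
            dendrites = []
            if dend_path.exists():
                dendrites = [
                    d
                    for d in read_dendrite_annotations(
                        dend_path,
                        shape,
                        planes["PSD95"].pixel_size_nm,
                        params.dendrite_width_um,
                    )
                    if d.field_id == field_id
                ]
            syn, dend = analyze_pv_dendrite_field(planes, dendrites, params)
            syn["kind"] = kind
            syn_all.append(syn)
            dend_all.append(dend)
        elif kind == "pv_soma":
            soma_all.append(analyze_pv_soma_field(planes["PV"], params))

    tables: dict[str, pd.DataFrame] = {}
    if syn_all:
        tables["synapses"] = pd.concat(syn_all, ignore_index=True)
    if fsum_all:
        tables["field_summaries"] = pd.DataFrame(fsum_all)
    if soma_all:
        tables["somata"] = pd.concat(soma_all, ignore_index=True)
    if dend_all:
        tables["dendrite_table"] = pd.concat(dend_all, ignore_index=True)
    tables["subject_summary"] = subject_summary(tables)
    for name, tab in tables.items():
        tab.to_csv(out_dir / f"{name}.csv", index=False)
    return tables


def subject_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per subject: the per-subject means all group tests consume."""
    rows: dict[str, dict] = {}

    def row(sid, cond):
        r = rows.setdefault(sid, {"subject_id": sid, "condition": cond})
        return r

    syn = tables.get("synapses")
    if syn is not None and len(syn):
        l2 = syn[syn["kind"] == "layer2"]
        for sid, g in l2.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            ok = ~g["touches_border"]
            r["area_um2"] = g.loc[ok, "area_um2"].mean()
            r["psd95_mean_intensity"] = g["PSD95_mean"].mean()
            r["n_synapses_layer2"] = len(g)
            paired = [
                c[:-5]
                for c in g.columns
                if c.endswith("_mean") and not c.startswith("PSD95")
            ]
            if paired:
                ch = paired[0]
                norm = normalize_to_psd95(
                    g.rename(columns={f"{ch}_mean": "paired_mean", "PSD95_mean": "psd95_mean"}),
                )
                r["paired_normalized_intensity"] = norm.mean()
        st = syn[syn["kind"] == "sted"]
        for sid, g in st.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            ok = ~g["touches_border"]
            r["nanocluster_count"] = g.loc[ok, "nanocluster_count"].mean()
            en = g.loc[ok & (g["view"] == "en_face"), "nanocluster_count"]
            if len(en):
                r["nanocluster_count_en_face"] = en.mean()
            r["sted_area_um2"] = g.loc[ok, "area_um2"].mean()
        pv = syn[syn["kind"] == "pv_dendrite"]
        for sid, g in pv.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            on = g["on_pv_dendrite"].astype(bool)
            r["psd95_integral_pv"] = g.loc[on, "psd95_integral"].mean()
            r["psd95_integral_nonpv"] = g.loc[~on, "psd95_integral"].mean()
            r["n_synapses_pv"] = int(on.sum())
            for ch in ("AMPAR", "GluN1", "GluN2B"):
                col = f"{ch}_normalized"
                if col in g.columns and on.any():
                    r[f"{ch}_pv_normalized"] = g.loc[on, col].mean()

    fs = tables.get("field_summaries")
    if fs is not None and len(fs):
        for sid, g in fs.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            r["density_per_um2"] = g["density_per_um2"].mean()
            r["mean_nnd_um"] = g["mean_nnd_um"].mean()

    som = tables.get("somata")
    if som is not None and len(som):
        for sid, g in som.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            r["somatic_pv_intensity"] = g["mean_intensity_bgsub"].mean()
            r["pv_cell_density"] = g["soma_density_per_um2"].mean()

    dend = tables.get("dendrite_table")
    if dend is not None and len(dend):
        for sid, g in dend.groupby("subject_id"):
            r = row(sid, g["condition"].iloc[0])
            r["synapses_per_um_pv_dendrite"] = g["synapses_per_um"].mean()

    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["subject_id"]))


def group_stats(
    summary: pd.DataFrame,
    measures: list[str] | None = None,
    holm_families: dict[str, tuple[str, ...]] | None = None,
    control_label: str = "control",
) -> pd.DataFrame:
    """Unpaired pooled t tests per measure on subject means, Holm per family.

    Returns one row per measure: group means +- SD, n, t, df, p, adjusted p
    (within the declared family) and the percent difference of the case group
    relative to control.
    """
    holm_families = holm_families if holm_families is not None else DEFAULT_HOLM_FAMILIES
    cond = summary["condition"]
    groups = sorted(cond.unique(), key=lambda c: c != control_label)
    if len(groups) != 2:
        raise ValueError("group_stats needs exactly two conditions")
    ctrl, case = groups
    if measures is None:
        measures = [
            c
            for c in summary.columns
            if c not in ("subject_id", "condition")
            and np.issubdtype(summary[c].dtype, np.number)
        ]
    rows = []
    for meas in measures:
        a = summary.loc[cond == ctrl, meas].dropna().to_numpy()
        b = summary.loc[cond == case, meas].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            continue
        res = t_unpaired(a, b)
        rows.append(
            {
                "measure": meas,
                "mean_control": res.mean1,
                "sd_control": res.sd1,
                "n_control": res.n1,
                "mean_case": res.mean2,
                "sd_case": res.sd2,
                "n_case": res.n2,
                "t": res.statistic,
                "df": res.df,
                "p": res.p,
                "percent_difference": (
                    percent_reduction(res.mean1, res.mean2) if res.mean1 > 0 else np.nan
                ),
                "test": res.kind,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = out["p"]
    for fam in holm_families.values():
        idx = out.index[out["measure"].isin(fam)]
        if len(idx):
            out.loc[idx, "p_adjusted"] = holm_bonferroni(out.loc[idx, "p"].to_numpy())
    return out


def stats_report(results: pd.DataFrame) -> str:
    """Human-readable summary of :func:`group_stats` output."""
    lines = ["Group comparison (subject means; unpaired pooled t, Holm per family)", ""]
    for _, r in results.iterrows():
        lines.append(
            f"{r['measure']}: control {r['mean_control']:.3g} ± {r['sd_control']:.3g} "
            f"(n={r['n_control']}) vs case {r['mean_case']:.3g} ± {r['sd_case']:.3g} "
            f"(n={r['n_case']}); t({r['df']:.0f}) = {r['t']:.2f}, p = {r['p']:.4g}, "
            f"p_adj = {r['p_adjusted']:.4g}"
        )
        if np.isfinite(r.get("percent_difference", np.nan)):
            lines.append(
                f"    {abs(r['percent_difference']):.0f}% "
                f"{'reduction' if r['percent_difference'] >= 0 else 'increase'} vs control"
            )
    return "\n".join(lines)
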