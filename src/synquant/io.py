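"""Cohort I/O: TIFF planes with a CSV metadata sidecar, ground-truth tables,
dendrite-annotation CSVs and a YAML run manifest.

Pixel sizes live in the metadata table, not in TIFF tags (tag metadata of
postmortem-archive images is unreliable).  All artifacts are plain standard
formats readable without this package.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import ImagePlane
from .segmentation import DendriteAnnotation

__all__ = [
    "save_plane",
    "load_plane",
    "save_label_map",
    "load_label_map",
    "write_dendrite_annotations",
    "read_dendrite_annotations",
    "write_cohort",
    "read_manifest",
    "load_field_planes",
]


def save_plane(plane: ImagePlane, path: str | Path) -> None:
    """Write one channel as a single-page float32 TIFF."""
    tifffile.imwrite(str(path), plane.pixels.astype(np.float32))


def load_plane(
    path: str | Path,
    pixel_size_nm: float,
    channel: str = "",
    field_id: str = "",
    subject_id: str = "",
    condition: str = "",
) -> ImagePlane:
    """Read a TIFF page into an :class:`ImagePlane` (scale from the caller)."""
    px = tifffile.imread(str(path))
    if px.ndim == 3:  # multi-page: first page
        px = px[0]
    return ImagePlane(
        np.asarray(px, dtype=np.float64),
        pixel_size_nm=pixel_size_nm,
        channel=channel,
        field_id=field_id,
        subject_id=subject_id,
        condition=condition,
    )


def save_label_map(labels, path: str | Path) -> None:
    """Persist a label map as 16-bit TIFF (label ids are preserved)."""
    lab = labels.labels
    if lab.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(str(path), lab.astype(np.uint16))


def load_label_map(path: str | Path, pixel_size_nm: float, kind: str = "synapse"):
    """Read a 16-bit TIFF label map back into a :class:`LabelMap`."""
    from .core import LabelMap, border_touching_labels

    lab = tifffile.imread(str(path)).astype(np.int32)
    return LabelMap(lab, pixel_size_nm, kind, border_touching_labels(lab))


# ---------------------------------------------------------------------------
# dendrite annotations
# ---------------------------------------------------------------------------

def write_dendrite_annotations(dendrites: list[DendriteAnnotation], path: str | Path) -> None:
    """Persist polylines as tidy CSV (one row per vertex)."""
    rows = []
    for d in dendrites:
        for vi, (x, y) in enumerate(d.polyline_um):
            rows.append(
                {
                    "dendrite_id": d.dendrite_id,
                    "vertex_index": vi,
                    "x_um": x,
                    "y_um": y,
                    "pv_positive": d.pv_positive,
                    "is_myelinated_axon": d.is_myelinated_axon,
                    "subject_id": d.subject_id,
                    "field_id": d.field_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_dendrite_annotations(
    path: str | Path,
    shape: tuple[int, int],
    pixel_size_nm: float,
    width_um: float = 1.2,
) -> list[DendriteAnnotation]:
    """Rebuild dendrite annotations (masks rasterized at the given width)."""
    from .synthetic import _polyline_mask

    df = pd.read_csv(path)
    out = []
    for did, grp in df.sort_values(["dendrite_id", "vertex_index"]).groupby(
        "dendrite_id", sort=True
    ):
        pl = grp[["x_um", "y_um"]].to_numpy()
        out.append(
            DendriteAnnotation(
                dendrite_id=str(did),
                polyline_um=pl,
                mask=_polyline_mask(pl, shape, pixel_size_nm, width_um),
                pv_positive=bool(grp["pv_positive"].iloc[0]),
                is_myelinated_axon=bool(grp["is_myelinated_axon"].iloc[0]),
                subject_id=str(grp["subject_id"].iloc[0]),
                field_id=str(grp["field_id"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# cohort writer
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_cohort(
    config,
    outdir: str | Path,
    kinds: tuple[str, ...] = ("layer2", "sted", "pv_dendrite", "pv_soma"),
    overwrite: bool = False,
) -> Path:
    """Simulate and persist a full cohort: TIFFs, metadata, truth, manifest.

    Layout::

        outdir/
          metadata.csv              one row per image file
          manifest.yaml             config, seed, per-file checksums
          truth/synapses.csv, somata.csv, dendrites.csv
          <subject>/<field>_<channel>.tiff
    """
    from .synthetic import simulate_field, subject_table

    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{outdir} exists and is not empty; pass overwrite=True"
            )
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    subjects = subject_table(config)
    meta_rows = []
    truth_syn = []
    truth_som = []
    dendrites_all = []

    def _emit(planes: dict, subject, kind: str, reaction: int = 0) -> None:
        sdir = outdir / subject.subject_id
        sdir.mkdir(exist_ok=True)
        for chan, plane in planes.items():
            fname = f"{plane.field_id}_{chan.replace('/', '-')}.tiff"
            save_plane(plane, sdir / fname)
            meta_rows.append(
                {
                    "path": f"{subject.subject_id}/{fname}",
                    "subject_id": subject.subject_id,
                    "condition": subject.condition,
                    "field_id": plane.field_id,
                    "kind": kind,
                    "channel": chan,
                    "reaction": reaction,
                    "pixel_size_nm": plane.pixel_size_nm,
                }
            )

    for _, subject in subjects.iterrows():
        for fi in range(config.fields_per_subject):
            if "layer2" in kinds:
                planes, truth = simulate_field(config, subject, fi, "layer2")
                _emit(planes, subject, "layer2")
                truth_syn.append(truth)
            if "sted" in kinds:
                planes, truth = simulate_field(config, subject, fi, "sted")
                _emit(planes, subject, "sted")
                truth_syn.append(truth)
            if "pv_dendrite" in kinds:
                planes, truth, dend, _ = simulate_field(
                    config, subject, fi, "pv_dendrite"
                )
                _emit(planes, subject, "pv_dendrite")
                truth_syn.append(truth)
                dendrites_all.extend(dend)
            if "pv_soma" in kinds:
                planes, truth = simulate_field(config, subject, fi, "pv_soma")
                _emit(planes, subject, "pv_soma")
                truth_som.append(truth)

    subjects.to_csv(outdir / "subjects.csv", index=False)
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(outdir / "metadata.csv", index=False)
    if truth_syn:
        pd.concat(truth_syn, ignore_index=True).to_csv(
            outdir / "truth" / "synapses.csv", index=False
        )
    if truth_som:
        pd.concat(truth_som, ignore_index=True).to_csv(
            outdir / "truth" / "somata.csv", index=False
        )
    if dendrites_all:
        write_dendrite_annotations(dendrites_all, outdir / "truth" / "dendrites.csv")

    files = sorted(p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.yaml")
    manifest = {
        "seed": int(config.seed),
        "config": config.to_dict(),
        "kinds": list(kinds),
        "files": [
            {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)} for p in files
        ],
        "n_images": len(meta_rows),
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir


def read_manifest(cohort_dir: str | Path) -> dict:
    with open(Path(cohort_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)


def load_field_planes(cohort_dir: str | Path, meta: pd.DataFrame) -> dict[str, ImagePlane]:
    """Load all channels of one field from its metadata rows."""
    cohort_dir = Path(cohort_dir)
    planes = {}
    for _, row in meta.iterrows():
        planes[row["channel"]] = load_plane(
            cohort_dir / row["path"],
            pixel_size_nm=float(row["pixel_size_nm"]),
            channel=row["channel"],
            field_id=row["field_id"],
            subject_id=row["subject_id"],
            condition=row["condition"],
        )
    return planes
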