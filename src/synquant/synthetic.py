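"""Synthetic multi-channel immunofluorescence cohorts with ground truth.

The generator emulates the statistical structure the analysis assumes:
fields of PSD-95-positive puncta with en-face and side-view geometries,
paired-protein channels, Munc13-1 nanoclusters whose count scales linearly
with synapse area, PV+ somata, PV+ dendrites whose synapses carry reduced
PSD-95 and elevated receptor/PSD-95 ratios, per-reaction gain factors,
per-subject random effects, and Poisson + Gaussian noise over a smooth
background.  Every planted object is listed in a ground-truth table keyed to
pipeline detections.

Objects are rendered as rotated anisotropic Gaussian templates whose sigmas
already include the modality's point-spread function; the planted "area" of
a synapse is the above-half-max footprint of its noiseless template, the
quantity the thresholded mask area is comparable to.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import ImagePlane

__all__ = [
    "NoiseModel",
    "Layer2ConfocalModel",
    "StedModel",
    "NanoclusterModel",
    "PVDendriteModel",
    "PVSomaModel",
    "GeneratorConfig",
    "subject_table",
    "simulate_field",
    "simulate_subject_summaries",
    "make_sideview_fixture",
    "sideview_truth",
    "match_detections",
]

_HALF_MAX = 2.0 * np.pi * np.log(2.0)  # half-max footprint area of a Gaussian
                                       # = 2*pi*ln2 * sigma_major * sigma_minor


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class NoiseModel:
    """Poisson shot noise on (signal + background) plus Gaussian read noise.

    ``background_au`` is the mean background level; a smooth multiplicative
    modulation (relative amplitude ``background_modulation``, correlation
    scale ``background_scale_um``) emulates slowly varying staining
    background.
    """

    background_au: float = 50.0
    read_noise_sd: float = 3.0
    background_modulation: float = 0.10
    background_scale_um: float = 10.0


@dataclass
class Layer2ConfocalModel:
    """Layer-2 population imaging: 70 x 210 µm fields at 100 nm/px."""

    field_width_um: float = 70.0
    field_height_um: float = 210.0
    pixel_size_nm: float = 100.0
    density_per_um2: float = 0.15
    min_separation_um: float = 0.5  # hard core: the resolvable-punctum separation
    area_mean_um2: float = 0.11  # template (true) size; measured areas are larger
    area_min_um2: float = 0.04
    area_sigma_log: float = 0.5
    en_face_fraction: float = 196.0 / 264.0
    psd95_mean_intensity_au: float = 497.0
    paired_mean_ratio: float = 0.8
    intensity_sigma_log: float = 0.3
    psf_sigma_nm: float = 130.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(background_au=10.0, read_noise_sd=2.0))


@dataclass
class StedModel:
    """STED imaging of Layer-2 synapses: 10 x 10 µm fields at 20 nm/px."""

    field_width_um: float = 10.0
    field_height_um: float = 10.0
    pixel_size_nm: float = 20.0
    density_per_um2: float = 0.15
    min_separation_um: float = 0.5
    area_mean_um2: float = 0.11
    area_min_um2: float = 0.04
    area_sigma_log: float = 0.5
    en_face_fraction: float = 196.0 / 264.0
    psd95_mean_intensity_au: float = 30.0
    intensity_sigma_log: float = 0.5
    psf_sigma_nm: float = 40.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(background_au=3.0, read_noise_sd=1.0))


@dataclass
class NanoclusterModel:
    """Munc13-1 nanocluster model: count linear in synapse area.

    ``count = max(1, round(per_um2 * area) + Poisson(jitter) - jitter)``,
    with ``per_um2`` calibrated so the population mean over the default STED
    area distribution is 3.4 clusters per synapse.  Clusters keep a minimum
    spacing of ``min_spacing_nm``; in side-view synapses they sit on a line
    offset 40 nm presynaptically from the PSD-95 bar.
    """

    per_um2: float = 32.0
    jitter: float = 1.0
    min_spacing_nm: float = 60.0
    cluster_sigma_nm: float = 20.0
    cluster_integral_au: float = 4000.0
    sideview_offset_nm: float = 40.0


@dataclass
class PVDendriteModel:
    """Deep-layer (L3/4) sequential-labeling fields with PV+ dendrites."""

    field_width_um: float = 50.0
    field_height_um: float = 50.0
    pixel_size_nm: float = 100.0
    density_per_um2: float = 0.23
    min_separation_um: float = 0.5
    area_mean_um2: float = 0.11
    area_min_um2: float = 0.04
    area_sigma_log: float = 0.5
    psd95_integral_nonpv_au: float = 192.0
    psd95_pv_scale: float = 122.0 / 192.0
    integral_sigma_log: float = 0.5
    ratio_base: dict = field(
        default_factory=lambda: {"AMPAR": 0.5, "GluN1": 0.3, "GluN2B": 0.4}
    )
    ratio_sigma_log: float = 0.3
    pv_multiplier_mean: dict = field(
        default_factory=lambda: {
            "control": {"AMPAR": 1.72, "GluN1": 1.60, "GluN2B": 1.72},
            "schizophrenia": {"AMPAR": 1.54, "GluN1": 1.30, "GluN2B": 1.43},
        }
    )
    pv_multiplier_sd: dict = field(
        default_factory=lambda: {
            "control": {"AMPAR": 0.14, "GluN1": 0.15, "GluN2B": 0.25},
            "schizophrenia": {"AMPAR": 0.25, "GluN1": 0.19, "GluN2B": 0.21},
        }
    )
    dendrites_per_field: int = 2
    dendrite_width_um: float = 1.2
    synapses_per_um: float = 0.87
    myelinated_axons_per_field: int = 1
    psf_sigma_nm: float = 130.0
    noise: NoiseModel = field(default_factory=lambda: NoiseModel(background_au=0.5, read_noise_sd=0.5))


@dataclass
class PVSomaModel:
    """Low-magnification PV immunofluorescence for somatic intensity analysis."""

    field_width_um: float = 102.4
    field_height_um: float = 102.4
    pixel_size_nm: float = 400.0
    somata_per_field: int = 10
    soma_radius_um_mean: float = 7.5
    soma_radius_um_sd: float = 1.0
    somatic_intensity_mean: dict = field(
        default_factory=lambda: {"control": 1362.0, "schizophrenia": 955.0}
    )
    somatic_intensity_subject_sd: dict = field(
        default_factory=lambda: {"control": 151.0, "schizophrenia": 265.0}
    )
    soma_sigma_log: float = 0.10
    neuropil_au: float = 150.0
    process_amplitude_au: float = 150.0
    processes_per_field: int = 12
    noise: NoiseModel = field(
        default_factory=lambda: NoiseModel(background_au=100.0, read_noise_sd=5.0)
    )


@dataclass
class GeneratorConfig:
    """Full synthetic-cohort description (all stages)."""

    seed: int = 0
    n_control: int = 9
    n_schizophrenia: int = 6
    fields_per_subject: int = 1
    subject_gain_sigma_log: float = 0.15
    reaction_gain_sigma_log: float = 0.25
    n_reactions: int = 2
    null_cohort: bool = False  # disable every group effect (type-I suites)
    layer2: Layer2ConfocalModel = field(default_factory=Layer2ConfocalModel)
    sted: StedModel = field(default_factory=StedModel)
    nanoclusters: NanoclusterModel = field(default_factory=NanoclusterModel)
    pv_dendrite: PVDendriteModel = field(default_factory=PVDendriteModel)
    pv_soma: PVSomaModel = field(default_factory=PVSomaModel)
    age_range_years: tuple = (55.0, 85.0)
    pmi_mean_hours: float = 3.3
    pmi_sd_hours: float = 0.7

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key, sub in (
            ("layer2", Layer2ConfocalModel),
            ("sted", StedModel),
            ("nanoclusters", NanoclusterModel),
            ("pv_dendrite", PVDendriteModel),
            ("pv_soma", PVSomaModel),
        ):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                if "noise" in dd and isinstance(dd["noise"], dict):
                    dd["noise"] = NoiseModel(**dd["noise"])
                d[key] = sub(**dd)
        if "age_range_years" in d:
            d["age_range_years"] = tuple(d["age_range_years"])
        return cls(**d)


# ---------------------------------------------------------------------------
# subject-level bookkeeping
# ---------------------------------------------------------------------------

def _rng(config_seed: int, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(config_seed) & 0x7FFFFFFF, *streams])


def subject_table(config: GeneratorConfig) -> pd.DataFrame:
    """Cohort roster: one row per subject with condition, covariates and gains."""
    rng = _rng(config.seed, 0)
    rows = []
    for i in range(config.n_control + config.n_schizophrenia):
        cond = "control" if i < config.n_control else "schizophrenia"
        code = f"CON{i + 1:02d}" if cond == "control" else f"SCZ{i - config.n_control + 1:02d}"
        rows.append(
            {
                "subject_id": code,
                "condition": cond,
                "age_years": float(rng.uniform(*config.age_range_years)),
                "gender": "male" if rng.random() < 0.5 else "female",
                "pmi_hours": float(
                    np.clip(rng.normal(config.pmi_mean_hours, config.pmi_sd_hours), 0.5, None)
                ),
                "subject_gain": float(
                    rng.lognormal(0.0, config.subject_gain_sigma_log)
                ),
            }
        )
    return pd.DataFrame(rows)


def _reaction_gains(config: GeneratorConfig) -> np.ndarray:
    rng = _rng(config.seed, 1)
    return rng.lognormal(0.0, config.reaction_gain_sigma_log, config.n_reactions)


# ---------------------------------------------------------------------------
# rendering primitives
# ---------------------------------------------------------------------------

def _render_gaussian(
    canvas: np.ndarray,
    r0: float,
    c0: float,
    sigma_major_px: float,
    sigma_minor_px: float,
    theta: float,
    integral: float,
) -> None:
    """Add a rotated anisotropic Gaussian with exact total ``integral``."""
    ext = int(np.ceil(4.0 * sigma_major_px)) + 1
    rlo = max(int(np.floor(r0)) - ext, 0)
    rhi = min(int(np.ceil(r0)) + ext + 1, canvas.shape[0])
    clo = max(int(np.floor(c0)) - ext, 0)
    chi = min(int(np.ceil(c0)) + ext + 1, canvas.shape[1])
    if rlo >= rhi or clo >= chi:
        return
    rr, cc = np.mgrid[rlo:rhi, clo:chi]
    dr = rr - r0
    dc = cc - c0
    ca, sa = np.cos(theta), np.sin(theta)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    g = np.exp(-0.5 * ((u / sigma_major_px) ** 2 + (v / sigma_minor_px) ** 2))
    s = g.sum()
    if s > 0:
        canvas[rlo:rhi, clo:chi] += g * (integral / s)


def _smooth_unit_field(rng: np.random.Generator, shape, sigma_px: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.normal(size=shape), sigma_px, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _apply_noise(
    rng: np.random.Generator, clean: np.ndarray, noise: NoiseModel, pixel_size_nm: float
) -> np.ndarray:
    bg = noise.background_au * np.ones_like(clean)
    sigma_px = noise.background_scale_um * 1000.0 / pixel_size_nm
    # modulation only makes sense when its correlation scale fits the field
    if noise.background_modulation > 0 and sigma_px < min(clean.shape) / 4:
        bg = bg * np.clip(
            1.0
            + noise.background_modulation
            * _smooth_unit_field(rng, clean.shape, sigma_px),
            0.2,
            None,
        )
    lam = np.clip(clean + bg, 0, None)
    img = rng.poisson(lam).astype(np.float64)
    if noise.read_noise_sd > 0:
        img += rng.normal(0.0, noise.read_noise_sd, clean.shape)
    return np.clip(img, 0, None)


def _place_points(
    rng: np.random.Generator,
    n: int,
    w_um: float,
    h_um: float,
    min_sep_um: float,
    margin_um: float = 0.0,
    max_tries: int = 100,
) -> np.ndarray:
    """Hard-core point placement: n points with a minimum pairwise separation.

    Raises if the requested density cannot be placed without violating the
    overlap tolerance (>2% failed placements).
    """
    pts: list[tuple[float, float]] = []
    if min_sep_um <= 0:
        x = rng.uniform(margin_um, w_um - margin_um, n)
        y = rng.uniform(margin_um, h_um - margin_um, n)
        return np.column_stack([x, y])
    cell = min_sep_um
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    fails = 0
    for _ in range(n):
        placed = False
        for _try in range(max_tries):
            x = rng.uniform(margin_um, w_um - margin_um)
            y = rng.uniform(margin_um, h_um - margin_um)
            gx, gy = int(x / cell), int(y / cell)
            conflict = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for px, py in grid.get((gx + dx, gy + dy), ()):
                        if (px - x) ** 2 + (py - y) ** 2 < min_sep_um**2:
                            conflict = True
                            break
                    if conflict:
                        break
                if conflict:
                    break
            if not conflict:
                pts.append((x, y))
                grid.setdefault((gx, gy), []).append((x, y))
                placed = True
                break
        if not placed:
            fails += 1
    if fails > max(2, 0.02 * n):
        raise ValueError(
            "configured density too high to place objects without overlap"
        )
    return np.array(pts) if pts else np.empty((0, 2))


def _sample_geometry(rng, n, model):
    """Areas (µm²), aspect ratios, orientations and view classes for n synapses.

    Areas are lognormal, truncated below the minimum physical PSD size by
    resampling.
    """
    mu = np.log(model.area_mean_um2) - 0.5 * model.area_sigma_log**2
    areas = rng.lognormal(mu, model.area_sigma_log, n)
    amin = getattr(model, "area_min_um2", 0.0)
    for _ in range(50):
        low = areas < amin
        if not low.any():
            break
        areas[low] = rng.lognormal(mu, model.area_sigma_log, int(low.sum()))
    areas = np.clip(areas, amin, None)
    en_face = rng.random(n) < model.en_face_fraction
    ar = np.where(en_face, rng.uniform(1.0, 2.0, n), rng.uniform(3.5, 6.0, n))
    theta = rng.uniform(0.0, np.pi, n)
    return areas, ar, theta, en_face


def _sigmas_px(area_um2, ar, pixel_size_nm):
    """Template sigmas (px) whose half-max footprint equals ``area_um2``."""
    area_px = area_um2 / (pixel_size_nm / 1000.0) ** 2
    sig_minor = np.sqrt(area_px / (_HALF_MAX * ar))
    return ar * sig_minor, sig_minor


# ---------------------------------------------------------------------------
# field simulators
# ---------------------------------------------------------------------------

def _simulate_layer2_field(config, subject, field_index, reaction, paired_channel):
    m = config.layer2
    rng = _rng(config.seed, 10, int(subject.name), field_index)
    px_um = m.pixel_size_nm / 1000.0
    shape = (
        int(round(m.field_height_um / px_um)),
        int(round(m.field_width_um / px_um)),
    )
    area_um2 = m.field_width_um * m.field_height_um
    n = rng.poisson(m.density_per_um2 * area_um2)
    xy = _place_points(
        rng, n, m.field_width_um, m.field_height_um, m.min_separation_um
    )
    n = len(xy)
    r = xy[:, 1] / px_um
    c = xy[:, 0] / px_um
    areas, ar, theta, en_face = _sample_geometry(rng, n, m)
    sig_maj, sig_min = _sigmas_px(areas, ar, m.pixel_size_nm)
    gains = subject["subject_gain"] * _reaction_gains(config)[reaction]
    psd_int = (
        m.psd95_mean_intensity_au
        * (areas / (px_um**2))
        * rng.lognormal(0.0, m.intensity_sigma_log, n)
        * gains
    )
    paired_int = (
        m.paired_mean_ratio * psd_int * rng.lognormal(0.0, m.intensity_sigma_log, n)
    )
    psd = np.zeros(shape)
    paired = np.zeros(shape)
    for i in range(n):
        _render_gaussian(psd, r[i], c[i], sig_maj[i], sig_min[i], theta[i], psd_int[i])
        _render_gaussian(
            paired, r[i], c[i], sig_maj[i], sig_min[i], theta[i], paired_int[i]
        )
    field_id = f"{subject.subject_id}_L2_{field_index:02d}"
    meta = dict(
        pixel_size_nm=m.pixel_size_nm,
        field_id=field_id,
        subject_id=subject.subject_id,
        condition=subject.condition,
    )
    planes = {
        "PSD95": ImagePlane(
            _apply_noise(rng, psd, m.noise, m.pixel_size_nm), channel="PSD95", **meta
        ),
        paired_channel: ImagePlane(
            _apply_noise(rng, paired, m.noise, m.pixel_size_nm),
            channel=paired_channel,
            **meta,
        ),
    }
    truth = pd.DataFrame(
        {
            "object": "synapse",
            "subject_id": subject.subject_id,
            "condition": subject.condition,
            "field_id": field_id,
            "kind": "layer2",
            "reaction": reaction,
            "x_um": c * px_um,
            "y_um": r * px_um,
            "area_um2": areas,
            "aspect_ratio": ar,
            "view": np.where(en_face, "en_face", "side_view"),
            "psd95_integral": psd_int,
            "paired_integral": paired_int,
        }
    )
    return planes, truth


def _place_clusters(rng, count, a_px, b_px, theta, min_spacing_px, max_tries=200):
    """Uniform points in a rotated ellipse with a minimum pairwise spacing."""
    pts = []
    ca, sa = np.cos(theta), np.sin(theta)
    for _ in range(count):
        for _try in range(max_tries):
            u = rng.uniform(-1, 1)
            v = rng.uniform(-1, 1)
            if u**2 + v**2 > 1:
                continue
            du = u * a_px
            dv = v * b_px
            dr = du * ca - dv * sa
            dc = du * sa + dv * ca
            if all(
                (dr - p[0]) ** 2 + (dc - p[1]) ** 2 >= min_spacing_px**2 for p in pts
            ):
                pts.append((dr, dc))
                break
        else:  # crowded synapse: accept closest-legal point anyway
            pts.append((rng.uniform(-a_px, a_px), rng.uniform(-b_px, b_px)))
    return pts


def _simulate_sted_field(config, subject, field_index):
    m = config.sted
    nc = config.nanoclusters
    rng = _rng(config.seed, 20, int(subject.name), field_index)
    px_um = m.pixel_size_nm / 1000.0
    shape = (
        int(round(m.field_height_um / px_um)),
        int(round(m.field_width_um / px_um)),
    )
    n = rng.poisson(m.density_per_um2 * m.field_width_um * m.field_height_um)
    margin_um = 0.5  # keep templates clear of the border at STED scale
    xy = _place_points(
        rng,
        n,
        m.field_width_um,
        m.field_height_um,
        m.min_separation_um,
        margin_um=margin_um,
    )
    n = len(xy)
    r = xy[:, 1] / px_um
    c = xy[:, 0] / px_um
    areas, ar, theta, en_face = _sample_geometry(rng, n, m)
    sig_maj, sig_min = _sigmas_px(areas, ar, m.pixel_size_nm)
    psd_int = (
        m.psd95_mean_intensity_au
        * (areas / (px_um**2))
        * rng.lognormal(0.0, m.intensity_sigma_log, n)
        * subject["subject_gain"]
    )
    psd = np.zeros(shape)
    munc = np.zeros(shape)
    counts = np.zeros(n, dtype=int)
    csig = nc.cluster_sigma_nm / m.pixel_size_nm
    spacing_px = nc.min_spacing_nm / m.pixel_size_nm
    offset_px = nc.sideview_offset_nm / m.pixel_size_nm
    for i in range(n):
        _render_gaussian(psd, r[i], c[i], sig_maj[i], sig_min[i], theta[i], psd_int[i])
        k = int(round(nc.per_um2 * areas[i])) + int(rng.poisson(nc.jitter) - nc.jitter)
        k = max(1, k)
        counts[i] = k
        # half-max ellipse semi-axes of the synapse template
        a_px = sig_maj[i] * np.sqrt(2 * np.log(2))
        b_px = sig_min[i] * np.sqrt(2 * np.log(2))
        if en_face[i]:
            pts = _place_clusters(rng, k, a_px, b_px, theta[i], spacing_px)
            base_r, base_c = r[i], c[i]
        else:
            # clusters along the active zone, offset presynaptically
            pts = _place_clusters(rng, k, a_px, max(b_px * 0.3, 0.5), theta[i], spacing_px)
            base_r = r[i] - offset_px * np.sin(theta[i])
            base_c = c[i] + offset_px * np.cos(theta[i])
        for dr, dc in pts:
            _render_gaussian(
                munc,
                base_r + dr,
                base_c + dc,
                csig,
                csig,
                0.0,
                nc.cluster_integral_au * rng.lognormal(0.0, 0.2),
            )
    field_id = f"{subject.subject_id}_STED_{field_index:02d}"
    meta = dict(
        pixel_size_nm=m.pixel_size_nm,
        field_id=field_id,
        subject_id=subject.subject_id,
        condition=subject.condition,
    )
    planes = {
        "PSD95": ImagePlane(
            _apply_noise(rng, psd, m.noise, m.pixel_size_nm), channel="PSD95", **meta
        ),
        "Munc13-1": ImagePlane(
            _apply_noise(rng, munc, m.noise, m.pixel_size_nm),
            channel="Munc13-1",
            **meta,
        ),
    }
    truth = pd.DataFrame(
        {
            "object": "synapse",
            "subject_id": subject.subject_id,
            "condition": subject.condition,
            "field_id": field_id,
            "kind": "sted",
            "reaction": 0,
            "x_um": c * px_um,
            "y_um": r * px_um,
            "area_um2": areas,
            "aspect_ratio": ar,
            "view": np.where(en_face, "en_face", "side_view"),
            "psd95_integral": psd_int,
            "nanocluster_count": counts,
        }
    )
    return planes, truth


def _polyline_mask(polyline_um, shape, pixel_size_nm, width_um):
    """Rasterize a polyline (µm, (x, y)) into a tube mask of the given width."""
    px_um = pixel_size_nm / 1000.0
    raster = np.zeros(shape, dtype=bool)
    pl = np.asarray(polyline_um) / px_um  # now in px, (col, row)
    for (x0, y0), (x1, y1) in zip(pl[:-1], pl[1:]):
        length = np.hypot(x1 - x0, y1 - y0)
        steps = max(int(np.ceil(length * 2)), 1)
        t = np.linspace(0, 1, steps + 1)
        cs = np.clip(np.round(x0 + t * (x1 - x0)).astype(int), 0, shape[1] - 1)
        rs = np.clip(np.round(y0 + t * (y1 - y0)).astype(int), 0, shape[0] - 1)
        raster[rs, cs] = True
    radius = max(int(round(width_um / 2.0 / px_um)), 1)
    from .imageops import disk_footprint

    return ndimage.binary_dilation(raster, structure=disk_footprint(radius))


def _random_polyline(rng, w_um, h_um, n_vertices=3):
    """A gently bending line spanning a good fraction of the field."""
    margin = 2.0
    x0, y0 = rng.uniform(margin, w_um - margin), rng.uniform(margin, h_um - margin)
    angle = rng.uniform(0, 2 * np.pi)
    length = rng.uniform(0.6, 0.9) * min(w_um, h_um)
    pts = [(x0, y0)]
    seg = length / (n_vertices - 1)
    for _ in range(n_vertices - 1):
        angle += rng.normal(0, 0.3)
        x0 = float(np.clip(x0 + seg * np.cos(angle), margin, w_um - margin))
        y0 = float(np.clip(y0 + seg * np.sin(angle), margin, h_um - margin))
        pts.append((x0, y0))
    return np.array(pts)


def _simulate_pv_dendrite_field(config, subject, field_index):
    from .segmentation import DendriteAnnotation

    m = config.pv_dendrite
    rng = _rng(config.seed, 30, int(subject.name), field_index)
    px_um = m.pixel_size_nm / 1000.0
    shape = (
        int(round(m.field_height_um / px_um)),
        int(round(m.field_width_um / px_um)),
    )
    cond = "control" if config.null_cohort else subject.condition
    mult_rng = _rng(config.seed, 31, int(subject.name))
    multipliers = {
        ch: max(
            0.2,
            mult_rng.normal(
                m.pv_multiplier_mean[cond][ch], m.pv_multiplier_sd[cond][ch]
            ),
        )
        for ch in m.ratio_base
    }

    # non-PV population
    n_bg = rng.poisson(m.density_per_um2 * m.field_width_um * m.field_height_um)
    xy_bg = _place_points(
        rng, n_bg, m.field_width_um, m.field_height_um, m.min_separation_um
    )
    xs = xy_bg[:, 0]
    ys = xy_bg[:, 1]
    on_pv = np.zeros(len(xy_bg), dtype=bool)

    # PV dendrites and their synapses
    dendrites = []
    pv_canvas = np.zeros(shape)
    for d in range(m.dendrites_per_field + m.myelinated_axons_per_field):
        is_axon = d >= m.dendrites_per_field
        pl = _random_polyline(rng, m.field_width_um, m.field_height_um)
        width = m.dendrite_width_um * (1.8 if is_axon else 1.0)
        mask = _polyline_mask(pl, shape, m.pixel_size_nm, width)
        did = f"{subject.subject_id}_F{field_index}_D{d}" + ("_ax" if is_axon else "")
        dendrites.append(
            DendriteAnnotation(
                dendrite_id=did,
                polyline_um=pl,
                mask=mask,
                pv_positive=True,
                is_myelinated_axon=is_axon,
                subject_id=subject.subject_id,
                field_id=f"{subject.subject_id}_PV_{field_index:02d}",
            )
        )
        pv_canvas[mask] += m.psd95_integral_nonpv_au * (2.0 if is_axon else 1.0)
        if is_axon:
            continue
        # synapses along the dendrite at the configured linear density
        seglens = np.sqrt((np.diff(pl, axis=0) ** 2).sum(axis=1))
        total = seglens.sum()
        k = rng.poisson(m.synapses_per_um * total)
        s = np.sort(rng.uniform(0, total, k))
        cum = np.concatenate([[0], np.cumsum(seglens)])
        for si in s:
            j = min(np.searchsorted(cum, si, side="right") - 1, len(seglens) - 1)
            frac = (si - cum[j]) / seglens[j]
            p = pl[j] + frac * (pl[j + 1] - pl[j])
            jitter = rng.normal(0, 0.15, 2)
            xs = np.append(xs, p[0] + jitter[0])
            ys = np.append(ys, p[1] + jitter[1])
            on_pv = np.append(on_pv, True)

    n = len(xs)
    keep = (xs >= 0) & (xs < m.field_width_um) & (ys >= 0) & (ys < m.field_height_um)
    # non-PV synapses cannot occupy the space filled by a PV dendrite
    occupied = np.zeros(shape, dtype=bool)
    for d in dendrites:
        if not d.is_myelinated_axon:
            occupied |= d.mask
    # pad by a synapse radius so off-dendrite masks cannot touch the tube
    from .imageops import disk_footprint

    occupied = ndimage.binary_dilation(
        occupied, structure=disk_footprint(int(round(0.4 / px_um)))
    )
    rr_idx = np.clip((ys / px_um).astype(int), 0, shape[0] - 1)
    cc_idx = np.clip((xs / px_um).astype(int), 0, shape[1] - 1)
    keep &= on_pv | ~occupied[rr_idx, cc_idx]
    xs, ys, on_pv = xs[keep], ys[keep], on_pv[keep]
    n = len(xs)
    mu_area = np.log(m.area_mean_um2) - 0.5 * m.area_sigma_log**2
    areas = np.clip(rng.lognormal(mu_area, m.area_sigma_log, n), m.area_min_um2, None)
    ar = rng.uniform(1.0, 2.0, n)
    theta = rng.uniform(0, np.pi, n)
    sig_maj, sig_min = _sigmas_px(areas, ar, m.pixel_size_nm)
    base_int = m.psd95_integral_nonpv_au * rng.lognormal(0.0, m.integral_sigma_log, n)
    psd_int = np.where(on_pv, base_int * m.psd95_pv_scale, base_int)
    ratios = {}
    for ch, base in m.ratio_base.items():
        rch = base * rng.lognormal(0.0, m.ratio_sigma_log, n)
        rch = np.where(on_pv, rch * multipliers[ch], rch)
        ratios[ch] = rch

    canvases = {"PSD95": np.zeros(shape)}
    for ch in m.ratio_base:
        canvases[ch] = np.zeros(shape)
    rpix = ys / px_um
    cpix = xs / px_um
    for i in range(n):
        _render_gaussian(
            canvases["PSD95"], rpix[i], cpix[i], sig_maj[i], sig_min[i], theta[i], psd_int[i]
        )
        for ch in m.ratio_base:
            _render_gaussian(
                canvases[ch],
                rpix[i],
                cpix[i],
                sig_maj[i],
                sig_min[i],
                theta[i],
                ratios[ch][i] * psd_int[i],
            )
    field_id = f"{subject.subject_id}_PV_{field_index:02d}"
    meta = dict(
        pixel_size_nm=m.pixel_size_nm,
        field_id=field_id,
        subject_id=subject.subject_id,
        condition=subject.condition,
    )
    pv_blur = ndimage.gaussian_filter(pv_canvas, 5.0, mode="reflect")
    planes = {
        name: ImagePlane(
            _apply_noise(rng, canvas, m.noise, m.pixel_size_nm), channel=name, **meta
        )
        for name, canvas in canvases.items()
    }
    planes["PV"] = ImagePlane(
        _apply_noise(rng, pv_blur, m.noise, m.pixel_size_nm), channel="PV", **meta
    )
    truth = pd.DataFrame(
        {
            "object": "synapse",
            "subject_id": subject.subject_id,
            "condition": subject.condition,
            "field_id": field_id,
            "kind": "pv_dendrite",
            "reaction": 0,
            "x_um": xs,
            "y_um": ys,
            "area_um2": areas,
            "aspect_ratio": ar,
            "view": "en_face",
            "on_pv_dendrite": on_pv,
            "psd95_integral": psd_int,
            **{f"{ch}_ratio": ratios[ch] for ch in m.ratio_base},
        }
    )
    return planes, truth, dendrites, multipliers


def _simulate_pv_soma_field(config, subject, field_index):
    m = config.pv_soma
    rng = _rng(config.seed, 40, int(subject.name), field_index)
    px_um = m.pixel_size_nm / 1000.0
    shape = (
        int(round(m.field_height_um / px_um)),
        int(round(m.field_width_um / px_um)),
    )
    cond = "control" if config.null_cohort else subject.condition
    subj_rng = _rng(config.seed, 41, int(subject.name))
    subj_mean = max(
        100.0,
        subj_rng.normal(
            m.somatic_intensity_mean[cond], m.somatic_intensity_subject_sd[cond]
        ),
    )
    canvas = np.zeros(shape)
    # PV+ neuropil processes (excluded from the background mask by thresholding)
    for _ in range(m.processes_per_field):
        pl = _random_polyline(rng, m.field_width_um, m.field_height_um)
        mask = _polyline_mask(pl, shape, m.pixel_size_nm, 1.0)
        canvas[mask] += m.process_amplitude_au
    canvas += m.neuropil_au * _smooth_unit_field(rng, shape, 10.0) * 0.1
    canvas = np.clip(canvas, 0, None)
    rows = []
    centers = []
    for s in range(m.somata_per_field):
        radius_um = max(3.0, rng.normal(m.soma_radius_um_mean, m.soma_radius_um_sd))
        rad_px = radius_um / px_um
        for _try in range(100):
            r0 = rng.uniform(rad_px + 2, shape[0] - rad_px - 2)
            c0 = rng.uniform(rad_px + 2, shape[1] - rad_px - 2)
            if all(
                (r0 - rr) ** 2 + (c0 - cc) ** 2 > (2.4 * rad_px) ** 2
                for rr, cc in centers
            ):
                break
        centers.append((r0, c0))
        intensity = subj_mean * rng.lognormal(0.0, m.soma_sigma_log)
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        disc = ((rr - r0) ** 2 + (cc - c0) ** 2) <= rad_px**2
        canvas[disc] += intensity
        rows.append(
            {
                "object": "soma",
                "subject_id": subject.subject_id,
                "condition": subject.condition,
                "field_id": f"{subject.subject_id}_SOMA_{field_index:02d}",
                "kind": "pv_soma",
                "x_um": c0 * px_um,
                "y_um": r0 * px_um,
                "radius_um": radius_um,
                "somatic_intensity_au": intensity,
            }
        )
    canvas = ndimage.gaussian_filter(canvas, 1.0, mode="reflect")
    field_id = f"{subject.subject_id}_SOMA_{field_index:02d}"
    plane = ImagePlane(
        _apply_noise(rng, canvas, m.noise, m.pixel_size_nm),
        pixel_size_nm=m.pixel_size_nm,
        channel="PV",
        field_id=field_id,
        subject_id=subject.subject_id,
        condition=subject.condition,
    )
    return {"PV": plane}, pd.DataFrame(rows)


def simulate_field(
    config: GeneratorConfig,
    subject: pd.Series,
    field_index: int = 0,
    kind: str = "layer2",
    reaction: int = 0,
    paired_channel: str = "GluA2",
):
    """Render one synthetic field of the requested kind.

    ``subject`` is a row of :func:`subject_table` (its positional index seeds
    the per-subject random stream).  Returns ``(planes, truth)`` for
    ``layer2``/``sted``/``pv_soma`` and ``(planes, truth, dendrites,
    multipliers)`` for ``pv_dendrite``.
    """
    if kind == "layer2":
        return _simulate_layer2_field(config, subject, field_index, reaction, paired_channel)
    if kind == "sted":
        return _simulate_sted_field(config, subject, field_index)
    if kind == "pv_dendrite":
        return _simulate_pv_dendrite_field(config, subject, field_index)
    if kind == "pv_soma":
        return _simulate_pv_soma_field(config, subject, field_index)
    raise ValueError(f"unknown field kind {kind!r}")


# ---------------------------------------------------------------------------
# subject-summary fast path (calibration / power suites)
# ---------------------------------------------------------------------------

DEFAULT_SUMMARY_MEASURES = {
    # measure: (control mean, control SD, schizophrenia mean, schizophrenia SD)
    "density_per_um2": (0.15, 0.02, 0.18, 0.05),
    "mean_nnd_um": (1.13, 0.05, 1.09, 0.09),
    "area_um2": (0.256, 0.004, 0.255, 0.005),
    "nanocluster_count": (3.4, 0.5, 3.3, 0.5),
    "ampar_pv_normalized": (1.72, 0.14, 1.54, 0.25),
    "glun1_pv_normalized": (1.60, 0.15, 1.30, 0.19),
    "glun2b_pv_normalized": (1.72, 0.25, 1.43, 0.21),
}


def simulate_subject_summaries(
    rng: np.random.Generator,
    n_control: int = 9,
    n_schizophrenia: int = 6,
    measures: dict | None = None,
    null: bool = False,
) -> pd.DataFrame:
    """Draw per-subject measure means directly from the cohort model.

    This is the generator's statistical layer without image rendering: each
    subject's mean is Normal(group mean, subject SD).  With ``null=True`` the
    schizophrenia group uses the control distribution (type-I-error suites).
    """
    measures = measures or DEFAULT_SUMMARY_MEASURES
    rows = []
    for i in range(n_control + n_schizophrenia):
        cond = "control" if i < n_control else "schizophrenia"
        row = {"subject_id": f"S{i:02d}", "condition": cond}
        for name, (mc, sc, ms, ss) in measures.items():
            if cond == "control" or null:
                row[name] = rng.normal(mc, sc)
            else:
                row[name] = rng.normal(ms, ss)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic side-view fixture
# ---------------------------------------------------------------------------

_SIDEVIEW_OFFSETS_NM = {
    "PSD95": 0.0,
    "GluA2": 0.0,
    "Munc13-1": 40.0,
    "Bassoon": 100.0,
    "VGLUT1": 220.0,
}


def sideview_truth() -> pd.DataFrame:
    """Ground-truth channel offsets (nm) of the side-view synapse fixture."""
    return pd.DataFrame(
        {
            "channel": list(_SIDEVIEW_OFFSETS_NM),
            "offset_nm": list(_SIDEVIEW_OFFSETS_NM.values()),
        }
    )


def make_sideview_fixture() -> dict[str, ImagePlane]:
    """Deterministic multi-channel side-view synapse at 20 nm/px.

    Each channel is a vertical bar whose horizontal Gaussian profile is
    laterally shifted from the PSD-95 bar by the fixture truth offsets
    (integer multiples of the 20 nm pixel grid).  Noiseless and fully
    reproducible: repeated calls return identical arrays.
    """
    px_nm = 20.0
    shape = (128, 160)
    row0, col0 = 64.0, 70.0
    planes = {}
    for channel, off_nm in _SIDEVIEW_OFFSETS_NM.items():
        canvas = np.zeros(shape)
        _render_gaussian(
            canvas,
            row0,
            col0 + off_nm / px_nm,
            sigma_major_px=12.0,  # along the bar (rows)
            sigma_minor_px=2.0,  # across the cleft (cols)
            theta=0.0,
            integral=10000.0,
        )
        planes[channel] = ImagePlane(
            canvas,
            pixel_size_nm=px_nm,
            channel=channel,
            field_id="sideview_fixture",
            subject_id="fixture",
            condition="control",
        )
    return planes


# ---------------------------------------------------------------------------
# truth-detection matching
# ---------------------------------------------------------------------------

def match_detections(
    truth_xy_um: np.ndarray,
    detected_xy_um: np.ndarray,
    gate_um: float = 0.2,
) -> pd.DataFrame:
    """Greedy nearest-centroid matching of planted objects to detections.

    Each detection matches at most one truth object within ``gate_um``
    (closest pairs first).  Returns a table with ``truth_index``,
    ``detected_index`` and ``distance_um``.
    """
    truth_xy_um = np.asarray(truth_xy_um, dtype=float)
    detected_xy_um = np.asarray(detected_xy_um, dtype=float)
    if len(truth_xy_um) == 0 or len(detected_xy_um) == 0:
        return pd.DataFrame(columns=["truth_index", "detected_index", "distance_um"])
    from scipy.spatial import cKDTree

    tree = cKDTree(detected_xy_um)
    dists, idxs = tree.query(truth_xy_um, k=1, distance_upper_bound=gate_um)
    order = np.argsort(dists)
    used = set()
    rows = []
    for ti in order:
        if not np.isfinite(dists[ti]):
            continue
        di = int(idxs[ti])
        if di in used:
            # nearest detection taken; try the next within the gate
            cand = tree.query_ball_point(truth_xy_um[ti], gate_um)
            cand = [c for c in cand if c not in used]
            if not cand:
                continue
            di = min(
                cand,
                key=lambda c: np.linalg.norm(detected_xy_um[c] - truth_xy_um[ti]),
            )
        used.add(di)
        rows.append(
            {
                "truth_index": int(ti),
                "detected_index": di,
                "distance_um": float(
                    np.linalg.norm(detected_xy_um[di] - truth_xy_um[ti])
                ),
            }
        )
    return pd.DataFrame(rows, columns=["truth_index", "detected_index", "distance_um"])
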