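"""Low-level image operators the quantification workflow is built from.

Blur, histogram thresholds, prominence-based maxima detection with
watershed particle splitting, rolling-ball background estimation, mask
dilation and translation-only registration.  All operators are deterministic
and use reflective border handling unless stated otherwise.

The maxima detector reimplements the classic particle-splitting primitive of
interactive image analysis ("Find Maxima" with a noise tolerance): a local
maximum is accepted iff its topological persistence exceeds the tolerance,
i.e. one cannot reach a higher peak without descending more than
``prominence`` below it.  Equal-valued plateaus count as a single maximum
reported at the plateau centroid; maxima whose peak plateau touches the image
border are discarded.
"""

from __future__ import annotations

import warnings

import numpy as np
from numba import njit
from scipy import ndimage
from skimage import filters as _skfilters
from skimage.segmentation import watershed as _watershed

from .core import (
    DegenerateInputError,
    ImagePlane,
    MaximaResult,
    ParameterError,
    as_bool_mask,
)

__all__ = [
    "gaussian_blur",
    "threshold_otsu",
    "threshold_triangle",
    "threshold_mean",
    "find_maxima",
    "rolling_ball_background",
    "ball_structuring_element",
    "disk_footprint",
    "dilate_mask",
    "register_translation",
]


# ---------------------------------------------------------------------------
# blur and thresholds
# ---------------------------------------------------------------------------

def gaussian_blur(plane: ImagePlane, radius_px: float) -> ImagePlane:
    """Gaussian filter with sigma ``radius_px`` (kernel truncated at 4 sigma).

    Linear, intensity conserving (reflective borders).  The "radius" naming
    follows the interactive-tool convention the workflow parameters refer to.
    """
    if not radius_px > 0:
        raise ParameterError("radius_px must be > 0")
    out = ndimage.gaussian_filter(
        plane.pixels, sigma=radius_px, mode="reflect", truncate=4.0
    )
    return plane.with_pixels(out)


def _check_nonconstant(px: np.ndarray) -> None:
    if px.max() == px.min():
        raise DegenerateInputError("constant image has no threshold")


def threshold_otsu(plane: ImagePlane) -> float:
    """Otsu threshold on a 256-bin histogram spanning [min, max].

    Masks derived from it take pixels strictly above the returned value.
    """
    _check_nonconstant(plane.pixels)
    return float(_skfilters.threshold_otsu(plane.pixels, nbins=256))


def threshold_triangle(plane: ImagePlane) -> float:
    """Triangle-method threshold (max distance from the peak-tail chord)."""
    _check_nonconstant(plane.pixels)
    return float(_skfilters.threshold_triangle(plane.pixels, nbins=256))


def threshold_mean(plane: ImagePlane) -> float:
    """Arithmetic mean of all pixels."""
    return float(plane.pixels.mean())


# ---------------------------------------------------------------------------
# persistence-based Find Maxima
# ---------------------------------------------------------------------------

@njit(cache=False)
def _uf_find(parent, i):  # pragma: no cover - numba
    root = i
    while parent[root] != root:
        root = parent[root]
    while parent[i] != root:
        nxt = parent[i]
        parent[i] = root
        i = nxt
    return root


@njit(cache=False)
def _persistence_maxima(flat, order, nrows, ncols, prominence, floor):  # pragma: no cover
    """Union-find sweep over pixels in decreasing intensity order.

    Returns arrays (point_row, point_col, n_points).  A component's peak
    region (connected plateau at its maximum value) is tracked for centroid
    and border bookkeeping; a component killed at a merge is reported iff its
    persistence (peak - merge level) exceeds ``prominence``; surviving
    components are always reported.  Border-touching peak plateaus are
    discarded.
    """
    n = flat.size
    parent = np.full(n, -1, dtype=np.int64)
    peak_val = np.zeros(n, dtype=np.float64)
    sum_r = np.zeros(n, dtype=np.float64)
    sum_c = np.zeros(n, dtype=np.float64)
    cnt = np.zeros(n, dtype=np.int64)
    border = np.zeros(n, dtype=np.uint8)
    created = np.zeros(n, dtype=np.int64)
    first_px = np.zeros(n, dtype=np.int64)

    out_r = np.empty(n, dtype=np.int64)
    out_c = np.empty(n, dtype=np.int64)
    nout = 0
    ncreated = 0

    roots = np.empty(8, dtype=np.int64)
    for oi in range(order.size):
        p = order[oi]
        v = flat[p]
        r = p // ncols
        c = p % ncols
        onb = (r == 0) or (c == 0) or (r == nrows - 1) or (c == ncols - 1)
        nroots = 0
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                rr = r + dr
                cc = c + dc
                if rr < 0 or cc < 0 or rr >= nrows or cc >= ncols:
                    continue
                q = rr * ncols + cc
                if parent[q] == -1:
                    continue
                rq = _uf_find(parent, q)
                new = True
                for k in range(nroots):
                    if roots[k] == rq:
                        new = False
                        break
                if new:
                    roots[nroots] = rq
                    nroots += 1
        if nroots == 0:
            parent[p] = p
            peak_val[p] = v
            sum_r[p] = r
            sum_c[p] = c
            cnt[p] = 1
            border[p] = 1 if onb else 0
            created[p] = ncreated
            first_px[p] = p
            ncreated += 1
            continue
        # survivor: highest peak; ties -> earliest created
        s = roots[0]
        for k in range(1, nroots):
            t = roots[k]
            if peak_val[t] > peak_val[s] or (
                peak_val[t] == peak_val[s] and created[t] < created[s]
            ):
                s = t
        parent[p] = s
        if v == peak_val[s]:
            # plateau growth of the surviving component's peak region
            sum_r[s] += r
            sum_c[s] += c
            cnt[s] += 1
            if onb:
                border[s] = 1
        for k in range(nroots):
            t = roots[k]
            if t == s:
                continue
            pers = peak_val[t] - v
            if pers > prominence and border[t] == 0:
                cr = int(np.floor(sum_r[t] / cnt[t] + 0.5))
                cc2 = int(np.floor(sum_c[t] / cnt[t] + 0.5))
                if flat[cr * ncols + cc2] != peak_val[t]:
                    fp = first_px[t]
                    cr = fp // ncols
                    cc2 = fp % ncols
                out_r[nout] = cr
                out_c[nout] = cc2
                nout += 1
            if peak_val[t] == peak_val[s] and v == peak_val[s]:
                # plateau-with-plateau merge at peak level: one joint plateau
                sum_r[s] += sum_r[t]
                sum_c[s] += sum_c[t]
                cnt[s] += cnt[t]
                if border[t] == 1:
                    border[s] = 1
            parent[t] = s
    # surviving roots: persistence is bounded below by the support floor
    for i in range(n):
        if parent[i] == i:
            if border[i] == 0 and peak_val[i] - floor > prominence:
                cr = int(np.floor(sum_r[i] / cnt[i] + 0.5))
                cc2 = int(np.floor(sum_c[i] / cnt[i] + 0.5))
                if flat[cr * ncols + cc2] != peak_val[i]:
                    fp = first_px[i]
                    cr = fp // ncols
                    cc2 = fp % ncols
                out_r[nout] = cr
                out_c[nout] = cc2
                nout += 1
    return out_r[:nout], out_c[:nout]


def find_maxima(
    plane: ImagePlane,
    prominence: float,
    mode: str = "points",
    floor: float | None = None,
) -> MaximaResult:
    """Detect intensity maxima with a noise tolerance (``prominence``).

    Parameters
    ----------
    plane
        Input channel.
    prominence
        Noise tolerance: a maximum is accepted iff no higher peak is
        reachable without descending more than this amount below it
        (topological persistence strictly greater than ``prominence``).
    mode
        ``"points"`` returns maxima coordinates only; ``"segmented"``
        additionally floods every above-``floor`` pixel downhill to exactly
        one maximum (segmented-particles output), with 8-connectivity.
    floor
        Acceptance threshold: persistence is computed on the full image, but
        only maxima whose peak exceeds ``floor`` are reported (the globally
        surviving peak additionally needs ``peak - floor > prominence``, so a
        featureless above-floor field reports nothing).  In segmented mode
        ``floor`` also bounds the flooded support.  Default: no floor.
    """
    if prominence < 0:
        raise ParameterError("prominence must be >= 0")
    if mode not in ("points", "segmented"):
        raise ParameterError(f"unknown mode {mode!r}")
    px = plane.pixels
    flat = px.ravel()
    order = np.argsort(-flat, kind="stable").astype(np.int64)
    kernel_floor = -np.inf if floor is None else float(floor)
    rr, cc = _persistence_maxima(
        flat.astype(np.float64),
        order,
        px.shape[0],
        px.shape[1],
        float(prominence),
        kernel_floor,
    )
    pts = np.column_stack([rr, cc]).astype(np.int64)
    if floor is not None and len(pts):
        pts = pts[px[pts[:, 0], pts[:, 1]] > floor]
    # deterministic row-major ordering of the reported points
    if len(pts):
        pts = pts[np.lexsort((pts[:, 1], pts[:, 0]))]
    segments = None
    if mode == "segmented":
        segments = np.zeros(px.shape, dtype=np.int32)
        if len(pts):
            markers = np.zeros(px.shape, dtype=np.int32)
            markers[pts[:, 0], pts[:, 1]] = np.arange(1, len(pts) + 1)
            mask = np.ones(px.shape, dtype=bool) if floor is None else (px > floor)
            segments = _watershed(-px, markers=markers, mask=mask, connectivity=2)
    return MaximaResult(points=pts, prominence=float(prominence), segments=segments)


# ---------------------------------------------------------------------------
# rolling ball, dilation, registration
# ---------------------------------------------------------------------------

def ball_structuring_element(radius_px: float) -> np.ndarray:
    """Spherical-cap structuring element: height sqrt(r^2 - d^2) inside radius r.

    Pixels outside the radius are -inf (excluded from the grey morphology).
    """
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d2 = yy**2 + xx**2
    struct = np.full(d2.shape, -np.inf)
    inside = d2 <= radius_px**2
    struct[inside] = np.sqrt(radius_px**2 - d2[inside])
    return struct


def rolling_ball_background(
    plane: ImagePlane, radius_px: float, presmooth_px: int = 0
) -> ImagePlane:
    """Background estimate by rolling a ball of the given radius under the surface.

    Implemented as grayscale opening with a spherical-cap structuring element
    (no pre-downsampling).  On shot-noise-limited images the bare opening hugs
    noise minima and underestimates the background; ``presmooth_px`` > 0
    applies a small mean filter (side ``2*presmooth_px + 1``) before rolling,
    as interactive implementations do, and is clipped back below the original
    image.  Guarantees background <= image everywhere and exact reproduction
    of constant images.
    """
    if radius_px < 1:
        raise ParameterError("radius_px must be >= 1")
    px = plane.pixels
    if presmooth_px > 0:
        px = ndimage.uniform_filter(px, size=2 * int(presmooth_px) + 1, mode="reflect")
    struct = ball_structuring_element(radius_px)
    footprint = np.isfinite(struct)
    height = np.where(footprint, struct, 0.0)
    eroded = ndimage.grey_erosion(
        px, footprint=footprint, structure=height, mode="reflect"
    )
    opened = ndimage.grey_dilation(
        eroded, footprint=footprint, structure=height, mode="reflect"
    )
    # clip: the smoothed opening (or float rounding) may overshoot the raw
    # image, and the opening can undershoot zero on dark noisy fields
    background = np.clip(np.minimum(opened, plane.pixels), 0.0, None)
    return plane.with_pixels(background)


def disk_footprint(radius_px: int) -> np.ndarray:
    """Boolean disc of Euclidean radius ``radius_px``."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= r**2


def dilate_mask(mask: np.ndarray, px: int) -> np.ndarray:
    """Binary dilation by a Euclidean disc of radius ``px``."""
    if px < 1:
        raise ParameterError("px must be >= 1")
    m = as_bool_mask(mask)
    if not m.any():
        return m.copy()
    return ndimage.binary_dilation(m, structure=disk_footprint(px))


def register_translation(
    reference: ImagePlane, moving: ImagePlane
) -> tuple[int, int]:
    """Integer (dy, dx) shift maximizing the cross-correlation of the planes.

    ``moving`` is modelled as ``reference`` translated by (dy, dx); applying
    the negative shift to ``moving`` maximizes its overlap with ``reference``.
    Featureless (constant) inputs return (0, 0) with a warning.
    """
    a = reference.pixels
    b = moving.pixels
    if a.shape != b.shape:
        raise ParameterError("reference and moving must have the same shape")
    a0 = a - a.mean()
    b0 = b - b.mean()
    if not a0.any() or not b0.any():
        warnings.warn("featureless image in register_translation; returning (0, 0)")
        return (0, 0)
    cc = np.fft.ifft2(np.fft.fft2(b0) * np.conj(np.fft.fft2(a0))).real
    dy, dx = np.unravel_index(np.argmax(cc), cc.shape)
    if dy > a.shape[0] // 2:
        dy -= a.shape[0]
    if dx > a.shape[1] // 2:
        dx -= a.shape[1]
    return (int(dy), int(dx))
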