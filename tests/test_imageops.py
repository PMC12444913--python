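"""Low-level operator tests against independent brute-force oracles."""

import numpy as np
import pytest
from scipy import ndimage

from synquant.core import DegenerateInputError, ImagePlane, ParameterError
from synquant.imageops import (
    ball_structuring_element,
    dilate_mask,
    find_maxima,
    gaussian_blur,
    register_translation,
    rolling_ball_background,
    threshold_mean,
    threshold_otsu,
    threshold_triangle,
)
from conftest import make_plane


# ---------------------------------------------------------------------------
# gaussian blur
# ---------------------------------------------------------------------------

class TestGaussianBlur:
    def test_constant_is_fixed_point(self):
        p = make_plane(np.full((20, 30), 5.0))
        out = gaussian_blur(p, 2.0)
        assert np.allclose(out.pixels, 5.0)

    def test_impulse_kernel_is_normalized(self):
        z = np.zeros((33, 33))
        z[16, 16] = 1.0
        out = gaussian_blur(make_plane(z), 2.0)
        assert abs(out.pixels.sum() - 1.0) < 1e-6

    def test_matches_dense_convolution_oracle(self, rng):
        img = rng.uniform(0, 100, (32, 32))
        sigma = 2.0
        half = int(4 * sigma)
        x = np.arange(-half, half + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        kern = np.outer(k1, k1)
        # half-sample symmetric padding (the edge value is repeated)
        padded = np.pad(img, half, mode="symmetric")
        oracle = np.empty_like(img)
        for i in range(32):
            for j in range(32):
                oracle[i, j] = (padded[i : i + 2 * half + 1, j : j + 2 * half + 1] * kern).sum()
        out = gaussian_blur(make_plane(img), sigma)
        assert np.abs(out.pixels - oracle).max() < 1e-6

    def test_linearity(self, rng):
        a = rng.uniform(0, 10, (16, 16))
        b = rng.uniform(0, 10, (16, 16))
        lhs = gaussian_blur(make_plane(2 * a + 3 * b), 2.0).pixels
        rhs = 2 * gaussian_blur(make_plane(a), 2.0).pixels + 3 * gaussian_blur(
            make_plane(b), 2.0
        ).pixels
        assert np.abs(lhs - rhs).max() < 1e-6

    def test_intensity_conserved(self, rng):
        img = rng.uniform(0, 50, (40, 25))
        out = gaussian_blur(make_plane(img), 2.0)
        assert abs(out.pixels.sum() / img.sum() - 1) < 1e-6

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ParameterError):
            gaussian_blur(make_plane(np.ones((5, 5))), 0.0)


# ---------------------------------------------------------------------------
# histogram thresholds
# ---------------------------------------------------------------------------

def _otsu_exhaustive(img: np.ndarray) -> float:
    """256-bin exhaustive scan maximizing between-class variance."""
    hist, edges = np.histogram(img.ravel(), bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    best, best_t = -1.0, centers[0]
    for t in range(1, 256):
        w0 = hist[:t].sum()
        w1 = hist[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:t] * centers[:t]).sum() / w0
        m1 = (hist[t:] * centers[t:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best:
            best, best_t = v, centers[t - 1]
    return best_t


class TestThresholds:
    def test_otsu_separates_bimodal(self):
        img = np.concatenate([np.zeros(50), np.full(50, 200.0)]).reshape(10, 10)
        t = threshold_otsu(make_plane(img))
        assert 0 < t < 200
        assert ((img > t) == (img == 200)).all()

    def test_otsu_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            threshold_otsu(make_plane(np.full((8, 8), 3.0)))

    def test_otsu_matches_exhaustive_scan(self, rng):
        img = np.concatenate(
            [rng.normal(40, 8, 600), rng.normal(160, 20, 400)]
        ).clip(0).reshape(40, 25)
        t = threshold_otsu(make_plane(img))
        t_oracle = _otsu_exhaustive(img)
        binw = (img.max() - img.min()) / 256
        assert abs(t - t_oracle) <= binw

    def test_triangle_between_peak_and_tail(self, rng):
        img = np.concatenate(
            [rng.normal(10, 2, 5000), rng.uniform(10, 200, 300)]
        ).clip(0).reshape(100, 53)
        t = threshold_triangle(make_plane(img))
        assert 10 < t < 200

    def test_triangle_mirror_symmetry(self, rng):
        img = np.concatenate(
            [rng.normal(30, 5, 2000), rng.uniform(30, 250, 150)]
        ).clip(0, 255).reshape(50, 43)
        t = threshold_triangle(make_plane(img))
        t_mirror = threshold_triangle(make_plane(255.0 - img))
        binw = (img.max() - img.min()) / 256
        assert abs((255.0 - t_mirror) - t) <= 2 * binw

    def test_mean_threshold(self, rng):
        assert threshold_mean(make_plane([[0.0, 10.0]])) == 5.0
        assert threshold_mean(make_plane(np.full((4, 4), 7.0))) == 7.0
        img = rng.uniform(0, 9, (13, 17))
        assert threshold_mean(make_plane(img)) == pytest.approx(img.sum() / img.size)

    def test_thresholds_permutation_invariant(self, rng):
        img = rng.uniform(0, 100, (20, 20))
        perm = rng.permutation(img.ravel()).reshape(img.shape)
        assert threshold_otsu(make_plane(img)) == threshold_otsu(make_plane(perm))
        assert threshold_triangle(make_plane(img)) == threshold_triangle(make_plane(perm))
        assert threshold_mean(make_plane(img)) == pytest.approx(
            threshold_mean(make_plane(perm))
        )


# ---------------------------------------------------------------------------
# find_maxima vs brute-force persistence oracle
# ---------------------------------------------------------------------------

def _maxima_oracle(img: np.ndarray, prominence: float) -> int:
    """Level-descent oracle: count maxima with persistence > prominence.

    Independently of the union-find implementation, lower a threshold through
    the distinct pixel values; a new connected component is born at the level
    of its peak, and dies when it merges into a component with a higher (or
    equally high but earlier-born) peak.  Reported maxima are components with
    persistence > prominence (survivors count too), excluding components
    whose peak plateau touches the border.
    """
    values = np.unique(img)[::-1]
    comp_peak: dict[int, float] = {}
    comp_born: dict[int, int] = {}
    comp_border: dict[int, bool] = {}
    alive: dict[int, set] = {}  # id -> set of pixel tuples
    accepted = 0
    next_id = 0
    for v in values:
        mask = img >= v
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        new_alive: dict[int, set] = {}
        for region_id in range(1, n + 1):
            pix = set(zip(*np.where(lab == region_id)))
            members = [cid for cid, s in alive.items() if s & pix]
            if not members:
                cid = next_id
                next_id += 1
                comp_peak[cid] = v
                comp_born[cid] = cid
                comp_border[cid] = any(
                    r in (0, img.shape[0] - 1) or c in (0, img.shape[1] - 1)
                    for r, c in pix
                )
                new_alive[cid] = pix
            else:
                # survivor: highest peak, earliest born
                members.sort(key=lambda c: (-comp_peak[c], comp_born[c]))
                surv = members[0]
                for dead in members[1:]:
                    if comp_peak[dead] - v > prominence and not comp_border[dead]:
                        accepted += 1
                # plateau growth at the peak level extends the peak plateau
                if comp_peak[surv] == v:
                    grown = pix - set().union(*(alive[m] for m in members))
                    if any(
                        r in (0, img.shape[0] - 1) or c in (0, img.shape[1] - 1)
                        for r, c in grown
                    ):
                        comp_border[surv] = True
                    if any(
                        comp_peak[m] == v and comp_border[m] for m in members[1:]
                    ):
                        comp_border[surv] = True
                new_alive[surv] = pix
        alive = new_alive
    for cid in alive:
        if not comp_border[cid]:
            accepted += 1
    return accepted


class TestFindMaxima:
    def test_two_spots_split_by_prominence(self):
        img = np.zeros((7, 11))
        img[3, 2] = 100
        img[3, 8] = 100
        img[3, 3:8] = 80
        p = make_plane(img)
        assert find_maxima(p, 10).n_maxima == 2
        assert find_maxima(p, 30).n_maxima == 1

    def test_single_blurred_spot(self):
        z = np.zeros((33, 33))
        z[16, 16] = 1.0
        blurred = gaussian_blur(make_plane(z), 2.0)
        res = find_maxima(blurred, 0.0)
        assert res.n_maxima == 1
        assert tuple(res.points[0]) == (16, 16)

    def test_constant_image_has_no_maxima(self):
        assert find_maxima(make_plane(np.full((9, 9), 5.0)), 0).n_maxima == 0

    def test_plateau_reported_once_at_centroid(self):
        img = np.zeros((9, 9))
        img[3:6, 3:6] = 7.0  # 3x3 plateau centred at (4, 4)
        res = find_maxima(make_plane(img), 1.0)
        assert res.n_maxima == 1
        assert tuple(res.points[0]) == (4, 4)

    @pytest.mark.parametrize("prominence", [0.0, 1.0, 2.5, 5.0, 10.0])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_persistence_oracle_on_small_grids(self, prominence, seed):
        r = np.random.default_rng(seed)
        img = np.round(r.uniform(0, 20, (12, 13)), 1)
        ours = find_maxima(make_plane(img), prominence).n_maxima
        assert ours == _maxima_oracle(img, prominence)

    @pytest.mark.parametrize("seed", [10, 11])
    def test_oracle_agreement_with_plateaus(self, seed):
        r = np.random.default_rng(seed)
        img = r.integers(0, 6, (10, 10)).astype(float)  # heavy ties
        for prominence in (0.0, 1.0, 2.0):
            assert (
                find_maxima(make_plane(img), prominence).n_maxima
                == _maxima_oracle(img, prominence)
            )

    def test_count_nonincreasing_in_prominence(self, rng):
        img = ndimage.gaussian_filter(rng.uniform(0, 100, (40, 40)), 1.5)
        img -= img.min()
        counts = [find_maxima(make_plane(img), p).n_maxima for p in (0, 2, 5, 10, 20)]
        assert counts == sorted(counts, reverse=True)

    def test_segments_partition_support(self, rng):
        img = ndimage.gaussian_filter(rng.uniform(0, 100, (40, 40)), 2.0)
        img -= img.min()
        floor = float(np.percentile(img, 60))
        res = find_maxima(make_plane(img), 1.0, mode="segmented", floor=floor)
        segs = res.segments
        support = img > floor
        assert (support | (segs == 0)).all()  # segments never leave the support
        for i, (r, c) in enumerate(res.points, start=1):
            assert segs[r, c] == i  # each segment holds its own maximum
        assert len(np.unique(segs[segs > 0])) == res.n_maxima
        # unlabeled support pixels only occur in connected components that
        # contain no accepted maximum (e.g. border-excluded peaks)
        comp, _ = ndimage.label(support, structure=np.ones((3, 3)))
        has_max = set(comp[res.points[:, 0], res.points[:, 1]])
        unlabeled = support & (segs == 0)
        assert not any(cid in has_max for cid in np.unique(comp[unlabeled]) if cid)

    def test_negative_prominence_rejected(self):
        with pytest.raises(ParameterError):
            find_maxima(make_plane(np.ones((4, 4))), -1.0)


# ---------------------------------------------------------------------------
# rolling ball
# ---------------------------------------------------------------------------

def _opening_oracle(img: np.ndarray, radius: float) -> np.ndarray:
    """Brute-force grayscale opening with the ball structuring element."""
    struct = ball_structuring_element(radius)
    r = struct.shape[0] // 2
    h, w = img.shape
    pad = np.pad(img, r, mode="reflect")
    eroded = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            win = pad[i : i + 2 * r + 1, j : j + 2 * r + 1]
            eroded[i, j] = np.min(win - struct)
    padded_e = np.pad(eroded, r, mode="reflect")
    opened = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            win = padded_e[i : i + 2 * r + 1, j : j + 2 * r + 1]
            opened[i, j] = np.max(win + struct)
    return np.minimum(opened, img).clip(0)


class TestRollingBall:
    def test_constant_reproduced_exactly(self):
        p = make_plane(np.full((20, 20), 10.0))
        bg = rolling_ball_background(p, 7)
        assert np.allclose(bg.pixels, 10.0)

    def test_spike_not_entered(self):
        img = np.full((30, 30), 10.0)
        img[15, 15] = 110.0
        bg = rolling_ball_background(make_plane(img), 7)
        assert abs(bg.pixels[15, 15] - 10.0) < 5.0
        assert abs((img - bg.pixels)[15, 15] - 100.0) < 5.0

    def test_matches_opening_oracle(self, rng):
        img = ndimage.gaussian_filter(rng.uniform(0, 60, (32, 32)), 3.0) + 5
        bg = rolling_ball_background(make_plane(img), 7)
        assert np.abs(bg.pixels - _opening_oracle(img, 7)).max() < 1e-6

    def test_background_below_image(self, rng):
        img = rng.uniform(0, 100, (25, 25))
        bg = rolling_ball_background(make_plane(img), 7)
        assert (bg.pixels <= img + 1e-9).all()

    def test_offset_invariance(self, rng):
        img = ndimage.gaussian_filter(rng.uniform(0, 50, (24, 24)), 2.0) + 10
        bg0 = rolling_ball_background(make_plane(img), 7).pixels
        bg1 = rolling_ball_background(make_plane(img + 5.0), 7).pixels
        assert np.abs((bg1 - bg0) - 5.0).max() < 1e-9

    def test_monotone_in_input(self, rng):
        a = rng.uniform(5, 50, (20, 20))
        b = a + rng.uniform(0, 10, (20, 20))
        bg_a = rolling_ball_background(make_plane(a), 7).pixels
        bg_b = rolling_ball_background(make_plane(b), 7).pixels
        assert (bg_b >= bg_a - 1e-9).all()


# ---------------------------------------------------------------------------
# dilation and registration
# ---------------------------------------------------------------------------

class TestDilateAndRegister:
    def test_single_pixel_becomes_disc(self):
        m = np.zeros((11, 11), dtype=bool)
        m[5, 5] = True
        out = dilate_mask(m, 3)
        yy, xx = np.mgrid[-5:6, -5:6]
        assert (out == ((yy**2 + xx**2) <= 9)).all()

    def test_empty_mask_stays_empty(self):
        assert not dilate_mask(np.zeros((8, 8), dtype=bool), 2).any()

    def test_matches_distance_transform_oracle(self, rng):
        m = rng.random((30, 30)) < 0.05
        m[0, 0] = True
        out = dilate_mask(m, 3)
        dist = ndimage.distance_transform_edt(~m)
        assert (out == (dist <= 3)).all()

    def test_recovers_known_shift(self, rng):
        base = ndimage.gaussian_filter(rng.uniform(0, 100, (64, 64)), 2.0)
        moved = np.roll(np.roll(base, 3, axis=0), -2, axis=1)
        assert register_translation(make_plane(base), make_plane(moved)) == (3, -2)

    def test_identical_images_zero_shift(self, rng):
        img = rng.uniform(0, 10, (32, 32))
        assert register_translation(make_plane(img), make_plane(img)) == (0, 0)

    def test_noisy_shift_matches_bruteforce_scan(self, rng):
        base = ndimage.gaussian_filter(rng.uniform(0, 100, (64, 64)), 2.0)
        moved = np.roll(np.roll(base, -4, axis=0), 5, axis=1)
        moved = (moved + rng.normal(0, moved.std() / 10, moved.shape)).clip(0)
        # brute-force: maximize correlation over all circular shifts
        a0 = base - base.mean()
        b0 = moved - moved.mean()
        best, best_s = -np.inf, None
        for dy in range(-8, 9):
            for dx in range(-8, 9):
                s = (np.roll(np.roll(a0, dy, axis=0), dx, axis=1) * b0).sum()
                if s > best:
                    best, best_s = s, (dy, dx)
        assert register_translation(make_plane(base), make_plane(moved)) == best_s

    def test_featureless_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            shift = register_translation(
                make_plane(np.full((16, 16), 3.0)), make_plane(np.full((16, 16), 3.0))
            )
        assert shift == (0, 0)
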