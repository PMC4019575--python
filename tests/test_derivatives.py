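import math

import numpy as np
import pytest

from benthomap.core_io import RasterGrid
from benthomap.derivatives import (
    WindowSpec,
    aspect,
    bpi,
    complexity,
    glcm_features,
    glcm_window_features,
    hsi_rgb,
    max_curvature,
    rugosity,
    slope,
)


def _grid(values, cell=1.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, origin_x=0.0, origin_y=values.shape[0] * cell, cell_size=cell)


def _plane(nx=20, ny=20, gx=0.0, gy=0.0, cell=1.0, z0=0.0):
    """z = z0 + gx*x + gy*y on cell-centre coordinates."""
    grid = _grid(np.zeros((ny, nx)), cell)
    rows, cols = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    xs, ys = grid.cell_centre(rows, cols)
    return grid.copy_with(z0 + gx * xs + gy * ys)


def _interior(grid):
    return grid.values[2:-2, 2:-2]


class TestSlopeAspect:
    def test_slope_of_01_plane(self):
        g = _plane(gx=0.1)
        s = slope(g)
        np.testing.assert_allclose(_interior(s), math.degrees(math.atan(0.1)), atol=1e-6)

    def test_flat_plane(self):
        g = _plane()
        s = slope(g)
        np.testing.assert_allclose(_interior(s), 0.0, atol=1e-12)
        a = aspect(g)
        assert not a.mask()[2:-2, 2:-2].any()  # flat -> aspect nodata

    def test_aspect_east_dipping_plane(self):
        g = _plane(gx=-0.1)  # z decreasing eastward: downslope due east
        a = aspect(g)
        np.testing.assert_allclose(_interior(a), 90.0, atol=1e-9)

    def test_aspect_north_dipping_plane(self):
        g = _plane(gy=-0.1)  # z decreasing northward
        a = aspect(g)
        np.testing.assert_allclose(_interior(a), 0.0, atol=1e-9)

    def test_aspect_range(self):
        rng = np.random.default_rng(0)
        g = _grid(rng.normal(size=(15, 15)))
        a = aspect(g)
        vals = a.values[a.mask()]
        assert np.all((vals >= 0) & (vals < 360))


class TestRugosity:
    def test_flat_plane_ratio_one(self):
        r = rugosity(_plane())
        np.testing.assert_allclose(_interior(r), 1.0, atol=1e-12)

    def test_always_at_least_one(self):
        rng = np.random.default_rng(1)
        r = rugosity(_grid(rng.normal(size=(15, 15))))
        assert np.all(r.values[r.mask()] >= 1.0 - 1e-12)

    @pytest.mark.parametrize("gx", [0.05, 0.2, 0.5])
    def test_inclined_plane_closed_form(self, gx):
        r = rugosity(_plane(gx=gx, cell=2.5))
        expected = 1.0 / math.cos(math.atan(gx))
        np.testing.assert_allclose(_interior(r), expected, atol=1e-6)


class TestCurvature:
    def test_plane_zero(self):
        for mode in ("principal", "profile_plan"):
            c = max_curvature(_plane(gx=0.1, gy=-0.05), mode=mode)
            np.testing.assert_allclose(_interior(c), 0.0, atol=1e-9)

    def test_parabola_closed_form(self):
        # z = 0.01 x^2 -> Hessian eigenvalues (0.02, 0) -> max curvature 0.02
        grid = _grid(np.zeros((20, 20)), cell=1.0)
        rows, cols = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        xs, _ = grid.cell_centre(rows, cols)
        g = grid.copy_with(0.01 * xs**2)
        c = max_curvature(g)
        np.testing.assert_allclose(_interior(c), 0.02, atol=1e-6)

    def test_complexity_of_ramp_zero(self):
        c = complexity(_plane(gx=0.3))
        inner = c.values[3:-3, 3:-3]
        np.testing.assert_allclose(inner, 0.0, atol=1e-9)


class TestBPI:
    def test_flat_plane_zero(self):
        spec = WindowSpec(bpi_inner=3, bpi_outer=5)
        b = bpi(_plane(z0=12.0, nx=30, ny=30), spec)
        np.testing.assert_allclose(b.values[b.mask()], 0.0, atol=1e-9)

    def test_constant_gradient_plane_zero(self):
        spec = WindowSpec(bpi_inner=3, bpi_outer=5)
        b = bpi(_plane(gx=0.2, gy=-0.1, nx=30, ny=30), spec)
        np.testing.assert_allclose(b.values[b.mask()], 0.0, atol=1e-9)

    def test_bump_positive_at_crest(self):
        vals = np.zeros((31, 31))
        vals[15, 15] = 5.0
        spec = WindowSpec(bpi_inner=2, bpi_outer=4)
        b = bpi(_grid(vals), spec)
        assert b.values[15, 15] > 0

    def test_degenerate_ring_inner_equals_outer(self):
        spec = WindowSpec(bpi_inner=10, bpi_outer=10)
        b = bpi(_plane(gx=0.1, nx=41, ny=41), spec)
        assert b.mask().any()
        np.testing.assert_allclose(b.values[b.mask()], 0.0, atol=1e-9)

    def test_outer_smaller_than_inner_rejected(self):
        with pytest.raises(ValueError):
            bpi(_plane(), WindowSpec(bpi_inner=5, bpi_outer=3))

    def test_scaled_output_integer(self):
        rng = np.random.default_rng(2)
        g = _grid(rng.normal(size=(31, 31)))
        b = bpi(g, WindowSpec(bpi_inner=2, bpi_outer=4, bpi_scale_factor=125), scaled=True)
        vals = b.values[b.mask()]
        np.testing.assert_array_equal(vals, np.round(vals))


class TestHSI:
    def test_constant_mosaic_rgb_equal(self):
        g = _grid(np.full((20, 20), -30.0))
        bands = hsi_rgb(g)
        r, gr, b = (bands[k] for k in ("hsi_red", "hsi_green", "hsi_blue"))
        m = r.mask()
        assert m.any()
        np.testing.assert_allclose(r.values[m], gr.values[m], atol=1e-9)
        np.testing.assert_allclose(gr.values[m], b.values[m], atol=1e-9)

    def test_step_edge_highpass_support(self):
        from scipy import ndimage

        vals = np.zeros((20, 20))
        vals[:, 10:] = 10.0
        high = vals - ndimage.uniform_filter(vals, size=3, mode="nearest")
        nz_cols = np.unique(np.nonzero(high[5])[0])
        assert set(nz_cols) <= {9, 10}  # high-pass nonzero only within 1 cell of the edge

    def test_bands_0_255(self):
        rng = np.random.default_rng(3)
        g = _grid(rng.normal(-30, 5, size=(25, 25)))
        for band in hsi_rgb(g).values():
            vals = band.values[band.mask()]
            assert vals.min() >= 0 and vals.max() <= 255


# ---------------------------------------------------------------------------
# GLCM: independent brute-force oracle
# ---------------------------------------------------------------------------


def glcm_oracle(win):
    """Pair-enumeration GLCM features, written independently of the library.

    Builds the explicit symmetric co-occurrence dictionaries for the four
    directions with plain loops and computes homogeneity, entropy (natural
    log) and correlation from first principles.
    """
    h, w = win.shape
    feats = []
    for dr, dc in ((0, 1), (-1, 1), (-1, 0), (-1, -1)):
        pairs = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    i, j = int(win[r, c]), int(win[r2, c2])
                    pairs[(i, j)] = pairs.get((i, j), 0) + 1
                    pairs[(j, i)] = pairs.get((j, i), 0) + 1
        total = sum(pairs.values())
        hom = sum(n / (1 + (i - j) ** 2) for (i, j), n in pairs.items()) / total
        ent = -sum((n / total) * math.log(n / total) for n in pairs.values())
        mu_i = sum(i * n for (i, _), n in pairs.items()) / total
        mu_j = sum(j * n for (_, j), n in pairs.items()) / total
        var_i = sum((i - mu_i) ** 2 * n for (i, _), n in pairs.items()) / total
        var_j = sum((j - mu_j) ** 2 * n for (_, j), n in pairs.items()) / total
        if var_i > 0 and var_j > 0:
            cor = sum(
                (i - mu_i) * (j - mu_j) * n for (i, j), n in pairs.items()
            ) / total / math.sqrt(var_i * var_j)
        else:
            cor = 0.0
        feats.append((hom, ent, cor))
    return tuple(np.mean([f[k] for f in feats]) for k in range(3))


class TestGLCM:
    def test_constant_window(self):
        win = np.full((7, 7), 42, dtype=int)
        hom, ent, cor = glcm_window_features(win)
        assert hom == pytest.approx(1.0)
        assert ent == pytest.approx(0.0)
        assert cor == 0.0

    def test_checkerboard_hand_enumerated(self):
        win = np.zeros((4, 4), dtype=int)
        win[::2, 1::2] = 255
        win[1::2, ::2] = 255
        got = glcm_window_features(win)
        expected = glcm_oracle(win)
        np.testing.assert_allclose(got, expected, atol=1e-10)
        # horizontal/vertical pairs always differ; diagonal pairs always match:
        # homogeneity of 0/90 directions = 1/(1+255^2), of 45/135 = 1
        hom_hv = 1.0 / (1.0 + 255.0**2)
        assert got[0] == pytest.approx((2 * hom_hv + 2 * 1.0) / 4)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_patches_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        win = rng.integers(0, 256, size=(7, 7))
        got = glcm_window_features(win)
        expected = glcm_oracle(win)
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_bounds(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            win = rng.integers(0, 256, size=(7, 7))
            hom, ent, _ = glcm_window_features(win)
            assert 0 < hom <= 1
            assert ent >= 0

    def test_raster_wrapper_and_nodata(self):
        rng = np.random.default_rng(5)
        vals = rng.integers(0, 256, size=(12, 12)).astype(float)
        vals[0, 0] = -9999.0
        g = _grid(vals)
        out = glcm_features(g, window=7)
        hom = out["glcm_homogeneity"]
        # window touching the nodata cell -> nodata
        assert not hom.mask()[3, 3]
        assert hom.mask()[6, 6]
        # centre window is clean: value equals direct window computation
        win = vals[3:10, 3:10].astype(int)
        assert hom.values[6, 6] == pytest.approx(glcm_window_features(win)[0])

    def test_non_integer_input_rejected(self):
        g = _grid(np.full((9, 9), 0.5))
        with pytest.raises(ValueError, match="to_8bit"):
            glcm_features(g)


class TestNodataPropagation:
    @pytest.mark.parametrize("op", [slope, aspect, rugosity, max_curvature, complexity])
    def test_window_touching_nodata_is_nodata(self, op):
        vals = np.random.default_rng(0).normal(size=(12, 12))
        vals[5, 5] = -9999.0
        g = _grid(vals)
        out = op(g)
        assert not out.mask()[4:7, 4:7].any()

    def test_geometry_preserved(self):
        g = _plane(gx=0.1, cell=2.5)
        for op in (slope, aspect, rugosity, max_curvature, complexity):
            assert op(g).same_geometry(g)
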