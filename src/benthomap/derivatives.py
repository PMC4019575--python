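"""Bathymetry and backscatter-mosaic derivative layers.

Terrain operators (slope, aspect, rugosity, maximum curvature, complexity,
BPI) work on 3x3 windows except BPI, which compares each cell to the mean of
a surrounding annulus. Mosaic operators are the HSI-derived red/green/blue
bands (3x3 high-pass, 11x11 low-pass) and three GLCM texture features
(homogeneity, entropy, correlation) on a 7x7 window, averaged over the 0, 45,
90 and 135 degree directions.

All operators are nodata-strict: any window touching nodata emits nodata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import RasterGrid


@dataclass(frozen=True)
class WindowSpec:
    size: int = 3
    bpi_inner: int = 10
    bpi_outer: int = 10
    bpi_scale_factor: int = 125

    def __post_init__(self):
        if self.size % 2 == 0:
            raise ValueError("window size must be odd")


def _valid_window_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """True where every cell of the size x size window holds valid data."""
    return ndimage.minimum_filter(mask.astype(np.uint8), size=size, mode="constant", cval=0) == 1


def _with_nodata(template: RasterGrid, values: np.ndarray, ok: np.ndarray) -> RasterGrid:
    out_vals = np.where(ok, values, template.nodata)
    out = template.copy_with(out_vals)
    out.nodata = template.nodata
    return out


def _horn_gradients(grid: RasterGrid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Horn 3x3 gradients (dz/dx eastward, dz/dy northward) and valid mask."""
    z = grid.values
    cs = grid.cell_size
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * cs)
    # row index increases southward, so d/dy (north) = -d/drow
    ky = -np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float) / (8 * cs)
    gx = ndimage.correlate(z, kx, mode="nearest")
    gy = ndimage.correlate(z, ky, mode="nearest")
    ok = _valid_window_mask(grid.mask(), 3)
    return gx, gy, ok


def slope(bathy: RasterGrid) -> RasterGrid:
    """Steepest terrain gradient in degrees (Horn's method on a 3x3 window)."""
    gx, gy, ok = _horn_gradients(bathy)
    s = np.degrees(np.arctan(np.hypot(gx, gy)))
    return _with_nodata(bathy, s, ok)


def aspect(bathy: RasterGrid) -> RasterGrid:
    """Azimuth of the steepest downslope direction, degrees clockwise from north.

    Flat cells (zero gradient) are nodata.
    """
    gx, gy, ok = _horn_gradients(bathy)
    flat = (gx == 0) & (gy == 0)
    az = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    return _with_nodata(bathy, az, ok & ~flat)


def rugosity(bathy: RasterGrid) -> RasterGrid:
    """Surface-area / planar-area ratio from triangulated facets of the 3x3 window.

    The eight triangles fan out from the centre cell to its ring of neighbours;
    their summed 3-D area is divided by the projected planar area (2*cell)^2.
    A plane of slope s gives exactly 1/cos(s).
    """
    z = bathy.values
    cs = bathy.cell_size
    # ring of 8 neighbours in cyclic order (dr, dc)
    ring = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    shifted = [np.roll(np.roll(z, -dr, axis=0), -dc, axis=1) for dr, dc in ring]
    surf = np.zeros_like(z)
    for k in range(8):
        dr1, dc1 = ring[k]
        dr2, dc2 = ring[(k + 1) % 8]
        # triangle (centre, neighbour k, neighbour k+1); x east = +dc, y north = -dr
        ax, ay, az_ = dc1 * cs, -dr1 * cs, shifted[k] - z
        bx, by, bz = dc2 * cs, -dr2 * cs, shifted[(k + 1) % 8] - z
        cxv = ay * bz - az_ * by
        cyv = az_ * bx - ax * bz
        czv = ax * by - ay * bx
        surf += 0.5 * np.sqrt(cxv**2 + cyv**2 + czv**2)
    ratio = surf / (4.0 * cs**2)
    ok = _valid_window_mask(bathy.mask(), 3)
    # roll wraps at the border; border windows are invalid anyway
    ok[0, :] = ok[-1, :] = False
    ok[:, 0] = ok[:, -1] = False
    return _with_nodata(bathy, ratio, ok)


_QUAD_DESIGN: np.ndarray | None = None


def _quadratic_coeffs(grid: RasterGrid) -> tuple[np.ndarray, ...]:
    """Least-squares fit of z = ax^2 + by^2 + cxy + dx + ey + f per 3x3 window."""
    global _QUAD_DESIGN
    cs = grid.cell_size
    if _QUAD_DESIGN is None:
        pts = [(dc, -dr) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]
        X = np.array([[x * x, y * y, x * y, x, y, 1.0] for x, y in pts])
        _QUAD_DESIGN = np.linalg.pinv(X)
    # stack the 9 window values per cell, scaled to metres afterwards
    z = grid.values
    stacks = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            stacks.append(np.roll(np.roll(z, -dr, axis=0), -dc, axis=1))
    Z = np.stack(stacks, axis=0)  # (9, H, W)
    coef = np.tensordot(_QUAD_DESIGN, Z, axes=(1, 0))  # (6, H, W), in cell units
    a = coef[0] / cs**2
    b = coef[1] / cs**2
    c = coef[2] / cs**2
    d = coef[3] / cs
    e = coef[4] / cs
    return a, b, c, d, e


def max_curvature(bathy: RasterGrid, mode: str = "principal") -> RasterGrid:
    """Maximum curvature magnitude of the locally fitted quadratic surface.

    ``mode='principal'`` (default): largest-|.|" eigenvalue of the Hessian
    [[2a, c], [c, 2b]]. ``mode='profile_plan'``: max of |profile| and |plan|
    curvature magnitudes. Both are 0 on a plane; z = k*x^2 gives 2k.
    """
    a, b, c, d, e = _quadratic_coeffs(bathy)
    if mode == "principal":
        tr = a + b
        det = np.sqrt(((a - b)) ** 2 + c**2)
        k1 = tr + det
        k2 = tr - det
        out = np.where(np.abs(k1) >= np.abs(k2), np.abs(k1), np.abs(k2))
    elif mode == "profile_plan":
        g2 = d**2 + e**2
        safe = g2 > 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            prof = -2.0 * (a * d**2 + b * e**2 + c * d * e) / np.where(safe, g2, 1.0)
            plan = -2.0 * (a * e**2 + b * d**2 - c * d * e) / np.where(safe, g2, 1.0)
        # zero gradient: fall back to the Hessian extremes
        tr = a + b
        det = np.sqrt((a - b) ** 2 + c**2)
        fallback = np.maximum(np.abs(tr + det), np.abs(tr - det))
        out = np.where(safe, np.maximum(np.abs(prof), np.abs(plan)), fallback)
    else:
        raise ValueError("mode must be 'principal' or 'profile_plan'")
    ok = _valid_window_mask(bathy.mask(), 3)
    ok[0, :] = ok[-1, :] = False
    ok[:, 0] = ok[:, -1] = False
    return _with_nodata(bathy, out, ok)


def complexity(bathy: RasterGrid) -> RasterGrid:
    """Rate of change of slope: the slope operator applied to the slope raster."""
    return slope(slope(bathy))


def bpi(bathy: RasterGrid, spec: WindowSpec = WindowSpec(), scaled: bool = False) -> RasterGrid:
    """Bathymetric position index: elevation minus the mean of an annulus.

    The annulus holds cells at radius inner <= r <= outer (in cells), centre
    excluded. With ``scaled`` the value is multiplied by the spec's scale
    factor and rounded to an integer (the convention of the originating GIS
    tool is undocumented; unscaled natural units are the default).
    """
    if spec.bpi_outer < spec.bpi_inner:
        raise ValueError("outer radius must be >= inner radius")
    r = spec.bpi_outer
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.hypot(yy, xx)
    ann = (dist >= spec.bpi_inner) & (dist <= spec.bpi_outer) & (dist > 0)
    if not ann.any():
        raise ValueError("empty annulus: no cells between inner and outer radius")
    kernel = ann.astype(float) / ann.sum()
    mean_ann = ndimage.correlate(bathy.values, kernel, mode="nearest")
    out = bathy.values - mean_ann
    if scaled:
        out = np.round(out * spec.bpi_scale_factor)
    ok = _valid_window_mask(bathy.mask(), 2 * r + 1)
    return _with_nodata(bathy, out, ok)


# ---------------------------------------------------------------------------
# Mosaic derivatives
# ---------------------------------------------------------------------------


def _minmax01(values: np.ndarray, ok: np.ndarray) -> np.ndarray:
    if not ok.any():
        return np.zeros_like(values)
    v = values[ok]
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def hsi_rgb(mosaic: RasterGrid, high_pass_size: int = 3, low_pass_size: int = 11) -> dict[str, RasterGrid]:
    """Red/Green/Blue bands of an HSI composite of the mosaic.

    The low-pass (mean-filtered) image drives hue, the high-pass residual
    drives intensity, saturation is fixed at 0.5. The HSI->RGB transform is
    the standard sector formula; outputs are scaled 0-255.
    """
    z = mosaic.values
    low = ndimage.uniform_filter(z, size=low_pass_size, mode="nearest")
    high = z - ndimage.uniform_filter(z, size=high_pass_size, mode="nearest")
    ok = _valid_window_mask(mosaic.mask(), low_pass_size)

    hue = _minmax01(low, ok) * 2.0 * np.pi
    inten = _minmax01(np.abs(high), ok)
    sat = np.full_like(z, 0.5)

    r, g, b = _hsi_to_rgb(hue, sat, inten)
    out = {}
    for name, band in (("hsi_red", r), ("hsi_green", g), ("hsi_blue", b)):
        out[name] = _with_nodata(mosaic, np.clip(band * 255.0, 0, 255), ok)
    return out


def _hsi_to_rgb(h: np.ndarray, s: np.ndarray, i: np.ndarray):
    """Sector-based HSI to RGB (h in radians, s and i in [0, 1])."""
    h = np.mod(h, 2 * np.pi)
    r = np.zeros_like(h)
    g = np.zeros_like(h)
    b = np.zeros_like(h)
    third = 2 * np.pi / 3
    with np.errstate(divide="ignore", invalid="ignore"):
        for k, (c1, c2, c3) in enumerate((("b", "r", "g"), ("r", "g", "b"), ("g", "b", "r"))):
            sel = (h >= k * third) & (h < (k + 1) * third)
            hh = h - k * third
            x1 = i * (1 - s)
            x2 = i * (1 + s * np.cos(hh) / np.cos(np.pi / 3 - hh))
            x3 = 3 * i - (x1 + x2)
            for name, val in zip((c1, c2, c3), (x1, x2, x3)):
                band = {"r": r, "g": g, "b": b}[name]
                band[sel] = val[sel]
    return np.clip(r, 0, 1), np.clip(g, 0, 1), np.clip(b, 0, 1)


_GLCM_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))  # 0, 45, 90, 135 degrees


def _window_pairs(win: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """First/second pixel values of all co-occurring pairs inside a window."""
    h, w = win.shape
    r0, r1 = max(0, -dr), h - max(0, dr)
    c0, c1 = max(0, -dc), w - max(0, dc)
    a = win[r0:r1, c0:c1]
    b = win[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a.ravel(), b.ravel()


def glcm_window_features(win: np.ndarray) -> tuple[float, float, float]:
    """(homogeneity, entropy, correlation) for one integer window.

    Per direction the GLCM is symmetric and normalized; entropy uses the
    natural log (0 log 0 := 0); correlation is defined as 0 when the grey
    variance vanishes. The three features are averaged over the 4 directions.
    """
    hom = ent = cor = 0.0
    for dr, dc in _GLCM_DIRECTIONS:
        a, b = _window_pairs(win, dr, dc)
        # symmetric GLCM: count each pair in both orders
        both = np.concatenate([a, b])
        n = both.size  # total (ordered) pair entries
        diff = a.astype(np.int64) - b.astype(np.int64)
        hom += float(np.mean(1.0 / (1.0 + diff.astype(float) ** 2)))
        codes = np.concatenate([a.astype(np.int64) * 256 + b, b.astype(np.int64) * 256 + a])
        _, counts = np.unique(codes, return_counts=True)
        p = counts / n
        ent += float(-np.sum(p * np.log(p)))
        mu = float(both.mean())
        var = float(both.astype(float).var())
        if var > 0:
            cov = float(np.mean((a - mu) * (b - mu)))
            cor += cov / var
    return hom / 4.0, ent / 4.0, cor / 4.0


def glcm_features(mosaic_8bit: RasterGrid, window: int = 7) -> dict[str, RasterGrid]:
    """Per-pixel GLCM homogeneity, entropy and correlation over sliding windows."""
    vals = mosaic_8bit.values
    mask = mosaic_8bit.mask()
    ints = vals[mask]
    if ints.size and not np.allclose(ints, np.round(ints)):
        raise ValueError("glcm_features requires an integer 0-255 grid; run to_8bit first")
    if ints.size and (ints.min() < 0 or ints.max() > 255):
        raise ValueError("glcm_features requires grey levels in 0-255; run to_8bit first")
    img = np.where(mask, vals, 0).astype(np.int16)
    ok = _valid_window_mask(mask, window)
    h, w = img.shape
    half = window // 2
    hom = np.full((h, w), np.nan)
    ent = np.full((h, w), np.nan)
    cor = np.full((h, w), np.nan)
    for r in range(half, h - half):
        row_ok = ok[r]
        for c in range(half, w - half):
            if not row_ok[c]:
                continue
            win = img[r - half : r + half + 1, c - half : c + half + 1]
            hom[r, c], ent[r, c], cor[r, c] = glcm_window_features(win)
    return {
        "glcm_homogeneity": _with_nodata(mosaic_8bit, np.nan_to_num(hom), ok),
        "glcm_entropy": _with_nodata(mosaic_8bit, np.nan_to_num(ent), ok),
        "glcm_correlation": _with_nodata(mosaic_8bit, np.nan_to_num(cor), ok),
    }


def bathymetry_derivatives(bathy: RasterGrid, spec: WindowSpec = WindowSpec()) -> dict[str, RasterGrid]:
    """All six terrain layers keyed by canonical name."""
    return {
        "aspect": aspect(bathy),
        "rugosity": rugosity(bathy),
        "max_curvature": max_curvature(bathy),
        "bpi": bpi(bathy, spec),
        "slope": slope(bathy),
        "complexity": complexity(bathy),
    }


def mosaic_derivatives(mosaic: RasterGrid, mosaic_8bit: RasterGrid) -> dict[str, RasterGrid]:
    """All six mosaic layers: HSI red/green/blue + GLCM homogeneity/entropy/correlation."""
    out = hsi_rgb(mosaic)
    out.update(glcm_features(mosaic_8bit))
    return out
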