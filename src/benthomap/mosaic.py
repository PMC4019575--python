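"""Statistical angular compensation and gridding of backscatter samples.

Normalization follows the sliding-window scheme: each sample's level is
referenced to the mean level observed at a reference angle within a centred
window of consecutive pings on the same survey line, removing the angular
dependence while preserving spatial contrast. All averaging is done in dB
space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .core_io import BackscatterSample, RasterGrid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationConfig:
    window_pings: int = 25
    ref_angle: float = 30.0
    angle_bin: float = 1.0
    pool_sides: bool = True  # port/starboard already folded to unsigned angles

    def __post_init__(self):
        if self.window_pings < 1:
            raise ValueError("window_pings must be >= 1")
        if not 0 < self.ref_angle < 90:
            raise ValueError("ref_angle must be in (0, 90)")
        if self.angle_bin <= 0:
            raise ValueError("angle_bin must be > 0")


def angular_normalize(
    samples: list[BackscatterSample], cfg: NormalizationConfig = NormalizationConfig()
) -> list[BackscatterSample]:
    """Replace each sample's level with its angular-compensated value.

    normalized = raw - mean(level in this sample's angle bin over the window)
                     + mean(level in the reference-angle bin over the window)

    The window is ``cfg.window_pings`` consecutive pings centred on the
    sample's ping, restricted to the same survey line and truncated at line
    ends. Samples whose window holds no reference-angle observations are
    dropped (counted in the log).
    """
    if not samples:
        return []
    out: list[BackscatterSample] = []
    dropped = 0
    half = cfg.window_pings // 2
    ref_bin = int(np.floor(cfg.ref_angle / cfg.angle_bin))

    by_line: dict[int, list[BackscatterSample]] = {}
    for s in samples:
        by_line.setdefault(s.line_id, []).append(s)

    for line_id in sorted(by_line):
        line = sorted(by_line[line_id], key=lambda s: (s.ping_id, s.beam_id))
        pings = sorted({s.ping_id for s in line})
        ping_index = {p: i for i, p in enumerate(pings)}
        n_pings = len(pings)

        pidx = np.array([ping_index[s.ping_id] for s in line])
        bins = np.floor(np.array([s.angle for s in line]) / cfg.angle_bin).astype(int)
        levels = np.array([s.level for s in line])
        n_bins = int(bins.max()) + 1

        # per-ping per-bin sums and counts, then windowed via cumulative sums
        sums = np.zeros((n_pings, n_bins))
        counts = np.zeros((n_pings, n_bins))
        np.add.at(sums, (pidx, bins), levels)
        np.add.at(counts, (pidx, bins), 1.0)
        csum = np.vstack([np.zeros(n_bins), np.cumsum(sums, axis=0)])
        ccnt = np.vstack([np.zeros(n_bins), np.cumsum(counts, axis=0)])

        lo = np.maximum(pidx - half, 0)
        hi = np.minimum(pidx + half, n_pings - 1) + 1
        win_sum_own = csum[hi, bins] - csum[lo, bins]
        win_cnt_own = ccnt[hi, bins] - ccnt[lo, bins]

        # reference level: the ref-angle bin of the window, falling back to the
        # nearest populated bin when the beam geometry leaves it empty
        win_sum_all = csum[hi, :] - csum[lo, :]  # (n_line_samples, n_bins)
        win_cnt_all = ccnt[hi, :] - ccnt[lo, :]
        dist = np.abs(np.arange(n_bins) - min(ref_bin, n_bins - 1))
        order = np.lexsort((np.arange(n_bins), dist))
        populated = win_cnt_all[:, order] > 0
        first = np.argmax(populated, axis=1)
        ref_sel = order[first]
        has_ref = populated.any(axis=1)
        rows_idx = np.arange(len(line))
        win_sum_ref = win_sum_all[rows_idx, ref_sel]
        win_cnt_ref = np.where(has_ref, win_cnt_all[rows_idx, ref_sel], 0.0)

        ok = (win_cnt_own > 0) & (win_cnt_ref > 0)
        dropped += int((~ok).sum())
        norm = levels - win_sum_own / np.where(win_cnt_own > 0, win_cnt_own, 1) + (
            win_sum_ref / np.where(win_cnt_ref > 0, win_cnt_ref, 1)
        )
        for i, s in enumerate(line):
            if ok[i]:
                out.append(replace(s, level=float(norm[i])))
    if dropped:
        log.warning("angular_normalize dropped %d samples with no window support", dropped)
    return out


def grid_mosaic(samples: list[BackscatterSample], template: RasterGrid) -> RasterGrid:
    """Grid normalized samples into a mosaic: per-cell mean level in dB space."""
    sums = np.zeros(template.shape)
    counts = np.zeros(template.shape)
    n_in = 0
    for s in samples:
        row, col = template.cell_of(s.x, s.y)
        if 0 <= row < template.n_rows and 0 <= col < template.n_cols:
            sums[row, col] += s.level
            counts[row, col] += 1
            n_in += 1
    if n_in == 0:
        log.warning("grid_mosaic: no samples fall inside the template bounds")
    values = np.full(template.shape, template.nodata)
    hit = counts > 0
    values[hit] = sums[hit] / counts[hit]
    out = template.copy_with(values)
    out._cell_counts = counts  # diagnostic: per-cell contributing-sample counts
    return out


def to_8bit(mosaic: RasterGrid, lo_dB: float | None = None, hi_dB: float | None = None) -> RasterGrid:
    """Linearly quantise the mosaic to integers 0-255 (half-up rounding).

    Defaults lo/hi to the 1st/99th percentiles of the valid data. Values
    outside [lo, hi] are clipped; nodata is preserved.
    """
    mask = mosaic.mask()
    if lo_dB is None or hi_dB is None:
        if not mask.any():
            raise ValueError("cannot autoscale an all-nodata mosaic")
        vals = mosaic.values[mask]
        if lo_dB is None:
            lo_dB = float(np.percentile(vals, 1))
        if hi_dB is None:
            hi_dB = float(np.percentile(vals, 99))
    if not lo_dB < hi_dB:
        raise ValueError("lo_dB must be < hi_dB")
    scaled = (mosaic.values - lo_dB) / (hi_dB - lo_dB) * 255.0
    quant = np.clip(np.floor(scaled + 0.5), 0, 255)
    values = np.where(mask, quant, mosaic.nodata)
    return mosaic.copy_with(values)
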