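"""Per-segment angular response curves and their statistical features.

Backscatter samples taken BEFORE angular normalization are pooled per mosaic
segment and averaged (dB space) per 1-degree incidence-angle bin, giving one
mean angular-response curve per segment. Four features — mean, least-squares
slope, skewness and kurtosis — are computed from the curve over the 30-50
degree band and rasterised back onto the segment footprints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_io import BackscatterSample, RasterGrid, SegmentSet

log = logging.getLogger(__name__)

FEATURE_NAMES = ("ar_mean", "ar_slope", "ar_skew", "ar_kurt")


@dataclass
class ARCurve:
    """Mean backscatter level per incidence-angle bin for one segment."""

    segment_id: int
    bin_centres: np.ndarray  # degrees
    mean_dB: np.ndarray
    counts: np.ndarray

    def in_range(self, lo: float, hi: float) -> "ARCurve":
        sel = (self.bin_centres >= lo) & (self.bin_centres <= hi)
        return ARCurve(self.segment_id, self.bin_centres[sel], self.mean_dB[sel], self.counts[sel])


@dataclass(frozen=True)
class ARFeatures:
    segment_id: int
    ar_mean: float
    ar_slope: float
    ar_skew: float
    ar_kurt: float
    angle_lo: float = 30.0
    angle_hi: float = 50.0
    defined: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "ar_mean": self.ar_mean,
            "ar_slope": self.ar_slope,
            "ar_skew": self.ar_skew,
            "ar_kurt": self.ar_kurt,
        }

    @classmethod
    def undefined(cls, segment_id: int, lo: float = 30.0, hi: float = 50.0) -> "ARFeatures":
        nan = float("nan")
        return cls(segment_id, nan, nan, nan, nan, lo, hi, defined=False)


def compile_ar_curves(
    samples: list[BackscatterSample],
    segment_set: SegmentSet,
    bin_width: float = 1.0,
) -> tuple[list[ARCurve], int]:
    """Pool pre-normalization samples per segment and bin by incidence angle.

    Segment membership is decided by the label raster cell containing the
    sample position (every sample lands in exactly one segment or none).
    Returns (curves, n_outside) where n_outside counts samples falling on
    nodata or out of bounds. Segments with no samples are omitted with a
    warning.
    """
    grid = segment_set.label_raster
    labels = grid.values.astype(int)
    xs = np.array([s.x for s in samples])
    ys = np.array([s.y for s in samples])
    angles = np.array([s.angle for s in samples])
    levels = np.array([s.level for s in samples])

    inb = grid.in_bounds(xs, ys)
    rows, cols = grid.cell_of(xs[inb], ys[inb])
    seg = labels[rows, cols]
    valid = seg > 0
    n_outside = int((~inb).sum() + (~valid).sum())

    seg = seg[valid]
    bins = np.floor(angles[inb][valid] / bin_width).astype(int)
    lvl = levels[inb][valid]

    curves: list[ARCurve] = []
    n_bins = int(bins.max()) + 1 if len(bins) else 0
    for seg_id in segment_set.segment_ids:
        sel = seg == seg_id
        if not sel.any():
            log.warning("segment %d has no backscatter samples; curve omitted", seg_id)
            continue
        sums = np.bincount(bins[sel], weights=lvl[sel], minlength=n_bins)
        counts = np.bincount(bins[sel], minlength=n_bins)
        present = counts > 0
        centres = (np.nonzero(present)[0] + 0.5) * bin_width
        curves.append(
            ARCurve(
                segment_id=seg_id,
                bin_centres=centres,
                mean_dB=sums[present] / counts[present],
                counts=counts[present].astype(int),
            )
        )
    return curves, n_outside


def ar_features(
    curve: ARCurve,
    angle_lo: float = 30.0,
    angle_hi: float = 50.0,
    min_bins: int = 5,
) -> ARFeatures:
    """Mean, OLS slope, skewness and kurtosis of the curve over [angle_lo, angle_hi].

    Statistics are computed over the per-bin mean values. Skewness is
    m3 / m2^1.5 and kurtosis is non-excess m4 / m2^2 (normal -> 3); both are
    NaN when the curve is constant (m2 = 0). Fewer than ``min_bins`` populated
    bins in range -> the whole feature set is marked undefined.
    """
    sub = curve.in_range(angle_lo, angle_hi)
    y = np.asarray(sub.mean_dB, dtype=float)
    if len(y) < min_bins:
        return ARFeatures.undefined(curve.segment_id, angle_lo, angle_hi)
    x = np.asarray(sub.bin_centres, dtype=float)

    mean = float(np.mean(y))
    slope = float(np.polyfit(x, y, 1)[0])
    d = y - mean
    m2 = float(np.mean(d**2))
    if m2 == 0.0:
        skew = float("nan")
        kurt = float("nan")
    else:
        skew = float(np.mean(d**3) / m2**1.5)
        kurt = float(np.mean(d**4) / m2**2)
    return ARFeatures(curve.segment_id, mean, slope, skew, kurt, angle_lo, angle_hi)


def rasterize_features(
    segment_set: SegmentSet,
    features: list[ARFeatures],
    template: RasterGrid,
) -> dict[str, RasterGrid]:
    """Paint each segment's four feature values onto its pixels.

    Undefined feature sets (and segments without features) become nodata.
    Returns {'ar_mean': grid, 'ar_slope': grid, 'ar_skew': grid, 'ar_kurt': grid}.
    """
    labels = segment_set.label_raster.values.astype(int)
    by_id = {f.segment_id: f for f in features}
    out: dict[str, RasterGrid] = {}
    for name in FEATURE_NAMES:
        values = np.full(template.shape, template.nodata)
        for seg_id in segment_set.segment_ids:
            f = by_id.get(seg_id)
            if f is None or not f.defined:
                continue
            v = f.as_dict()[name]
            if np.isfinite(v):
                values[labels == seg_id] = v
        grid = template.copy_with(values)
        grid.nodata = template.nodata
        out[name] = grid
    return out


def features_to_csv(curves: list[ARCurve], features: list[ARFeatures], path: str) -> None:
    """Per-segment CSV of curve support and the four features."""
    import csv

    by_id = {f.segment_id: f for f in features}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["segment_id", "n_bins", "n_samples", "ar_mean", "ar_slope", "ar_skew", "ar_kurt", "defined"]
        )
        for c in curves:
            f = by_id.get(c.segment_id)
            row = [c.segment_id, len(c.bin_centres), int(c.counts.sum())]
            if f is None:
                row += ["", "", "", "", False]
            else:
                row += [f.ar_mean, f.ar_slope, f.ar_skew, f.ar_kurt, f.defined]
            writer.writerow(row)
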