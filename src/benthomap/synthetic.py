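"""Synthetic multibeam survey generator.

Produces a bathymetry grid, a habitat class map, per-beam backscatter samples
whose angular dependence is class-specific, and labelled ground-truth points —
everything the downstream pipeline needs, fully deterministic under a seed.

The per-class angular model is piecewise: a linear segment over 25-60 degrees
(so the 30-50 degree feature band has closed-form mean and slope) plus an
optional quadratic near-nadir rise below 25 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import CLASS_LABELS, BackscatterSample, GroundTruthPoint, RasterGrid

_LINEAR_LO = 25.0  # degrees; below this the optional near-nadir rise applies


@dataclass(frozen=True)
class ClassARModel:
    """Angular response model for one habitat class.

    ``mu`` is the mean level at 40 degrees (dB), ``slope`` the dB-per-degree
    gradient over the linear segment, ``shape`` the extra dB reached at nadir
    relative to the linear segment's value at 25 degrees, and ``noise_sd`` the
    per-sample Gaussian noise in dB.
    """

    label: str
    mu: float
    slope: float
    shape: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def level(self, angle) -> np.ndarray:
        """Noise-free backscatter level at unsigned incidence angle(s) in degrees."""
        a = np.abs(np.asarray(angle, dtype=float))
        linear = self.mu + self.slope * (a - 40.0)
        at_lo = self.mu + self.slope * (_LINEAR_LO - 40.0)
        rise = at_lo + self.shape * ((_LINEAR_LO - a) / _LINEAR_LO) ** 2
        return np.where(a < _LINEAR_LO, rise, linear)


@dataclass
class SimConfig:
    """All knobs of the synthetic survey in one place."""

    extent: float = 500.0          # metres, square study area
    cell_size: float = 2.5         # metres
    n_classes: int = 2
    base_depth: float = 30.0       # metres, positive down
    depth_trend: tuple[float, float] = (0.0, 0.0)   # m per m in (x, y)
    bump_amplitude: float = 0.0    # metres
    n_bumps: int = 4
    bump_scale: float = 80.0       # metres, gaussian bump sigma
    line_spacing: float = 60.0     # metres between survey lines
    ping_spacing: float = 2.0      # metres along track
    n_beams: int = 64
    angular_span: float = 60.0     # degrees, half swath
    patch_scale: float = 40.0      # metres, habitat patch smoothness
    depth_split: float | None = None  # metres; classes are zoned above/below
    gain_drift_sd: float = 0.0     # dB; along-track gain drift (ping-level, all beams)
    gain_drift_len: float = 20.0   # pings; correlation length of the drift
    seed: int = 0

    def __post_init__(self):
        if self.extent <= 0 or self.cell_size <= 0:
            raise ValueError("extent and cell_size must be > 0")
        if not 1 <= self.n_classes <= len(CLASS_LABELS):
            raise ValueError(f"n_classes must be in 1..{len(CLASS_LABELS)}")
        if self.angular_span < 50.0:
            raise ValueError("angular span must cover at least 0-50 degrees")
        if self.patch_scale < self.cell_size:
            raise ValueError("patch scale must be at least one cell")

    @property
    def n_cells(self) -> int:
        return int(round(self.extent / self.cell_size))

    def grid_template(self) -> RasterGrid:
        n = self.n_cells
        return RasterGrid(
            values=np.zeros((n, n)),
            origin_x=0.0,
            origin_y=self.extent,
            cell_size=self.cell_size,
        )

    def class_labels(self) -> list[str]:
        return list(CLASS_LABELS[: self.n_classes])


def default_ar_models(cfg: SimConfig, mu_lo: float = -38.0, mu_step: float = 4.0,
                      slope_lo: float = 0.1, slope_step: float = 0.15,
                      noise_sd: float = 0.0, shape: float = 8.0) -> dict[int, ClassARModel]:
    """A convenient family of class models with configurable separation."""
    return {
        i: ClassARModel(
            label=lab,
            mu=mu_lo + i * mu_step,
            slope=slope_lo + i * slope_step,
            shape=shape,
            noise_sd=noise_sd,
        )
        for i, lab in enumerate(cfg.class_labels())
    }


def gen_bathymetry(cfg: SimConfig) -> RasterGrid:
    """Depth surface = base + linear trend + smooth Gaussian bumps (positive down)."""
    grid = cfg.grid_template()
    rows = np.arange(grid.n_rows)
    cols = np.arange(grid.n_cols)
    xs, ys = grid.cell_centre(*np.meshgrid(rows, cols, indexing="ij"))
    depth = cfg.base_depth + cfg.depth_trend[0] * xs + cfg.depth_trend[1] * ys
    if cfg.bump_amplitude > 0 and cfg.n_bumps > 0:
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.n_bumps):
            cx, cy = rng.uniform(0, cfg.extent, size=2)
            amp = rng.uniform(-cfg.bump_amplitude, cfg.bump_amplitude)
            depth = depth + amp * np.exp(
                -((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * cfg.bump_scale**2)
            )
    return grid.copy_with(depth)


def gen_habitat_map(cfg: SimConfig, bathymetry: RasterGrid) -> RasterGrid:
    """Habitat class-id map as contiguous patches of a smoothed random field.

    With ``cfg.depth_split`` set, class ids are zoned: the first half of the
    configured classes occur only where depth < split, the rest only where
    depth >= split (each zone gets its own patch field).
    """
    if bathymetry.shape != (cfg.n_cells, cfg.n_cells):
        raise ValueError("bathymetry is not co-registered with the configured extent")
    rng = np.random.default_rng(cfg.seed + 1)
    noise = rng.standard_normal(bathymetry.shape)
    sigma = cfg.patch_scale / cfg.cell_size
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")

    labels = np.zeros(bathymetry.shape, dtype=int)
    if cfg.depth_split is None or cfg.n_classes == 1:
        labels = _quantile_classes(smooth, np.ones(smooth.shape, bool), cfg.n_classes)
    else:
        shallow = bathymetry.values < cfg.depth_split
        n_shallow = cfg.n_classes // 2 + cfg.n_classes % 2
        n_deep = cfg.n_classes - n_shallow
        labels[shallow] = _quantile_classes(smooth, shallow, n_shallow)[shallow]
        labels[~shallow] = (
            n_shallow + _quantile_classes(smooth, ~shallow, n_deep)[~shallow]
        )
    out = bathymetry.copy_with(labels.astype(float))
    out.nodata = -1.0
    return out


def _quantile_classes(field_: np.ndarray, where: np.ndarray, k: int) -> np.ndarray:
    """Threshold a continuous field into k roughly equal-mass classes."""
    out = np.zeros(field_.shape, dtype=int)
    if k <= 1 or not where.any():
        return out
    qs = np.quantile(field_[where], np.linspace(0, 1, k + 1)[1:-1])
    out[where] = np.searchsorted(qs, field_[where], side="right")
    return out


def simulate_survey(
    cfg: SimConfig,
    bathymetry: RasterGrid,
    habitat: RasterGrid,
    models: dict[int, ClassARModel],
) -> tuple[list[BackscatterSample], int]:
    """Run parallel north-south survey lines and emit per-beam samples.

    For each ping and each beam steering angle theta, the across-track seafloor
    position is computed on a flat-seafloor approximation (incidence angle =
    |theta|); the sample level is the habitat class's angular model evaluated
    at theta plus Gaussian noise. Returns (samples, n_skipped) where skipped
    samples are beam footprints landing outside the raster.
    """
    class_ids = set(np.unique(habitat.values[habitat.mask()]).astype(int))
    missing = class_ids - set(models)
    if missing:
        raise ValueError(f"no ClassARModel provided for class id(s) {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed + 2)
    # midpoint spacing: beams at +-(k + 0.5) * (2 span / n_beams) - span, so with
    # n_beams = 2 * span the unsigned angles sit exactly on 1-degree bin centres
    step = 2.0 * cfg.angular_span / cfg.n_beams
    thetas = -cfg.angular_span + (np.arange(cfg.n_beams) + 0.5) * step
    line_xs = np.arange(cfg.line_spacing / 2.0, cfg.extent, cfg.line_spacing)
    ping_ys = np.arange(cfg.ping_spacing / 2.0, cfg.extent, cfg.ping_spacing)

    samples: list[BackscatterSample] = []
    skipped = 0
    ping_counter = 0
    for line_id, lx in enumerate(line_xs):
        # slowly varying along-track gain error shared by all beams of a ping;
        # emulates the residual calibration artefacts of real mosaics
        if cfg.gain_drift_sd > 0:
            white = rng.standard_normal(len(ping_ys))
            drift = ndimage.gaussian_filter1d(white, sigma=cfg.gain_drift_len, mode="reflect")
            sd = drift.std()
            drift = cfg.gain_drift_sd * drift / sd if sd > 0 else drift * 0.0
        else:
            drift = np.zeros(len(ping_ys))
        for ping_i, py in enumerate(ping_ys):
            ping_counter += 1
            row, col = bathymetry.cell_of(lx, py)
            if not (0 <= row < bathymetry.n_rows and 0 <= col < bathymetry.n_cols):
                skipped += cfg.n_beams
                continue
            nadir_depth = bathymetry.values[row, col]
            offs = nadir_depth * np.tan(np.radians(thetas))
            sx = lx + offs
            sy = np.full_like(sx, py)
            inb = habitat.in_bounds(sx, sy)
            rr, cc = habitat.cell_of(sx[inb], sy[inb])
            cls = habitat.values[rr, cc].astype(int)
            kept_thetas = thetas[inb]
            kept_beams = np.nonzero(inb)[0]
            skipped += int((~inb).sum())
            noise = rng.standard_normal(len(kept_thetas))
            for i, (theta, beam, c) in enumerate(zip(kept_thetas, kept_beams, cls)):
                m = models[int(c)]
                lvl = float(m.level(abs(theta))) + m.noise_sd * noise[i] + drift[ping_i]
                samples.append(
                    BackscatterSample(
                        ping_id=ping_counter,
                        beam_id=int(beam),
                        x=float(sx[kept_beams[i]]),
                        y=float(py),
                        depth=float(bathymetry.values[rr[i], cc[i]]),
                        angle=abs(float(theta)),
                        level=lvl,
                        line_id=line_id,
                    )
                )
    return samples, skipped


def gen_ground_truth(
    habitat: RasterGrid, n_per_class: int, seed: int, train_fraction: float = 0.7
) -> list[GroundTruthPoint]:
    """Draw labelled points at cell centres of each class, split 70/30 per class."""
    labels_present = np.unique(habitat.values[habitat.mask()]).astype(int)
    rng = np.random.default_rng(seed)
    points: list[GroundTruthPoint] = []
    for cls in labels_present:
        rows, cols = np.nonzero(habitat.values == cls)
        if len(rows) == 0:
            raise ValueError(f"class {CLASS_LABELS[cls]} absent from the habitat map")
        if n_per_class > len(rows):
            raise ValueError(
                f"requested {n_per_class} points for class {CLASS_LABELS[cls]} "
                f"but only {len(rows)} cells exist"
            )
        pick = rng.choice(len(rows), size=n_per_class, replace=False)
        n_train = int(round(train_fraction * n_per_class))
        for k, idx in enumerate(pick):
            x, y = habitat.cell_centre(rows[idx], cols[idx])
            points.append(
                GroundTruthPoint(
                    x=float(x),
                    y=float(y),
                    label=CLASS_LABELS[cls],
                    split="train" if k < n_train else "test",
                )
            )
    return points
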