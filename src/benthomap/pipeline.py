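"""End-to-end orchestration: synthetic world -> 18-layer stack -> model runs.

This is the programmatic counterpart of chaining the CLI subcommands, used by
the recovery experiments and the acceptance checks: it builds the full layer
set (bathymetry + 6 terrain derivatives + mosaic + 6 mosaic derivatives + 4
angular-response features) for a simulated survey and fits paired
random-forest models with and without the angular-response features.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import angular, mosaic as mosaic_mod, segmentation
from .core_io import FeatureStack, GroundTruthPoint, RasterGrid, stack_layers
from .derivatives import WindowSpec, bathymetry_derivatives, mosaic_derivatives
from .model import ModelRun, RFConfig, run_model
from .synthetic import (
    ClassARModel,
    SimConfig,
    gen_bathymetry,
    gen_ground_truth,
    gen_habitat_map,
    simulate_survey,
)

#: Layer names of the mosaic-and-bathymetry-only model (Model-1 analogue).
BASE_LAYERS = (
    "bathymetry", "aspect", "rugosity", "max_curvature", "bpi", "slope", "complexity",
    "mosaic", "hsi_red", "hsi_green", "hsi_blue",
    "glcm_homogeneity", "glcm_entropy", "glcm_correlation",
)
#: The four angular-response layers added by the full model (Model-2 analogue).
AR_LAYERS = ("ar_mean", "ar_slope", "ar_skew", "ar_kurt")


@dataclass
class PipelineResult:
    stack: FeatureStack
    habitat: RasterGrid
    points: list[GroundTruthPoint]
    segments: segmentation.SegmentSet = None
    n_segments: int = 0


def recovery_world(
    seed: int, extent: float = 500.0, noise_sd: float = 8.0, gain_drift_sd: float = 4.0
) -> tuple[SimConfig, dict[int, ClassARModel]]:
    """A 4-class world where class is driven jointly by depth band and AR level.

    The two shallow-zone classes and the two deep-zone classes reuse the same
    pair of mean levels (-36 and -28 dB), so neither bathymetry nor the
    angular response alone separates all four classes — both must rank high.
    All classes share the angular slope, making ar_mean the discriminating AR
    feature, and per-sample noise is large enough that the gridded mosaic is a
    visibly degraded version of the class signal while the segment-averaged
    angular response stays clean.
    """
    cfg = SimConfig(
        extent=extent,
        cell_size=2.5,
        n_classes=4,
        base_depth=25.0,
        depth_trend=(0.05, 0.0),
        depth_split=25.0 + 0.05 * extent / 2.0,
        line_spacing=60.0,
        ping_spacing=2.5,
        n_beams=120,
        angular_span=60.0,
        patch_scale=80.0,
        gain_drift_sd=gain_drift_sd,
        gain_drift_len=20.0,
        seed=seed,
    )
    labels = cfg.class_labels()
    mus = (-36.0, -28.0, -36.0, -28.0)  # shallow pair, then deep pair
    models = {
        i: ClassARModel(label=labels[i], mu=mus[i], slope=0.3, shape=8.0, noise_sd=noise_sd)
        for i in range(4)
    }
    return cfg, models


def build_feature_stack(
    cfg: SimConfig,
    models: dict[int, ClassARModel],
    n_per_class: int = 150,
    similarity_threshold: float = 20.0,
    area_threshold: int = 150,
    bpi_spec: WindowSpec | None = None,
) -> PipelineResult:
    """Run every pipeline stage on a synthetic survey and assemble the stack."""
    bathy = gen_bathymetry(cfg)
    habitat = gen_habitat_map(cfg, bathy)
    samples, _ = simulate_survey(cfg, bathy, habitat, models)
    points = gen_ground_truth(habitat, n_per_class=n_per_class, seed=cfg.seed + 17)

    normed = mosaic_mod.angular_normalize(samples)
    mos = mosaic_mod.grid_mosaic(normed, bathy)
    mos8 = mosaic_mod.to_8bit(mos)

    seg_cfg = segmentation.SegmentationConfig(
        similarity_threshold=similarity_threshold, area_threshold=area_threshold
    )
    segments = segmentation.region_grow(mos8, seg_cfg)
    curves, _ = angular.compile_ar_curves(samples, segments)
    feats = [angular.ar_features(c) for c in curves]
    ar_grids = angular.rasterize_features(segments, feats, mos)

    if bpi_spec is None:
        bpi_spec = WindowSpec(bpi_inner=5, bpi_outer=8)
    layers: dict[str, RasterGrid] = {"bathymetry": bathy}
    layers.update(bathymetry_derivatives(bathy, bpi_spec))
    layers["mosaic"] = mos
    layers.update(mosaic_derivatives(mos, mos8))
    layers.update(ar_grids)

    # harmonise nodata across layers so model rows are either complete or dropped
    stack = stack_layers(layers)
    result = PipelineResult(stack=stack, habitat=habitat, points=points)
    result.segments = segments
    result.n_segments = len(segments)
    return result


def paired_model_runs(
    result: PipelineResult, seed: int, ntree: int = 200
) -> tuple[ModelRun, ModelRun]:
    """(without-AR, with-AR) model runs on the same seed and ground truth."""
    cfg = RFConfig(ntree=ntree, seed=seed)
    base = run_model(result.stack, result.points, list(BASE_LAYERS), cfg)
    full = run_model(result.stack, result.points, list(BASE_LAYERS) + list(AR_LAYERS), cfg)
    return base, full
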