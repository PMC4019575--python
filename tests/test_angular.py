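import numpy as np
import pytest

from benthomap.angular import (
    ARCurve,
    ar_features,
    compile_ar_curves,
    features_to_csv,
    rasterize_features,
)
from benthomap.core_io import RasterGrid, SegmentSet
from benthomap.segmentation import SegmentationConfig, region_grow
from benthomap.synthetic import (
    ClassARModel,
    SimConfig,
    gen_bathymetry,
    gen_habitat_map,
    simulate_survey,
)


def _linear_curve(mu=-30.0, slope=0.5, lo=30, hi=50, seg_id=1):
    centres = np.arange(lo, hi + 1, dtype=float)
    return ARCurve(
        segment_id=seg_id,
        bin_centres=centres,
        mean_dB=mu + slope * (centres - 40.0),
        counts=np.full(len(centres), 10),
    )


def _moments_oracle(values):
    """Independent brute-force central moments (plain Python loops)."""
    n = len(values)
    mean = sum(values) / n
    m2 = sum((v - mean) ** 2 for v in values) / n
    m3 = sum((v - mean) ** 3 for v in values) / n
    m4 = sum((v - mean) ** 4 for v in values) / n
    return mean, m2, m3, m4


class TestARFeatures:
    def test_symmetric_linear_curve(self):
        f = ar_features(_linear_curve())
        assert f.ar_mean == pytest.approx(-30.0, abs=1e-12)
        assert f.ar_slope == pytest.approx(0.5, abs=1e-12)
        assert f.ar_skew == pytest.approx(0.0, abs=1e-12)

    def test_kurtosis_matches_moment_oracle(self):
        curve = _linear_curve()
        values = list(curve.mean_dB)
        _, m2, _, m4 = _moments_oracle(values)
        f = ar_features(curve)
        assert f.ar_kurt == pytest.approx(m4 / m2**2, abs=1e-12)

    def test_constant_curve_degenerate(self):
        centres = np.arange(30, 51, dtype=float)
        curve = ARCurve(1, centres, np.full(len(centres), -25.0), np.full(len(centres), 5))
        f = ar_features(curve)
        assert f.ar_mean == -25.0
        assert f.ar_slope == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(f.ar_skew) and np.isnan(f.ar_kurt)
        assert f.defined

    def test_too_few_bins_undefined(self):
        centres = np.array([30.0, 35.0, 40.0])
        curve = ARCurve(1, centres, np.array([-30.0, -29.0, -28.0]), np.array([1, 1, 1]))
        f = ar_features(curve, min_bins=5)
        assert not f.defined

    def test_slope_invariant_to_constant_shift(self):
        rng = np.random.default_rng(0)
        centres = np.arange(30, 51, dtype=float)
        vals = rng.normal(-30, 2, len(centres))
        a = ar_features(ARCurve(1, centres, vals, np.ones(21, int)))
        b = ar_features(ARCurve(1, centres, vals + 7.3, np.ones(21, int)))
        assert b.ar_slope == pytest.approx(a.ar_slope, abs=1e-12)
        assert b.ar_mean == pytest.approx(a.ar_mean + 7.3, abs=1e-12)

    def test_skewness_zero_for_symmetric_curve(self):
        centres = np.arange(30, 51, dtype=float)
        vals = (centres - 40.0) ** 3  # value multiset symmetric about its mean (0)
        f = ar_features(ARCurve(1, centres, vals, np.ones(21, int)))
        assert abs(f.ar_skew) < 1e-12

    def test_slope_unbiased_under_noise(self):
        """Monte-Carlo: mean estimated slope within 3 SE of the true slope."""
        rng = np.random.default_rng(42)
        centres = np.arange(30, 51, dtype=float)
        true = 0.5
        n_rep = 200
        slopes = []
        for _ in range(n_rep):
            vals = -30 + true * (centres - 40) + rng.normal(0, 1.0, len(centres))
            slopes.append(ar_features(ARCurve(1, centres, vals, np.ones(21, int))).ar_slope)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(n_rep)
        assert abs(slopes.mean() - true) < 3 * se


class TestCompileCurves:
    def _one_segment_world(self, flat_cfg, flat_model):
        bathy = gen_bathymetry(flat_cfg)
        hab = gen_habitat_map(flat_cfg, bathy)
        samples, _ = simulate_survey(flat_cfg, bathy, hab, {0: flat_model})
        labels = bathy.copy_with(np.ones(bathy.shape))
        labels.nodata = 0.0
        seg = SegmentSet(label_raster=labels, areas={1: bathy.values.size})
        return samples, seg

    def test_noiseless_linear_identity(self, flat_cfg, flat_model):
        samples, seg = self._one_segment_world(flat_cfg, flat_model)
        curves, outside = compile_ar_curves(samples, seg)
        assert outside == 0
        assert len(curves) == 1
        c = curves[0]
        sel = (c.bin_centres >= 30) & (c.bin_centres <= 50)
        np.testing.assert_allclose(
            c.mean_dB[sel], flat_model.level(c.bin_centres[sel]), atol=1e-12
        )
        f = ar_features(c)
        assert f.ar_mean == pytest.approx(-30.0, abs=1e-9)
        assert f.ar_slope == pytest.approx(0.5, abs=1e-9)

    def test_two_segment_simulator_oracle(self):
        """Each compiled curve matches its generating class model bin-by-bin."""
        cfg = SimConfig(
            extent=200, n_classes=2, seed=4, n_beams=120, angular_span=60.0,
            line_spacing=40.0, ping_spacing=2.5, patch_scale=50.0,
        )
        bathy = gen_bathymetry(cfg)
        hab = gen_habitat_map(cfg, bathy)
        models = {
            0: ClassARModel("MB", mu=-35.0, slope=0.2, shape=6.0),
            1: ClassARModel("INV", mu=-25.0, slope=0.6, shape=6.0),
        }
        samples, _ = simulate_survey(cfg, bathy, hab, models)
        # segments = true class patches (labels are class id + 1)
        labels = hab.copy_with(hab.values + 1.0)
        labels.nodata = 0.0
        areas = {i + 1: int((hab.values == i).sum()) for i in (0, 1)}
        seg = SegmentSet(label_raster=labels, areas=areas)
        curves, _ = compile_ar_curves(samples, seg)
        assert len(curves) == 2
        for curve in curves:
            model = models[curve.segment_id - 1]
            np.testing.assert_allclose(curve.mean_dB, model.level(curve.bin_centres), atol=1e-12)

    def test_boundary_sample_assigned_once(self, small_grid):
        from benthomap.core_io import BackscatterSample

        labels = small_grid.copy_with(np.repeat([[1, 1, 2, 2, 2]], 5, axis=0).astype(float))
        labels.nodata = 0.0
        seg = SegmentSet(label_raster=labels, areas={1: 10, 2: 15})
        # sample exactly on the cell boundary x = 5.0 -> containment by cell rule
        s = BackscatterSample(1, 1, x=5.0, y=6.25, depth=30, angle=40.0, level=-30.0)
        curves, outside = compile_ar_curves([s] * 40, seg, bin_width=1.0)
        assert outside == 0
        assert len(curves) == 1  # exactly one segment received the samples

    def test_empty_segment_omitted(self, small_grid):
        from benthomap.core_io import BackscatterSample

        labels = small_grid.copy_with(np.repeat([[1, 1, 1, 1, 2]], 5, axis=0).astype(float))
        labels.nodata = 0.0
        seg = SegmentSet(label_raster=labels, areas={1: 20, 2: 5})
        s = BackscatterSample(1, 1, x=1.0, y=6.25, depth=30, angle=40.0, level=-30.0)
        curves, _ = compile_ar_curves([s], seg)
        assert [c.segment_id for c in curves] == [1]


class TestRasterize:
    def _seg_and_features(self, small_grid):
        labels = small_grid.copy_with(np.repeat([[1, 1, 2, 2, 2]], 5, axis=0).astype(float))
        labels.nodata = 0.0
        seg = SegmentSet(label_raster=labels, areas={1: 10, 2: 15})
        feats = [
            ar_features(_linear_curve(mu=-20.0, slope=0.0, seg_id=1)),
            ar_features(_linear_curve(mu=-40.0, slope=0.0, seg_id=2)),
        ]
        return seg, feats

    def test_piecewise_constant(self, small_grid):
        seg, feats = self._seg_and_features(small_grid)
        grids = rasterize_features(seg, feats, small_grid)
        vals = grids["ar_mean"].values
        assert set(np.unique(vals)) == {-20.0, -40.0}

    def test_histogram_mass_equals_areas(self, small_grid):
        seg, feats = self._seg_and_features(small_grid)
        grids = rasterize_features(seg, feats, small_grid)
        vals = grids["ar_mean"].values
        assert (vals == -20.0).sum() == 10
        assert (vals == -40.0).sum() == 15

    def test_zonal_mean_roundtrip(self, small_grid):
        seg, feats = self._seg_and_features(small_grid)
        grids = rasterize_features(seg, feats, small_grid)
        labels = seg.label_raster.values
        for f in feats:
            zone = grids["ar_mean"].values[labels == f.segment_id]
            assert zone.mean() == pytest.approx(f.ar_mean)

    def test_undefined_features_nodata(self, small_grid):
        labels = small_grid.copy_with(np.ones((5, 5)))
        labels.nodata = 0.0
        seg = SegmentSet(label_raster=labels, areas={1: 25})
        from benthomap.angular import ARFeatures

        grids = rasterize_features(seg, [ARFeatures.undefined(1)], small_grid)
        assert not grids["ar_mean"].mask().any()


def test_features_csv(tmp_path, small_grid):
    curve = _linear_curve()
    feats = [ar_features(curve)]
    path = tmp_path / "f.csv"
    features_to_csv([curve], feats, str(path))
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2
    assert lines[0].startswith("segment_id")


def test_full_pipeline_segment_recovery(flat_cfg, flat_model):
    """Region-grown segments of a noiseless mosaic give exact AR features."""
    from benthomap.mosaic import angular_normalize, grid_mosaic, to_8bit

    bathy = gen_bathymetry(flat_cfg)
    hab = gen_habitat_map(flat_cfg, bathy)
    samples, _ = simulate_survey(flat_cfg, bathy, hab, {0: flat_model})
    mosaic = grid_mosaic(angular_normalize(samples), bathy)
    m8 = to_8bit(mosaic, -60, -10)
    seg = region_grow(m8, SegmentationConfig(similarity_threshold=1, area_threshold=50))
    assert len(seg) == 1
    curves, _ = compile_ar_curves(samples, seg)
    f = ar_features(curves[0])
    assert f.ar_mean == pytest.approx(-30.0, abs=1e-9)
    assert f.ar_slope == pytest.approx(0.5, abs=1e-9)
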