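import numpy as np
import pytest

from mitofoi import (
    AnnotationSet,
    CellAnnotation,
    CellLabel,
    Detection,
    FOIShape,
    GridSpec,
    PatchFrame,
    SlideGeometry,
    detections_to_points,
    noisy_oracle,
    oracle_density,
    segmap_to_density,
    segmentation_target,
    windowed_count_map,
)


def _shape(w, h):
    return FOIShape(area_mm2=w * h * 6.25 / 1e6, aspect_w=1, aspect_h=1, width_px=w, height_px=h, mpp=2.5)


class TestOracleDensity:
    def test_delegates_to_windowed_count_map(self, small_aset):
        shape = _shape(400, 300)
        grid = GridSpec.cover(small_aset.geometry, 50)
        est = oracle_density(small_aset, shape, grid)
        ref = windowed_count_map(
            small_aset.points(CellLabel.MITOSIS), small_aset.geometry, shape, grid
        )
        np.testing.assert_array_equal(est.density.values, ref.values)
        assert est.provenance == "oracle" and not est.per_patch

    def test_empty_and_negatives_only(self):
        g = SlideGeometry(500, 400, 2.5)
        grid = GridSpec.cover(g, 50)
        shape = _shape(200, 150)
        empty = AnnotationSet("e", g, [])
        assert not oracle_density(empty, shape, grid).density.values.any()
        hn = AnnotationSet("h", g, [CellAnnotation(10, 10, CellLabel.HARD_NEGATIVE)])
        assert not oracle_density(hn, shape, grid).density.values.any()


class TestNoisyOracle:
    def test_degenerate_noise_equals_oracle(self, small_aset):
        shape = _shape(400, 300)
        grid = GridSpec.cover(small_aset.geometry, 50)
        est = noisy_oracle(small_aset, shape, grid, fn_rate=0.0, fp_per_mm2=0.0, seed=3)
        ref = oracle_density(small_aset, shape, grid)
        np.testing.assert_array_equal(est.density.values, ref.density.values)

    def test_total_miss_gives_zero_map(self, small_aset):
        shape = _shape(400, 300)
        grid = GridSpec.cover(small_aset.geometry, 50)
        est = noisy_oracle(small_aset, shape, grid, fn_rate=1.0, seed=3)
        assert not est.density.values.any()

    def test_binomial_retention(self):
        """With fn_rate=0.3 over 1000 true figures, the retained count behaves
        binomially: each seed within 4 sigma, the mean across seeds within
        3 sigma of its standard error."""
        rng = np.random.default_rng(0)
        g = SlideGeometry(2000, 2000, 2.5)
        cells = [
            CellAnnotation(int(x), int(y), CellLabel.MITOSIS)
            for x, y in rng.integers(0, 2000, (1000, 2))
        ]
        aset = AnnotationSet("big", g, cells)
        # one grid cell, window = whole slide => map value == retained count
        grid = GridSpec(stride=1, origin_x=1000, origin_y=1000, n_cols=1, n_rows=1)
        shape = _shape(2000, 2000)
        sigma = np.sqrt(1000 * 0.7 * 0.3)
        counts = []
        for seed in range(30):
            est = noisy_oracle(aset, shape, grid, fn_rate=0.3, seed=seed)
            c = est.density.values[0, 0]
            counts.append(c)
            assert abs(c - 700) <= 4 * sigma
        assert abs(np.mean(counts) - 700) <= 3 * sigma / np.sqrt(len(counts))

    def test_nested_retention_across_fn_rates(self, small_aset):
        """Same seed, higher fn_rate: the retained point set shrinks, so every
        map value is non-increasing in fn_rate (common-random-numbers coupling)."""
        shape = _shape(400, 300)
        grid = GridSpec.cover(small_aset.geometry, 50)
        prev = None
        for fn in (0.0, 0.3, 0.6, 1.0):
            vals = noisy_oracle(small_aset, shape, grid, fn_rate=fn, seed=11).density.values
            if prev is not None:
                assert np.all(vals <= prev)
            prev = vals


class TestDetectionsToPoints:
    DETS = [
        Detection(0, 0, 0.9, 0.9),
        Detection(1, 0, 0.9, 0.4),
        Detection(2, 0, 0.4, 0.9),
        Detection(3, 0, 0.6, None),
        Detection(4, 0, 0.5, 0.5),
        Detection(5, 0, 0.2, None),
    ]

    def test_zero_thresholds_keep_all(self):
        assert len(detections_to_points(self.DETS, 0, 0)) == 6

    def test_hand_enumerated_filter(self):
        # t1=t2=0.5: kept are 0 (0.9/0.9), 3 (0.6/none), 4 (0.5/0.5)
        pts = detections_to_points(self.DETS, 0.5, 0.5)
        assert pts[:, 0].tolist() == [0, 3, 4]

    def test_stage2_filter(self):
        pts = detections_to_points([Detection(7, 8, 0.9, 0.4)], 0.5, 0.5)
        assert len(pts) == 0

    def test_antitone_in_thresholds(self):
        rng = np.random.default_rng(6)
        dets = [
            Detection(i, 0, float(rng.random()), float(rng.random()) if rng.random() < 0.7 else None)
            for i in range(50)
        ]
        for _ in range(20):
            t1a, t1b = sorted(rng.random(2))
            t2a, t2b = sorted(rng.random(2))
            lo = {tuple(p) for p in detections_to_points(dets, t1b, t2b)}
            hi = {tuple(p) for p in detections_to_points(dets, t1a, t2a)}
            assert lo <= hi

    def test_score_validation(self):
        with pytest.raises(ValueError):
            Detection(0, 0, 1.5)
        with pytest.raises(ValueError):
            detections_to_points(self.DETS, -0.1, 0.5)


class TestSegmapToDensity:
    def test_empty_mask_zero(self):
        grid = GridSpec(stride=50, origin_x=100, origin_y=100, n_cols=3, n_rows=2)
        est = segmap_to_density(np.zeros((300, 400), bool), _shape(200, 150), grid, d=30)
        assert not est.density.values.any()

    def test_single_disc_counts_about_one(self):
        """A complete disc of diameter d inside the window scores ~1 figure."""
        d = 30
        mask = segmentation_target(PatchFrame(400, 300, [(0, 0)]), d=d)
        grid = GridSpec(stride=1, origin_x=200, origin_y=150, n_cols=1, n_rows=1)
        est = segmap_to_density(mask, _shape(300, 200), grid, d=d)
        assert 0.92 <= est.density.values[0, 0] <= 1.08

    def test_additive_in_disjoint_discs(self):
        d = 30
        one = segmentation_target(PatchFrame(400, 300, [(-80, 0)]), d=d)
        two = segmentation_target(PatchFrame(400, 300, [(-80, 0), (80, 0)]), d=d)
        grid = GridSpec(stride=1, origin_x=200, origin_y=150, n_cols=1, n_rows=1)
        v1 = segmap_to_density(one, _shape(300, 200), grid, d=d).density.values[0, 0]
        v2 = segmap_to_density(two, _shape(300, 200), grid, d=d).density.values[0, 0]
        assert v2 == pytest.approx(2 * v1, rel=1e-9)

    def test_approximates_oracle_for_separated_figures(self):
        """Converting the full-slide segmentation target back through the
        density adapter recovers the windowed figure count within
        disc-discretization error."""
        d = 30
        g = SlideGeometry(600, 450, 2.5)
        pts_rel = [(-200, -150), (0, 0), (180, 120), (-150, 140), (120, -130)]
        mask = segmentation_target(PatchFrame(600, 450, pts_rel), d=d)
        pts_abs = np.array([(x + 300, y + 225) for x, y in pts_rel])
        shape = _shape(560, 420)
        grid = GridSpec(stride=1, origin_x=300, origin_y=225, n_cols=1, n_rows=1)
        seg = segmap_to_density(mask, shape, grid, d=d, geometry=g)
        oracle = windowed_count_map(pts_abs, g, shape, grid)
        assert oracle.values[0, 0] == 5
        assert seg.density.values[0, 0] == pytest.approx(5, rel=0.08)
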