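"""Detector backends: reference blob detector, oracle, score filter."""

import numpy as np
import pytest

from organoidquant import (
    Box,
    Detection,
    DetectorConfig,
    OracleDetector,
    ReferenceBlobDetector,
    SceneSpec,
    generate_scene,
    iou,
    score_threshold_filter,
)


def render_clean_patch(seed=7, n=3, size=450):
    spec = SceneSpec(
        width=size, height=size, n_organoids=n,
        radius_range=(18.0, 45.0), overlap_allowed=False,
        noise_sigma=1.0, seed=seed,
    )
    return generate_scene(spec)


class TestReferenceBlobDetector:
    def test_recovers_well_separated_organoids(self, easy_scene):
        img, gt = easy_scene
        dets = ReferenceBlobDetector().detect(img)
        assert len(dets) == len(gt.boxes)
        m_iou = [max(iou(b, d.box) for d in dets) for b in gt.boxes]
        assert all(v >= 0.7 for v in m_iou)

    def test_heavily_blurred_organoid_rejected_by_focus_gate(self):
        spec = SceneSpec(
            width=450, height=450, n_organoids=3,
            radius_range=(18.0, 40.0), overlap_allowed=False,
            defocus_fraction=1 / 3, defocus_sigma=12.0,
            noise_sigma=1.0, seed=21,
        )
        img, gt = generate_scene(spec)
        blurred = [b for b, f in zip(gt.boxes, gt.in_focus_flags) if not f]
        sharp = [b for b, f in zip(gt.boxes, gt.in_focus_flags) if f]
        assert len(blurred) == 1
        dets = ReferenceBlobDetector().detect(img)
        assert all(max((iou(b, d.box) for d in dets), default=0) >= 0.7
                   for b in sharp)
        assert max((iou(blurred[0], d.box) for d in dets), default=0) < 0.5

    def test_blank_noisy_patch_yields_nothing(self, rng):
        patch = np.clip(
            rng.normal(224, 2.0, (450, 450)), 0, 255
        ).astype(np.uint8)
        assert ReferenceBlobDetector().detect(patch) == []

    def test_uniform_patch_yields_nothing(self):
        patch = np.full((300, 300), 224, dtype=np.uint8)
        assert ReferenceBlobDetector().detect(patch) == []

    def test_deterministic_output(self, easy_scene):
        img, _ = easy_scene
        det = ReferenceBlobDetector()
        assert det.detect(img) == det.detect(img)

    def test_boxes_inside_patch_and_scores_valid(self, easy_scene):
        img, _ = easy_scene
        size = img.shape[0]
        for d in ReferenceBlobDetector().detect(img):
            assert 0 <= d.box.xmin < d.box.xmax <= size
            assert 0 <= d.box.ymin < d.box.ymax <= size
            assert 0.0 <= d.score <= 1.0

    def test_translation_equivariance_away_from_border(self):
        # render one organoid, embed at two offsets in a larger patch
        spec = SceneSpec(
            width=200, height=200, n_organoids=1, radius_range=(20.0, 30.0),
            noise_sigma=0.0, seed=13,
        )
        small, gt = generate_scene(spec)
        background = small[0, 0]
        det = ReferenceBlobDetector()

        def embed(dx, dy):
            patch = np.full((450, 450), background, dtype=np.uint8)
            patch[dy : dy + 200, dx : dx + 200] = small
            return patch

        d1 = det.detect(embed(40, 60))
        d2 = det.detect(embed(140, 110))
        assert len(d1) == len(d2) == 1
        shifted = d1[0].box.translate(100, 50)
        assert shifted == d2[0].box

    def test_raising_score_floor_never_adds_detections(self, easy_scene):
        img, _ = easy_scene
        low = ReferenceBlobDetector(DetectorConfig(score_floor=0.0)).detect(img)
        high = ReferenceBlobDetector(DetectorConfig(score_floor=0.3)).detect(img)
        low_boxes = {d.box for d in low}
        assert {d.box for d in high} <= low_boxes

    def test_non_finite_pixels_rejected(self):
        patch = np.full((100, 100), 0.5)
        patch[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            ReferenceBlobDetector().detect(patch)

    def test_non_square_patch_rejected(self):
        with pytest.raises(ValueError, match="square"):
            ReferenceBlobDetector().detect(np.zeros((100, 200), dtype=np.uint8))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectorConfig(smoothing_sigma_fine=10.0, smoothing_sigma_coarse=5.0)
        with pytest.raises(ValueError):
            DetectorConfig(min_area=0)


class TestOracleDetector:
    def test_returns_ground_truth_clipped_to_tile(self):
        boxes = [Box(10, 10, 50, 50), Box(400, 400, 460, 470), Box(600, 600, 650, 650)]
        det = OracleDetector(boxes)
        patch = np.zeros((450, 450), dtype=np.uint8)
        out = det.detect(patch, origin=(0, 0))
        assert [d.box for d in out] == [Box(10, 10, 50, 50), Box(400, 400, 450, 450)]
        out2 = det.detect(patch, origin=(300, 300))
        # boxes shifted into tile-local coordinates
        assert [d.box for d in out2] == [
            Box(100, 100, 160, 170),
            Box(300, 300, 350, 350),
        ]


class TestScoreThresholdFilter:
    def make(self, scores):
        return [Detection(Box(10 * i, 0, 10 * i + 5, 5), s) for i, s in
                enumerate(scores)]

    def test_zero_threshold_is_identity(self):
        dets = self.make([0.3, 0.8, 0.9])
        assert score_threshold_filter(dets, 0.0) == dets

    def test_cut_keeps_order_and_counts(self):
        dets = self.make([0.3, 0.8, 0.9])
        out = score_threshold_filter(dets, 0.5)
        assert [d.score for d in out] == [0.8, 0.9]

    def test_threshold_one_keeps_only_perfect_scores(self):
        dets = self.make([1.0, 0.999])
        assert [d.score for d in score_threshold_filter(dets, 1.0)] == [1.0]
        with pytest.raises(ValueError):
            score_threshold_filter(dets, 1.1)
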