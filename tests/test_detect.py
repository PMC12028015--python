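import numpy as np
import pytest
import shapely

import cordquant as cq
from cordquant._bruteforce import (
    between_class_variance,
    flood_fill_particle_count,
    otsu_exhaustive,
)
from cordquant.detect import probmap_to_detections, segment_neurons, select_threshold
from cordquant.synthdata import SectionImage


class TestSelectThreshold:
    def test_separable_two_level_image(self):
        rng = np.random.default_rng(0)
        img = np.where(rng.random((50, 50)) < 0.9, 10.0, 200.0)
        t = select_threshold(img, "otsu")
        assert 10.0 < t < 200.0

    def test_fixed_is_identity(self):
        img = np.zeros((5, 5))
        assert select_threshold(img, "fixed", 50.0) == 50.0

    def test_otsu_matches_exhaustive_between_class_variance(self):
        rng = np.random.default_rng(1)
        img = np.concatenate(
            [rng.normal(40, 8, 2000), rng.normal(180, 15, 500)]
        ).reshape(50, 50)
        t_fast = select_threshold(img, "otsu")
        t_brute = otsu_exhaustive(img)
        # both cuts attain (essentially) the maximal between-class variance
        v_fast = between_class_variance(img, t_fast)
        v_brute = between_class_variance(img, t_brute)
        # 256-bin discretisation leaves sub-percent slack between the cuts
        assert v_fast >= 0.995 * v_brute
        # and both fall in the valley between the two modes
        assert 55.0 < t_fast < 150.0 and 55.0 < t_brute < 150.0

    def test_constant_image_fallback(self):
        img = np.full((8, 8), 7.0)
        for method in ("otsu", "triangle", "isodata", "mean", "auto"):
            assert select_threshold(img, method) == 7.0

    def test_auto_picks_a_separating_cut(self):
        rng = np.random.default_rng(2)
        img = np.where(rng.random((60, 60)) < 0.8, 20.0, 220.0) + rng.normal(0, 2, (60, 60))
        t = select_threshold(img, "auto")
        # the chosen cut must separate the two populations (~20% bright)
        assert 0.15 < (img > t).mean() < 0.25

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            select_threshold(np.ones((4, 4)), "median")  # type: ignore[arg-type]


def _single_disc_image(radius_um=3.1, pixel_size=1.0, size=40, with_nucleus=True):
    s = pixel_size
    img = np.zeros((size, size), dtype=np.float32)
    nuc = np.zeros_like(img)
    cx = cy = size * s / 2
    ii, jj = np.mgrid[:size, :size]
    d2 = ((ii + 0.5) * s - cy) ** 2 + ((jj + 0.5) * s - cx) ** 2
    img[d2 <= radius_um**2] = 200.0
    if with_nucleus:
        nuc[d2 <= (0.7 * radius_um) ** 2] = 150.0
    return SectionImage(neuronal=img, nuclear=nuc, pixel_size=s), (cx, cy)


class TestSegmentNeurons:
    def test_blank_image(self):
        image = SectionImage(
            neuronal=np.zeros((20, 20), np.float32),
            nuclear=np.zeros((20, 20), np.float32),
            pixel_size=1.0,
        )
        _, det = segment_neurons(image, cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0))
        assert len(det) == 0

    def test_single_disc_detected_at_centroid(self):
        image, (cx, cy) = _single_disc_image(radius_um=3.1)  # ~30 µm²
        labels, det = segment_neurons(
            image, cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0)
        )
        assert len(det) == 1
        assert abs(det.x[0] - cx) <= 1.0 and abs(det.y[0] - cy) <= 1.0
        assert det.area_um2[0] > 25.0
        assert labels.max() == 1

    def test_area_filter_strict(self):
        image, _ = _single_disc_image(radius_um=2.0)  # ~12 µm² < 25
        _, det = segment_neurons(
            image, cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0)
        )
        assert len(det) == 0

    def test_colocalization_required(self):
        image, _ = _single_disc_image(radius_um=3.1, with_nucleus=False)
        params_on = cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0)
        _, det_on = segment_neurons(image, params_on)
        assert len(det_on) == 0  # soma without a nucleus is dropped
        params_off = cq.DetectParams(
            threshold_method="fixed", fixed_threshold=50.0,
            require_nuclear_colocalization=False,
        )
        _, det_off = segment_neurons(image, params_off)
        assert len(det_off) == 1

    def test_noiseless_section_count_matches_truth(self, atlas, noiseless_section):
        """On a clean rendering the macro count equals the truth count
        (minus any merged touching pairs)."""
        image, truth = noiseless_section
        params = cq.DetectParams(
            threshold_method="fixed", fixed_threshold=50.0,
            grey_mask=atlas.grey_outline, split_touching=True,
        )
        _, det = segment_neurons(image, params)
        assert abs(len(det) - len(truth)) <= 0.05 * len(truth)

    def test_colocalization_removes_all_artifact_only_objects(self, atlas, noiseless_section):
        image, truth = noiseless_section
        base = dict(threshold_method="fixed", fixed_threshold=50.0, grey_mask=atlas.grey_outline)
        _, det_on = segment_neurons(image, cq.DetectParams(**base))
        _, det_off = segment_neurons(
            image, cq.DetectParams(require_nuclear_colocalization=False, **base)
        )
        assert len(det_off) >= len(det_on)
        # with colocalization every detection lies near a true neuron
        for x, y in zip(det_on.x, det_on.y):
            d = np.hypot(truth.x - x, truth.y - y)
            assert d.min() < 15.0

    def test_mask_restriction(self, atlas, noiseless_section):
        image, _ = noiseless_section
        params = cq.DetectParams(
            threshold_method="fixed", fixed_threshold=50.0, grey_mask=atlas.grey_outline
        )
        _, det = segment_neurons(image, params)
        outline = atlas.outline_polygon.buffer(5.0)  # centroid tolerance at the rim
        assert shapely.intersects_xy(outline, det.x, det.y).all()

    def test_min_area_monotonicity(self, noiseless_section):
        image, _ = noiseless_section
        counts = []
        for a in (10.0, 25.0, 60.0, 120.0):
            _, det = segment_neurons(
                image, cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0,
                                       min_area_um2=a)
            )
            counts.append(len(det))
        assert counts == sorted(counts, reverse=True)

    def test_missing_nuclear_data_rejected(self):
        with pytest.raises(ValueError):
            cq.DetectParams(threshold_method="fixed")  # fixed needs a value
        with pytest.raises(ValueError):
            cq.DetectParams(fixed_threshold=10.0)  # value needs method fixed


class TestProbmapToDetections:
    def test_uniform_zero_map(self):
        det = probmap_to_detections(np.zeros((30, 30)), pixel_size=1.0)
        assert len(det) == 0

    def test_boundary_area_rejected(self):
        """A 24-pixel particle at 1 µm/px is 24 µm² — below the strict cut."""
        prob = np.zeros((20, 20))
        prob[5:9, 5:11] = 0.9  # 4 × 6 = 24 px
        assert len(probmap_to_detections(prob, 1.0)) == 0
        prob[9, 5:7] = 0.9  # grow to 26 px
        assert len(probmap_to_detections(prob, 1.0)) == 1

    def test_exact_25_um2_rejected(self):
        prob = np.zeros((20, 20))
        prob[5:10, 5:10] = 1.0  # exactly 25 px = 25 µm²
        assert len(probmap_to_detections(prob, 1.0)) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        prob = rng.random((50, 50))
        det = probmap_to_detections(prob, pixel_size=2.0, p_cut=0.5, min_area_um2=25.0)
        n_oracle, areas = flood_fill_particle_count(prob > 0.5, min_area_px=25.0 / 4.0)
        assert len(det) == n_oracle
        assert sorted(det.area_um2.tolist()) == pytest.approx(sorted(a * 4.0 for a in areas))

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            probmap_to_detections(np.full((5, 5), 1.5), 1.0)


def test_area_bookkeeping(noiseless_section):
    """Σ component areas never exceeds the suprathreshold area."""
    image, _ = noiseless_section
    params = cq.DetectParams(threshold_method="fixed", fixed_threshold=50.0)
    _, det = segment_neurons(image, params)
    supra = float((image.neuronal > 50.0).sum()) * image.pixel_size**2
    assert det.area_um2.sum() <= supra + 1e-6
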