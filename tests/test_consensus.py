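import numpy as np
import pytest
from scipy import stats

import cordquant as cq
from cordquant._bruteforce import exhaustive_min_cost_partition
from cordquant.detect import DetectionSet

from conftest import jittered_sets


def _set(points, source_id, section_id="sec"):
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    return DetectionSet(x=pts[:, 0], y=pts[:, 1], source_id=source_id, section_id=section_id)


def _random_clustered_instance(rng, n_sets=3, n_clusters=5, jitter=0.5, spacing=100.0):
    """Well-separated truth clusters sampled by several sources."""
    centres = rng.uniform(0, spacing * n_clusters, (n_clusters, 2))
    # enforce separation
    centres = np.array(
        [[spacing * i + rng.uniform(0, 20), rng.uniform(0, 50)] for i in range(n_clusters)]
    )
    sets = []
    for si in range(n_sets):
        pts = []
        for c in centres:
            if rng.random() < 0.8:
                pts.append(c + rng.normal(0, jitter, 2))
        arr = np.asarray(pts) if pts else np.empty((0, 2))
        sets.append(_set(arr, f"s{si}"))
    return sets


class TestMatchDetectionSets:
    def test_identical_sets_all_k2(self):
        a = _set([(0, 0), (50, 50), (90, 10)], "a")
        b = _set([(0, 0), (50, 50), (90, 10)], "b")
        table = cq.match_detection_sets([a, b], radius=10)
        assert len(table) == 3
        assert all(obj.k == 2 for obj in table.objects)

    def test_far_points_never_linked(self):
        a = _set([(0, 0), (100, 0)], "a")
        b = _set([(50, 50)], "b")
        table = cq.match_detection_sets([a, b], radius=5)
        assert len(table) == 3
        assert all(obj.k == 1 for obj in table.objects)

    def test_point_conservation(self):
        rng = np.random.default_rng(0)
        sets = _random_clustered_instance(rng, n_sets=4)
        table = cq.match_detection_sets(sets, radius=10)
        assert sum(obj.k for obj in table.objects) == sum(len(s) for s in sets)
        for obj in table.objects:
            assert len(obj.contributions) == obj.k  # ≤ 1 point per source

    def test_same_source_points_never_merge(self):
        a = _set([(0, 0), (1, 1)], "a")
        table = cq.match_detection_sets([a], radius=10)
        assert len(table) == 2

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        sets = _random_clustered_instance(rng, n_sets=4)
        t1 = cq.match_detection_sets(sets, radius=10)
        t2 = cq.match_detection_sets(sets[::-1], radius=10)
        np.testing.assert_array_equal(t1.class_counts(), t2.class_counts())
        assert cq.reference_number_of_neurons(t1) == pytest.approx(
            cq.reference_number_of_neurons(t2)
        )

    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            cq.match_detection_sets([_set([(0, 0)], "a")], radius=0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_min_cost_partition(self, seed):
        """Greedy partition equals the exhaustive optimum on small instances."""
        rng = np.random.default_rng(seed)
        n_sets = int(rng.integers(2, 6))
        n_clusters = int(rng.integers(2, 9))
        sets = _random_clustered_instance(rng, n_sets=n_sets, n_clusters=n_clusters)
        radius = 10.0
        table = cq.match_detection_sets(sets, radius=radius)
        n_opt, _, _ = exhaustive_min_cost_partition(sets, radius)
        assert len(table) == n_opt


class TestAgreementHistogram:
    def test_no_extra_sets_class0_empty(self):
        a = _set([(0, 0)], "a")
        b = _set([(0, 1)], "b")
        table = cq.match_detection_sets([a, b], radius=10)
        freqs = cq.agreement_histogram(table)
        assert freqs[0] == 0

    def test_binomial_recovery(self, atlas, config):
        """K=5 observers at sensitivity 0.8: classes follow Binomial(5, 0.8)."""
        _, truth = cq.simulate_section(atlas, config, seed=500)
        sets = jittered_sets(truth, atlas, k=5, sensitivity=0.8, jitter=1.0, seed0=100)
        table = cq.match_detection_sets(sets, radius=10)
        observed = table.class_counts().astype(float)
        observed[0] = len(truth) - len(table)  # truths missed by everyone
        expected = stats.binom.pmf(np.arange(6), 5, 0.8) * len(truth)
        # pool cells with tiny expectation into their neighbour
        while expected[0] < 1.0:
            expected[1] += expected[0]
            observed[1] += observed[0]
            expected, observed = expected[1:], observed[1:]
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert chi2 < stats.chi2.ppf(0.99, len(expected) - 1)

    def test_normalization_contract(self, atlas, config):
        _, truth = cq.simulate_section(atlas, config, seed=501)
        sets = jittered_sets(truth, atlas, k=3, sensitivity=0.9, jitter=1.0, seed0=7)
        table = cq.match_detection_sets(sets, radius=10)
        freqs = cq.agreement_histogram(table, normalize=True)
        assert freqs[1:].sum() == pytest.approx(100.0)

    def test_extra_sets_populate_class0(self):
        a = _set([(0, 0), (50, 50)], "a")
        b = _set([(0, 1), (50, 51)], "b")
        table = cq.match_detection_sets([a, b], radius=10)
        method = _set([(0, 0), (50, 50), (200, 200)], "macro")
        freqs = cq.agreement_histogram(table, [method])
        assert freqs[0] == 1  # only the unmatched point forms a class-0 object
        assert freqs[2] == 2


class TestReferenceNumberOfNeurons:
    def test_unanimous_analysts(self):
        pts = [(i * 30.0, 0.0) for i in range(7)]
        sets = [_set(pts, f"a{i}") for i in range(4)]
        table = cq.match_detection_sets(sets, radius=10)
        assert cq.reference_number_of_neurons(table) == pytest.approx(7.0)

    def test_single_analyst(self):
        table = cq.match_detection_sets([_set([(0, 0), (30, 0)], "a")], radius=10)
        assert cq.reference_number_of_neurons(table) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_rnn_equals_mean_of_per_analyst_counts(self, seed):
        rng = np.random.default_rng(seed)
        sets = _random_clustered_instance(rng, n_sets=int(rng.integers(1, 6)))
        table = cq.match_detection_sets(sets, radius=10)
        mean_count = np.mean([len(s) for s in sets])
        assert cq.reference_number_of_neurons(table) == pytest.approx(mean_count, abs=1e-9)


class TestMethodOverlap:
    def test_method_identical_to_one_analyst(self):
        pts = [(i * 40.0, 0.0) for i in range(5)]
        sets = [_set(pts, "a"), _set([(p[0], p[1] + 1) for p in pts], "b")]
        table = cq.match_detection_sets(sets, radius=10)
        res = cq.method_overlap_stats(_set(pts, "macro"), table)
        assert res["extra_percent"] == 0.0
        assert res["n_extra"] == 0

    def test_empty_method_set(self):
        table = cq.match_detection_sets([_set([(0, 0)], "a")], radius=10)
        res = cq.method_overlap_stats(_set(np.empty((0, 2)), "macro"), table)
        assert res["extra_percent"] == 0.0
        assert res["detection_fraction_by_class"][1] == 0.0

    def test_detection_fraction_nondecreasing_in_k(self, atlas, config):
        """A method that sees all truth detects high-agreement objects
        at least as often as doubtful ones."""
        _, truth = cq.simulate_section(atlas, config, seed=502)
        sets = jittered_sets(truth, atlas, k=5, sensitivity=0.7, jitter=1.5,
                             fp_rate=3.0, seed0=40)
        table = cq.match_detection_sets(sets, radius=10)
        method = DetectionSet(x=truth.x, y=truth.y, source_id="truth-method")
        res = cq.method_overlap_stats(method, table)
        fr = res["detection_fraction_by_class"]
        vals = [fr[k] for k in sorted(fr) if not np.isnan(fr[k])]
        assert all(b >= a - 0.1 for a, b in zip(vals, vals[1:]))
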