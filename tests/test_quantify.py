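import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cordquant as cq
from cordquant.quantify import _kw_statistic


def _meta(rows):
    return pd.DataFrame(rows)


def _assignments(layout):
    """layout: {section_id: {region_id: n}}"""
    rows = []
    for sid, regions in layout.items():
        for rid, n in regions.items():
            rows.extend({"section_id": sid, "region_id": rid} for _ in range(n))
    return pd.DataFrame(rows, columns=["section_id", "region_id"])


META = _meta(
    [
        {"section_id": "c1", "individual": "m1", "condition": "control", "distance_mm": None},
        {"section_id": "c2", "individual": "m2", "condition": "control", "distance_mm": None},
        {"section_id": "c3", "individual": "m3", "condition": "control", "distance_mm": None},
        {"section_id": "i1", "individual": "m4", "condition": "injury", "distance_mm": 0.6},
        {"section_id": "i2", "individual": "m5", "condition": "injury", "distance_mm": 1.0},
    ]
)


class TestRegionCounts:
    def test_empty_assignments_zero_row(self):
        rc = cq.region_counts(_assignments({}), META, region_order=["L1", "L2"])
        assert rc.counts.shape == (5, 2)
        assert (rc.counts.to_numpy() == 0).all()

    def test_conservation_row_sum_plus_outside(self):
        layout = {"c1": {"L1": 3, "L2": 5, "outside": 2}, "i1": {"L1": 1}}
        rc = cq.region_counts(_assignments(layout), META, region_order=["L1", "L2"])
        assert rc.counts.loc["c1"].sum() + rc.outside.loc["c1"] == 10
        assert rc.counts.loc["i1"].sum() + rc.outside.loc["i1"] == 1

    def test_duplicate_sections_rejected(self):
        meta = pd.concat([META, META.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            cq.region_counts(_assignments({}), meta)

    def test_unknown_section_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            cq.region_counts(_assignments({"zz": {"L1": 1}}), META)

    def test_csv_roundtrip(self, tmp_path):
        layout = {"c1": {"L1": 3}, "i1": {"L1": 1, "L2": 7, "outside": 1}}
        rc = cq.region_counts(_assignments(layout), META, region_order=["L1", "L2"])
        path = tmp_path / "counts.csv"
        rc.to_csv(path)
        back = cq.RegionCounts.from_csv(path)
        pd.testing.assert_frame_equal(back.counts, rc.counts)
        assert back.outside.loc["i1"] == 1

    def test_matrix_matches_truth_on_synthetic_data(self, atlas, config):
        _, truth = cq.simulate_section(atlas, config, seed=63, section_id="s")
        assignments = pd.DataFrame(
            {"section_id": "s", "region_id": truth.region_id.astype(str)}
        )
        meta = _meta([{"section_id": "s", "individual": "m", "condition": "control",
                       "distance_mm": None}])
        rc = cq.region_counts(assignments, meta, region_order=atlas.region_ids)
        for rid, n in truth.region_counts().items():
            assert rc.counts.loc["s", rid] == n


class TestSurvivalPercent:
    @staticmethod
    def _counts(ctrl=(100, 120, 110), injured=None):
        injured = injured or {}
        rows, meta = {}, []
        for i, c in enumerate(ctrl):
            sid = f"c{i}"
            rows[sid] = {"L1": c, "L2": c // 2}
            meta.append({"section_id": sid, "individual": f"m{i}", "condition": "control",
                         "distance_mm": None})
        for sid, (d, counts) in injured.items():
            rows[sid] = counts
            meta.append({"section_id": sid, "individual": sid, "condition": "injury",
                         "distance_mm": d})
        return cq.region_counts(_assignments(rows), _meta(meta), region_order=["L1", "L2"])

    def test_control_medians_are_reference(self):
        rc = self._counts()
        prof = cq.survival_percent(rc)
        assert prof.control_reference["L1"] == 110
        assert prof.control_total == pytest.approx(110 + 55)

    def test_injured_equal_to_reference_is_100(self):
        rc = self._counts(injured={"i1": (1.0, {"L1": 110, "L2": 55})})
        prof = cq.survival_percent(rc)
        assert prof.survival.loc["i1", "L1"] == pytest.approx(100.0)
        assert prof.total_survival.loc["i1"] == pytest.approx(100.0)

    def test_empty_injured_section_zero_everywhere(self):
        rc = self._counts(injured={"i1": (0.6, {})})
        prof = cq.survival_percent(rc)
        assert prof.survival.loc["i1", "L1"] == 0.0
        assert prof.total_survival.loc["i1"] == 0.0

    def test_zero_control_median_flagged(self):
        rc = self._counts(ctrl=(0, 0, 0))
        prof = cq.survival_percent(rc)
        assert "L1" in prof.undefined_regions
        assert np.isnan(prof.survival["L1"]).all()

    def test_no_control_rejected(self):
        rc = self._counts(injured={"i1": (0.6, {"L1": 5})})
        obj = cq.RegionCounts(
            counts=rc.counts.loc[["i1"]], outside=rc.outside.loc[["i1"]],
            meta=rc.meta.loc[["i1"]],
        )
        with pytest.raises(ValueError):
            cq.survival_percent(obj)

    def test_parameter_recovery_from_generator(self, atlas, config):
        """Truth counts thinned by the survival curve recover ~100·s."""
        ctrl_counts, inj_counts = [], []
        for s in range(12):
            _, t = cq.simulate_section(atlas, config, None, seed=900 + s)
            ctrl_counts.append(len(t))
        for s in range(12):
            _, t = cq.simulate_section(atlas, config, 1.0, seed=950 + s)
            inj_counts.append(len(t))
        recovered = 100.0 * np.median(inj_counts) / np.median(ctrl_counts)
        assert recovered == pytest.approx(40.0, abs=8.0)


class TestKruskalWallis:
    def test_identical_groups(self):
        h, p = cq.kruskal_wallis([[5, 5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        """{1,2,3} vs {10,11,12}: H = 3.857 with no ties."""
        h, p = cq.kruskal_wallis([[1, 2, 3], [10, 11, 12]])
        assert h == pytest.approx(3.857142857, abs=1e-6)

    def test_own_statistic_matches_scipy(self):
        rng = np.random.default_rng(11)
        groups = [rng.poisson(20, 8).astype(float) for _ in range(3)]
        h_own = _kw_statistic([np.asarray(g) for g in groups])
        h_scipy, _ = stats.kruskal(*groups)
        assert h_own == pytest.approx(h_scipy, abs=1e-10)

    def test_permutation_close_to_chi2_for_moderate_n(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(loc, 1.0, 15) for loc in (0.0, 0.4, 0.8)]
        h, p_chi2 = cq.kruskal_wallis(groups)
        h2, p_perm = cq.kruskal_wallis_permutation(groups, n_permutations=20000, seed=5)
        assert h2 == pytest.approx(h)
        assert abs(p_chi2 - p_perm) < 0.03

    def test_invalid_groups(self):
        with pytest.raises(ValueError):
            cq.kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            cq.kruskal_wallis([[1.0], []])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.poisson(30, 6).astype(float) + rng.random(6) for _ in range(3)]
        h1, _ = cq.kruskal_wallis(groups)
        h2, _ = cq.kruskal_wallis([np.exp(g / 10.0) for g in groups])
        assert h1 == pytest.approx(h2, abs=1e-9)


class TestDistanceProfile:
    @staticmethod
    def _profile(distances, totals, ctrl_total=200):
        rows, meta = {}, []
        for i in range(3):
            rows[f"c{i}"] = {"L1": ctrl_total}
            meta.append({"section_id": f"c{i}", "individual": f"m{i}",
                         "condition": "control", "distance_mm": None})
        for i, (d, t) in enumerate(zip(distances, totals)):
            rows[f"i{i}"] = {"L1": t}
            meta.append({"section_id": f"i{i}", "individual": f"n{i}",
                         "condition": "injury", "distance_mm": d})
        rc = cq.region_counts(_assignments(rows), _meta(meta), region_order=["L1"])
        return cq.survival_percent(rc)

    def test_single_distance_no_increment(self):
        dp = cq.distance_profile(self._profile([0.6], [20]))
        inj = dp[dp.condition == "injury"]
        assert len(inj) == 1
        assert np.isnan(inj["increment_pct"].iloc[0])

    def test_control_sections_at_100(self):
        dp = cq.distance_profile(self._profile([0.6], [20]))
        ctrl = dp[dp.condition == "control"]
        assert ctrl["median_total_survival_pct"].iloc[0] == pytest.approx(100.0)

    def test_gradient_increments(self):
        dp = cq.distance_profile(
            self._profile([0.6, 0.8, 1.0, 1.2], [5, 40, 80, 80])
        )
        inj = dp[dp.condition == "injury"].sort_values("distance_mm")
        med = inj["median_total_survival_pct"].to_numpy()
        assert med == pytest.approx([2.5, 20.0, 40.0, 40.0])
        inc = inj["increment_pct"].to_numpy()
        assert inc[1] == pytest.approx(17.5)
        assert inc[3] == pytest.approx(0.0)
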