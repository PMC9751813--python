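import itertools

import numpy as np
import pandas as pd
import pytest

from seedage.omics import (
    FeatureTable,
    SelectionRule,
    correlate,
    filter_features,
    normalize_internal_standard,
    pca_scores,
    percent_of_initial,
    retention_index,
    select_top,
    venn_sets,
)


class TestFilterFeatures:
    def test_detection_count_rule(self, toy_feature_table):
        out = filter_features(toy_feature_table, min_samples=3, min_abundance=15000)
        assert list(out.intensities.columns) == ["A", "IS"]  # B only 2x, Z never

    def test_strict_inequality_at_threshold(self):
        x = pd.DataFrame({"A": [15000.0, 15000.0, 15000.0, 16000.0]})
        table = FeatureTable(intensities=x)
        out = filter_features(table, min_samples=3, min_abundance=15000)
        assert out.n_compounds == 0  # exactly 15,000 does not count

    def test_zero_thresholds_identity(self, toy_feature_table):
        out = filter_features(toy_feature_table, min_samples=0, min_abundance=0)
        assert list(out.intensities.columns) == list(
            toy_feature_table.intensities.columns
        )

    def test_idempotent(self, toy_feature_table):
        once = filter_features(toy_feature_table)
        twice = filter_features(once)
        pd.testing.assert_frame_equal(once.intensities, twice.intensities)


class TestNormalizeInternalStandard:
    def test_constant_is_leaves_table_unchanged(self, toy_feature_table):
        out = normalize_internal_standard(toy_feature_table)
        pd.testing.assert_frame_equal(
            out.intensities, toy_feature_table.intensities
        )

    def test_double_is_halves_sample(self, toy_feature_table):
        x = toy_feature_table.intensities.copy()
        x.loc["s0"] *= 2  # simulate a sample injected at double strength
        table = FeatureTable(
            intensities=x, sample_meta=toy_feature_table.sample_meta, is_channel="IS"
        )
        out = normalize_internal_standard(table)
        mean_is = x["IS"].mean()
        expected = toy_feature_table.intensities.loc["s0", "A"] * (mean_is / 1e5)
        assert out.intensities.loc["s0", "A"] == pytest.approx(expected)
        assert out.intensities["IS"].std() == pytest.approx(0.0, abs=1e-9)

    def test_dilution_invariance_of_correlations(self, toy_feature_table):
        before = correlate(
            normalize_internal_standard(toy_feature_table), "germination_pct"
        )
        x = toy_feature_table.intensities.copy()
        x.loc["s2"] *= 3.0  # 3x dilution factor on one sample
        diluted = FeatureTable(
            intensities=x, sample_meta=toy_feature_table.sample_meta, is_channel="IS"
        )
        after = correlate(normalize_internal_standard(diluted), "germination_pct")
        np.testing.assert_allclose(
            before["r"].to_numpy(float), after["r"].to_numpy(float), atol=1e-9
        )

    def test_nonpositive_is_rejected_with_sample_name(self, toy_feature_table):
        x = toy_feature_table.intensities.copy()
        x.loc["s3", "IS"] = 0.0
        table = FeatureTable(
            intensities=x, sample_meta=toy_feature_table.sample_meta, is_channel="IS"
        )
        with pytest.raises(ValueError, match="s3"):
            normalize_internal_standard(table)


class TestCorrelate:
    def test_affine_decreasing_compound(self):
        germ = np.array([95.0, 80.0, 50.0, 20.0])
        x = pd.DataFrame({"A": 1000.0 - 5.0 * germ})
        meta = pd.DataFrame({"germination_pct": germ}, index=x.index)
        res = correlate(FeatureTable(intensities=x, sample_meta=meta), "germination_pct")
        assert res.loc["A", "r"] == pytest.approx(-1.0, abs=1e-12)

    def test_textbook_formula_oracle(self):
        vals = np.array([120.0, 340.0, 80.0, 560.0])
        germ = np.array([90.0, 60.0, 95.0, 20.0])
        x = pd.DataFrame({"A": vals})
        meta = pd.DataFrame({"germination_pct": germ}, index=x.index)
        res = correlate(FeatureTable(intensities=x, sample_meta=meta), "germination_pct")
        oracle = np.sum((vals - vals.mean()) * (germ - germ.mean())) / np.sqrt(
            np.sum((vals - vals.mean()) ** 2) * np.sum((germ - germ.mean()) ** 2)
        )
        assert res.loc["A", "r"] == pytest.approx(oracle, abs=1e-12)

    def test_null_compound_rarely_exceeds_point_two(self):
        rng = np.random.default_rng(11)
        n, reps = 200, 100
        germ = rng.uniform(0, 100, n)
        meta = pd.DataFrame({"germination_pct": germ})
        hits = 0
        x = pd.DataFrame(
            {f"C{i}": rng.lognormal(10, 0.5, n) for i in range(reps)}
        )
        res = correlate(FeatureTable(intensities=x, sample_meta=meta), "germination_pct")
        hits = int((res["r"].abs() < 0.2).sum())
        assert hits >= 95

    def test_sign_flip_under_negative_scaling(self, toy_feature_table):
        res = correlate(toy_feature_table, "storage_days")
        x = toy_feature_table.intensities.copy()
        # affine flip must negate r exactly; keep values non-negative
        x["A"] = x["A"].max() - x["A"]
        flipped = FeatureTable(
            intensities=x, sample_meta=toy_feature_table.sample_meta
        )
        res2 = correlate(flipped, "storage_days")
        assert res2.loc["A", "r"] == pytest.approx(-res.loc["A", "r"], abs=1e-12)

    def test_constant_trait_rejected(self, toy_feature_table):
        meta = toy_feature_table.sample_meta.assign(flat=1.0)
        table = FeatureTable(
            intensities=toy_feature_table.intensities, sample_meta=meta
        )
        with pytest.raises(ValueError, match="constant"):
            correlate(table, "flat")


class TestSelectTop:
    def test_strict_threshold_boundary(self):
        res = pd.DataFrame({"r": [-0.99, -0.98, -0.97]}, index=["a", "b", "c"])
        assert select_top(res, SelectionRule("r", "<", -0.98)) == {"a"}

    def test_all_zero_empty(self):
        res = pd.DataFrame({"r": [0.0, 0.0]}, index=["a", "b"])
        assert select_top(res, ("r", "<", -0.5)) == set()
        assert select_top(res, ("r", ">", 0.5)) == set()

    def test_unknown_rule_rejected(self):
        res = pd.DataFrame({"r": [0.1]}, index=["a"])
        with pytest.raises(ValueError):
            select_top(res, ("r", ">=", 0.5))
        with pytest.raises(ValueError):
            select_top(res, ("q", ">", 0.5))


class TestPercentOfInitial:
    def test_identity_doubling_decline(self, toy_feature_table):
        pct = percent_of_initial(toy_feature_table, "storage_days", 0)
        a0 = toy_feature_table.intensities.loc["s0", "A"]
        assert pct.loc[0, "A"] == pytest.approx(100.0)
        assert pct.loc[14, "A"] == pytest.approx(
            100.0 * toy_feature_table.intensities.loc["s1", "A"] / a0
        )

    def test_declining_channel_below_100(self):
        x = pd.DataFrame({"Q9": [1000.0, 907.0, 796.0]})
        meta = pd.DataFrame({"storage_days": [0, 14, 56]}, index=x.index)
        pct = percent_of_initial(
            FeatureTable(intensities=x, sample_meta=meta), "storage_days", 0
        )
        assert pct.loc[14, "Q9"] == pytest.approx(90.7)
        assert pct.loc[56, "Q9"] == pytest.approx(79.6)

    def test_zero_initial_mean_undefined(self):
        x = pd.DataFrame({"A": [0.0, 10.0]})
        meta = pd.DataFrame({"storage_days": [0, 14]}, index=x.index)
        pct = percent_of_initial(
            FeatureTable(intensities=x, sample_meta=meta), "storage_days", 0
        )
        assert pct["A"].isna().all()


class TestVennSets:
    def test_identical_and_disjoint(self):
        same = {"A": {1, 2}, "B": {1, 2}}
        out = venn_sets(same)
        common = out[(out["A"]) & (out["B"])]
        assert common["count"].iloc[0] == 2 and len(out) == 1
        disjoint = venn_sets({"A": {1}, "B": {2}})
        assert not ((disjoint["A"]) & (disjoint["B"])).any()

    def test_against_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        labels = [f"x{i}" for i in range(100)]
        sets = {
            name: set(rng.choice(labels, size=rng.integers(10, 60), replace=False))
            for name in "ABCD"
        }
        out = venn_sets(sets).set_index(["A", "B", "C", "D"])
        for pattern in itertools.product([True, False], repeat=4):
            if not any(pattern):
                continue
            cell = set.intersection(
                *(sets[n] for n, inc in zip("ABCD", pattern) if inc)
            ) - set.union(
                set(), *(sets[n] for n, inc in zip("ABCD", pattern) if not inc)
            )
            expected = len(cell)
            got = out.loc[pattern, "count"] if pattern in out.index else 0
            assert got == expected

    def test_inclusion_exclusion_totals(self):
        sets = {"A": {1, 2, 3}, "B": {2, 3, 4}, "C": {3, 5}}
        out = venn_sets(sets)
        assert out["count"].sum() == len({1, 2, 3, 4, 5})
        for name, s in sets.items():
            assert out.loc[out[name], "count"].sum() == len(s)


class TestRetentionIndex:
    LADDER = [(n, float(n)) for n in range(8, 23)]  # rt == carbon number

    def test_alkane_anchor_and_midpoint(self):
        assert retention_index(10.0, self.LADDER) == pytest.approx(1000.0)
        assert retention_index(10.5, self.LADDER) == pytest.approx(1050.0)

    def test_matches_independent_interpolation(self):
        rng = np.random.default_rng(3)
        ladder = [(n, 0.5 * n**1.1) for n in range(8, 23)]
        rts = np.array([r for _, r in ladder])
        for rt in rng.uniform(rts[0], rts[-1], 20):
            i = np.searchsorted(rts, rt) - 1
            i = np.clip(i, 0, len(ladder) - 2)
            n = ladder[i][0]
            oracle = 100 * (n + (rt - rts[i]) / (rts[i + 1] - rts[i]))
            assert retention_index(rt, ladder) == pytest.approx(oracle, abs=1e-9)

    def test_no_silent_extrapolation(self):
        with pytest.raises(ValueError):
            retention_index(7.0, self.LADDER)
        with pytest.raises(ValueError):
            retention_index(23.0, self.LADDER)


class TestPcaScores:
    def test_two_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, size=(10, 30))
        b = rng.normal(8, 1, size=(10, 30))
        x = pd.DataFrame(np.vstack([a, b]))
        x = x - x.min().min()  # non-negative intensities
        scores, evr = pca_scores(FeatureTable(intensities=x), n_components=2)
        pc1 = scores["PC1"].to_numpy()
        assert (pc1[:10].mean() < pc1[10:].mean()) or (
            pc1[:10].mean() > pc1[10:].mean()
        )
        assert abs(pc1[:10].mean() - pc1[10:].mean()) > 3 * pc1[:10].std()
        assert evr[0] > 0.5

    def test_duplicate_samples_identical_scores(self):
        x = pd.DataFrame(
            np.random.default_rng(1).uniform(0, 100, size=(4, 6))
        )
        x.iloc[3] = x.iloc[0]
        scores, _ = pca_scores(FeatureTable(intensities=x), n_components=2)
        np.testing.assert_allclose(
            scores.iloc[3].to_numpy(), scores.iloc[0].to_numpy(), atol=1e-9
        )

    def test_explained_variance_non_increasing(self):
        x = pd.DataFrame(np.random.default_rng(2).uniform(0, 10, size=(8, 5)))
        _, evr = pca_scores(FeatureTable(intensities=x), n_components=4)
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9
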