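"""Standardization, Spearman matrices, and Ward source clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from streamscreen import clustering
from streamscreen.clustering import (
    CorrelationMatrix,
    ZeroVarianceError,
    spearman_matrix,
    spearman_pair,
    ward_cluster,
    zscore_levels,
)
from streamscreen.types import InvalidArgument


class TestZscore:
    def test_unit_scale(self):
        z = zscore_levels(pd.Series([1.0, 2.0, 3.0]))
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=0) == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ZeroVarianceError):
            zscore_levels(pd.Series([2.0, 2.0, 2.0, 2.0]))

    def test_half_loq_substitution_matches_hand_computation(self):
        v = pd.Series([10.0, 20.0, np.nan, np.nan, 40.0])
        nd = pd.Series([False, False, True, True, False])
        loq = pd.Series([1.0, 1.0, 2.0, 4.0, 1.0])
        z = zscore_levels(v, nondetect_policy="half_loq", nondetect=nd,
                          loq=loq)
        hand = pd.Series([10.0, 20.0, 1.0, 2.0, 40.0])
        expected = (hand - hand.mean()) / hand.std(ddof=0)
        pd.testing.assert_series_equal(z, expected)

    def test_exclude_policy_drops_nondetects(self):
        v = pd.Series([1.0, 2.0, 3.0, 99.0])
        nd = pd.Series([False, False, False, True])
        z = zscore_levels(v, nondetect_policy="exclude", nondetect=nd)
        assert np.isnan(z.iloc[3])
        assert z.iloc[:3].mean() == pytest.approx(0.0, abs=1e-12)

    def test_log_transform_requires_positive(self):
        with pytest.raises(InvalidArgument):
            zscore_levels(pd.Series([0.0, 1.0, 2.0]), log_transform=True)


class TestSpearmanPair:
    def test_perfect_monotone(self):
        rho, p = spearman_pair([1, 2, 3, 4, 5], [10, 20, 25, 50, 100])
        assert rho == pytest.approx(1.0)

    def test_rank_arithmetic_example(self):
        rho, _ = spearman_pair([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6)

    def test_exact_pvalue_matches_exhaustive_enumeration(self, rng):
        # independent brute-force oracle over all 6! pairings
        x = rng.normal(size=6)
        y = rng.normal(size=6)
        rho, p = spearman_pair(x, y)
        rx = stats.rankdata(x)
        null = []
        for perm in itertools.permutations(stats.rankdata(y)):
            null.append(abs(stats.pearsonr(rx, np.asarray(perm)).statistic))
        expected = np.mean(np.asarray(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)

    def test_exact_pvalue_with_ties(self):
        x = [1.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 3.0, 5.0, 4.0, 6.0]
        rho, p = spearman_pair(x, y)
        rx = stats.rankdata(x)
        null = []
        for perm in itertools.permutations(stats.rankdata(y)):
            null.append(abs(stats.pearsonr(rx, np.asarray(perm)).statistic))
        expected = np.mean(np.asarray(null) >= abs(rho) - 1e-12)
        assert p == pytest.approx(expected)

    def test_large_n_matches_scipy(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman_pair(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestSpearmanMatrix:
    def test_equals_scipy_cell_by_cell_fast_path(self, rng,
                                                 attribute_frame):
        levels = pd.DataFrame(
            rng.normal(size=(20, 5)), index=attribute_frame.index,
            columns=list("abcde"))
        m = spearman_matrix(levels, attribute_frame)
        for item in levels.columns:
            for attr in attribute_frame.columns:
                ref = stats.spearmanr(levels[item],
                                      attribute_frame[attr])
                assert m.rho.loc[item, attr] == pytest.approx(ref.statistic)
                assert m.pvalue.loc[item, attr] == pytest.approx(
                    ref.pvalue, rel=1e-9)

    def test_missing_cells_flagged(self, attribute_frame, rng):
        levels = pd.DataFrame(
            rng.normal(size=(20, 2)), index=attribute_frame.index,
            columns=["u", "v"])
        levels.loc[levels.index[:18], "v"] = np.nan  # 2 pairs < min_pairs
        m = spearman_matrix(levels, attribute_frame)
        assert m.pvalue.loc["v"].isna().all()
        assert m.rho.loc["u"].notna().all()

    def test_bh_qvalues_monotone_in_p(self, rng):
        p = pd.DataFrame(rng.uniform(size=(6, 4)))
        q = clustering.bh_qvalues(p)
        flat = pd.DataFrame({"p": p.to_numpy().ravel(),
                             "q": q.to_numpy().ravel()}).sort_values("p")
        assert (flat["q"].diff().dropna() >= -1e-12).all()
        assert ((q >= p - 1e-12) & (q <= 1.0)).all().all()


def _block_matrix():
    """Two well-separated blocks of duplicated correlation rows."""
    rows = {}
    for i in range(4):
        rows[f"x{i}"] = [0.9, 0.8, 0.0, 0.0]
    for i in range(3):
        rows[f"y{i}"] = [0.0, 0.0, 0.9, 0.8]
    rho = pd.DataFrame(rows, index=["ag_pct", "cafo_count",
                                    "septic_density", "dev_pct"]).T
    p = rho * 0.0
    return CorrelationMatrix(rho=rho, pvalue=p)


class TestWardCluster:
    def test_k_equals_n_gives_singletons(self):
        m = _block_matrix()
        out = ward_cluster(m, k=len(m.rho))
        assert len(set(out.labels.values())) == len(m.rho)

    def test_two_blocks_recovered_exactly(self):
        m = _block_matrix()
        out = ward_cluster(m, k=2)
        xs = {out.labels[f"x{i}"] for i in range(4)}
        ys = {out.labels[f"y{i}"] for i in range(3)}
        assert len(xs) == 1 and len(ys) == 1 and xs != ys

    def test_k_too_large_rejected(self):
        with pytest.raises(InvalidArgument):
            ward_cluster(_block_matrix(), k=100)

    def test_row_order_invariance(self, rng):
        rho = pd.DataFrame(rng.uniform(-1, 1, size=(10, 4)),
                           index=[f"i{j}" for j in range(10)],
                           columns=["a", "b", "c", "d"])
        m1 = CorrelationMatrix(rho=rho, pvalue=rho * 0)
        shuffled = rho.sample(frac=1.0, random_state=1)
        m2 = CorrelationMatrix(rho=shuffled, pvalue=shuffled * 0)
        out1 = ward_cluster(m1, k=3).labels
        out2 = ward_cluster(m2, k=3).labels
        # memberships agree up to label renaming
        pairs1 = {(a, b) for a in out1 for b in out1
                  if a < b and out1[a] == out1[b]}
        pairs2 = {(a, b) for a in out2 for b in out2
                  if a < b and out2[a] == out2[b]}
        assert pairs1 == pairs2

    def test_merge_heights_nondecreasing(self, rng):
        rho = pd.DataFrame(rng.uniform(-1, 1, size=(12, 5)))
        rho.index = [f"i{j}" for j in range(12)]
        m = CorrelationMatrix(rho=rho, pvalue=rho * 0)
        out = ward_cluster(m, k=3)
        heights = out.linkage_matrix[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestLabelClusters:
    def test_agricultural_block_labeled_a(self):
        m = _block_matrix()
        out = ward_cluster(m, k=2)
        # force k=3 path not taken -> raw ids returned
        assert set(clustering.label_clusters(out, m).values()) <= {"1", "2"}

    def test_three_cluster_semantics(self):
        rows = {}
        attrs = ["ag_pct", "cafo_count", "rpi", "septic_density",
                 "dev_pct", "road_density", "pop_density", "wwtp_capacity"]
        for i in range(3):
            rows[f"a{i}"] = [0.8, 0.7, 0.6, 0, 0, 0, 0, 0]
            rows[f"b{i}"] = [0, 0, 0, 0.8, 0.7, 0.7, 0.6, 0]
            rows[f"c{i}"] = [0, 0, 0, 0, 0, 0, 0, 0.9]
        rho = pd.DataFrame(rows, index=attrs).T
        m = CorrelationMatrix(rho=rho, pvalue=rho * 0)
        labels = clustering.label_clusters(ward_cluster(m, k=3), m)
        assert all(labels[f"a{i}"] == "A" for i in range(3))
        assert all(labels[f"b{i}"] == "B" for i in range(3))
        assert all(labels[f"c{i}"] == "C" for i in range(3))

    def test_all_zero_matrix_uses_priority_order(self):
        attrs = ["ag_pct", "cafo_count", "rpi", "septic_density",
                 "dev_pct", "road_density", "pop_density", "wwtp_capacity"]
        rho = pd.DataFrame(0.0, index=["x", "y", "z"], columns=attrs)
        rho.loc["x", "ag_pct"] = 1e-9   # separate rows minimally
        rho.loc["y", "dev_pct"] = 2e-9
        m = CorrelationMatrix(rho=rho, pvalue=rho * 0)
        labels = clustering.label_clusters(ward_cluster(m, k=3), m)
        assert set(labels.values()) == {"A", "B", "C"}


class TestSourceRecovery:
    def test_planted_clusters_recovered(self, default_cohort):
        from streamscreen import experiments
        meas = default_cohort.measurements
        levels = meas.pivot(index="site_id", columns="compound",
                            values="m_pocis")
        _, labels, _ = clustering.cluster_items(
            levels, default_cohort.sites_frame, k=3)
        truth = default_cohort.truth.source_cluster
        common = [c for c in labels if c in truth]
        ari = experiments.adjusted_rand_index(
            [truth[c] for c in common], [labels[c] for c in common])
        assert ari >= 0.8
        acc = np.mean([truth[c] == labels[c] for c in common])
        assert acc >= 0.9

    def test_ari_helper_matches_sklearn(self, rng):
        from sklearn.metrics import adjusted_rand_score
        from streamscreen.experiments import adjusted_rand_index
        for _ in range(5):
            a = rng.integers(0, 3, size=30)
            b = rng.integers(0, 3, size=30)
            assert adjusted_rand_index(a, b) == pytest.approx(
                adjusted_rand_score(a, b))
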