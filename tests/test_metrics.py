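import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn import metrics as skm

import oracles
from dropstab import metrics as dm

A = ["A", "A", "B", "B"]


class TestPrintedExamples:
    @pytest.mark.parametrize("truth, pred, expected", [
        (A, [1, 1, 2, 2], 1.0),          # pure clusters
        (A, [1, 1, 1, 1], 0.0),          # one cluster mixes both classes
        (["A"] * 4, [1, 2, 1, 2], 1.0),  # H(C) = 0 convention
    ])
    def test_homogeneity(self, truth, pred, expected):
        assert dm.homogeneity(truth, pred) == pytest.approx(expected)

    def test_completeness_single_cluster_is_one(self):
        assert dm.completeness(A, [1, 1, 1, 1]) == 1.0

    def test_completeness_singletons_matches_entropy_oracle(self):
        pred = [1, 2, 3, 4]
        assert dm.completeness(A, pred) == pytest.approx(
            oracles.completeness(A, pred), abs=1e-12)
        # H(K) = ln 4, H(K|C) = ln 2 (each class splits into 2 singletons)
        assert dm.completeness(A, pred) == pytest.approx(0.5)

    def test_completeness_is_dual_of_homogeneity(self):
        pred = [1, 1, 2, 3]
        assert dm.completeness(A, pred) == dm.homogeneity(pred, A)

    @pytest.mark.parametrize("h, c, beta, expected", [
        (1.0, 1.0, 1.0, 1.0),
        (0.5, 1.0, 1.0, 2 * 0.5 * 1 / 1.5),
        (0.0, 1.0, 1.0, 0.0),
    ])
    def test_v_measure_formula(self, h, c, beta, expected, monkeypatch):
        monkeypatch.setattr(dm, "homogeneity", lambda *_: h)
        monkeypatch.setattr(dm, "completeness", lambda *_: c)
        assert dm.v_measure(A, A, beta) == pytest.approx(expected)

    @pytest.mark.parametrize("a, b, expected", [
        (A, A, 1.0),
        (A, [1, 2, 1, 2], 2 / 6),        # 2 of 6 pairs agree
        ([1, 2, 3, 4], ["w", "x", "y", "z"], 1.0),  # all pairs TN
    ])
    def test_rand_index(self, a, b, expected):
        assert dm.rand_index(a, b) == pytest.approx(expected)

    def test_ari_identical_partitions(self):
        assert dm.adjusted_rand_index(A, A) == 1.0

    def test_ari_brute_force_zero_case(self):
        # index=1, expected=2*3/6=1, max=2.5 -> (1-1)/1.5 = 0
        assert dm.adjusted_rand_index(A, [1, 1, 1, 2]) == pytest.approx(0.0)

    def test_ari_degenerate_trivial_partitions(self):
        assert dm.adjusted_rand_index([1, 1, 1], [2, 2, 2]) == 1.0


class TestOracleEquivalence:
    def test_matches_pair_enumeration_and_entropy_oracles(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            a, b = oracles.random_partition_pair(rng, max_n=120)
            assert dm.rand_index(a, b) == pytest.approx(
                oracles.rand_index(a, b), abs=1e-12)
            assert dm.adjusted_rand_index(a, b) == pytest.approx(
                oracles.adjusted_rand_index(a, b), abs=1e-12)
            assert dm.homogeneity(a, b) == pytest.approx(
                oracles.homogeneity(a, b), abs=1e-12)
            assert dm.v_measure(a, b) == pytest.approx(
                oracles.v_measure(a, b), abs=1e-12)

    def test_matches_reference_toolkit(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a, b = oracles.random_partition_pair(rng)
            assert dm.adjusted_rand_index(a, b) == pytest.approx(
                skm.adjusted_rand_score(a, b), abs=1e-10)
            h, c, v = skm.homogeneity_completeness_v_measure(a, b)
            assert dm.homogeneity(a, b) == pytest.approx(h, abs=1e-10)
            assert dm.completeness(a, b) == pytest.approx(c, abs=1e-10)
            assert dm.v_measure(a, b) == pytest.approx(v, abs=1e-10)


labelings = st.lists(st.integers(0, 5), min_size=2, max_size=40)


class TestProperties:
    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ranges_and_permutation_invariance(self, data):
        a = np.array(data.draw(labelings))
        b = np.array(data.draw(st.lists(st.integers(0, 5), min_size=len(a),
                                        max_size=len(a))))
        assert 0.0 <= dm.homogeneity(a, b) <= 1.0
        assert 0.0 <= dm.v_measure(a, b) <= 1.0
        assert 0.0 <= dm.rand_index(a, b) <= 1.0
        assert dm.adjusted_rand_index(a, b) <= 1.0
        # relabeling clusters changes nothing
        remap = {v: i + 100 for i, v in enumerate(np.unique(b))}
        b2 = np.array([remap[x] for x in b])
        assert dm.v_measure(a, b2) == pytest.approx(dm.v_measure(a, b))
        assert dm.adjusted_rand_index(a, b2) == pytest.approx(
            dm.adjusted_rand_index(a, b))

    @given(st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_v_measure_symmetric_at_beta_one(self, data):
        a = np.array(data.draw(labelings))
        b = np.array(data.draw(st.lists(st.integers(0, 5), min_size=len(a),
                                        max_size=len(a))))
        assert dm.v_measure(a, b) == pytest.approx(dm.v_measure(b, a))


class TestContracts:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            dm.homogeneity([1, 2], [1, 2, 3])

    def test_mismatched_cell_sets_rejected(self):
        a = pd.Series([1, 1], index=["c1", "c2"])
        b = pd.Series([1, 2], index=["c1", "c9"])
        with pytest.raises(ValueError, match="different cell sets"):
            dm.adjusted_rand_index(a, b)

    def test_series_aligned_by_cell_id(self):
        a = pd.Series([1, 1, 2, 2], index=list("wxyz"))
        b = pd.Series([5, 5, 6, 6], index=list("zyxw"))  # same cells, reordered
        assert dm.adjusted_rand_index(a, b) == pytest.approx(
            dm.adjusted_rand_index(a.to_numpy(), b.reindex(a.index).to_numpy()))

    def test_contingency_counts_and_marginals(self):
        t = dm.pairwise_contingency(A, [1, 1, 1, 2])
        assert t.n == 4
        assert t.counts.sum() == 4
        np.testing.assert_array_equal(t.row_marginals, [2, 2])
        np.testing.assert_array_equal(t.col_marginals, [3, 1])
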