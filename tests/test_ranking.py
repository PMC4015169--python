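"""Rank aggregation and the Wilcoxon signed-rank significance machinery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata
from scipy.stats import wilcoxon as scipy_wilcoxon

from pcmbench.ranking import (RankTable, aggregate_ranks, build_rank_table,
                              rank_experiment, significance_matrix,
                              wilcoxon_signed_rank)


class TestRankExperiment:
    def test_average_tie_rule(self):
        np.testing.assert_array_equal(
            rank_experiment([0.43, 0.50, 0.43], better="lower"), [1.5, 3, 1.5])

    def test_strict_order_is_sort_permutation(self):
        vals = [0.3, 0.9, 0.5, 0.1]
        np.testing.assert_array_equal(rank_experiment(vals, "higher"),
                                      [3, 1, 2, 4])
        np.testing.assert_array_equal(rank_experiment(vals, "lower"),
                                      [2, 4, 3, 1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=16),
           st.sampled_from(["higher", "lower"]))
    def test_rank_sum_law(self, values, better):
        d = len(values)
        ranks = rank_experiment(values, better)
        assert np.sum(ranks) == pytest.approx(d * (d + 1) / 2)

    def test_nan_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_experiment([1.0, float("nan")])


class TestAggregation:
    def test_hand_computed(self):
        med, mad = aggregate_ranks(np.array([[1.0, 2.0, 3.0, 4.0]]))
        assert med[0] == 2.5 and mad[0] == 1.0

    def test_constant_descriptor(self):
        med, mad = aggregate_ranks(np.full((1, 14), 16.0))
        assert med[0] == 16.0 and mad[0] == 0.0

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 17, size=14).astype(float)
        m1 = aggregate_ranks(row[None, :])
        m2 = aggregate_ranks(rng.permutation(row)[None, :])
        assert m1[0][0] == m2[0][0] and m1[1][0] == m2[1][0]


def oracle_wilcoxon_two_sided(d):
    """Exhaustive sign enumeration of the two-sided signed-rank p-value."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = []
    for signs in itertools.product([0, 1], repeat=len(d)):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.array(ws)
    cdf = np.mean(ws <= w_obs)
    sf = np.mean(ws >= w_obs)
    return min(1.0, 2 * min(cdf, sf))


class TestWilcoxon:
    def test_identical_vectors(self):
        with pytest.warns(UserWarning, match="zero"):
            res = wilcoxon_signed_rank(np.arange(5.0), np.arange(5.0))
        assert res["p_value"] == 1.0

    def test_uniform_sweep_exact_p(self):
        # one method strictly better in all 14 experiments
        res = wilcoxon_signed_rank(np.arange(1.0, 15.0), np.arange(2.0, 16.0))
        assert res["method"] == "exact"
        assert res["p_value"] == pytest.approx(2 / 2 ** 14)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(5, 10), st.integers(0, 2 ** 31 - 1))
    def test_exact_matches_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=n).astype(float)
        if np.all(d == 0):
            d[0] = 1.0
        res = wilcoxon_signed_rank(d)
        assert res["p_value"] == pytest.approx(oracle_wilcoxon_two_sided(d),
                                               abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            d = rng.normal(size=12)  # continuous -> no ties, no zeros
            ours = wilcoxon_signed_rank(d)
            ref = scipy_wilcoxon(d, alternative="two-sided", mode="exact")
            assert ours["p_value"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_large_n(self):
        rng = np.random.default_rng(6)
        d = rng.normal(loc=0.3, size=40)
        ours = wilcoxon_signed_rank(d)
        assert ours["method"] == "normal_approx"
        ref = scipy_wilcoxon(d, alternative="two-sided", mode="approx",
                             correction=True)
        assert ours["p_value"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_pratt_zero_handling_available(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, -3.0, 4.0, 5.0])
        wil = wilcoxon_signed_rank(d, zero_method="wilcox")
        pratt = wilcoxon_signed_rank(d, zero_method="pratt")
        assert wil["n"] == pratt["n"] == 5
        assert wil["statistic"] != pratt["statistic"]

    @settings(max_examples=30, deadline=None)
    @given(st.integers(6, 14), st.integers(0, 2 ** 31 - 1))
    def test_scale_free_in_metric_transforms(self, n, seed):
        """Monotone metric transforms leave ranks and p-values unchanged."""
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        ra, rb = rankdata(a), rankdata(b)
        ta, tb = rankdata(np.exp(a)), rankdata(np.exp(b))
        np.testing.assert_array_equal(ra, ta)
        p1 = wilcoxon_signed_rank(ra, rb)["p_value"]
        p2 = wilcoxon_signed_rank(ta, tb)["p_value"]
        assert p1 == pytest.approx(p2, abs=1e-15)


class TestRankTable:
    def _table(self, ranks):
        d, e = ranks.shape
        return RankTable(descriptors=[f"d{i}" for i in range(d)],
                         experiments=[f"e{j}" for j in range(e)], ranks=ranks)

    def test_column_sum_invariant_enforced(self):
        bad = np.array([[1.0, 1.0], [3.0, 3.0]])
        with pytest.raises(ValueError, match="sum"):
            self._table(bad)

    def test_build_from_metric_table(self):
        import pandas as pd

        metrics = pd.DataFrame(
            {"ace_7030_rmse": [0.43, 0.50, 0.45],
             "ace_7030_r0_squared": [0.80, 0.60, 0.75]},
            index=["zs3", "feat", "mswhim"])
        table = build_rank_table(metrics)
        np.testing.assert_array_equal(table.ranks[:, 0], [1, 3, 2])  # lower rmse
        np.testing.assert_array_equal(table.ranks[:, 1], [1, 3, 2])  # higher r0
        assert table.median_rank() == {"zs3": 1.0, "feat": 3.0, "mswhim": 2.0}

    def test_significance_matrix_shape_and_symmetry(self):
        rng = np.random.default_rng(1)
        cols = [rankdata(rng.normal(size=5)) for _ in range(14)]
        table = self._table(np.column_stack(cols))
        signif = significance_matrix(table)
        p = signif.p_values
        assert p.shape == (5, 5)
        assert np.isnan(np.diag(p)).all()
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_array_equal(p[off], p.T[off])
        iu = np.triu_indices(5, k=1)
        assert np.count_nonzero(~np.isnan(p[iu])) == 10  # D(D-1)/2 entries

    def test_consistently_worst_descriptor_is_significant(self):
        # one method last (rank 4) and one first (rank 1) in all 14 experiments
        d, e = 4, 14
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ranks = np.tile(base[:, None], (1, e))
        table = self._table(ranks)
        signif = significance_matrix(table)
        frame = signif.to_frame()
        assert frame.loc["d3", "d0"] < 0.05
        assert signif.metadata["adjustment"] == "none"
        bonf = signif.to_frame(bonferroni=True)
        assert bonf.loc["d3", "d0"] >= frame.loc["d3", "d0"]
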