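"""Normalization, filtering, differential expression, ranking, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import stats

from cnadose.expression import (
    cluster_samples,
    differential_expression,
    filter_low_expression,
    quantile_normalize,
    select_significant,
    signal_to_noise_ranking,
)
from conftest import make_matrix
from oracles import brute_force_bh


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        em = make_matrix([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]])
        out = quantile_normalize(em)
        np.testing.assert_allclose(out.values.to_numpy(), em.values.to_numpy())

    def test_hand_computed_two_columns(self):
        # columns [1,2,3] and [4,6,8]: row means of sorted = [2.5, 4.0, 5.5]
        em = make_matrix([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]])
        out = quantile_normalize(em).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 4.0, 5.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 4.0, 5.5])

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(make_matrix([[1.0], [2.0]]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(np.float64, (13, 4),
                      elements=st.floats(-50, 50, allow_nan=False)))
    def test_shared_distribution_and_mean_preserved(self, x):
        out = quantile_normalize(make_matrix(x)).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)
        assert np.isclose(out.mean(), np.asarray(x).mean())


class TestFilterLowExpression:
    def test_quartile_of_eight(self):
        em = make_matrix(np.arange(16.0).reshape(8, 2))
        assert filter_low_expression(em, 0.25).n_genes == 6

    def test_zero_fraction_is_identity(self):
        em = make_matrix(np.arange(8.0).reshape(4, 2))
        out = filter_low_expression(em, 0.0)
        assert out.gene_ids == em.gene_ids

    def test_means_1_to_100(self):
        means = np.arange(1.0, 101.0)
        em = make_matrix(np.column_stack([means, means]))
        out = filter_low_expression(em, 0.25)
        # brute-force: sort means, drop lowest 25 -> means 26..100 survive
        kept_means = out.values.mean(axis=1).to_numpy()
        np.testing.assert_allclose(np.sort(kept_means), np.arange(26.0, 101.0))

    def test_at_least_one_gene_survives(self):
        em = make_matrix(np.arange(8.0).reshape(4, 2))
        out = filter_low_expression(em, 0.9)
        assert out.n_genes == 1
        assert out.gene_ids == ["g3"]  # the highest-mean gene
        with pytest.raises(ValueError):
            filter_low_expression(em, 1.0)


class TestDifferentialExpression:
    def test_identical_groups_null(self):
        x = np.array([[2.0, 2.1, 1.9, 2.0, 2.1, 1.9],
                      [5.0, 4.0, 6.0, 5.0, 4.0, 6.0]])
        em = make_matrix(x, groups=["a"] * 3 + ["b"] * 3)
        table = differential_expression(em, ["s0", "s1", "s2"],
                                        ["s3", "s4", "s5"])
        np.testing.assert_allclose(table["log2_fc"], 0.0)
        np.testing.assert_allclose(table["t"], 0.0)
        np.testing.assert_allclose(table["p"], 1.0)

    def test_matches_independent_welch(self):
        a = [2.0, 2.1, 1.9]
        b = [1.0, 1.1, 0.9]
        em = make_matrix([a + b], groups=["a"] * 3 + ["b"] * 3)
        table = differential_expression(em, ["s0", "s1", "s2"],
                                        ["s3", "s4", "s5"])
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=False)
        assert table["log2_fc"].iloc[0] == pytest.approx(1.0)
        assert table["t"].iloc[0] == pytest.approx(t_ref)
        assert table["p"].iloc[0] == pytest.approx(p_ref)

    def test_vectorized_matches_scipy_per_gene(self):
        rng = np.random.default_rng(5)
        x = rng.normal(5, 1, (40, 11))
        em = make_matrix(x, groups=["a"] * 6 + ["b"] * 5)
        ga, gb = [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 11)]
        table = differential_expression(em, ga, gb)
        t_ref, p_ref = stats.ttest_ind(x[:, :6], x[:, 6:], axis=1,
                                       equal_var=False)
        np.testing.assert_allclose(table["t"], t_ref, rtol=1e-10)
        np.testing.assert_allclose(table["p"], p_ref, rtol=1e-10)

    def test_six_vs_five_design_accepted(self):
        rng = np.random.default_rng(0)
        em = make_matrix(rng.normal(7, 1, (10, 11)),
                         groups=["naive"] * 6 + ["treated"] * 5)
        table = differential_expression(
            em, [f"s{j}" for j in range(6)], [f"s{j}" for j in range(6, 11)])
        assert len(table) == 10

    def test_small_group_rejected(self):
        em = make_matrix(np.ones((3, 3)))
        with pytest.raises(ValueError):
            differential_expression(em, ["s0"], ["s1", "s2"])

    def test_zero_variance_unequal_means_finite(self):
        em = make_matrix([[1.0, 1.0, 2.0, 2.0]], groups=list("aabb"))
        table = differential_expression(em, ["s0", "s1"], ["s2", "s3"])
        assert np.isfinite(table["t"].iloc[0])
        assert 0.0 < table["p"].iloc[0] < 1.0 or table["p"].iloc[0] == 0.0
        assert table["p"].iloc[0] > 0.0

    def test_bh_q_matches_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(0, 1, (60, 8))
            x[:10, :4] += rng.normal(2, 0.5, (10, 4))
            em = make_matrix(x, groups=["a"] * 4 + ["b"] * 4)
            table = differential_expression(
                em, [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)])
            np.testing.assert_allclose(
                table["q"], brute_force_bh(table["p"].to_numpy()), atol=1e-12)


class TestSelectSignificant:
    def test_nothing_passes(self):
        import pandas as pd
        table = pd.DataFrame({"log2_fc": [0.1, -0.2], "q": [0.5, 0.9]},
                             index=["g1", "g2"])
        out = select_significant(table)
        assert out == {"up": [], "down": []}

    def test_matches_enumeration_and_disjoint(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            {"log2_fc": rng.normal(0, 1, 10), "q": rng.uniform(0, 0.2, 10)},
            index=[f"g{i}" for i in range(10)],
        )
        out = select_significant(table, 0.05, 0.6)
        up = [g for g in table.index
              if table.loc[g, "q"] < 0.05 and table.loc[g, "log2_fc"] > 0.6]
        down = [g for g in table.index
                if table.loc[g, "q"] < 0.05 and table.loc[g, "log2_fc"] < -0.6]
        assert out["up"] == up
        assert out["down"] == down
        assert not set(out["up"]) & set(out["down"])


class TestSignalToNoiseRanking:
    def test_equal_groups_zero_metric(self):
        em = make_matrix([[1.0, 1.0, 1.0, 1.0]], groups=list("aabb"))
        s = signal_to_noise_ranking(em, ["s0", "s1"], ["s2", "s3"])
        assert s.iloc[0] == 0.0

    def test_floored_sd_hand_value(self):
        # a = {3,3}, b = {1,1}: sds 0 -> floors 0.6 and 0.2 -> 2/0.8 = 2.5
        em = make_matrix([[3.0, 3.0, 1.0, 1.0]], groups=list("aabb"))
        s = signal_to_noise_ranking(em, ["s0", "s1"], ["s2", "s3"])
        assert s.iloc[0] == pytest.approx(2.5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        em = make_matrix(rng.normal(5, 2, (30, 8)),
                         groups=["a"] * 4 + ["b"] * 4)
        ga, gb = [f"s{j}" for j in range(4)], [f"s{j}" for j in range(4, 8)]
        fwd = signal_to_noise_ranking(em, ga, gb)
        rev = signal_to_noise_ranking(em, gb, ga)
        np.testing.assert_allclose(fwd.sort_index(), -rev.sort_index())
        assert list(fwd.index) == list(rev.index[::-1])


class TestClusterSamples:
    def test_duplicate_samples_merge_at_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(5, 1, 40)
        x = np.column_stack([base, base, rng.normal(5, 1, 40),
                             rng.normal(5, 1, 40)])
        nwk = cluster_samples(make_matrix(x), top_fraction=1.0)
        assert "(s0:0,s1:0)" in nwk or "(s1:0,s0:0)" in nwk

    def test_block_correlated_topology(self):
        # A,B strongly correlated; C,D strongly correlated; cross blocks not
        rng = np.random.default_rng(2)
        u, v = rng.normal(0, 1, 60), rng.normal(0, 1, 60)
        x = np.column_stack(
            [u + rng.normal(0, 0.1, 60), u + rng.normal(0, 0.1, 60),
             v + rng.normal(0, 0.1, 60), v + rng.normal(0, 0.1, 60)]
        ) + 10.0
        nwk = cluster_samples(
            make_matrix(x, sample_ids=list("ABCD")), top_fraction=1.0)
        import skbio
        tree = skbio.TreeNode.read([nwk])
        siblings = {
            frozenset(t.name for t in node.tips())
            for node in tree.non_tips()
        }
        assert frozenset("AB") in siblings
        assert frozenset("CD") in siblings

    def test_constant_sample_rejected(self):
        x = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0)**2])
        with pytest.raises(ValueError, match="s0"):
            cluster_samples(make_matrix(x), top_fraction=1.0)

    def test_treated_naive_separation_on_synthetic(self, small_expression):
        import skbio
        nwk = cluster_samples(small_expression)
        tree = skbio.TreeNode.read([nwk])
        # the two arms should form two clades at the root
        children = tree.children
        assert len(children) == 2
        sides = [{t.name[0] for t in c.tips()} if not c.is_tip() else
                 {c.name[0]} for c in children]
        assert {"T"} in sides or {"N"} in sides
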