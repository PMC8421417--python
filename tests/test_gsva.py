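import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from oracles import gsva_oracle
from persistsig import (ExpressionMatrix, SignatureCollection,
                        filter_zero_genes, gsva_scores, kernel_cdf_transform,
                        rank_center, random_walk_es, upper_quartile_normalize)
from persistsig.gsva import CenteredRanks, GsvaOptions


class TestUpperQuartile:
    def test_identical_samples_unchanged_up_to_constant(self):
        col = np.array([1.0, 4, 2, 8, 3])
        m = ExpressionMatrix([f"g{i}" for i in range(5)], ["a", "b"],
                             np.column_stack([col, col]), "counts")
        out = upper_quartile_normalize(m)
        ratio = out.values / m.values
        assert np.allclose(ratio, ratio.flat[0])

    def test_doubled_sample_rescaled_to_match(self):
        col = np.array([1.0, 4, 2, 8, 3])
        m = ExpressionMatrix([f"g{i}" for i in range(5)], ["a", "b"],
                             np.column_stack([col, 2 * col]), "counts")
        out = upper_quartile_normalize(m)
        np.testing.assert_allclose(out.values[:, 0], out.values[:, 1])

    def test_scale_factors_follow_geometric_mean(self):
        # constant columns: the 75th percentile IS the column value
        cols = np.column_stack([np.full(4, 4.0), np.full(4, 8.0),
                                np.full(4, 16.0)])
        m = ExpressionMatrix([f"g{i}" for i in range(4)], ["a", "b", "c"],
                             cols, "counts")
        out = upper_quartile_normalize(m)
        factors = out.values[0] / m.values[0]
        np.testing.assert_allclose(factors, [2.0, 1.0, 0.5])

    def test_zero_sample_named_in_error(self):
        m = ExpressionMatrix(["g1"], ["a", "bad"],
                             np.array([[1.0, 0.0]]), "counts")
        with pytest.raises(ValueError, match="bad"):
            upper_quartile_normalize(m)


class TestFilterZeroGenes:
    def test_counts_and_error(self):
        values = np.array([[1.0, 2], [0, 3], [4, 5], [6, 0], [7, 8]])
        m = ExpressionMatrix([f"g{i}" for i in range(5)], ["a", "b"],
                             values, "counts")
        out = filter_zero_genes(m)
        assert out.gene_ids == ["g0", "g2", "g4"]
        zeros = ExpressionMatrix(["g1"], ["a"], np.array([[0.0]]), "counts")
        with pytest.raises(ValueError):
            filter_zero_genes(zeros)

    def test_all_positive_unchanged(self, toy_lognorm):
        m = ExpressionMatrix(toy_lognorm.gene_ids, toy_lognorm.unit_ids,
                             toy_lognorm.values + 1, "counts")
        assert filter_zero_genes(m).gene_ids == m.gene_ids


class TestKernelTransform:
    def test_constant_gene_gaussian_gives_half(self):
        m = ExpressionMatrix(["g1"], ["a", "b", "c"],
                             np.full((1, 3), 2.5), "lognorm")
        out = kernel_cdf_transform(m, "gaussian")
        np.testing.assert_allclose(out.values, 0.5)

    def test_two_sample_gaussian_closed_form(self):
        m = ExpressionMatrix(["g1"], ["a", "b"],
                             np.array([[0.0, 1.0]]), "lognorm")
        out = kernel_cdf_transform(m, "gaussian")
        h = np.std([0.0, 1.0], ddof=1) / 4.0
        expected_hi = (norm.cdf(0.0) + norm.cdf(1.0 / h)) / 2.0
        assert out.values[0, 1] == pytest.approx(expected_hi)
        assert out.values[0, 1] > 0.5

    def test_poisson_monotone_in_count(self):
        m = ExpressionMatrix(["g1"], ["a", "b", "c"],
                             np.array([[1.0, 5.0, 20.0]]), "counts")
        out = kernel_cdf_transform(m, "poisson")
        assert out.values[0, 0] < out.values[0, 1] < out.values[0, 2]

    def test_values_in_open_unit_interval(self, toy_counts):
        out = kernel_cdf_transform(toy_counts, "poisson")
        assert np.all(out.values > 0) and np.all(out.values < 1)

    def test_kernel_kind_checks(self, toy_counts, toy_lognorm):
        with pytest.raises(ValueError):
            kernel_cdf_transform(toy_counts, "gaussian")
        with pytest.raises(ValueError):
            kernel_cdf_transform(toy_lognorm, "poisson")


class TestRankCenter:
    def test_three_distinct_genes(self):
        m = ExpressionMatrix(["g1", "g2", "g3"], ["a", "b", "c"],
                             np.array([[1.0, 2, 3], [5, 1, 1], [9, 9, 2]]),
                             "lognorm")
        r = rank_center(kernel_cdf_transform(m, "gaussian"))
        assert sorted(r.values[:, 0]) == [-1.0, 0.0, 1.0]

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(2, 12), st.integers(2, 4), st.integers(0, 10_000))
    def test_centered_ranks_sum_to_zero(self, p, n, seed):
        rng = np.random.default_rng(seed)
        m = ExpressionMatrix([f"g{i:02d}" for i in range(p)],
                             [f"s{j}" for j in range(n)],
                             rng.integers(0, 4, (p, n)).astype(float) + 0.5,
                             "lognorm")
        r = rank_center(kernel_cdf_transform(m, "gaussian"))
        np.testing.assert_allclose(r.values.sum(axis=0), 0.0, atol=1e-9)

    def test_tie_broken_in_gene_id_order(self):
        # g2 and g3 tie on the transformed value; g2 gets the lower rank
        from persistsig.gsva import KernelTransformed
        t = KernelTransformed(["g4", "g3", "g2", "g1"], ["s"],
                              np.array([[0.9], [0.4], [0.4], [0.1]]),
                              "gaussian")
        r = rank_center(t)
        by_gene = dict(zip(t.gene_ids, r.values[:, 0]))
        assert by_gene["g1"] < by_gene["g2"] < by_gene["g3"] < by_gene["g4"]


def _ranks(values, gene_ids=None):
    gene_ids = gene_ids or [f"g{i}" for i in range(len(values))]
    return CenteredRanks(gene_ids, ["s"], np.asarray(values, float)[:, None])


class TestRandomWalk:
    def test_top_positions_maximal_concordance(self):
        r = _ranks([2.0, 1.0, 0.0, -1.0, -2.0])
        sig = SignatureCollection(["top"], {"top": ["g0", "g1"]})
        res = random_walk_es(r, sig, "s", "top", keep_path=True)
        assert res.es_plus == pytest.approx(1.0)
        # hand-enumerated: steps 2/3, 1/3 in-set; 1/3 each out-of-set
        np.testing.assert_allclose(res.path, [2 / 3, 1.0, 2 / 3, 1 / 3, 0.0],
                                   atol=1e-12)
        assert res.score == pytest.approx(1.0)

    def test_bottom_positions_mirror_negative(self):
        r = _ranks([2.0, 1.0, 0.0, -1.0, -2.0])
        sig = SignatureCollection(["bot"], {"bot": ["g3", "g4"]})
        res = random_walk_es(r, sig, "s", "bot")
        assert res.score == pytest.approx(-1.0)

    def test_interior_set_hand_enumerated(self):
        # set {g1, g3}: walk 2/5-steps out, |r|-share steps in
        r = _ranks([2.0, 1.0, 0.0, -1.0, -2.0])
        sig = SignatureCollection(["mid"], {"mid": ["g1", "g3"]})
        res = random_walk_es(r, sig, "s", "mid", keep_path=True)
        expected = [-1 / 3, -1 / 3 + 1 / 2, 1 / 6 - 1 / 3, -1 / 6 + 1 / 2,
                    1 / 3 - 1 / 3]
        np.testing.assert_allclose(res.path, expected, atol=1e-12)
        assert res.score == pytest.approx(abs(1 / 3) - abs(1 / 3), abs=1e-12)

    def test_set_covering_matrix_rejected(self):
        r = _ranks([1.0, -1.0])
        sig = SignatureCollection(["all"], {"all": ["g0", "g1"]})
        with pytest.raises(ValueError, match="out-of-set"):
            random_walk_es(r, sig, "s", "all")

    def test_antisymmetry_under_rank_negation(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(9) - 4.0)
        sig = SignatureCollection(["s"], {"s": ["g1", "g4", "g6"]})
        plus = random_walk_es(_ranks(list(vals)), sig, "s", "s").score
        minus = random_walk_es(_ranks(list(-vals)), sig, "s", "s").score
        assert minus == pytest.approx(-plus)

    def test_two_direction_set_cancels(self):
        vals = list(np.arange(20) - 9.5)
        ids = [f"g{i:02d}" for i in range(20)]
        top = [ids[i] for i in np.argsort(vals)[-3:]]
        bottom = [ids[i] for i in np.argsort(vals)[:3]]
        both = SignatureCollection(["b"], {"b": top + bottom})
        only_top = SignatureCollection(["t"], {"t": top})
        s_both = random_walk_es(_ranks(vals, ids), both, "s", "b").score
        s_top = random_walk_es(_ranks(vals, ids), only_top, "s", "t").score
        assert abs(s_both) < s_top


class TestGsvaScores:
    def test_gene_order_invariance(self, toy_counts):
        sig = SignatureCollection(["s"], {"s": ["g0", "g3"]})
        base = gsva_scores(toy_counts, sig).values
        perm = np.random.default_rng(1).permutation(toy_counts.n_genes)
        shuffled = ExpressionMatrix(
            [toy_counts.gene_ids[i] for i in perm],
            toy_counts.unit_ids, toy_counts.values[perm], "counts")
        np.testing.assert_allclose(gsva_scores(shuffled, sig).values, base)

    def test_sample_permutation_equivariance(self, toy_counts):
        sig = SignatureCollection(["s"], {"s": ["g0", "g3"]})
        base = gsva_scores(toy_counts, sig).values
        perm = [2, 0, 3, 1]
        shuffled = ExpressionMatrix(
            toy_counts.gene_ids, [toy_counts.unit_ids[j] for j in perm],
            toy_counts.values[:, perm], "counts")
        np.testing.assert_allclose(gsva_scores(shuffled, sig).values,
                                   base[:, perm])

    @pytest.mark.parametrize("value_kind,cohort", [("counts", False),
                                                   ("counts", True),
                                                   ("lognorm", False)])
    def test_matches_independent_oracle(self, value_kind, cohort):
        rng = np.random.default_rng(17)
        values = rng.integers(0, 6, (8, 4)).astype(float)
        values[values.sum(axis=1) == 0, 0] = 1  # avoid all-zero genes
        if value_kind == "lognorm":
            values = values + 0.5
        m = ExpressionMatrix([f"g{i}" for i in range(8)],
                             [f"s{j}" for j in range(4)], values, value_kind)
        sig = SignatureCollection(["a", "b"],
                                  {"a": ["g0", "g5"], "b": ["g2", "g3", "g7"]})
        got = gsva_scores(m, sig, GsvaOptions(cohort_mode=cohort)).values
        want = gsva_oracle(values.tolist(), m.gene_ids, m.unit_ids,
                           sig.member_genes, value_kind, cohort_mode=cohort)
        for k, name in enumerate(sig.names):
            np.testing.assert_allclose(got[k], want[name], atol=1e-10)

    def test_scores_bounded(self, toy_counts, toy_lognorm):
        sig = SignatureCollection(["s"], {"s": ["g0", "g3"]})
        for m in (toy_counts,):
            v = gsva_scores(m, sig).values
            assert np.all(v >= -1) and np.all(v <= 1)
        sig2 = SignatureCollection(["s"], {"s": ["g00", "g13", "g29"]})
        v = gsva_scores(toy_lognorm, sig2).values
        assert np.all(v >= -1) and np.all(v <= 1)

    def test_few_samples_warns(self):
        m = ExpressionMatrix(["g1", "g2", "g3"], ["a", "b"],
                             np.array([[1.0, 2], [3, 1], [2, 5]]), "counts")
        sig = SignatureCollection(["s"], {"s": ["g1"]})
        with pytest.warns(UserWarning, match="fewer than 3"):
            gsva_scores(m, sig)
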