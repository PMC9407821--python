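import numpy as np
import pandas as pd
import pytest

from convergeomics import normalize
from convergeomics.exceptions import AnalysisError
from convergeomics.io import OrthologCountMatrix
from oracles import tmm_factors_literal


def _matrix(counts, lengths, species):
    counts = np.asarray(counts)
    sample_ids = [f"s{i}" for i in range(counts.shape[1])]
    samples = pd.DataFrame(
        {"species": species, "tissue": "stomach", "group": "x"},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return OrthologCountMatrix(
        counts=pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])], columns=sample_ids),
        gene_lengths=pd.Series(lengths, index=[f"g{i}" for i in range(counts.shape[0])]),
        samples=samples,
    )


class TestLowExpressionFilter:
    def test_zero_in_one_sample_removes_gene(self):
        m = _matrix([[5, 0, 3, 4], [1, 2, 3, 4]], [1000, 1000], ["a", "a", "b", "b"])
        out = normalize.filter_low_expression(m)
        assert out.gene_ids == ["g1"]

    def test_any_species_mode_keeps_gene_expressed_in_one_species(self):
        m = _matrix([[5, 6, 0, 4], [0, 2, 3, 0]], [1000, 1000], ["a", "a", "b", "b"])
        out = normalize.filter_low_expression(m, mode="any_species")
        assert out.gene_ids == ["g0"]  # fully expressed in species a; g1 in neither

    def test_all_positive_unchanged_and_all_zero_removed(self):
        m = _matrix([[5, 6, 3, 4], [0, 0, 0, 0]], [1000, 1000], ["a", "a", "b", "b"])
        out = normalize.filter_low_expression(m)
        assert out.gene_ids == ["g0"]
        m2 = _matrix([[5, 6, 3, 4]], [1000], ["a", "a", "b", "b"])
        assert normalize.filter_low_expression(m2).gene_ids == ["g0"]


class TestRpk:
    def test_arithmetic(self):
        m = _matrix([[100, 0], [7, 7]], [2000, 500], ["a", "b"])
        table = normalize.rpk(m)
        assert table.loc["g0", "s0"] == 50.0
        assert table.loc["g0", "s1"] == 0.0
        assert table.loc["g1", "s0"] == 14.0


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 500, 100).astype(float)
        table = pd.DataFrame({f"s{i}": col for i in range(4)})
        factors, _ = normalize.tmm_factors(table)
        assert np.allclose(factors, 1.0)

    def test_pure_depth_difference_absorbed_by_library_size(self):
        # B = 2*A elementwise: all M ratios are 0 so both factors are 1
        rng = np.random.default_rng(1)
        a = rng.integers(1, 500, 200).astype(float)
        table = pd.DataFrame({"A": a, "B": 2 * a})
        factors, _ = normalize.tmm_factors(table)
        assert np.allclose(factors, [1.0, 1.0])

    def test_asymmetric_shift_lowers_factor(self):
        # 20 of 200 genes 8-fold higher in B: B's factor must fall below A's
        rng = np.random.default_rng(2)
        a = rng.integers(10, 500, 200).astype(float)
        b = a.copy()
        b[:20] *= 8
        factors, _ = normalize.tmm_factors(pd.DataFrame({"A": a, "B": b}))
        assert factors["B"] < 1.0 < factors["A"]

    def test_matches_literal_transcription(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            table = pd.DataFrame(
                rng.gamma(2.0, 50.0, size=(200, 6)),
                columns=[f"s{i}" for i in range(6)],
            )
            factors, ref = normalize.tmm_factors(table)
            expected, ref_oracle = tmm_factors_literal(table.to_numpy().tolist())
            assert ref == f"s{ref_oracle}"
            assert np.max(np.abs(factors.to_numpy() - np.array(expected))) < 1e-10


class TestGetmm:
    def test_worked_three_gene_example(self):
        # counts (10,20,70) over lengths (1,2,7) kb -> RPK (10,10,10) -> thirds of 1e6
        m = _matrix([[10, 10], [20, 20], [70, 70]], [1000, 2000, 7000], ["a", "b"])
        norm = normalize.getmm(m)
        assert np.allclose(norm.values.to_numpy(), 1e6 / 3)

    def test_column_sums_equal_million_over_factor(self, small_config):
        from convergeomics.simulate import simulate_expression

        m, _ = simulate_expression(small_config)
        m = normalize.filter_low_expression(m)
        norm = normalize.getmm(m)
        sums = norm.values.sum(axis=0)
        assert np.allclose(sums * norm.tmm_factors, 1e6, rtol=1e-9)

    def test_depth_scaling_invariance(self, small_config):
        from convergeomics.simulate import simulate_expression

        m, _ = simulate_expression(small_config)
        m = normalize.filter_low_expression(m)
        norm1 = normalize.getmm(m)
        doubled = m.counts.copy()
        doubled.iloc[:, 0] *= 2
        m2 = OrthologCountMatrix(counts=doubled, gene_lengths=m.gene_lengths, samples=m.samples)
        norm2 = normalize.getmm(m2)
        # M, A and the trims are depth-invariant; only the delta-method
        # precision weights shift slightly with depth, so the column agrees
        # to well under a percent rather than to machine precision.
        assert np.allclose(
            norm1.values.iloc[:, 0], norm2.values.iloc[:, 0], rtol=1e-2
        )


class TestLogAndVarianceFilter:
    def test_log_transform_values(self):
        table = pd.DataFrame({"a": [0.0, 1.0, 1023.0]})
        out = normalize.log_transform(table)
        assert list(out["a"]) == [0.0, 1.0, 10.0]

    def test_variance_filter_keeps_top_half(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(0, np.arange(1, 11)[:, None], size=(10, 8)))
        out = normalize.variance_filter(table, quantile=0.5)
        assert len(out) == 5
        variances = table.var(axis=1)
        assert set(out.index) == set(variances.nlargest(5).index)

    def test_quantile_zero_is_identity_and_constant_rows_drop(self):
        table = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 5.0, 9.0]])
        assert normalize.variance_filter(table, quantile=0.0).equals(table)
        assert list(normalize.variance_filter(table, quantile=0.5).index) == [1]

    def test_bad_quantile_rejected(self):
        with pytest.raises(AnalysisError):
            normalize.variance_filter(pd.DataFrame([[1.0, 2.0]]), quantile=1.0)


class TestPca:
    def test_two_cluster_structure(self):
        rng = np.random.default_rng(5)
        base_a = rng.normal(0, 1, 50)
        base_b = base_a + 5
        table = pd.DataFrame(
            {"a1": base_a, "a2": base_a, "b1": base_b, "b2": base_b},
        )
        res = normalize.pca(table)
        assert res.explained_variance[0] > 0.999
        pc1 = res.pca_scores["PC1"]
        assert np.sign(pc1["a1"]) == np.sign(pc1["a2"]) != np.sign(pc1["b1"])

    def test_explained_fractions_and_orthogonality(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(40, 6)))
        res = normalize.pca(table)
        assert abs(res.explained_variance.sum() - 1.0) < 1e-9
        gram = res.pca_loadings.to_numpy().T @ res.pca_loadings.to_numpy()
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_constant_input_rejected(self):
        with pytest.raises(AnalysisError):
            normalize.pca(pd.DataFrame(np.ones((5, 4))))


class TestSpearmanCluster:
    def test_self_correlation_and_rank_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        table = pd.DataFrame({"a": x, "b": x**3, "c": rng.normal(size=30)})
        res = normalize.spearman_cluster(table)
        assert res.spearman.loc["a", "a"] == 1.0
        # b is a monotone transform of a -> perfect rank correlation
        assert res.spearman.loc["a", "b"] == pytest.approx(1.0)
        assert np.allclose(res.spearman, res.spearman.T)

    def test_three_point_complete_linkage_merge_order(self):
        # engineered distances: d(A,B)=small, both far from C -> ((A,B),C)
        rng = np.random.default_rng(8)
        a = np.arange(30, dtype=float)
        b = a.copy()
        b[:2] = b[:2][::-1]  # tiny perturbation: high correlation
        c = rng.permutation(a)
        res = normalize.spearman_cluster(pd.DataFrame({"A": a, "B": b, "C": c}))
        first_merge = res.linkage[0, :2].astype(int)
        assert set(first_merge) == {0, 1}  # A and B merge first
        assert res.newick.startswith("((A") or "(A:" in res.newick
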