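import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sfcomod.io import ExpressionMatrix, ValidationError
from sfcomod.correlation import (
    mean_panel_correlation,
    pearson_cross,
    pearson_matrix,
    spearman_per_gene,
)


def brute_force_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Two-pass product-moment formula, the independent oracle."""
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


def _matrix(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestPearsonMatrix:
    def test_worked_examples(self):
        X = _matrix([[1, 2, 3, 4], [6, 4, 2, 0], [1, 3, 2, 4]], ["g1", "g2", "g3"])
        C = pearson_matrix(X, ["g1", "g2", "g3"])
        assert C.data.loc["g1", "g1"] == 1.0
        assert C.data.loc["g1", "g2"] == pytest.approx(-1.0)
        # (1,2,3,4) vs (1,3,2,4): direct product-moment evaluation gives 0.8
        assert C.data.loc["g1", "g3"] == pytest.approx(0.8)

    def test_matches_brute_force_oracle(self, rng):
        values = rng.normal(size=(10, 20))
        genes = [f"g{i}" for i in range(10)]
        C = pearson_matrix(_matrix(values, genes), genes)
        for i in range(10):
            for j in range(10):
                expected = brute_force_pearson(values[i], values[j])
                assert C.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance(self, rng):
        values = rng.normal(size=(5, 12))
        genes = [f"g{i}" for i in range(5)]
        C1 = pearson_matrix(_matrix(values, genes), genes)
        scaled = values * rng.uniform(0.5, 3.0, size=(5, 1)) + rng.normal(size=(5, 1))
        C2 = pearson_matrix(_matrix(scaled, genes), genes)
        np.testing.assert_allclose(C1.values, C2.values, atol=1e-12)

    def test_symmetry_exact(self, rng):
        values = rng.normal(size=(6, 15))
        genes = [f"g{i}" for i in range(6)]
        C = pearson_matrix(_matrix(values, genes), genes)
        np.testing.assert_array_equal(C.values, C.values.T)
        np.testing.assert_array_equal(np.diag(C.values), np.ones(6))

    def test_zero_variance_named(self):
        X = _matrix([[1, 1, 1], [1, 2, 3]], ["flat", "ok"])
        with pytest.raises(ValidationError, match="flat"):
            pearson_matrix(X, ["flat", "ok"])

    def test_missing_panel_gene_listed(self, tiny_expr):
        with pytest.raises(ValidationError, match="absent"):
            pearson_matrix(tiny_expr, ["g1", "nope"])


class TestPearsonCross:
    def test_consistent_with_square_matrix(self, tiny_expr):
        genes = tiny_expr.gene_ids
        C_sq = pearson_matrix(tiny_expr, genes)
        C_x = pearson_cross(tiny_expr, genes, genes)
        np.testing.assert_allclose(C_x.values, C_sq.values, atol=1e-12)

    def test_self_pair_is_one(self, tiny_expr):
        C = pearson_cross(tiny_expr, ["g1"], ["g1", "g2"])
        assert C.data.loc["g1", "g1"] == pytest.approx(1.0)

    def test_two_matrix_sample_alignment(self, tiny_expr):
        shuffled = ExpressionMatrix(tiny_expr.data[["s3", "s1", "s4", "s2"]])
        C1 = pearson_cross(tiny_expr, ["g1"], ["g2"], Y=tiny_expr)
        C2 = pearson_cross(tiny_expr, ["g1"], ["g2"], Y=shuffled)
        np.testing.assert_allclose(C1.values, C2.values, atol=1e-12)

    def test_sample_mismatch_rejected(self, tiny_expr):
        other = ExpressionMatrix(tiny_expr.data.rename(columns={"s1": "zz"}))
        with pytest.raises(ValidationError, match="mismatch"):
            pearson_cross(tiny_expr, ["g1"], ["g2"], Y=other)


class TestMeanPanelCorrelation:
    def _corr(self):
        df = pd.DataFrame(
            [[1.0, 0.2, 0.2], [0.6, 1.0, 0.6], [0.2, 0.6, 1.0]],
            index=list("abc"),
            columns=list("abc"),
        )
        from sfcomod.correlation import CorrelationMatrix

        return CorrelationMatrix(df)

    def test_hand_summed_grand_mean(self):
        C = self._corr()
        per_gene, grand = mean_panel_correlation(C, ["a", "b"], ["c"])
        assert per_gene["a"] == pytest.approx(0.2)
        assert per_gene["b"] == pytest.approx(0.6)
        assert grand == pytest.approx(0.4)

    def test_self_pair_excluded(self):
        C = self._corr()
        per_gene, _ = mean_panel_correlation(C, ["a"], ["a", "b"])
        assert per_gene["a"] == pytest.approx(0.2)  # only the a-b entry

    def test_empty_after_exclusion_rejected(self):
        C = self._corr()
        with pytest.raises(ValidationError, match="empty target"):
            mean_panel_correlation(C, ["a"], ["a"])


class TestSpearman:
    def test_monotone_transform_is_one(self):
        rna = _matrix([[1.0, 2, 3, 4, 5]], ["g"], list("abcde"))
        protein = _matrix([[np.exp(v) for v in [1, 2, 3, 4, 5]]], ["g"], list("abcde"))
        rho, mean_rho = spearman_per_gene(rna, protein, ["g"])
        assert rho["g"] == pytest.approx(1.0)
        assert mean_rho == pytest.approx(1.0)

    def test_worked_example(self):
        # ranks differ by d^2 = (4, 1, 1): rho = 1 - 6*6/(3*8) = -0.5
        rna = _matrix([[1.0, 2, 3]], ["g"], list("abc"))
        protein = _matrix([[3.0, 1, 2]], ["g"], list("abc"))
        rho, _ = spearman_per_gene(rna, protein, ["g"])
        assert rho["g"] == pytest.approx(-0.5)

    def test_constant_vector_flagged_undefined(self):
        rna = _matrix([[1.0, 2, 3], [1, 2, 3]], ["g1", "g2"], list("abc"))
        protein = _matrix([[5.0, 5, 5], [3, 1, 2]], ["g1", "g2"], list("abc"))
        rho, mean_rho = spearman_per_gene(rna, protein, ["g1", "g2"])
        assert np.isnan(rho["g1"])
        assert mean_rho == pytest.approx(-0.5)

    def test_too_few_shared_samples(self):
        rna = _matrix([[1.0, 2]], ["g"], ["a", "b"])
        protein = _matrix([[1.0, 2]], ["g"], ["a", "b"])
        with pytest.raises(ValidationError, match="3 shared"):
            spearman_per_gene(rna, protein, ["g"])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_pearson_matches_numpy_on_random_data(seed):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(4, 8))
    genes = [f"g{i}" for i in range(4)]
    C = pearson_matrix(_matrix(values, genes), genes)
    np.testing.assert_allclose(C.values, np.corrcoef(values), atol=1e-12)
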