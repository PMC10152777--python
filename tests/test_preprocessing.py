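import numpy as np
import pytest

from scea import ExpressionMatrix
from scea.preprocessing import (
    filter_cells_quartile_fence, filter_genes_high_expression,
    filter_genes_min_cells, library_normalize_log, preprocess,
)


def em(values, prefix=("c", "g")):
    values = np.asarray(values)
    return ExpressionMatrix(
        values,
        [f"{prefix[0]}{i}" for i in range(values.shape[0])],
        [f"{prefix[1]}{j}" for j in range(values.shape[1])],
    )


class TestMinCells:
    def test_boundary_three_or_more(self):
        # gene 0: all zero; gene 1: nonzero in 2 cells; gene 2: nonzero in 3
        v = np.zeros((4, 3))
        v[:2, 1] = 5
        v[:3, 2] = 1
        out, rep = filter_genes_min_cells(em(v), min_cells=3)
        assert out.gene_ids == ["g2"]
        assert rep.genes_removed_min_cells == 2

    def test_matches_bruteforce_nonzero_scan(self):
        rng = np.random.default_rng(0)
        v = rng.poisson(0.3, size=(50, 200))
        out, _ = filter_genes_min_cells(em(v), min_cells=3)
        expected = [j for j in range(200) if sum(v[i, j] > 0 for i in range(50)) >= 3]
        assert out.gene_ids == [f"g{j}" for j in expected]

    def test_gene_order_and_cells_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.poisson(1.0, size=(10, 30))
        out, _ = filter_genes_min_cells(em(v), min_cells=2)
        assert out.cell_ids == [f"c{i}" for i in range(10)]
        assert out.gene_ids == sorted(out.gene_ids, key=lambda g: int(g[1:]))

    def test_all_removed_raises(self):
        with pytest.raises(ValueError, match="relax"):
            filter_genes_min_cells(em(np.zeros((5, 3))), min_cells=1)


class TestHighExpression:
    def test_quantile_oracle_four_genes(self):
        # aggregates (1, 2, 3, 100); linear-interpolation Q3 = 27.25
        v = np.array([[1.0, 2.0, 3.0, 100.0]] * 1) * np.ones((1, 4))
        v = np.vstack([v, np.zeros((3, 4))])  # aggregates unchanged
        assert np.quantile(v.sum(axis=0), 0.75) == pytest.approx(27.25)
        out, rep = filter_genes_high_expression(em(v), quantile=0.75)
        assert out.gene_ids == ["g0", "g1", "g2"]
        assert rep.genes_removed_high_expression == 1

    def test_equal_aggregates_nothing_strictly_exceeds(self):
        out, rep = filter_genes_high_expression(em(np.ones((5, 6))), quantile=0.75)
        assert rep.genes_removed_high_expression == 0
        assert out.values.shape == (5, 6)

    def test_extreme_quantile_removes_at_most_top_gene(self):
        rng = np.random.default_rng(2)
        v = rng.poisson(5.0, size=(8, 10)).astype(float)
        out, rep = filter_genes_high_expression(em(v), quantile=0.999)
        assert rep.genes_removed_high_expression <= 1
        if rep.genes_removed_high_expression == 1:
            top = int(np.argmax(v.sum(axis=0)))
            assert f"g{top}" not in out.gene_ids

    def test_too_few_genes_raises(self):
        with pytest.raises(ValueError):
            filter_genes_high_expression(em(np.ones((5, 1))))


class TestCellFence:
    def test_hand_oracle_nine_cells(self):
        # totals (10 x 8, 1000): Q1 = Q3 = 10, IQR = 0, fence = [10, 10]
        v = np.full((9, 1), 10.0)
        v[8, 0] = 1000.0
        out, rep = filter_cells_quartile_fence(em(v), fence_multiplier=1.5)
        assert rep.cells_removed == 1
        assert "c8" not in out.cell_ids

    def test_identical_cells_none_removed(self):
        out, rep = filter_cells_quartile_fence(em(np.ones((6, 4))))
        assert rep.cells_removed == 0

    def test_huge_multiplier_keeps_all(self):
        rng = np.random.default_rng(3)
        v = rng.poisson(2.0, size=(12, 5)).astype(float)
        out, rep = filter_cells_quartile_fence(em(v), fence_multiplier=1e12)
        assert rep.cells_removed == 0
        assert out.values.shape == (12, 5)

    def test_genes_unchanged(self):
        rng = np.random.default_rng(4)
        v = rng.poisson(2.0, size=(12, 5)).astype(float)
        out, _ = filter_cells_quartile_fence(em(v))
        assert out.gene_ids == [f"g{j}" for j in range(5)]


class TestNormalize:
    def test_single_expressed_gene(self):
        out = library_normalize_log(em(np.array([[0.0, 0.0, 10.0]])), scale=10)
        assert np.allclose(out.values, [[0.0, 0.0, np.log(11.0)]])

    def test_zero_total_cell_identified(self):
        v = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="c1"):
            library_normalize_log(em(v))

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(5)
        v = rng.poisson(3.0, size=(10, 20)).astype(float) + 1
        out = library_normalize_log(em(v), scale=1e4)
        expected = np.log1p(v / v.sum(axis=1, keepdims=True) * 1e4)
        assert np.allclose(out.values, expected, atol=1e-12)


class TestFilterProperties:
    @pytest.fixture()
    def random_counts(self):
        rng = np.random.default_rng(6)
        return em(rng.negative_binomial(2, 0.3, size=(30, 60)).astype(float))

    def test_min_cells_filter_idempotent(self, random_counts):
        # removing genes cannot change any surviving gene's expressing-cell
        # count, so a second pass is the identity
        once, _ = filter_genes_min_cells(random_counts, 3)
        twice, _ = filter_genes_min_cells(once, 3)
        assert np.array_equal(once.values, twice.values)

    def test_quantile_filters_fixed_point_wrt_recorded_cutoff(self, random_counts):
        # the quantile-based filters recompute their cutoff on reduced data,
        # so strict idempotence is not guaranteed; the contract is that no
        # survivor exceeds the threshold recorded in the report
        out, rep = filter_genes_high_expression(random_counts, 0.75)
        cutoff = rep.thresholds_used["high_expression_cutoff"]
        assert (out.values.sum(axis=0) <= cutoff).all()
        out, rep = filter_cells_quartile_fence(random_counts, 1.5)
        fences = rep.thresholds_used["cell_fences"]["total_umi"]
        totals = out.values.sum(axis=1)
        assert ((totals >= fences["lower"]) & (totals <= fences["upper"])).all()

    def test_filters_commute_with_permutation(self, random_counts):
        rng = np.random.default_rng(7)
        pc = rng.permutation(30)
        pg = rng.permutation(60)
        permuted = ExpressionMatrix(
            random_counts.values[np.ix_(pc, pg)],
            [random_counts.cell_ids[i] for i in pc],
            [random_counts.gene_ids[j] for j in pg])
        a, _ = filter_genes_min_cells(random_counts, 3)
        b, _ = filter_genes_min_cells(permuted, 3)
        # same genes survive regardless of ordering
        assert set(a.gene_ids) == set(b.gene_ids)

    def test_report_reconstructs_dimensions(self, random_counts):
        out, rep = preprocess(random_counts, normalize=False)
        assert out.values.shape[0] + rep.cells_removed == 30
        assert (out.values.shape[1] + rep.genes_removed_min_cells
                + rep.genes_removed_high_expression == 60)
        assert rep.filter_order == [
            "genes_min_cells", "cells_quartile_fence", "genes_high_expression"]
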