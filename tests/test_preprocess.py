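import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sccluster import (
    CountMatrix,
    QCConfig,
    filter_cells,
    filter_genes,
    fit_variance_trend,
    normalize,
    select_hvg,
    standard_scale,
)
from sccluster.errors import (
    ConstantRowError,
    DegenerateInputError,
    EmptyResultError,
    ZeroTotalCountError,
)
from sccluster.preprocess import NormalizedMatrix, _trend_curve


def _counts(values, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{j}" for j in range(values.shape[1])]
    return CountMatrix(values, [f"c{i}" for i in range(values.shape[0])], genes)


class TestFilterCells:
    def test_high_mito_cell_removed(self):
        # cell 0: 6 of 100 counts mitochondrial (> 5%); cell 1 clean
        vals = np.array([[6, 94, 0], [0, 50, 50]])
        m = _counts(vals, genes=["MT-ND1", "g1", "g2"])
        cfg = QCConfig(max_mito_fraction=0.05, min_genes_per_cell=1, max_genes_per_cell=10)
        out = filter_cells(m, cfg)
        assert out.cell_ids == ["c1"]

    def test_low_complexity_cell_removed(self):
        # cell 0 expresses 99 genes, cell 1 expresses 100
        vals = np.zeros((2, 150), dtype=int)
        vals[0, :99] = 1
        vals[1, :100] = 1
        cfg = QCConfig(max_mito_fraction=1.0, min_genes_per_cell=100,
                       max_genes_per_cell=10_000, mito_gene_prefix="MT-")
        out = filter_cells(_counts(vals), cfg)
        assert out.cell_ids == ["c1"]

    def test_vacuous_filter_is_identity(self):
        vals = np.array([[1, 2], [3, 4]])
        cfg = QCConfig(max_mito_fraction=1.0, min_genes_per_cell=0,
                       max_genes_per_cell=10**9)
        out = filter_cells(_counts(vals), cfg)
        np.testing.assert_array_equal(out.toarray(), vals)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = _counts(rng.integers(0, 3, size=(20, 30)))
        cfg = QCConfig(max_mito_fraction=1.0, min_genes_per_cell=5,
                       max_genes_per_cell=25)
        once = filter_cells(m, cfg)
        twice = filter_cells(once, cfg)
        assert once.cell_ids == twice.cell_ids

    def test_excluded_barcodes_and_empty_error(self):
        m = _counts(np.ones((2, 3), dtype=int))
        cfg = QCConfig(max_mito_fraction=1.0, min_genes_per_cell=0,
                       max_genes_per_cell=10, excluded_barcodes={"c0", "c1"})
        with pytest.raises(EmptyResultError):
            filter_cells(m, cfg)


class TestFilterGenes:
    def test_all_zero_gene_removed(self):
        m = _counts(np.array([[1, 0], [2, 0]]))
        out = filter_genes(m, 1)
        assert out.gene_ids == ["g0"]

    def test_zero_threshold_identity(self):
        m = _counts(np.array([[1, 0], [2, 0]]))
        assert filter_genes(m, 0) is m

    def test_counted_nonzero_cells(self):
        # gene 1 expressed in exactly 2 of 4 cells; threshold 3 removes it
        vals = np.array([[1, 1, 1], [1, 1, 1], [1, 0, 1], [1, 0, 1]])
        out = filter_genes(_counts(vals), 3)
        assert out.gene_ids == ["g0", "g2"]


class TestNormalize:
    def test_median_depth_and_scaling(self):
        vals = np.diag([10, 20, 30])
        nm = normalize(_counts(vals))
        assert nm.L == 20
        np.testing.assert_allclose(nm.size_factors, [0.5, 1.0, 1.5])
        # cell 0 counts doubled before log1p
        assert nm.values[0, 0] == pytest.approx(np.log1p(20))
        np.testing.assert_allclose(nm.pre_log().sum(axis=1), 20, rtol=1e-6)

    def test_already_at_depth_is_identity_prelog(self):
        vals = np.full((3, 2), 5)
        nm = normalize(_counts(vals))
        np.testing.assert_allclose(nm.pre_log(), vals, rtol=1e-12)

    def test_single_cell(self):
        nm = normalize(_counts(np.array([[3, 4]])))
        assert nm.L == 7
        np.testing.assert_allclose(nm.pre_log(), [[3, 4]], rtol=1e-12)

    def test_zero_total_cell_raises(self):
        with pytest.raises(ZeroTotalCountError):
            normalize(_counts(np.array([[0, 0], [1, 2]])))

    def test_per_cell_totals_equal_L(self, default_sim):
        nm = normalize(default_sim.counts)
        np.testing.assert_allclose(nm.pre_log().sum(axis=1), nm.L, rtol=1e-6)


def _on_curve_matrix(means, a, b, p, n_cells=40):
    """Cells x genes matrix whose per-gene mean/variance sit exactly on the curve."""
    g = len(means)
    target_var = _trend_curve(np.asarray(means, float), a, b, p)
    half = n_cells // 2
    offs = np.sqrt(target_var * (n_cells - 1) / n_cells)
    x = np.empty((n_cells, g))
    x[:half] = means + offs
    x[half:] = means - offs
    return NormalizedMatrix(x, np.ones(n_cells), 1.0)


class TestVarianceTrend:
    def test_parameter_recovery_on_noiseless_points(self):
        means = np.linspace(0.2, 8.0, 60)
        nm = _on_curve_matrix(means, a=2.0, b=1.0, p=1.0)
        fit = fit_variance_trend(nm)
        assert fit.a == pytest.approx(2.0, rel=1e-3)
        assert fit.b == pytest.approx(1.0, rel=1e-3)
        assert fit.exponent == pytest.approx(1.0, rel=1e-3)
        assert np.max(np.abs(fit.per_gene_deviation)) < 1e-6

    def test_displaced_gene_has_largest_deviation(self):
        means = np.linspace(0.2, 8.0, 60)
        nm = _on_curve_matrix(means, a=2.0, b=1.0, p=1.0)
        # displace gene 30 upward by +5 variance
        extra = np.sqrt(nm.values.var(axis=0, ddof=1)[30] ** 2)  # noqa: F841
        target = nm.values.var(axis=0, ddof=1)[30] + 5.0
        col = nm.values[:, 30]
        scale = np.sqrt(target / col.var(ddof=1))
        nm.values[:, 30] = col.mean() + (col - col.mean()) * scale
        fit = fit_variance_trend(nm)
        assert np.argmax(fit.per_gene_deviation) == 30
        assert fit.per_gene_deviation[30] == pytest.approx(5.0, abs=0.5)

    def test_degenerate_input_raises(self):
        nm = NormalizedMatrix(np.zeros((5, 4)), np.ones(5), 1.0)
        with pytest.raises(DegenerateInputError):
            fit_variance_trend(nm)

    def test_deviation_definition(self, default_sim):
        from sccluster import normalize as _norm

        nm = _norm(default_sim.counts)
        fit = fit_variance_trend(nm)
        np.testing.assert_allclose(
            fit.per_gene_deviation,
            fit.per_gene_variance - fit.per_gene_expected_variance,
        )


class TestSelectHVG:
    def test_ordering_and_truncation(self):
        means = np.linspace(0.2, 8.0, 10)
        nm = _on_curve_matrix(means, a=2.0, b=1.0, p=1.0)
        fit = fit_variance_trend(nm)
        fit.per_gene_deviation = np.array([0, 10, -1, 3, 2, 5, 5, 0, -2, 1], float)
        top3 = select_hvg(nm, fit, 3)
        np.testing.assert_array_equal(top3, [1, 5, 6])  # tie 5/6 -> index order

    def test_all_genes_when_n_large(self):
        means = np.linspace(0.2, 8.0, 10)
        nm = _on_curve_matrix(means, a=2.0, b=1.0, p=1.0)
        fit = fit_variance_trend(nm)
        assert len(select_hvg(nm, fit, 5000)) == 10

    def test_permutation_invariance(self, default_sim, rng):
        from sccluster import normalize as _norm

        nm = _norm(default_sim.counts)
        fit = fit_variance_trend(nm)
        sel = select_hvg(nm, fit, 50)
        perm = rng.permutation(nm.n_genes)
        nm2 = NormalizedMatrix(nm.values[:, perm], nm.size_factors, nm.L,
                               nm.cell_ids, [nm.gene_ids[j] for j in perm])
        fit2 = fit_variance_trend(nm2)
        sel2 = select_hvg(nm2, fit2, 50)
        names = {nm.gene_ids[j] for j in sel}
        names2 = {nm2.gene_ids[j] for j in sel2}
        assert names == names2


class TestStandardScale:
    def test_known_row(self):
        out = standard_scale(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.2247, 0.0, 1.2247]], atol=1e-4)

    def test_idempotent_on_scaled_row(self):
        row = np.array([[-1.2247448, 0.0, 1.2247448]])
        np.testing.assert_allclose(standard_scale(row), row, atol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    def test_rows_mean0_sd1(self, seed):
        x = np.random.default_rng(seed).normal(size=(5, 8))
        out = standard_scale(x)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-9)

    def test_constant_row_raises(self):
        with pytest.raises(ConstantRowError):
            standard_scale(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))

    def test_gene_axis_option(self):
        x = np.random.default_rng(3).normal(size=(6, 4))
        out = standard_scale(x, axis="genes")
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=0), 1.0, atol=1e-9)
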