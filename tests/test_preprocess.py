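import numpy as np
import pytest

from conftest import make_counts, make_norm
from ikap.preprocess import (
    compute_pca,
    filter_cells,
    normalize,
    regress_and_scale,
    select_variable_genes,
)


def _qc_matrix(n_genes=260, cells=()):
    """Matrix whose columns are dicts {gene_row: count}; first row is MT-."""
    mat = np.zeros((n_genes, len(cells)), dtype=int)
    for j, spec in enumerate(cells):
        for i, v in spec.items():
            mat[i, j] = v
    return make_counts(mat, gene_ids=["MT-1"] + [f"g{i}" for i in range(n_genes - 1)])


class TestFilterCells:
    def test_gene_count_boundary_is_strict_below_200(self):
        cells = [
            {i: 1 for i in range(1, 200)},  # 199 genes -> removed
            {i: 1 for i in range(1, 201)},  # 200 genes -> kept
        ]
        out = filter_cells(_qc_matrix(cells=cells))
        assert list(out.cell_ids) == ["cell1"]

    def test_mito_fraction_exactly_5_percent_kept(self):
        # 200 expressed non-mito genes, 190 total... build: 199 genes at 1 + one
        # gene at 286 -> non-mito total 485; mito 485*0.05/0.95 is not integral.
        # Use non-mito total 380 (199 genes of 1, one of 182) and mito 20:
        # 20/400 = 5% exactly; 200 genes expressed.
        spec = {i: 1 for i in range(1, 200)}
        spec[1] = 182
        spec[0] = 20
        over = dict(spec)
        over[0] = 21  # 21/401 > 5% -> removed
        out = filter_cells(_qc_matrix(cells=[spec, over]))
        assert list(out.cell_ids) == ["cell0"]

    def test_no_mito_genes_only_gene_filter_applies(self):
        mat = np.ones((250, 2), dtype=int)
        mat[:40, 1] = 0  # second cell expresses 210 genes; first 250
        rc = make_counts(mat)  # gene ids g0.. -> no MT- match
        out = filter_cells(rc)
        assert out.n_cells == 2

    def test_all_cells_removed_errors_with_counts(self):
        cells = [{1: 5}, {2: 3}]
        with pytest.raises(ValueError, match="below 200 genes"):
            filter_cells(_qc_matrix(cells=cells))

    def test_idempotent(self):
        cells = [
            {i: 1 for i in range(1, 220)},
            {i: 1 for i in range(1, 150)},
        ]
        once = filter_cells(_qc_matrix(cells=cells))
        twice = filter_cells(once)
        assert list(once.cell_ids) == list(twice.cell_ids)
        assert (once.matrix != twice.matrix).nnz == 0


class TestNormalize:
    def test_closed_form(self):
        mat = np.zeros((3, 1), dtype=int)
        mat[0, 0] = 10
        mat[1, 0] = 9990
        norm = normalize(make_counts(mat))
        # count 10 in a cell of total 10,000 -> ln(1 + 10)
        assert norm.matrix[0, 0] == pytest.approx(np.log(11), abs=1e-12)
        assert norm.matrix[2, 0] == 0.0

    def test_doubling_counts_leaves_cell_unchanged(self):
        mat = np.array([[3, 6], [7, 14], [0, 0]])
        norm = normalize(make_counts(mat))
        a, b = norm.matrix[:, 0].toarray(), norm.matrix[:, 1].toarray()
        assert np.allclose(a, b)

    def test_zero_total_cell_errors(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize(make_counts(np.array([[1, 0], [2, 0]])))


class TestRegressAndScale:
    def test_zscore_with_sample_sd(self):
        norm = make_norm([[1.0, 2.0, 3.0]])
        out = regress_and_scale(norm)
        assert np.allclose(out.matrix, [[-1.0, 0.0, 1.0]])

    def test_constant_gene_scales_to_zero(self):
        out = regress_and_scale(make_norm([[2.0, 2.0, 2.0]]))
        assert np.all(out.matrix == 0)

    def test_covariate_equal_to_gene_gives_zero(self):
        vals = np.array([0.5, 1.5, 2.5, 4.0])
        out = regress_and_scale(make_norm([vals]), covariates=vals[:, None])
        assert np.allclose(out.matrix, 0.0, atol=1e-10)

    def test_residual_moments(self, rng):
        Y = rng.gamma(2.0, 1.0, size=(20, 50))
        cov = rng.standard_normal((50, 2))
        out = regress_and_scale(make_norm(Y), covariates=cov, clip=10)
        assert np.allclose(out.matrix.mean(axis=1), 0.0, atol=1e-8)
        assert np.allclose(out.matrix.std(axis=1, ddof=1), 1.0, atol=1e-6)

    def test_rank_deficient_covariates_warn_and_drop(self, rng):
        Y = rng.standard_normal((5, 30))
        c = rng.standard_normal(30)
        cov = np.column_stack([c, 2 * c])
        with pytest.warns(UserWarning, match="redundant covariate"):
            out = regress_and_scale(make_norm(Y), covariates=cov)
        assert out.matrix.shape == (5, 30)

    def test_clipping(self, rng):
        vals = np.ones(100)
        vals[0] = 1e6  # huge outlier
        out = regress_and_scale(make_norm([vals]), clip=10)
        assert out.matrix.max() <= 10.0 and out.matrix.min() >= -10.0


class TestSelectVariableGenes:
    def test_high_variance_gene_at_equal_mean_selected(self, rng):
        """A gene with 10x the variance of background genes at the same mean
        must be picked up by the within-bin dispersion z-score."""
        n = 400
        means = np.linspace(1.0, 9.0, 100)  # background spans the mean range
        bg = rng.gamma(50.0, means[:, None] / 50.0, size=(100, n))  # var = m^2/50
        hot = rng.gamma(5.0, 5.0 / 5.0, size=(1, n))  # mean 5, var = m^2/5
        mat = np.log1p(np.vstack([bg, hot]))
        norm = make_norm(mat)
        genes = select_variable_genes(norm, min_dispersion_z=1.0)
        assert "gene100" in set(genes)

    def test_constant_genes_never_selected_and_output_unique_subset(self, rng):
        mat = np.vstack([
            np.full((5, 100), 2.0),
            rng.gamma(1.0, 1.0, size=(50, 100)),
        ])
        norm = make_norm(mat)
        genes = select_variable_genes(norm, min_dispersion_z=0.5)
        assert set(genes) <= set(norm.gene_ids)
        assert len(set(genes)) == len(genes)
        assert not set(genes) & {f"gene{i}" for i in range(5)}

    def test_too_few_survivors_error(self):
        norm = make_norm(np.full((30, 20), 1.0))
        with pytest.raises(ValueError, match="variable genes"):
            select_variable_genes(norm)


class TestComputePCA:
    def _scaled(self, X):
        from ikap.preprocess import ScaledMatrix

        X = np.asarray(X, dtype=float)
        return ScaledMatrix(
            matrix=X,
            gene_ids=np.array([f"g{i}" for i in range(X.shape[0])], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(X.shape[1])], dtype=object),
            clip=10.0,
        )

    def test_sdev_nonincreasing_and_scores_orthogonal(self, rng):
        X = rng.standard_normal((20, 60))
        pc = compute_pca(self._scaled(X), 10)
        assert np.all(np.diff(pc.sdev) <= 1e-12)
        G = pc.scores.T @ pc.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-6 * np.abs(np.diag(G)).max()

    def test_two_separated_clouds_split_on_pc1(self, rng):
        from sklearn.metrics import silhouette_score

        X = rng.standard_normal((10, 80))
        X[:, 40:] += 10.0  # offset 10x the noise sd
        pc = compute_pca(self._scaled(X), 3)
        labels = np.repeat([0, 1], 40)
        assert silhouette_score(pc.scores[:, :1], labels) > 0.8

    def test_identical_cells_zero_embedding_with_warning(self):
        X = np.tile(np.arange(8, dtype=float)[:, None], (1, 30))
        with pytest.warns(UserWarning, match="identical"):
            pc = compute_pca(self._scaled(X), 3)
        assert np.all(pc.scores == 0) and np.all(pc.sdev == 0)

    def test_too_many_components_errors(self, rng):
        X = rng.standard_normal((5, 10))
        with pytest.raises(ValueError, match="n_components"):
            compute_pca(self._scaled(X), 6)

    def test_matches_eigendecomposition_oracle(self, rng):
        """z-score + PCA equals the eigendecomposition of the correlation
        structure: leading subspaces agree up to sign."""
        Y = rng.standard_normal((30, 40)) + rng.standard_normal((1, 40))
        norm = make_norm(Y)
        scaled = regress_and_scale(norm)
        pc = compute_pca(scaled, 5)

        Z = scaled.matrix.T  # cells x genes, z-scored
        Zc = Z - Z.mean(axis=0)
        evals, evecs = np.linalg.eigh(Zc.T @ Zc)
        order = np.argsort(evals)[::-1][:5]
        oracle_scores = Zc @ evecs[:, order]
        for j in range(5):
            c = np.corrcoef(pc.scores[:, j], oracle_scores[:, j])[0, 1]
            assert abs(c) > 1 - 1e-8
        assert np.allclose(
            pc.sdev**2 * (Z.shape[0] - 1), np.sort(evals)[::-1][:5], rtol=1e-8
        )
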