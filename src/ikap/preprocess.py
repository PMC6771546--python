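"""Cell QC, normalization, scaling, variable genes and PCA.

The preprocessing convention is the standard log-normalization pipeline of the
single-cell ecosystem: per-cell totals are rescaled to ``scale_factor`` UMI
and log1p-transformed; covariates (by default the per-cell total UMI and the
mitochondrial fraction) are regressed out gene-wise by OLS; residuals are
standardized with the sample (n-1) standard deviation and clipped.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import RawCounts

log = logging.getLogger(__name__)

__all__ = [
    "NormalizedMatrix",
    "ScaledMatrix",
    "PCEmbedding",
    "filter_cells",
    "normalize",
    "regress_and_scale",
    "select_variable_genes",
    "compute_pca",
]


@dataclasses.dataclass
class NormalizedMatrix:
    """Genes x cells log-normalized expression plus per-cell QC covariates."""

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    total_umi: np.ndarray
    mito_frac: np.ndarray

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def dense_rows(self, genes) -> np.ndarray:
        """Dense (len(genes) x cells) block of normalized expression."""
        order = pd.Index(self.gene_ids)
        idx = order.get_indexer(genes)
        if np.any(idx < 0):
            missing = [g for g, i in zip(genes, idx) if i < 0]
            raise KeyError(f"genes not found: {missing[:5]}")
        return np.asarray(self.matrix[idx].todense())


@dataclasses.dataclass
class ScaledMatrix:
    """Variable-genes x cells covariate-regressed, standardized, clipped."""

    matrix: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    clip: float


@dataclasses.dataclass
class PCEmbedding:
    """Cells x P principal-component scores and their explained sdev."""

    scores: np.ndarray
    sdev: np.ndarray
    genes_used: np.ndarray
    cell_ids: np.ndarray

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def filter_cells(
    raw: RawCounts, min_genes: int = 200, max_mito_frac: float = 0.05
) -> RawCounts:
    """Keep cells with >= ``min_genes`` expressed genes and mito UMI fraction
    <= ``max_mito_frac``.

    Both bounds are inclusive on the kept side: the QC rule removes cells with
    *fewer than* ``min_genes`` genes or *more than* 100*``max_mito_frac``
    percent mitochondrial UMI.
    """
    counts = raw.matrix
    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    totals = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    mito = raw.mito_mask
    if mito.any():
        mito_umi = np.asarray(counts[mito].sum(axis=0)).ravel().astype(float)
    else:
        mito_umi = np.zeros(raw.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_umi / np.maximum(totals, 1e-300), 0.0)

    gene_ok = genes_per_cell >= min_genes
    mito_ok = mito_frac <= max_mito_frac
    keep = gene_ok & mito_ok
    if not keep.any():
        raise ValueError(
            "all cells removed by QC: "
            f"{int((~gene_ok).sum())} below {min_genes} genes, "
            f"{int((~mito_ok).sum())} above mito fraction {max_mito_frac}"
        )
    log.info(
        "filter_cells kept %d/%d cells (%d failed gene filter, %d failed mito filter)",
        int(keep.sum()), raw.n_cells, int((~gene_ok).sum()), int((~mito_ok).sum()),
    )
    out = raw.subset_cells(keep)
    out.provenance = dict(raw.provenance)
    out.provenance["kept_cell_mask"] = keep
    return out


def normalize(raw: RawCounts, scale_factor: float = 1e4) -> NormalizedMatrix:
    """Log-normalize: entry = ln(1 + count / cell_total * scale_factor)."""
    counts = sp.csr_matrix(raw.matrix, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cells with zero total UMI present; filter them first")
    mito = raw.mito_mask
    mito_umi = (
        np.asarray(counts[mito].sum(axis=0)).ravel() if mito.any() else np.zeros(raw.n_cells)
    )
    norm = counts @ sp.diags(scale_factor / totals)
    norm = sp.csr_matrix(norm)
    norm.data = np.log1p(norm.data)
    return NormalizedMatrix(
        matrix=norm,
        gene_ids=raw.gene_ids,
        cell_ids=raw.cell_ids,
        total_umi=totals,
        mito_frac=mito_umi / totals,
    )


def _gene_expm1_moments(norm: NormalizedMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and variance of expm1(normalized expression)."""
    mat = norm.matrix.copy()
    mat.data = np.expm1(mat.data)
    n = norm.n_cells
    s1 = np.asarray(mat.sum(axis=1)).ravel()
    mat.data = mat.data**2
    s2 = np.asarray(mat.sum(axis=1)).ravel()
    mean = s1 / n
    var = s2 / n - mean**2
    var = np.maximum(var, 0.0) * (n / max(n - 1, 1))
    return mean, var


def select_variable_genes(
    norm: NormalizedMatrix,
    n_bins: int = 20,
    min_mean: float = 0.1,
    max_mean: float = 8.0,
    min_dispersion_z: float = 1.0,
) -> np.ndarray:
    """Mean/dispersion variable-gene selection.

    Per gene, the log mean of expm1(expression) (log1p of the mean) and the
    log dispersion log(variance/mean) are computed; genes are binned by log
    mean into ``n_bins`` equal-width bins and the dispersion is z-scored
    within each bin.  Kept genes satisfy ``min_mean < log mean < max_mean``
    and dispersion z >= ``min_dispersion_z`` (the log-scale mean/dispersion
    convention and default cutoffs of the classic mean.var.plot method).
    """
    raw_mean, var = _gene_expm1_moments(norm)
    mean = np.log1p(raw_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        dispersion = np.where(
            (raw_mean > 0) & (var > 0),
            np.log(np.maximum(var, 1e-300) / np.maximum(raw_mean, 1e-300)),
            0.0,
        )

    lo, hi = float(mean.min()), float(mean.max())
    if hi <= lo:
        bins = np.zeros(len(mean), dtype=int)
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        bins = np.clip(np.digitize(mean, edges[1:-1]), 0, n_bins - 1)

    z = np.zeros(len(mean))
    for b in np.unique(bins):
        members = bins == b
        d = dispersion[members]
        sd = d.std(ddof=1) if members.sum() > 1 else 0.0
        if sd > 0:
            z[members] = (d - d.mean()) / sd

    keep = (mean > min_mean) & (mean < max_mean) & (z >= min_dispersion_z)
    genes = norm.gene_ids[keep]
    if len(genes) < 2:
        raise ValueError(
            f"only {len(genes)} variable genes selected; relax the cutoffs"
        )
    return genes


def _drop_rank_deficient(X: np.ndarray) -> np.ndarray:
    """Greedily drop columns (never the intercept) until X has full rank."""
    keep = [0]
    rank = 1
    for j in range(1, X.shape[1]):
        cand = X[:, keep + [j]]
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            keep.append(j)
            rank = r
        else:
            warnings.warn(f"dropping redundant covariate column {j}", stacklevel=3)
    return X[:, keep]


def regress_and_scale(
    norm: NormalizedMatrix,
    covariates: pd.DataFrame | np.ndarray | None = None,
    clip: float = 10.0,
    genes: np.ndarray | None = None,
) -> ScaledMatrix:
    """Regress covariates out of each gene's expression and standardize.

    Ordinary least squares of expression on the covariates (plus intercept),
    gene by gene; residuals are divided by their sample (n-1) standard
    deviation and clipped to ``[-clip, clip]``.  With no covariates this is a
    per-gene z-score.  Constant genes scale to all zeros.
    """
    gene_ids = np.asarray(genes if genes is not None else norm.gene_ids, dtype=object)
    Y = norm.dense_rows(gene_ids)  # genes x cells
    n = Y.shape[1]

    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows do not align with cells")
    X = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X = _drop_rank_deficient(X)

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y - (X @ beta).T
    sd = resid.std(axis=1, ddof=1) if n > 1 else np.zeros(Y.shape[0])
    nonconst = sd > 1e-12
    scaled = np.zeros_like(resid)
    scaled[nonconst] = resid[nonconst] / sd[nonconst, None]
    np.clip(scaled, -clip, clip, out=scaled)
    return ScaledMatrix(scaled, gene_ids, norm.cell_ids, clip)


def compute_pca(scaled: ScaledMatrix, n_components: int) -> PCEmbedding:
    """PCA of the gene-standardized matrix.

    Scores are cell coordinates on the top components; ``sdev`` are the
    singular values divided by sqrt(n_cells - 1), nonincreasing.  The sign of
    each component is fixed so its largest-magnitude gene loading is positive.
    """
    X = scaled.matrix.T  # cells x genes
    n, g = X.shape
    if n_components > min(n, g) - 1:
        raise ValueError(
            f"n_components={n_components} exceeds min(genes, cells) - 1 = {min(n, g) - 1}"
        )
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    if S[0] < 1e-12:
        warnings.warn("all cells identical after scaling; returning zero embedding")
        return PCEmbedding(
            np.zeros((n, n_components)), np.zeros(n_components),
            scaled.gene_ids, scaled.cell_ids,
        )
    U, S, Vt = U[:, :n_components], S[:n_components], Vt[:n_components]
    # deterministic sign: largest-magnitude loading positive
    flip = Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)] < 0
    U[:, flip] *= -1
    scores = U * S
    sdev = S / np.sqrt(max(n - 1, 1))
    return PCEmbedding(scores, sdev, scaled.gene_ids, scaled.cell_ids)
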