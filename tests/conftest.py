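import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from ikap.cluster import Grouping
from ikap.io import RawCounts
from ikap.preprocess import NormalizedMatrix, PCEmbedding


def make_embedding(centers, n_per, noise=0.1, extra_dims=0, seed=0):
    """Gaussian blobs around the given centers, as a PCEmbedding.

    sdev is a plausible decreasing sequence; scores are the blob coordinates
    (optionally padded with low-variance noise dimensions).
    """
    rng = np.random.default_rng(seed)
    centers = np.asarray(centers, dtype=float)
    pts = np.vstack(
        [c + noise * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    if extra_dims:
        pts = np.hstack([pts, 0.05 * rng.standard_normal((len(pts), extra_dims))])
    labels = np.repeat(np.arange(len(centers)), n_per)
    d = pts.shape[1]
    sdev = np.linspace(2.0, 1.0, d)
    return (
        PCEmbedding(
            scores=pts,
            sdev=sdev,
            genes_used=np.array([f"g{i}" for i in range(d)], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(len(pts))], dtype=object),
        ),
        labels,
    )


def make_norm(matrix, gene_ids=None, cell_ids=None):
    """Wrap a dense genes x cells array of normalized expression."""
    matrix = np.asarray(matrix, dtype=float)
    g, n = matrix.shape
    gene_ids = gene_ids or [f"gene{i}" for i in range(g)]
    cell_ids = cell_ids or [f"cell{i}" for i in range(n)]
    return NormalizedMatrix(
        matrix=sp.csr_matrix(matrix),
        gene_ids=np.asarray(gene_ids, dtype=object),
        cell_ids=np.asarray(cell_ids, dtype=object),
        total_umi=np.full(n, 1000.0),
        mito_frac=np.zeros(n),
    )


def make_counts(matrix, gene_ids=None, cell_ids=None, mito_pattern="MT-"):
    matrix = np.asarray(matrix)
    g, n = matrix.shape
    gene_ids = gene_ids or [f"gene{i}" for i in range(g)]
    cell_ids = cell_ids or [f"cell{i}" for i in range(n)]
    return RawCounts(sp.csr_matrix(matrix), gene_ids, cell_ids, mito_pattern)


def grouping_from_labels(labels, nPC=2):
    labels = np.asarray(labels, dtype=int)
    return Grouping(labels, k=int(labels.max()) + 1, nPC=nPC)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
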