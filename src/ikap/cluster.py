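"""Graph clustering and automatic sweep-bound determination.

Cells are clustered by modularity community detection on a shared-nearest-
neighbour (SNN) graph built in the top-nPC principal-component space: 20
nearest neighbours (including the cell itself), Jaccard-weighted shared-
neighbour edges, weights below 1/15 pruned.  The resolution parameter of the
modularity objective plays the role of the granularity knob r.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import igraph
import leidenalg
import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .config import RunConfig
from .preprocess import PCEmbedding

__all__ = [
    "Grouping",
    "SweepBounds",
    "cluster",
    "choose_npc_min",
    "sweep_bounds",
    "initial_partition",
]


@dataclasses.dataclass
class Grouping:
    """A partition of cells into k groups labelled 0..k-1."""

    labels: np.ndarray
    k: int
    nPC: int
    resolution: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(self.k)):
            raise ValueError(f"labels must cover 0..{self.k - 1}; got {present}")

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclasses.dataclass
class SweepBounds:
    """The (nPC, k) search-space bounds of a sweep."""

    nPC_min: int
    nPC_max: int
    k_max: int
    k_ini: int

    def __post_init__(self) -> None:
        if not (1 <= self.nPC_min <= self.nPC_max):
            raise ValueError("need 1 <= nPC_min <= nPC_max")
        if not (2 <= self.k_max <= self.k_ini):
            raise ValueError("need 2 <= k_max <= k_ini")


def snn_graph(
    coords: np.ndarray, n_neighbors: int = 20, prune: float = 1.0 / 15.0
) -> sp.csr_matrix:
    """Jaccard-weighted shared-nearest-neighbour graph (symmetric CSR)."""
    n = coords.shape[0]
    k = n_neighbors
    if n <= k:
        warnings.warn(f"only {n} cells; reducing neighbour count from {k} to {n}")
        k = n
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(coords)
    # self always counts as a neighbour; duplicate entries collapse to 1
    rows = np.concatenate([np.repeat(np.arange(n), k), np.arange(n)])
    cols = np.concatenate([idx.ravel(), np.arange(n)])
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    A.data = np.minimum(A.data, 1.0)
    sizes = np.asarray(A.sum(axis=1)).ravel()
    shared = (A @ A.T).tocoo()
    union = sizes[shared.row] + sizes[shared.col] - shared.data
    jacc = shared.data / union
    keep = (jacc >= prune) & (shared.row != shared.col)
    G = sp.csr_matrix((jacc[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return G


def cluster(pc: PCEmbedding, nPC: int, resolution: float, seed: int) -> Grouping:
    """Cluster cells in the top-nPC space at the given resolution.

    Deterministic for a fixed seed; groups are relabelled 0..k-1 by
    decreasing size (ties by first-found community id).
    """
    if nPC > pc.n_components:
        raise ValueError(f"nPC={nPC} exceeds available components {pc.n_components}")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    coords = pc.scores[:, :nPC]
    if np.allclose(coords, coords[0]):
        # degenerate input: no geometry to cluster on
        return Grouping(
            np.zeros(coords.shape[0], dtype=int), k=1, nPC=nPC, resolution=resolution
        )
    G = snn_graph(coords)
    coo = sp.triu(G, k=1).tocoo()
    g = igraph.Graph(
        n=coords.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed) % (2**31 - 1),
        n_iterations=2,
    )
    membership = np.asarray(part.membership)
    sizes = np.bincount(membership)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(len(order))
    labels = remap[membership]
    return Grouping(labels, k=len(sizes), nPC=nPC, resolution=resolution)


def choose_npc_min(sdev: np.ndarray) -> int:
    """Elbow rule: smallest 1-based index i such that every later relative
    drop in explained standard deviation is below 10%.

    Falls back to len(sdev) - 1 (with a warning) when even the final drop is
    >= 10%.
    """
    s = np.asarray(sdev, dtype=float)
    if len(s) < 2:
        raise ValueError("need at least 2 components")
    if np.any(s <= 0):
        raise ValueError("sdev must be positive")
    if np.any(np.diff(s) > 1e-12):
        raise ValueError("sdev must be nonincreasing")
    drops = (s[:-1] - s[1:]) / s[:-1]  # drops[j] is the drop after component j+1
    big = np.flatnonzero(drops >= 0.10)
    if len(big) == 0:
        return 1
    last_bad = int(big[-1]) + 1  # 1-based index of the last component with a big drop
    if last_bad == len(s) - 1:
        warnings.warn(
            "no component satisfies the elbow rule; falling back to len(sdev) - 1"
        )
        return len(s) - 1
    return last_bad + 1


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def sweep_bounds(pc: PCEmbedding, cfg: RunConfig) -> SweepBounds:
    """Determine nPC_min (elbow rule), nPC_max (= nPC_min + span, capped at
    the available components) and k_max (round-half-up average of the group
    counts at r_ini for the two nPC extremes, floored at 2)."""
    P = pc.n_components
    npc_min = choose_npc_min(pc.sdev)
    npc_max = npc_min + cfg.npc_span
    if npc_max > P:
        warnings.warn(f"nPC_max capped at available components P={P}")
        npc_max = P
    k_lo = cluster(pc, npc_min, cfg.r_ini, seed=_stage_seed(cfg.seed, "bounds", npc_min)).k
    k_hi = cluster(pc, npc_max, cfg.r_ini, seed=_stage_seed(cfg.seed, "bounds", npc_max)).k
    k_max = max(2, _round_half_up((k_lo + k_hi) / 2))
    return SweepBounds(npc_min, npc_max, k_max, k_ini=max(k_lo, k_hi, k_max))


def initial_partition(
    pc: PCEmbedding, nPC: int, k_max: int, cfg: RunConfig, seed: int | None = None
) -> Grouping:
    """First partition along r = r_start, r_start + r_step, ... with
    k >= k_max groups; errors past r_cap."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    seed = cfg.seed if seed is None else seed
    r = cfg.r_start
    while r <= cfg.r_cap + 1e-9:
        grouping = cluster(pc, nPC, r, seed=seed)
        if grouping.k >= k_max:
            return grouping
        r = round(r + cfg.r_step, 10)
    raise RuntimeError(
        f"resolution cap {cfg.r_cap} reached without finding {k_max} groups at "
        f"nPC={nPC}; consider a smaller k_max"
    )


def _stage_seed(seed: int, tag: str, *extra: int) -> int:
    """Deterministic child seed (< 2^31) for a named pipeline stage."""
    import zlib

    h = zlib.crc32(tag.encode())
    for e in extra:
        h = zlib.crc32(str(e).encode(), h)
    return int((seed * 1000003 + h) % (2**31 - 1))
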