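"""Nested merge series, within-group dispersion and the gap statistic.

For each nPC the initial fine partition is coarsened by iteratively merging
the two groups with the nearest centroids in the top-nPC space, producing
nested partitions for k = 1..k_max.  Each partition is scored with a gap
statistic: the expected log within-group dispersion of uniform draws from the
axis-aligned bounding box of the data minus the observed log dispersion.
Gap increases Gap(k) - Gap(k-1) are tabulated over (nPC, k) into the matrix
from which candidates are selected.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import pdist

from .cluster import Grouping, SweepBounds, _stage_seed, initial_partition
from .config import RunConfig
from .preprocess import PCEmbedding

__all__ = [
    "GroupingSeries",
    "GapMatrix",
    "merge_series",
    "within_dispersion",
    "gap_statistic",
    "gap_increase_matrix",
]


@dataclasses.dataclass
class GroupingSeries:
    """Nested partitions k = 1..k_max for one nPC, plus the merge trace."""

    nPC: int
    partitions: dict[int, Grouping]  # k -> Grouping with exactly k groups
    merge_trace: list[tuple[int, int, float]]  # (group_a, group_b, centroid distance)

    def __getitem__(self, k: int) -> Grouping:
        return self.partitions[k]


@dataclasses.dataclass
class GapMatrix:
    """Gap statistics and gap increases over the (nPC, k) grid.

    Rows follow ``npcs`` (nPC_min..nPC_max); columns are k = 1..k_max.
    ``increase[:, 0]`` (k = 1) is NaN by construction.
    """

    npcs: np.ndarray
    k_max: int
    gap: np.ndarray
    increase: np.ndarray
    B: int
    seed: int


def _relabel_compact(labels: np.ndarray) -> tuple[np.ndarray, int]:
    ids = np.unique(labels)
    remap = {g: i for i, g in enumerate(ids)}
    return np.array([remap[g] for g in labels]), len(ids)


def merge_series(
    pc: PCEmbedding, nPC: int, initial: Grouping, k_max: int
) -> GroupingSeries:
    """Merge the nearest-centroid pair iteratively down to k = 1, retaining
    the partitions with k <= k_max.

    Centroids are unweighted means of member-cell coordinates, recomputed
    after each merge.  Distance ties are broken by the smallest
    (group_a, group_b) id pair under the current labelling.
    """
    if initial.k < k_max:
        raise ValueError(f"initial partition has {initial.k} < k_max={k_max} groups")
    coords = pc.scores[:, :nPC]
    labels = initial.labels.copy()
    ids = sorted(np.unique(labels).tolist())
    centroids = {g: coords[labels == g].mean(axis=0) for g in ids}

    partitions: dict[int, Grouping] = {}
    trace: list[tuple[int, int, float]] = []

    def snapshot(k: int) -> None:
        compact, kk = _relabel_compact(labels)
        assert kk == k
        partitions[k] = Grouping(compact, k=k, nPC=nPC, resolution=None)

    k = len(ids)
    if k <= k_max:
        snapshot(k)
    while k > 1:
        C = np.vstack([centroids[g] for g in ids])
        d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=-1)
        iu = np.triu_indices(k, 1)
        flat = d[iu]
        best = flat.min()
        # ties -> lexicographically smallest (a, b) id pair; ids are sorted so
        # the first index pair attaining the minimum is the smallest pair
        pos = int(np.flatnonzero(flat <= best + 1e-15)[0])
        a, b = ids[iu[0][pos]], ids[iu[1][pos]]
        labels[labels == b] = a
        trace.append((a, b, float(best)))
        ids.remove(b)
        centroids.pop(b)
        centroids[a] = coords[labels == a].mean(axis=0)
        k -= 1
        if k <= k_max:
            snapshot(k)
    return GroupingSeries(nPC=nPC, partitions=partitions, merge_trace=trace)


def within_dispersion(
    pc: PCEmbedding, nPC: int, grouping: Grouping, normalization: str = "normalized"
) -> float:
    """Within-group dispersion W of a partition in the top-nPC space.

    With ``normalization="normalized"``, W = sum_r D_r / (2 n_r) where D_r is
    the sum of Euclidean distances over all *ordered* within-group pairs and
    n_r the group size; ``"raw_sum"`` returns sum_r D_r.
    """
    coords = pc.scores[:, :nPC]
    return _dispersion_from_coords(coords, grouping.labels, grouping.k, normalization)


def _dispersion_from_coords(
    coords: np.ndarray, labels: np.ndarray, k: int, normalization: str
) -> float:
    W = 0.0
    for g in range(k):
        pts = coords[labels == g]
        if len(pts) < 2:
            continue
        D = 2.0 * pdist(pts).sum()  # ordered pairs count each pair twice
        W += D / (2.0 * len(pts)) if normalization == "normalized" else D
    return W


# ---------------------------------------------------------------------------
# reference partitions: k-means batched over reference draws


def _batched_kmeans(
    X: np.ndarray, k: int, restarts: int, rng: np.random.Generator, max_iter: int = 15
) -> np.ndarray:
    """Lloyd k-means run independently on each of B stacked datasets.

    X has shape (B, n, d); returns labels of shape (B, n).  Random-point
    initialisation per restart; empty clusters are reseeded to the point
    currently farthest from its centre; iteration stops when assignments
    stabilise or after ``max_iter`` rounds (late Lloyd iterations move the
    log-dispersion of uniform draws by well under one draw-to-draw standard
    deviation, so a modest cap is safe).  The best restart per dataset
    (lowest inertia) wins.
    """
    B, n, d = X.shape
    if k >= n:
        raise ValueError("k must be < n")
    R = restarts
    Xf = np.ascontiguousarray(X, dtype=np.float32)
    # restarts join the batch axis: one Lloyd iteration updates all B*R runs
    Xr = np.broadcast_to(Xf[None], (R, B, n, d)).reshape(R * B, n, d)
    init = np.argsort(rng.random((R * B, n)), axis=1)[:, :k]
    C = np.take_along_axis(Xr, init[:, :, None], axis=1)  # (R*B, k, d)
    labels = np.zeros((R * B, n), dtype=int)
    eye = np.arange(k)
    for _it in range(max_iter):
        # relative squared distance: ||c||^2 - 2 x.c (||x||^2 is constant per
        # point and does not affect the argmin)
        d2 = np.einsum("bkd,bkd->bk", C, C)[:, None, :] - 2.0 * np.matmul(
            Xr, C.transpose(0, 2, 1)
        )
        new_labels = d2.argmin(axis=2)
        if _it > 0 and np.array_equal(new_labels, labels):
            break
        labels = new_labels
        onehot = (labels[:, :, None] == eye).astype(np.float32)  # (R*B, n, k)
        counts = onehot.sum(axis=1)  # (R*B, k)
        sums = np.matmul(onehot.transpose(0, 2, 1), Xr)  # (R*B, k, d)
        empty_b, empty_k = np.nonzero(counts == 0)
        if len(empty_b):
            mind2 = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0]
            for b, j in zip(empty_b, empty_k):
                i = int(mind2[b].argmax())
                sums[b, j] = Xr[b, i]
                counts[b, j] = 1.0
        C = sums / counts[:, :, None]
    rel = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0]
    inertia = rel.sum(axis=1, dtype=np.float64).reshape(R, B)  # shifted by
    # sum ||x||^2, identical across restarts of the same draw
    best = inertia.argmin(axis=0)  # (B,)
    return labels.reshape(R, B, n)[best, np.arange(B)]


def _merge_reference_labels(
    X: np.ndarray, k: int, restarts: int, rng: np.random.Generator
) -> np.ndarray:
    """Fine k-means then nearest-centroid merging down to k, per draw."""
    B, n, _ = X.shape
    k_fine = min(max(4 * k, k + 1), n - 1)
    fine = _batched_kmeans(X, k_fine, restarts=max(1, restarts // 2), rng=rng)
    out = np.empty((B, n), dtype=int)
    for b in range(B):
        labels = fine[b].copy()
        ids = sorted(np.unique(labels).tolist())
        centroids = {g: X[b][labels == g].mean(axis=0) for g in ids}
        while len(ids) > k:
            C = np.vstack([centroids[g] for g in ids])
            d = np.linalg.norm(C[:, None, :] - C[None, :, :], axis=-1)
            iu = np.triu_indices(len(ids), 1)
            pos = int(d[iu].argmin())
            a, bb = ids[iu[0][pos]], ids[iu[1][pos]]
            labels[labels == bb] = a
            ids.remove(bb)
            centroids.pop(bb)
            centroids[a] = X[b][labels == a].mean(axis=0)
        out[b], _ = _relabel_compact(labels)
    return out


def _reference_draws(
    coords: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    return rng.uniform(lo, hi, size=(B, *coords.shape))


def _reference_log_dispersions(
    draws: np.ndarray,
    k: int,
    rng: np.random.Generator,
    restarts: int,
    normalization: str,
    mode: str = "kmeans",
) -> np.ndarray:
    B, n, _ = draws.shape
    if k == 1:
        labels = np.zeros((B, n), dtype=int)
    elif mode == "merge":
        labels = _merge_reference_labels(draws, k, restarts, rng)
    else:
        labels = _batched_kmeans(draws, k, restarts=restarts, rng=rng)
    out = np.empty(B)
    for b in range(B):
        Wb = _dispersion_from_coords(draws[b], labels[b], k, normalization)
        out[b] = np.log(Wb)
    return out


def gap_statistic(
    pc: PCEmbedding,
    nPC: int,
    grouping: Grouping,
    B: int,
    seed: int,
    restarts: int = 10,
    normalization: str = "normalized",
    reference_partition: str = "kmeans",
) -> float:
    """Gap = mean_b log W_b* - log W_obs.

    Each of the B reference draws samples n cells uniformly in the axis-
    aligned bounding box of the observed top-nPC coordinates and is
    partitioned into ``grouping.k`` groups by seeded k-means.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    coords = pc.scores[:, :nPC]
    W_obs = within_dispersion(pc, nPC, grouping, normalization)
    if W_obs <= 0:
        raise ValueError("observed within-group dispersion is zero (duplicate points?)")
    rng = np.random.default_rng(seed)
    draws = _reference_draws(coords, B, rng)
    logWb = _reference_log_dispersions(
        draws, grouping.k, rng, restarts, normalization, reference_partition
    )
    return float(logWb.mean() - np.log(W_obs))


def gap_increase_matrix(
    pc: PCEmbedding, bounds: SweepBounds, cfg: RunConfig
) -> tuple[GapMatrix, dict[int, GroupingSeries]]:
    """Gap statistics and gap increases for every (nPC, k) in the sweep.

    For each nPC: initial fine partition -> nested merge series ->
    Gap(nPC, k) for k = 1..k_max, sharing one set of B reference draws across
    k.  The increase matrix holds Gap(nPC, k) - Gap(nPC, k-1) for k >= 2
    (NaN at k = 1).
    """
    npcs = np.arange(bounds.nPC_min, bounds.nPC_max + 1)
    k_max = bounds.k_max
    gap = np.full((len(npcs), k_max), np.nan)
    series_map: dict[int, GroupingSeries] = {}
    for i, npc in enumerate(npcs):
        part = initial_partition(
            pc, int(npc), k_max, cfg, seed=_stage_seed(cfg.seed, "initial", int(npc))
        )
        series = merge_series(pc, int(npc), part, k_max)
        series_map[int(npc)] = series
        coords = pc.scores[:, :npc]
        rng = np.random.default_rng(_stage_seed(cfg.seed, "gapref", int(npc)))
        draws = _reference_draws(coords, cfg.gap_B, rng)
        for k in range(1, k_max + 1):
            W_obs = within_dispersion(pc, int(npc), series[k], cfg.gap_normalization)
            if W_obs <= 0:
                raise ValueError(f"zero dispersion at nPC={npc}, k={k}")
            logWb = _reference_log_dispersions(
                draws, k, rng, cfg.kmeans_restarts, cfg.gap_normalization,
                cfg.reference_partition,
            )
            gap[i, k - 1] = logWb.mean() - np.log(W_obs)
    increase = np.full_like(gap, np.nan)
    increase[:, 1:] = gap[:, 1:] - gap[:, :-1]
    matrix = GapMatrix(
        npcs=npcs, k_max=k_max, gap=gap, increase=increase, B=cfg.gap_B, seed=cfg.seed
    )
    return matrix, series_map
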