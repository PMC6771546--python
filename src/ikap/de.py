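"""DE genes, AUROC, decision-tree classification error and the summary table.

DE genes are found one-vs-rest per group with a two-sided Wilcoxon rank-sum
test on log-normalized expression; only upregulated genes (positive average
log fold change) are reported.  Separability of a candidate grouping is
scored by per-group binary CART trees on the union of DE genes: the rpart-
style relative training error (misclassified / minority-class count at the
root) is read off the cost-complexity pruning path at split counts
nsplit = 5..15, weighted by group cell fraction, summed over groups and
averaged over nsplit.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.tree import DecisionTreeClassifier

from .cluster import Grouping
from .preprocess import NormalizedMatrix

log = logging.getLogger(__name__)

__all__ = [
    "ClassifierReport",
    "find_de_genes",
    "compute_auroc",
    "classification_error",
    "aggregate_errors",
    "summarize",
]

DE_COLUMNS = ["gene", "group", "avg_logFC", "p", "p_adj", "pct_in", "pct_out", "auroc"]


@dataclasses.dataclass
class ClassifierReport:
    """Relative training errors per group and their weighted aggregate."""

    nsplits: np.ndarray
    relative_errors: dict[int, np.ndarray]  # group -> error at each nsplit
    group_fractions: dict[int, float]
    set_error_by_nsplit: np.ndarray
    final_error: float


def compute_auroc(values_in: np.ndarray, values_out: np.ndarray) -> float:
    """AUROC for in-group vs out-of-group expression; ties count 0.5.

    Equals the Mann-Whitney U statistic divided by n_in * n_out.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both vectors must be nonempty")
    ranks = scipy.stats.rankdata(np.concatenate([a, b]))
    u = ranks[: len(a)].sum() - len(a) * (len(a) + 1) / 2.0
    return float(u / (len(a) * len(b)))


def find_de_genes(
    norm: NormalizedMatrix,
    grouping: Grouping,
    min_logfc: float = 0.25,
    min_pct: float = 0.1,
    max_padj: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest upregulated marker genes for every group.

    Genes are tested when expressed in at least ``min_pct`` of cells on either
    side and upregulated by at least ``min_logfc`` (natural log of
    (mean expm1 + 1) ratios).  P-values are Bonferroni-adjusted over the
    tested genes of each group; genes with adjusted p <= ``max_padj`` are
    reported together with their AUROC.
    """
    if grouping.k < 2:
        raise ValueError("need at least 2 groups for DE testing")
    X = norm.matrix
    Xe = X.copy()
    Xe.data = np.expm1(Xe.data)
    rows = []
    labels = grouping.labels
    for g in range(grouping.k):
        in_mask = labels == g
        n_in = int(in_mask.sum())
        n_out = len(labels) - n_in
        if n_in < 3:
            log.warning("group %d has %d cells (<3); skipping DE", g, n_in)
            continue
        Xin, Xout = X[:, in_mask], X[:, ~in_mask]
        pct_in = np.asarray((Xin > 0).sum(axis=1)).ravel() / n_in
        pct_out = np.asarray((Xout > 0).sum(axis=1)).ravel() / n_out
        mean_in = np.asarray(Xe[:, in_mask].sum(axis=1)).ravel() / n_in
        mean_out = np.asarray(Xe[:, ~in_mask].sum(axis=1)).ravel() / n_out
        lfc = np.log1p(mean_in) - np.log1p(mean_out)

        tested = ((pct_in >= min_pct) | (pct_out >= min_pct)) & (lfc >= min_logfc)
        idx = np.flatnonzero(tested)
        if len(idx) == 0:
            continue
        A = np.asarray(Xin[idx].todense())
        Bv = np.asarray(Xout[idx].todense())
        with np.errstate(invalid="ignore", divide="ignore"):
            res = scipy.stats.mannwhitneyu(
                A, Bv, axis=1, alternative="two-sided", method="asymptotic"
            )
        p = np.nan_to_num(res.pvalue, nan=1.0)
        auroc = res.statistic / (n_in * n_out)
        p_adj = np.minimum(p * len(idx), 1.0)
        keep = p_adj <= max_padj
        for i, r in enumerate(idx):
            if keep[i]:
                rows.append(
                    (norm.gene_ids[r], g, lfc[r], p[i], p_adj[i],
                     pct_in[r], pct_out[r], auroc[i])
                )
    return pd.DataFrame(rows, columns=DE_COLUMNS)


def _tree_error_path(
    X: np.ndarray, y: np.ndarray, random_state: int, max_leaf_nodes: int = 32
) -> list[tuple[int, int]]:
    """(nsplit, training misclassifications) along the cost-complexity
    pruning path of a binary CART tree, sorted by nsplit."""
    full = DecisionTreeClassifier(
        criterion="gini", random_state=random_state, max_leaf_nodes=max_leaf_nodes
    ).fit(X, y)
    alphas = np.unique(np.clip(full.cost_complexity_pruning_path(X, y).ccp_alphas, 0, None))
    best: dict[int, int] = {}
    for a in alphas:
        t = DecisionTreeClassifier(
            criterion="gini", random_state=random_state,
            max_leaf_nodes=max_leaf_nodes, ccp_alpha=float(a),
        ).fit(X, y)
        nsplit = int(t.tree_.node_count - t.tree_.n_leaves)
        err = int((t.predict(X) != y).sum())
        if nsplit not in best or err < best[nsplit]:
            best[nsplit] = err
    return sorted(best.items())


def aggregate_errors(
    relative_errors: dict[int, np.ndarray],
    group_fractions: dict[int, float],
    nsplits: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Set-level error per nsplit (sum of relative error x group fraction)
    and the final error (mean over nsplit)."""
    set_err = np.zeros(len(nsplits))
    for g, rel in relative_errors.items():
        set_err += np.asarray(rel) * group_fractions[g]
    return set_err, float(set_err.mean())


def classification_error(
    norm: NormalizedMatrix,
    grouping: Grouping,
    de: pd.DataFrame,
    nsplit_range: tuple[int, int] = (5, 15),
    random_state: int = 0,
) -> ClassifierReport:
    """Decision-tree separability score of a candidate grouping.

    One binary CART tree per group (group vs rest) on the normalized
    expression of the union of DE genes.  For each nsplit in the range, the
    relative training error of the deepest subtree with at most that many
    splits is taken (relative to the minority-class count at the root), scaled
    by the group's cell fraction, summed over groups, and finally averaged
    over the nsplit range.
    """
    if de is None or len(de) == 0:
        raise ValueError("cannot evaluate: no DE genes")
    genes = pd.unique(de["gene"])
    X = norm.dense_rows(genes).T  # cells x genes
    labels = grouping.labels
    n = len(labels)
    nsplits = np.arange(nsplit_range[0], nsplit_range[1] + 1)

    rel_errors: dict[int, np.ndarray] = {}
    fractions: dict[int, float] = {}
    for g in range(grouping.k):
        y = labels == g
        baseline = int(min(y.sum(), (~y).sum()))
        fractions[g] = float(y.sum()) / n
        if baseline == 0:
            rel_errors[g] = np.zeros(len(nsplits))
            continue
        path = _tree_error_path(X, y, random_state)
        rel = np.empty(len(nsplits))
        for j, target in enumerate(nsplits):
            usable = [(ns, err) for ns, err in path if ns <= target]
            ns, err = usable[-1] if usable else path[0]
            rel[j] = err / baseline
        rel_errors[g] = rel
    set_err, final = aggregate_errors(rel_errors, fractions, nsplits)
    return ClassifierReport(
        nsplits=nsplits,
        relative_errors=rel_errors,
        group_fractions=fractions,
        set_error_by_nsplit=set_err,
        final_error=final,
    )


def summarize(
    candidates: list, cutoffs: tuple[float, ...] = (0.8, 0.85, 0.9)
) -> pd.DataFrame:
    """Performance summary over candidate sets; marks exactly one best.

    Per candidate and AUROC cutoff: the median over groups of the number of DE
    genes above the cutoff.  The fold-change metric is the median over groups
    of the mean avg_logFC of each group's top-10 (or all, if fewer)
    AUROC > 0.8 DE genes, reported in natural log and log2.  The candidate
    with the lowest final classification error is the best (ties go to the
    smaller k).
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    rows = []
    for cand in candidates:
        de = cand.de if cand.de is not None else pd.DataFrame(columns=DE_COLUMNS)
        groups = np.arange(cand.k)
        row: dict = {
            "candidate": cand.name,
            "nPC": cand.nPC,
            "k": cand.k,
            "gap_increase": cand.gap_increase,
        }
        for cut in cutoffs:
            counts = (
                de[de["auroc"] > cut].groupby("group").size()
                .reindex(groups, fill_value=0)
            )
            row[f"n_de_auroc_{cut:g}"] = float(np.median(counts))
        means = []
        for g in groups:
            d = de[(de["group"] == g) & (de["auroc"] > 0.8)]
            top = d.sort_values("avg_logFC", ascending=False).head(10)
            means.append(float(top["avg_logFC"].mean()) if len(top) else 0.0)
        med = float(np.median(means)) if means else 0.0
        row["median_top10_avg_logFC"] = med
        row["median_top10_avg_log2FC"] = med / np.log(2)
        row["classification_error"] = (
            float(cand.report.final_error) if cand.report is not None else np.nan
        )
        rows.append(row)
    summary = pd.DataFrame(rows)
    order = summary.sort_values(
        ["classification_error", "k"], kind="stable"
    ).index
    best = order[0]
    summary["is_best"] = False
    summary.loc[best, "is_best"] = True
    return summary
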