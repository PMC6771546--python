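"""End-to-end orchestration: the full sweep and the recursive cell ontology.

`run_ikap` (or the `IKAP` facade) takes raw counts through QC, normalization,
covariate regression, variable genes, PCA, the (nPC, k) sweep, candidate
selection and DE/decision-tree evaluation, returning an `IkapResult`.
`build_ontology` applies the same run recursively inside chosen groups to
delineate cell identities layer by layer.
"""

from __future__ import annotations

import dataclasses
import logging
import zlib

import numpy as np
import pandas as pd

from . import __version__
from .candidates import CandidateSet, materialize_candidates, select_candidates
from .cluster import SweepBounds, sweep_bounds
from .config import RunConfig
from .de import ClassifierReport, classification_error, find_de_genes, summarize
from .gap import GapMatrix, gap_increase_matrix
from .io import RawCounts
from .preprocess import (
    compute_pca,
    filter_cells,
    normalize,
    regress_and_scale,
    select_variable_genes,
)

log = logging.getLogger(__name__)

__all__ = ["IkapResult", "IKAP", "OntologyNode", "run_ikap", "build_ontology",
           "benchmark_grid"]


@dataclasses.dataclass
class IkapResult:
    """Everything a sweep produced: bounds, gap matrix, evaluated candidates."""

    bounds: SweepBounds
    gap: GapMatrix
    candidates: list[CandidateSet]
    best: int
    summary: pd.DataFrame
    config: RunConfig
    cell_ids: np.ndarray
    n_variable_genes: int

    @property
    def best_candidate(self) -> CandidateSet:
        return self.candidates[self.best]

    def summary_table(self) -> pd.DataFrame:
        return self.summary

    def manifest(self) -> dict:
        return {
            "version": __version__,
            "config": self.config.to_dict(),
            "seed": self.config.seed,
            "bounds": dataclasses.asdict(self.bounds),
            "n_cells": int(len(self.cell_ids)),
            "n_variable_genes": int(self.n_variable_genes),
            "candidates": [
                {"name": c.name, "nPC": c.nPC, "k": c.k, "gap_increase": c.gap_increase}
                for c in self.candidates
            ],
            "best": self.candidates[self.best].name if self.candidates else None,
        }

    def __repr__(self) -> str:
        names = ", ".join(c.name for c in self.candidates)
        return (
            f"<IkapResult: {len(self.cell_ids)} cells, candidates [{names}], "
            f"best {self.best_candidate.name}>"
        )


def run_ikap(
    counts: RawCounts,
    cfg: RunConfig | None = None,
    covariates: pd.DataFrame | str | None = "auto",
) -> IkapResult:
    """Run the full sweep on a count matrix.

    ``covariates="auto"`` regresses out per-cell total UMI and mitochondrial
    fraction (the default QC covariates); pass an aligned numeric table for
    custom covariates or ``None`` to disable regression.
    """
    cfg = cfg or RunConfig()
    if cfg.filter_cells:
        counts = filter_cells(counts, cfg.min_genes, cfg.max_mito_frac)
    if counts.n_cells < cfg.min_cells_recurse:
        raise ValueError(
            f"{counts.n_cells} cells after filtering, below minimum "
            f"{cfg.min_cells_recurse}"
        )
    norm = normalize(counts)
    if isinstance(covariates, str) and covariates == "auto":
        cov = np.column_stack([norm.total_umi, norm.mito_frac])
    else:
        cov = covariates
    var_genes = select_variable_genes(norm)
    scaled = regress_and_scale(norm, cov, genes=var_genes)
    n_pcs = min(cfg.max_pcs, len(var_genes) - 1, counts.n_cells - 1)
    pc = compute_pca(scaled, n_pcs)

    bounds = sweep_bounds(pc, cfg)
    log.info("sweep bounds: %s", bounds)
    gap, series = gap_increase_matrix(pc, bounds, cfg)
    picks = select_candidates(gap, cfg.candidate_sd_factor)
    cands = materialize_candidates(picks, series)

    for cand in cands:
        cand.de = find_de_genes(
            norm, cand.grouping, cfg.min_logfc, cfg.min_pct, cfg.max_padj
        )
        if len(cand.de) == 0:
            log.warning(
                "candidate %s produced no DE genes; assigning worst error", cand.name
            )
            nsplits = np.arange(cfg.nsplit_range[0], cfg.nsplit_range[1] + 1)
            cand.report = ClassifierReport(
                nsplits=nsplits,
                relative_errors={},
                group_fractions={},
                set_error_by_nsplit=np.ones(len(nsplits)),
                final_error=1.0,
            )
        else:
            cand.report = classification_error(
                norm, cand.grouping, cand.de, cfg.nsplit_range, random_state=cfg.seed
            )

    summary = summarize(cands, cfg.auroc_cutoffs)
    best = int(np.flatnonzero(summary["is_best"].to_numpy())[0])
    return IkapResult(
        bounds=bounds,
        gap=gap,
        candidates=cands,
        best=best,
        summary=summary,
        config=cfg,
        cell_ids=counts.cell_ids,
        n_variable_genes=len(var_genes),
    )


class IKAP:
    """Model-style facade: construct from counts, ``fit()`` to get results.

    Examples
    --------
    >>> result = IKAP(counts, RunConfig(seed=1)).fit()
    >>> result.summary_table()
    """

    def __init__(
        self,
        counts: RawCounts,
        config: RunConfig | None = None,
        covariates: pd.DataFrame | str | None = "auto",
    ) -> None:
        self.counts = counts
        self.config = config or RunConfig()
        self.covariates = covariates

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        orientation: str = "genes_by_cells",
        config: RunConfig | None = None,
    ) -> "IKAP":
        import scipy.sparse as sp

        if orientation == "cells_by_genes":
            df = df.T
        counts = RawCounts(
            sp.csr_matrix(df.to_numpy().astype(np.int64)),
            np.asarray(df.index, dtype=object),
            np.asarray(df.columns, dtype=object),
        )
        return cls(counts, config)

    def fit(self) -> IkapResult:
        return run_ikap(self.counts, self.config, self.covariates)


# ---------------------------------------------------------------------------
# recursive ontology


@dataclasses.dataclass
class OntologyNode:
    """A node of the recursive cell ontology.

    ``result`` is None for leaf groups that were not re-analysed (too small,
    too deep, or untargeted); ``children`` holds one node per group of the
    chosen candidate when the node was expanded.
    """

    name: str
    cell_ids: np.ndarray
    result: IkapResult | None
    chosen_candidate: int | None
    children: list["OntologyNode"] = dataclasses.field(default_factory=list)
    labels: np.ndarray | None = None  # per-cell group of the chosen candidate

    @property
    def short_name(self) -> str:
        return self.name.rsplit("/", 1)[-1]

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def leaves(self) -> list["OntologyNode"]:
        if not self.children:
            return [self]
        out = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def to_dict(self, include_labels: bool = False) -> dict:
        d: dict = {
            "name": self.name,
            "n_cells": self.n_cells,
            "candidate": (
                self.result.candidates[self.chosen_candidate].name
                if self.result is not None
                else None
            ),
            "children": [c.to_dict(include_labels) for c in self.children],
        }
        if include_labels and self.labels is not None:
            d["groups"] = {
                str(cid): int(lab) for cid, lab in zip(self.cell_ids, self.labels)
            }
        return d


def _child_seed(seed: int, name: str) -> int:
    return int((seed * 1000003 + zlib.crc32(name.encode())) % (2**31 - 1))


def build_ontology(
    counts: RawCounts,
    cfg: RunConfig | None = None,
    max_depth: int = 2,
    targets: str = "largest",
    chosen: dict[str, int] | None = None,
    _name: str = "root",
) -> OntologyNode:
    """Run the sweep, then re-run it recursively inside chosen groups.

    ``targets="largest"`` expands only the largest group at each level (the
    default demonstration mode); ``"all"`` expands every group with at least
    ``min_cells_recurse`` cells.  ``chosen`` optionally pins a candidate index
    per node name (default: the best candidate).  Cell QC is applied only at
    the root; subset re-runs recompute variable genes, PCA and bounds within
    the subset.
    """
    if max_depth < 0:
        raise ValueError("max_depth must be >= 0")
    cfg = cfg or RunConfig()
    result = run_ikap(counts, cfg)
    pick = (chosen or {}).get(_name, result.best)
    if not (0 <= pick < len(result.candidates)):
        raise ValueError(f"invalid candidate index {pick} for node {_name}")
    grouping = result.candidates[pick].grouping
    node = OntologyNode(
        name=_name,
        cell_ids=result.cell_ids,
        result=result,
        chosen_candidate=pick,
        labels=grouping.labels,
    )
    if max_depth == 0:
        return node

    sizes = grouping.sizes
    if targets == "largest":
        expand = {int(np.argmax(sizes))}
    elif targets == "all":
        expand = set(range(grouping.k))
    else:
        raise ValueError(f"unknown targets mode {targets!r}")

    kept = counts
    if cfg.filter_cells:
        keep_idx = pd.Index(counts.cell_ids).get_indexer(result.cell_ids)
        kept = counts.subset_cells(keep_idx)
    sub_cfg = cfg.replace(filter_cells=False)
    for g in range(grouping.k):
        mask = grouping.labels == g
        child_name = f"{_name}/g{g}"
        if g in expand and int(mask.sum()) >= cfg.min_cells_recurse:
            child = build_ontology(
                kept.subset_cells(mask),
                sub_cfg.replace(seed=_child_seed(cfg.seed, child_name)),
                max_depth=max_depth - 1,
                targets=targets,
                chosen=chosen,
                _name=child_name,
            )
        else:
            if g in expand:
                log.info(
                    "group %s has %d cells (< %d); leaving as leaf",
                    child_name, int(mask.sum()), cfg.min_cells_recurse,
                )
            child = OntologyNode(
                name=child_name,
                cell_ids=result.cell_ids[mask],
                result=None,
                chosen_candidate=None,
            )
        node.children.append(child)
    return node


# ---------------------------------------------------------------------------
# trial-grid benchmark


def benchmark_grid(
    counts: RawCounts,
    cfg: RunConfig | None = None,
    npcs: tuple[int, ...] = (5, 10, 15, 20),
    resolutions: tuple[float, ...] = (0.1, 0.2, 0.4, 0.6, 1.0),
) -> pd.DataFrame:
    """Evaluate a fixed grid of (nPC, r) clusterings with the same DE-based
    metrics as the sweep's performance summary (the trial-set comparison)."""
    from .cluster import _stage_seed, cluster

    cfg = cfg or RunConfig()
    if cfg.filter_cells:
        counts = filter_cells(counts, cfg.min_genes, cfg.max_mito_frac)
    norm = normalize(counts)
    cov = np.column_stack([norm.total_umi, norm.mito_frac])
    var_genes = select_variable_genes(norm)
    scaled = regress_and_scale(norm, cov, genes=var_genes)
    max_npc = max(npcs)
    n_pcs = min(max(max_npc, cfg.max_pcs), len(var_genes) - 1, counts.n_cells - 1)
    pc = compute_pca(scaled, n_pcs)

    trials = []
    for npc in npcs:
        if npc > pc.n_components:
            log.warning("skipping nPC=%d (> %d components)", npc, pc.n_components)
            continue
        for r in resolutions:
            grouping = cluster(pc, npc, r, seed=_stage_seed(cfg.seed, "trial", npc))
            cand = CandidateSet(
                name=f"PC{npc}R{r:g}", nPC=npc, k=grouping.k,
                gap_increase=float("nan"), grouping=grouping,
            )
            if grouping.k >= 2:
                cand.de = find_de_genes(
                    norm, grouping, cfg.min_logfc, cfg.min_pct, cfg.max_padj
                )
                if len(cand.de):
                    cand.report = classification_error(
                        norm, grouping, cand.de, cfg.nsplit_range, random_state=cfg.seed
                    )
            trials.append((r, cand))
    rows = summarize([c for _, c in trials], cfg.auroc_cutoffs)
    rows = rows.drop(columns=["is_best", "gap_increase"])
    rows.insert(2, "resolution", [r for r, _ in trials])
    return rows
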