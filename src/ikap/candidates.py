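"""Candidate (nPC, k) selection from the gap-increase matrix.

The selection rule: (0) drop entries with gap increase <= mean + sd over all
finite entries of the matrix; (1) per column k keep the surviving entry with
the largest (positive) increase, ties to the smaller nPC; (2) sort kept
entries by increase descending, ties to the smaller k; (3) greedily accept an
entry iff both its nPC and its k strictly exceed those of every entry already
accepted (the first entry is always accepted).  If the filter removes
everything, the single global-maximum entry is returned with a warning.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np

from .cluster import Grouping
from .gap import GapMatrix, GroupingSeries

log = logging.getLogger(__name__)

__all__ = ["CandidatePick", "CandidateSet", "greedy_accept", "select_candidates",
           "materialize_candidates"]


@dataclasses.dataclass
class CandidatePick:
    nPC: int
    k: int
    gap_increase: float
    rank: int = 0


@dataclasses.dataclass
class CandidateSet:
    """A chosen (nPC, k) grouping with its evaluation artifacts."""

    name: str
    nPC: int
    k: int
    gap_increase: float
    grouping: Grouping
    de: object | None = None  # DataFrame of DE genes
    report: object | None = None  # ClassifierReport


def greedy_accept(picks: list[CandidatePick]) -> list[CandidatePick]:
    """Accept entries of a descending-gap-increase list whose nPC and k both
    strictly exceed all accepted so far; the first entry is always accepted."""
    accepted: list[CandidatePick] = []
    for pick in picks:
        if not accepted or (
            pick.nPC > max(p.nPC for p in accepted)
            and pick.k > max(p.k for p in accepted)
        ):
            accepted.append(
                CandidatePick(pick.nPC, pick.k, pick.gap_increase, rank=len(accepted))
            )
    return accepted


def select_candidates(M: GapMatrix, sd_factor: float = 1.0) -> list[CandidatePick]:
    """Apply the filter + column-max + greedy procedure to a gap matrix."""
    inc = M.increase
    finite = np.isfinite(inc)
    if not finite.any():
        raise ValueError("gap-increase matrix has no finite entries")
    vals = inc[finite]
    threshold = vals.mean() + sd_factor * vals.std(ddof=1) if len(vals) > 1 else vals.mean()

    surviving = finite & (inc > threshold) & (inc > 0)
    if not surviving.any():
        # degenerate matrix: fall back to the single global-max entry
        warnings.warn("no gap increase exceeds mean + sd; falling back to the global maximum")
        masked = np.where(finite, inc, -np.inf)
        i, j = np.unravel_index(int(masked.argmax()), masked.shape)
        return [CandidatePick(int(M.npcs[i]), j + 1, float(inc[i, j]), rank=0)]

    column_max: list[CandidatePick] = []
    for j in range(inc.shape[1]):
        col = np.where(surviving[:, j], inc[:, j], -np.inf)
        if not np.isfinite(col.max()) or col.max() == -np.inf:
            continue
        i = int(col.argmax())  # argmax returns the first (smallest nPC) on ties
        column_max.append(CandidatePick(int(M.npcs[i]), j + 1, float(inc[i, j])))

    # descending gap increase; ties to the smaller k
    column_max.sort(key=lambda p: (-p.gap_increase, p.k))
    accepted = greedy_accept(column_max)
    if len(accepted) > 4:
        log.warning("%d candidate sets selected (typically 1-4)", len(accepted))
    return accepted


def materialize_candidates(
    picks: list[CandidatePick], series: dict[int, GroupingSeries]
) -> list[CandidateSet]:
    """Attach the k-group partition from each pick's nPC merge series;
    candidates are named "PC{nPC}K{k}"."""
    out = []
    for pick in picks:
        if pick.nPC not in series:
            raise KeyError(f"no grouping series for nPC={pick.nPC}")
        grouping = series[pick.nPC][pick.k]
        assert grouping.k == pick.k
        out.append(
            CandidateSet(
                name=f"PC{pick.nPC}K{pick.k}",
                nPC=pick.nPC,
                k=pick.k,
                gap_increase=pick.gap_increase,
                grouping=grouping,
            )
        )
    return out
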