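"""Run-level configuration for the parameter sweep.

All knobs of the pipeline live in :class:`RunConfig`.  Defaults follow the
conventions of the Seurat-era single-cell stack (neighbour count 20, SNN prune
1/15, DE thresholds logFC 0.25 / min.pct 0.1 / adjusted p 0.05) and the sweep
defaults of the algorithm itself (r_ini = 1.5, nPC span 20, resolution ladder
1.0 + 0.2 steps, nsplit 5..15).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml


@dataclasses.dataclass
class RunConfig:
    """Parameters controlling a full sweep run.

    Attributes
    ----------
    r_ini
        Resolution used to estimate ``k_max`` (clustering at ``nPC_min`` and
        ``nPC_max``; their group counts are averaged).
    npc_span
        ``nPC_max - nPC_min``.
    r_start, r_step, r_cap
        Resolution ladder for the initial fine partition: start at ``r_start``
        and increment by ``r_step`` until at least ``k_max`` groups appear,
        erroring beyond ``r_cap``.
    gap_B
        Number of uniform reference draws for the gap statistic.
    seed
        Master seed; every stochastic stage derives a child seed from it.
    nsplit_range
        Inclusive range of decision-tree split counts averaged into the final
        classification error.
    auroc_cutoffs
        AUROC thresholds for the "high-AUROC DE gene" counts.
    min_logfc, min_pct, max_padj
        DE gene thresholds (natural-log fold change, minimum expressing
        fraction, Bonferroni-adjusted p cutoff).
    min_cells_recurse
        Minimum number of cells for a (sub)run; ontology recursion stops below.
    min_genes, max_mito_frac, filter_cells
        Cell QC: keep cells with >= ``min_genes`` expressed genes and
        mitochondrial UMI fraction <= ``max_mito_frac``; ``filter_cells=False``
        disables QC (mouse-cortex-style runs).
    n_neighbors, snn_prune
        kNN count and Jaccard prune threshold of the shared-nearest-neighbour
        graph.
    max_pcs
        Upper bound on the number of principal components computed.
    gap_normalization
        ``"normalized"`` uses W = sum_r D_r / (2 n_r); ``"raw_sum"`` uses the
        plain sum of within-group pairwise distances.
    reference_partition
        ``"kmeans"`` partitions reference draws by seeded k-means;
        ``"merge"`` uses a fine k-means followed by nearest-centroid merging,
        mirroring the observed-data pipeline (fidelity experiments).
    kmeans_restarts
        Restarts for reference-draw k-means.
    candidate_sd_factor
        The candidate filter keeps entries with gap increase
        > mean + candidate_sd_factor * sd.
    """

    r_ini: float = 1.5
    npc_span: int = 20
    r_start: float = 1.0
    r_step: float = 0.2
    r_cap: float = 5.0
    gap_B: int = 100
    seed: int = 0
    nsplit_range: tuple[int, int] = (5, 15)
    auroc_cutoffs: tuple[float, ...] = (0.8, 0.85, 0.9)
    min_logfc: float = 0.25
    min_pct: float = 0.1
    max_padj: float = 0.05
    min_cells_recurse: int = 100
    min_genes: int = 200
    max_mito_frac: float = 0.05
    filter_cells: bool = True
    n_neighbors: int = 20
    snn_prune: float = 1.0 / 15.0
    max_pcs: int = 40
    gap_normalization: str = "normalized"
    reference_partition: str = "kmeans"
    kmeans_restarts: int = 10
    candidate_sd_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.r_ini <= 0:
            raise ValueError("r_ini must be > 0")
        if self.npc_span < 0:
            raise ValueError("npc_span must be >= 0")
        if self.gap_B < 1:
            raise ValueError("gap_B must be >= 1")
        lo, hi = self.nsplit_range
        if lo > hi:
            raise ValueError("nsplit_range must be nondecreasing")
        if self.gap_normalization not in ("normalized", "raw_sum"):
            raise ValueError("gap_normalization must be 'normalized' or 'raw_sum'")
        if self.reference_partition not in ("kmeans", "merge"):
            raise ValueError("reference_partition must be 'kmeans' or 'merge'")

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["nsplit_range"] = list(self.nsplit_range)
        d["auroc_cutoffs"] = list(self.auroc_cutoffs)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("nsplit_range", "auroc_cutoffs"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def replace(self, **changes: Any) -> "RunConfig":
        return dataclasses.replace(self, **changes)
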