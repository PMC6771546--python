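"""Hierarchical UMI-like synthetic datasets with ground-truth labels.

The generator emulates droplet scRNA-seq of a tissue containing a few
well-separated major cell populations, each optionally containing
subpopulations distinguished by fewer and weaker marker genes.  Counts are
negative binomial (gamma-Poisson): per-gene baseline means are log-normal,
marker effects act multiplicatively on the mean (subgroup effects compose
with major effects), and per-cell library-size factors are log-normal with
mean one.  A small block of genes is prefixed "MT-" and carries a configured
share of each cell's expected counts so QC filtering is exercised.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.sparse as sp

from .io import RawCounts

__all__ = ["SubSpec", "MajorSpec", "SyntheticSpec", "GroundTruth", "generate", "preset"]


@dataclasses.dataclass
class SubSpec:
    """A subpopulation within a major group."""

    fraction: float
    n_markers: int
    marker_log_effect: float


@dataclasses.dataclass
class MajorSpec:
    """A major population: size, marker count and marker strength."""

    n_cells: int
    n_markers: int
    marker_log_effect: float
    subs: list[SubSpec] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class SyntheticSpec:
    n_genes: int = 1200
    baseline_log_mean: float = -0.7
    baseline_log_sd: float = 1.3
    # marker genes draw their baseline from a separate, moderately expressed
    # regime: real annotated markers are reliably detected genes, and a
    # fold-change on a never-detected gene carries no signal
    marker_baseline_log_mean: float = 0.0
    marker_baseline_log_sd: float = 0.5
    dispersion: float = 2.0  # negative-binomial size parameter
    majors: list[MajorSpec] = dataclasses.field(default_factory=list)
    library_size_sd: float = 0.25  # log-normal sd of per-cell library factors
    mito_fraction_mean: float = 0.02
    n_mito_genes: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not self.majors:
            raise ValueError("spec needs at least one major population")
        n_marker_genes = sum(
            m.n_markers + sum(s.n_markers for s in m.subs) for m in self.majors
        )
        if n_marker_genes + self.n_mito_genes > self.n_genes:
            raise ValueError("not enough genes for disjoint marker sets")
        for m in self.majors:
            if m.marker_log_effect < 0 or any(s.marker_log_effect < 0 for s in m.subs):
                raise ValueError("marker effects must be >= 0")
            if m.subs and abs(sum(s.fraction for s in m.subs) - 1.0) > 1e-9:
                raise ValueError("sub fractions per major must sum to 1")


@dataclasses.dataclass
class GroundTruth:
    major_label: np.ndarray  # per-cell, e.g. "M0"
    sub_label: np.ndarray  # per-cell, e.g. "M0S1" ("" when the major has no subs)
    markers: dict[str, list[str]]  # group name -> marker gene ids
    expected_library: float = 0.0  # expected per-cell total UMI


def _allocate_cells(n: int, fractions: list[float]) -> list[int]:
    counts = [int(np.floor(f * n)) for f in fractions]
    i = 0
    while sum(counts) < n:
        counts[i % len(counts)] += 1
        i += 1
    return counts


def generate(spec: SyntheticSpec) -> tuple[RawCounts, GroundTruth]:
    """Draw a (RawCounts, GroundTruth) pair; deterministic given spec.seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    base = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    # mito block: rescale so the expected mito share of counts matches the spec
    n_mt = spec.n_mito_genes
    if n_mt > 0 and spec.mito_fraction_mean > 0:
        other_sum = base[n_mt:].sum()
        target = spec.mito_fraction_mean / (1 - spec.mito_fraction_mean) * other_sum
        base[:n_mt] *= target / base[:n_mt].sum()
    gene_ids = np.array(
        [f"MT-SIM{i + 1}" for i in range(n_mt)]
        + [f"GENE{i + 1:05d}" for i in range(spec.n_genes - n_mt)],
        dtype=object,
    )

    # disjoint marker blocks, walked over the non-mito genes
    cursor = n_mt
    markers: dict[str, list[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    effects: dict[str, float] = {}
    for mi, major in enumerate(spec.majors):
        name = f"M{mi}"
        marker_idx[name] = np.arange(cursor, cursor + major.n_markers)
        markers[name] = gene_ids[marker_idx[name]].tolist()
        effects[name] = major.marker_log_effect
        cursor += major.n_markers
        for si, sub in enumerate(major.subs):
            sname = f"{name}S{si}"
            marker_idx[sname] = np.arange(cursor, cursor + sub.n_markers)
            markers[sname] = gene_ids[marker_idx[sname]].tolist()
            effects[sname] = sub.marker_log_effect
            cursor += sub.n_markers
    all_marker_idx = np.concatenate(list(marker_idx.values())) if marker_idx else []
    if len(all_marker_idx):
        base[all_marker_idx] = rng.lognormal(
            spec.marker_baseline_log_mean,
            spec.marker_baseline_log_sd,
            len(all_marker_idx),
        )

    major_label, sub_label = [], []
    for mi, major in enumerate(spec.majors):
        name = f"M{mi}"
        if major.subs:
            counts = _allocate_cells(major.n_cells, [s.fraction for s in major.subs])
            for si, c in enumerate(counts):
                major_label += [name] * c
                sub_label += [f"{name}S{si}"] * c
        else:
            major_label += [name] * major.n_cells
            sub_label += [""] * major.n_cells
    major_label = np.array(major_label, dtype=object)
    sub_label = np.array(sub_label, dtype=object)
    n_cells = len(major_label)

    lib = rng.lognormal(-spec.library_size_sd**2 / 2, spec.library_size_sd, n_cells)

    log_effect = np.zeros((spec.n_genes, n_cells))
    for name, idx in marker_idx.items():
        in_group = (sub_label == name) if "S" in name else (major_label == name)
        if in_group.any():
            log_effect[np.ix_(idx, np.flatnonzero(in_group))] += effects[name]

    # expression profiles are relative: marker effects reshape a cell's
    # transcriptome but do not inflate its library, which is a technical
    # factor independent of cell type
    profile = base[:, None] * np.exp(log_effect)
    target_library = base.sum()
    mean = profile / profile.sum(axis=0) * target_library * lib[None, :]
    theta = spec.dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.int64)

    cell_ids = np.array([f"cell{i + 1:05d}" for i in range(n_cells)], dtype=object)
    raw = RawCounts(sp.csr_matrix(counts), gene_ids, cell_ids, mito_pattern="MT-")
    truth = GroundTruth(
        major_label, sub_label, markers, expected_library=float(target_library)
    )
    return raw, truth


def preset(name: str, seed: int = 0) -> SyntheticSpec:
    """Documented fixture specifications.

    - ``flat5``: 5 equally sized, strongly separated major populations
      (200 cells and 40 markers at 2.5 log-units each).
    - ``hier3x3``: 3 majors; the largest (360 cells) splits into 3 equal
      subtypes whose markers are half as strong and fewer (1.25 log-units,
      15 markers vs 2.5 log-units, 40 markers).
    - ``single_blob``: one unstructured population, no marker genes.
    - ``pbmc_like``: 7 majors with strong size imbalance, mimicking the
      group-count regime of a PBMC run.
    """
    if name == "flat5":
        majors = [MajorSpec(200, 40, 2.5) for _ in range(5)]
        return SyntheticSpec(n_genes=1200, majors=majors, seed=seed)
    if name == "hier3x3":
        subs = [SubSpec(1 / 3, 15, 1.25) for _ in range(3)]
        majors = [
            MajorSpec(360, 40, 2.5, subs=subs),
            MajorSpec(240, 40, 2.5),
            MajorSpec(200, 40, 2.5),
        ]
        return SyntheticSpec(n_genes=1200, majors=majors, seed=seed)
    if name == "single_blob":
        return SyntheticSpec(n_genes=1000, majors=[MajorSpec(300, 0, 0.0)], seed=seed)
    if name == "pbmc_like":
        sizes = [500, 350, 250, 150, 100, 70, 40]
        majors = [MajorSpec(s, 30, 2.0) for s in sizes]
        return SyntheticSpec(n_genes=1500, majors=majors, seed=seed)
    raise ValueError(f"unknown preset {name!r}")
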