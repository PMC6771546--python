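"""Reading count matrices and writing run artifacts.

Matrices are held genes x cells throughout the package (the 10x Matrix Market
convention); dense tables may be supplied in either orientation via a flag.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
import logging
from pathlib import Path
from typing import IO, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

log = logging.getLogger(__name__)

__all__ = ["RawCounts", "read_counts", "write_results"]


@dataclasses.dataclass
class RawCounts:
    """A genes x cells matrix of non-negative integer UMI counts.

    ``mito_pattern`` is a case-insensitive gene-symbol prefix flagging
    mitochondrial genes (default ``"MT-"``).
    """

    matrix: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    mito_pattern: str = "MT-"
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell_ids are not unique")
        data = self.matrix.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    @property
    def mito_mask(self) -> np.ndarray:
        """Boolean per-gene mask of mitochondrial genes (prefix match)."""
        pat = self.mito_pattern.upper()
        return np.array([str(g).upper().startswith(pat) for g in self.gene_ids])

    def subset_cells(self, mask_or_index: np.ndarray) -> "RawCounts":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return RawCounts(
            self.matrix[:, idx],
            self.gene_ids,
            self.cell_ids[idx],
            self.mito_pattern,
        )


def _make_unique(names: list[str]) -> np.ndarray:
    """Disambiguate duplicate names by suffixing "-1", "-2", ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    existing = set(names)
    for name in names:
        if name not in seen:
            seen[name] = 0
            out.append(name)
            continue
        while True:
            seen[name] += 1
            candidate = f"{name}-{seen[name]}"
            if candidate not in existing:
                break
        existing.add(candidate)
        out.append(candidate)
    return np.asarray(out, dtype=object)


def _open_maybe_gz(path: Path) -> IO:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find_one(directory: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    raise FileNotFoundError(f"none of {stems} found in {directory}")


def _read_mtx_dir(directory: Path, mito_pattern: str) -> RawCounts:
    mtx_path = _find_one(directory, ["matrix.mtx"])
    genes_path = _find_one(directory, ["features.tsv", "genes.tsv"])
    barcodes_path = _find_one(directory, ["barcodes.tsv"])

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)

    genes = pd.read_csv(genes_path, sep="\t", header=None)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)
    # 10x v2 gene tables have 2 columns (id, symbol), v3 adds a feature type;
    # the symbol column is used when present.
    sym_col = 1 if genes.shape[1] >= 2 else 0
    gene_ids = _make_unique([str(g) for g in genes.iloc[:, sym_col]])
    cell_ids = _make_unique([str(b) for b in barcodes.iloc[:, 0]])

    if mat.shape[0] != len(gene_ids):
        raise ValueError(
            f"matrix declares {mat.shape[0]} genes but gene table has {len(gene_ids)} rows"
        )
    if mat.shape[1] != len(cell_ids):
        raise ValueError(
            f"matrix declares {mat.shape[1]} cells but barcode table has {len(cell_ids)} rows"
        )
    return RawCounts(mat, gene_ids, cell_ids, mito_pattern)


def _read_dense(path: Path, sep: str, orientation: str, mito_pattern: str) -> RawCounts:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "cells_by_genes":
        df = df.T
    elif orientation != "genes_by_cells":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or np.any(values != np.round(values)):
        raise ValueError("dense count table contains non-integer entries")
    gene_ids = _make_unique([str(g) for g in df.index])
    cell_ids = _make_unique([str(c) for c in df.columns])
    return RawCounts(sp.csr_matrix(values.astype(np.int64)), gene_ids, cell_ids, mito_pattern)


def read_counts(
    path: str | Path,
    format: str = "auto",
    orientation: str = "genes_by_cells",
    mito_pattern: str = "MT-",
) -> RawCounts:
    """Read a UMI count matrix.

    Parameters
    ----------
    path
        A 10x Matrix Market directory (``matrix.mtx[.gz]`` +
        ``genes.tsv``/``features.tsv`` + ``barcodes.tsv``) or a dense CSV/TSV
        table with gene/cell headers.
    format
        ``"mtx_dir"``, ``"csv"``, ``"tsv"`` or ``"auto"`` (directory -> mtx_dir,
        else by extension).
    orientation
        Orientation of dense tables; Matrix Market input is always taken as
        genes x cells.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        if path.is_dir():
            format = "mtx_dir"
        elif path.suffix in (".tsv", ".txt"):
            format = "tsv"
        else:
            format = "csv"
    if format == "mtx_dir":
        return _read_mtx_dir(path, mito_pattern)
    if format == "csv":
        return _read_dense(path, ",", orientation, mito_pattern)
    if format == "tsv":
        return _read_dense(path, "\t", orientation, mito_pattern)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# writing


def _write_assignments(path: Path, cell_ids: np.ndarray, labels: np.ndarray) -> None:
    pd.DataFrame({"cell_id": cell_ids, "group": labels}).to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str, "group": int})


def _gap_frame(gapmatrix) -> pd.DataFrame:
    return pd.DataFrame(
        gapmatrix.increase,
        index=pd.Index(gapmatrix.npcs, name="nPC"),
        columns=[f"k{k}" for k in range(1, gapmatrix.k_max + 1)],
    )


def write_results(result, outdir: str | Path) -> list[Path]:
    """Write run artifacts to ``outdir``; returns the paths written.

    For a sweep result: per-candidate assignment and DE TSVs, the gap-increase
    matrix TSV, the performance summary TSV and a JSON manifest.  For an
    ontology root node: additionally a nested ``ontology.json`` with per-node
    labels, with each node's artifacts in a directory tree.
    """
    from .model import IkapResult, OntologyNode  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if isinstance(result, OntologyNode):
        payload = result.to_dict(include_labels=True)
        path = outdir / "ontology.json"
        path.write_text(json.dumps(payload, indent=1))
        written.append(path)
        for node, rel in _walk_nodes(result):
            node_dir = outdir / rel
            if node.result is not None:
                written.extend(write_results(node.result, node_dir))
        return written

    if not isinstance(result, IkapResult):
        raise TypeError(f"cannot write {type(result).__name__}")

    for cand in result.candidates:
        apath = outdir / f"{cand.name}_assignments.tsv"
        _write_assignments(apath, result.cell_ids, cand.grouping.labels)
        written.append(apath)
        dpath = outdir / f"{cand.name}_de_genes.tsv"
        de = cand.de if cand.de is not None else pd.DataFrame(
            columns=["gene", "group", "avg_logFC", "p", "p_adj", "pct_in", "pct_out", "auroc"]
        )
        de.to_csv(dpath, sep="\t", index=False)
        written.append(dpath)
    if not result.candidates:
        log.warning("no candidates to write; emitting gap matrix and manifest only")

    gpath = outdir / "gap_increase.tsv"
    _gap_frame(result.gap).to_csv(gpath, sep="\t")
    written.append(gpath)

    if result.summary is not None and len(result.summary):
        spath = outdir / "performance_summary.tsv"
        result.summary.to_csv(spath, sep="\t", index=False)
        written.append(spath)

    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(result.manifest(), indent=1, sort_keys=True))
    written.append(mpath)
    return written


def _walk_nodes(node, rel: str = "root") -> Iterator[tuple[object, str]]:
    yield node, rel
    for child in node.children:
        yield from _walk_nodes(child, f"{rel}/{child.short_name}")
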