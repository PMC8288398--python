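"""Reading/writing matrix bundles, QC filtering and log-normalization.

A *bundle* is a directory with::

    matrix.mtx    MatrixMarket sparse counts, genes x cells
    genes.tsv     one gene id per line
    barcodes.tsv  one cell id per line
    metadata.tsv  cell_id, donor_id, age_group, sex[, cell_type]

A dense fallback (``matrix.tsv``: gene rows, cell columns, first column gene
ids, header cell ids) is accepted in place of the MTX triplet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .matrix import LOGNORM, RAW, ExpressionMatrix, align_metadata

log = logging.getLogger(__name__)

_MTX = "matrix.mtx"
_GENES = "genes.tsv"
_BARCODES = "barcodes.tsv"
_META = "metadata.tsv"
_DENSE = "matrix.tsv"


def read_matrix_bundle(path) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Read a bundle directory into an aligned (matrix, metadata) pair."""
    path = Path(path)
    if (path / _MTX).exists():
        values = np.asarray(spio.mmread(path / _MTX).todense())
        genes = _read_ids(path / _GENES)
        cells = _read_ids(path / _BARCODES)
    elif (path / _DENSE).exists():
        df = pd.read_csv(path / _DENSE, sep="\t", index_col=0)
        values = df.to_numpy()
        genes = df.index.astype(str).to_numpy()
        cells = df.columns.astype(str).to_numpy()
    else:
        raise FileNotFoundError(f"no {_MTX} or {_DENSE} under {path}")
    if values.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {values.shape} inconsistent with "
            f"{len(genes)} genes / {len(cells)} cells"
        )
    layer = RAW if np.array_equal(values, np.floor(values)) else LOGNORM
    if layer == RAW:
        values = values.astype(np.int32)
    m = ExpressionMatrix(values, genes, cells, layer=layer)
    meta = pd.read_csv(path / _META, sep="\t", dtype=str)
    meta = align_metadata(meta, m)
    return m, meta


def write_matrix_bundle(m: ExpressionMatrix, meta: pd.DataFrame, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(path / _MTX, sparse.csr_matrix(m.values))
    _write_ids(path / _GENES, m.gene_ids)
    _write_ids(path / _BARCODES, m.cell_ids)
    meta.to_csv(path / _META, sep="\t", index=False)


def _read_ids(p: Path) -> np.ndarray:
    return np.array(p.read_text().split(), dtype=object)


def _write_ids(p: Path, ids) -> None:
    p.write_text("\n".join(map(str, ids)) + "\n")


# ---------------------------------------------------------------------------
@dataclass
class QCReport:
    """Per-cell QC record plus the thresholds that produced it."""

    table: pd.DataFrame  # cell_id, genes_detected, total_counts, kept
    min_genes: int
    min_counts: int

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())


def qc_filter(
    m: ExpressionMatrix, min_genes: int = 1000, min_counts: int = 10000
) -> tuple[ExpressionMatrix, QCReport]:
    """Drop cells below detection/count thresholds; genes are untouched.

    The report lists every input cell with its ``kept`` flag, so filtering is
    auditable after the fact. Idempotent for fixed thresholds.
    """
    if min_genes < 0 or min_counts < 0:
        raise ValueError("QC thresholds must be non-negative")
    if m.layer != RAW:
        raise ValueError("QC operates on raw counts")
    detected = (m.values > 0).sum(axis=0)
    totals = m.values.sum(axis=0)
    kept = (detected >= min_genes) & (totals >= min_counts)
    report = QCReport(
        pd.DataFrame(
            {
                "cell_id": m.cell_ids,
                "genes_detected": detected.astype(int),
                "total_counts": totals.astype(np.int64),
                "kept": kept,
            }
        ),
        min_genes,
        min_counts,
    )
    log.info(
        "qc_filter: kept %d/%d cells (min_genes=%d, min_counts=%d)",
        kept.sum(), m.n_cells, min_genes, min_counts,
    )
    return m.subset_cells(kept), report


def normalize_log(m: ExpressionMatrix, scale: float = 1e5) -> ExpressionMatrix:
    """Per-cell total-count scaling to ``scale`` followed by log2(x+1).

    Zero-count cells are an error: QC must remove them first.
    """
    if m.layer != RAW:
        raise ValueError("normalize_log expects the raw layer")
    if scale <= 0:
        raise ValueError("scale must be positive")
    totals = m.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero counts (run qc_filter first): "
            f"{list(m.cell_ids[zero[:5]])}"
        )
    values = np.log2(m.values * (scale / totals)[None, :] + 1.0)
    return ExpressionMatrix(values, m.gene_ids, m.cell_ids, layer=LOGNORM)


def expression_fraction(m: ExpressionMatrix, gene: str, cells=None) -> float:
    """Fraction of (a subset of) cells with non-zero expression of ``gene``."""
    v = m.gene_values(gene)
    if cells is not None:
        v = v[m.cell_mask(cells)]
    if v.size == 0:
        raise ValueError("empty cell subset")
    return float((v > 0).mean())


# ---------------------------------------------------------------------------
def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene-set file: name <tab> description <tab> gene...; returns
    name -> unique gene list (order preserved)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, genes = parts[0], parts[2:]
        sets[name] = list(dict.fromkeys(g for g in genes if g))
    return sets


def read_gene_list(path) -> list[str]:
    """One gene per line (first whitespace-separated token)."""
    return [
        ln.split()[0]
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
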