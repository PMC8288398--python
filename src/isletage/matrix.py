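"""Core in-memory containers: the expression matrix and per-cell metadata.

The matrix is stored genes x cells (the orientation UMI-count bundles are
written in), dense, with a ``layer`` tag distinguishing raw integer counts
from log-normalized values. Metadata is a plain pandas DataFrame with a fixed
column contract (see :data:`META_COLUMNS`), one row per cell, aligned to the
matrix column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RAW = "raw"
LOGNORM = "lognorm"

#: required metadata columns; ``cell_type`` may be absent until annotation.
META_COLUMNS = ("cell_id", "donor_id", "age_group", "sex")
AGE_GROUPS = ("young", "old")
SEXES = ("F", "M")


@dataclass
class ExpressionMatrix:
    """Genes x cells expression values with aligned ID vectors.

    Parameters
    ----------
    values
        2-D array, rows are genes, columns are cells. Integer-valued when
        ``layer == "raw"``.
    gene_ids, cell_ids
        Unique ordered string identifiers for rows / columns.
    layer
        Either ``"raw"`` (UMI counts) or ``"lognorm"`` (per-cell scaled,
        log2(x+1) transformed values).
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    layer: str = RAW
    _gene_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (genes x cells)")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene IDs")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell IDs")
        if self.layer not in (RAW, LOGNORM):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.layer == RAW:
            if np.issubdtype(self.values.dtype, np.floating) and not np.array_equal(
                self.values, np.floor(self.values)
            ):
                raise ValueError("raw layer must be integer-valued")
            if self.values.size and self.values.min() < 0:
                raise ValueError("raw counts must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic introspection -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    # -- subsetting ----------------------------------------------------------
    def cell_mask(self, cells: Sequence[str] | np.ndarray) -> np.ndarray:
        """Boolean mask over columns for a cell-id list or boolean mask."""
        cells = np.asarray(cells)
        if cells.dtype == bool:
            if cells.shape != (self.n_cells,):
                raise ValueError("boolean cell mask has wrong length")
            return cells
        wanted = set(cells)
        missing = wanted - set(self.cell_ids)
        if missing:
            raise KeyError(f"cells not in matrix: {sorted(missing)[:5]}")
        return np.fromiter((c in wanted for c in self.cell_ids), bool, self.n_cells)

    def subset_cells(self, cells) -> "ExpressionMatrix":
        mask = self.cell_mask(cells)
        return replace(
            self, values=self.values[:, mask], cell_ids=self.cell_ids[mask]
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        idx = np.array([self.gene_index(g) for g in genes], dtype=int)
        return replace(
            self, values=self.values[idx], gene_ids=self.gene_ids[idx]
        )

    def to_anndata(self, meta: pd.DataFrame | None = None):
        """Cells x genes AnnData view, for interop with scanpy-style tools."""
        import anndata as ad

        obs = None
        if meta is not None:
            validate_metadata(meta, self.cell_ids)
            obs = meta.set_index(meta["cell_id"].astype(str))
        return ad.AnnData(
            X=np.asarray(self.values.T, dtype=np.float32),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )


def validate_metadata(meta: pd.DataFrame, cell_ids: Sequence[str]) -> None:
    """Check the metadata contract against a matrix's cell IDs.

    Raises ``ValueError`` naming offending cells/columns.
    """
    for col in META_COLUMNS:
        if col not in meta.columns:
            raise ValueError(f"metadata missing column {col!r}")
    if meta["cell_id"].duplicated().any():
        dup = meta.loc[meta["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValueError(f"duplicate metadata cell_id {dup!r}")
    missing = [c for c in cell_ids if c not in set(meta["cell_id"])]
    if missing:
        raise ValueError(f"cells missing from metadata: {missing[:5]}")
    bad_age = set(meta["age_group"]) - set(AGE_GROUPS)
    if bad_age or meta["age_group"].isna().any():
        raise ValueError(f"invalid age_group values: {sorted(map(str, bad_age))}")
    bad_sex = set(meta["sex"]) - set(SEXES)
    if bad_sex or meta["sex"].isna().any():
        raise ValueError(f"invalid sex values: {sorted(map(str, bad_sex))}")


def align_metadata(meta: pd.DataFrame, m: ExpressionMatrix) -> pd.DataFrame:
    """Return metadata reordered to the matrix column order."""
    validate_metadata(meta, m.cell_ids)
    meta = meta.set_index("cell_id", drop=False)
    return meta.loc[list(m.cell_ids)].reset_index(drop=True)
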