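"""Cell-to-cell transcriptional noise per cell type.

The statistic: restrict to genes expressed in at least ``frac_min`` of the
type's cells, compute the mean log-normalized profile ("centroid") per
(cell type, age group), and measure each cell's Euclidean distance to its
own group's centroid, divided by sqrt(number of genes used) so the value is
stable under gene-subset size. Centroids are per age group on purpose: mean
aging shifts (DEGs) would otherwise masquerade as noise — the statistic is
meant to isolate dispersion around the group mean. Old-vs-young noise is
compared with a Welch two-tailed t-test per cell type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LOGNORM, ExpressionMatrix
from .stats import bh_fdr, pearson_vs_vector, welch_t


@dataclass
class NoiseVector:
    """Per-cell noise values for one cell type plus the recipe that made
    them (gene subset, per-group centroid definition)."""

    values: pd.Series  # cell_id -> noise
    cell_type: str
    genes_used: list[str]
    age_groups: pd.Series  # cell_id -> age_group
    metric: str = "euclidean"


def transcriptional_noise(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    frac_min: float = 0.10,
    metric: str = "euclidean",
) -> NoiseVector:
    """Distance of each cell of ``cell_type`` to its (type, age group)
    centroid over the expressed-gene subset.

    ``metric`` is ``"euclidean"`` (default; scaled by 1/sqrt(n_genes)) or
    ``"pearson"`` (1 - Pearson correlation to the centroid).
    """
    if m.layer != LOGNORM:
        raise ValueError("transcriptional_noise expects log-normalized values")
    if metric not in ("euclidean", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    meta = meta.set_index("cell_id", drop=False).loc[list(m.cell_ids)]
    mask = (meta["cell_type"] == cell_type).to_numpy()
    if mask.sum() < 2:
        raise ValueError(f"too few {cell_type} cells")
    sub = m.values[:, mask]
    ages = meta["age_group"].to_numpy()[mask]
    ids = m.cell_ids[mask]

    expressed = (sub > 0).mean(axis=1) >= frac_min
    if not expressed.any():
        raise ValueError("empty gene subset at this frac_min")
    sub = sub[expressed]
    genes_used = list(m.gene_ids[expressed])

    noise = np.empty(mask.sum())
    for grp in np.unique(ages):
        cols = ages == grp
        if cols.sum() < 2:
            raise ValueError(f"age group {grp!r} has < 2 {cell_type} cells")
        centroid = sub[:, cols].mean(axis=1, keepdims=True)
        dev = sub[:, cols] - centroid
        if metric == "euclidean":
            noise[cols] = np.sqrt((dev**2).mean(axis=0))
        else:
            cnorm = np.linalg.norm(centroid - centroid.mean())
            xc = sub[:, cols] - sub[:, cols].mean(axis=0, keepdims=True)
            cc = (centroid - centroid.mean()).ravel()
            denom = np.linalg.norm(xc, axis=0) * cnorm
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xc.T @ cc) / denom
            noise[cols] = 1.0 - np.nan_to_num(r, nan=0.0)
    return NoiseVector(
        pd.Series(noise, index=pd.Index(ids, name="cell_id")),
        cell_type,
        genes_used,
        pd.Series(ages, index=pd.Index(ids, name="cell_id")),
        metric,
    )


def compare_noise(noise: NoiseVector) -> tuple[float, float, dict[str, float]]:
    """Welch two-tailed t-test of per-cell noise, old vs young.

    Returns ``(t, p, group_means)``; t > 0 means old cells are noisier.
    """
    old = noise.values[noise.age_groups == "old"].to_numpy()
    young = noise.values[noise.age_groups == "young"].to_numpy()
    if old.size < 2 or young.size < 2:
        raise ValueError("both age groups need >= 2 cells")
    t, p = welch_t(old, young)
    return t, p, {"old": float(old.mean()), "young": float(young.mean())}


def noise_correlated_genes(
    m: ExpressionMatrix,
    noise: NoiseVector,
    r_min: float = 0.6,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Genes whose expression tracks transcriptional noise across cells.

    Pearson r of each gene's log-normalized expression against the per-cell
    noise value, two-sided p, BH-FDR; ``passes`` requires r > ``r_min``
    (positive correlation only) and FDR <= ``fdr_max``. Genes constant
    across the analyzed cells are reported with ``defined = False``.
    """
    cells = list(noise.values.index)
    sub = m.subset_cells(cells)
    y = noise.values.loc[list(sub.cell_ids)].to_numpy()
    r, p, defined = pearson_vs_vector(sub.values, y)
    fdr = bh_fdr(p)
    passes = defined & (r > r_min) & (fdr <= fdr_max)
    return pd.DataFrame(
        {
            "gene": sub.gene_ids,
            "r": r,
            "p": p,
            "fdr": fdr,
            "defined": defined,
            "passes": passes,
        }
    )


def bin_cells_by_noise(noise: NoiseVector, n_bins: int) -> pd.Series:
    """Rank cells by noise within each age group and split into near-equal
    bins (sizes differ by at most one; earlier bins take the remainder).

    Returns cell_id -> bin index (0-based, ordered low to high noise within
    each age group); bin-mean noise is non-decreasing across bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > len(noise.values):
        raise ValueError("more bins than cells")
    out = {}
    for grp in np.unique(noise.age_groups):
        vals = noise.values[noise.age_groups == grp]
        order = vals.sort_values(kind="mergesort").index
        splits = np.array_split(np.arange(len(order)), n_bins)
        for b, idxs in enumerate(splits):
            for i in idxs:
                out[order[i]] = b
    return pd.Series(out, name="noise_bin").reindex(noise.values.index)
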