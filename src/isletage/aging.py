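"""PCA aging axis: find the principal component that separates young from
old cells of one type consistently across donors, define young-like /
old-like cell states along it, and call aging-associated DEGs.

The procedure mirrors the age-separating-PC idea: donor batch variation
spreads over many components, but only a component driven by age separates
*every* donor's cells to its age group's side. Consistency is judged at the
donor level (donor median scores) because age is constant within a donor, so
donors — not cells — are the honest replication unit. When no component is
fully consistent (e.g. delta/PP cells, or no aging signal), the axis is
``None`` rather than forced.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .matrix import LOGNORM, ExpressionMatrix
from .stats import bh_fdr, group_log2fc, mannwhitney_auc, rank_sum_genes


@dataclass
class PCAResult:
    scores: np.ndarray  # cells x components
    loadings: np.ndarray  # genes x components, orthonormal columns
    variance_explained: np.ndarray
    cell_ids: np.ndarray
    gene_ids: np.ndarray


@dataclass
class AgingAxis:
    cell_type: str
    pc_index: int  # 1-based
    orientation: int  # +1/-1; oriented scores put old cells high
    scores: pd.Series  # cell_id -> oriented score
    auc: float  # old-vs-young separation, in [0.5, 1] after orientation
    donor_medians: pd.DataFrame  # donor_id, age_group, median_score, consistent
    loading: pd.Series  # gene -> oriented loading


def fit_pca(
    m: ExpressionMatrix,
    cells=None,
    n_components: int = 10,
    seed: int = 0,
    scale: bool = False,
) -> PCAResult:
    """PCA over cells (genes centered; optionally unit-scaled)."""
    if m.layer != LOGNORM:
        raise ValueError("fit_pca expects log-normalized values")
    sub = m if cells is None else m.subset_cells(cells)
    if n_components > min(sub.n_cells, sub.n_genes):
        raise ValueError("n_components exceeds matrix rank bound")
    x = np.asarray(sub.values.T, dtype=np.float64)  # cells x genes
    if scale:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, random_state=seed)
    scores = pca.fit_transform(x)
    return PCAResult(
        scores=scores,
        loadings=pca.components_.T,
        variance_explained=pca.explained_variance_ratio_,
        cell_ids=sub.cell_ids,
        gene_ids=sub.gene_ids,
    )


def select_age_pc(
    pca: PCAResult,
    meta: pd.DataFrame,
    cell_type: str = "",
    max_pc: int = 10,
) -> AgingAxis | None:
    """Pick the age-separating component, if any.

    For each component up to ``max_pc``: orient so old cells score higher,
    compute the cell-level old-vs-young AUC, and check donor consistency —
    every donor's median score must fall on its age group's side of the
    midpoint between the two age-group medians. The component with the
    highest AUC among fully consistent ones is returned; ``None`` when no
    component is consistent.
    """
    meta = meta.set_index("cell_id", drop=False).loc[list(pca.cell_ids)]
    age = meta["age_group"].to_numpy()
    donors = meta["donor_id"].to_numpy()
    old = age == "old"
    if old.all() or not old.any():
        raise ValueError("both age groups required")
    for grp in ("young", "old"):
        if len(set(donors[age == grp])) < 2:
            warnings.warn(
                f"only one {grp} donor: donor consistency is degenerate",
                stacklevel=2,
            )
    max_pc = min(max_pc, pca.scores.shape[1])
    best = None
    for k in range(max_pc):
        s = pca.scores[:, k].copy()
        orient = 1
        if s[old].mean() < s[~old].mean():
            s, orient = -s, -1
        med_old = np.median(s[old])
        med_young = np.median(s[~old])
        midpoint = 0.5 * (med_old + med_young)
        rows = []
        consistent = True
        for d in pd.unique(donors):
            dm = donors == d
            med = np.median(s[dm])
            is_old = age[dm][0] == "old"
            ok = med > midpoint if is_old else med < midpoint
            consistent &= bool(ok)
            rows.append(
                {"donor_id": d, "age_group": "old" if is_old else "young",
                 "median_score": med, "consistent": bool(ok)}
            )
        if not consistent:
            continue
        auc = mannwhitney_auc(s[old], s[~old])
        if best is None or auc > best.auc:
            best = AgingAxis(
                cell_type=cell_type,
                pc_index=k + 1,
                orientation=orient,
                scores=pd.Series(s, index=pd.Index(pca.cell_ids, name="cell_id")),
                auc=auc,
                donor_medians=pd.DataFrame(rows),
                loading=pd.Series(orient * pca.loadings[:, k],
                                  index=pd.Index(pca.gene_ids, name="gene")),
            )
    return best


def assign_age_states(axis: AgingAxis, meta: pd.DataFrame) -> pd.Series:
    """young-like / old-like / excluded states along the axis.

    Threshold = midpoint of the two age-group median scores. Old-donor cells
    above it are "old-like"; young-donor cells below it are "young-like";
    everything else is "excluded" — a cell can never be assigned against its
    donor's age group.
    """
    meta = meta.set_index("cell_id", drop=False).loc[list(axis.scores.index)]
    age = meta["age_group"].to_numpy()
    s = axis.scores.to_numpy()
    old = age == "old"
    thr = 0.5 * (np.median(s[old]) + np.median(s[~old]))
    state = np.where(
        old & (s > thr), "old-like", np.where(~old & (s < thr), "young-like", "excluded")
    )
    return pd.Series(state, index=axis.scores.index, name="age_state")


def call_degs(
    m: ExpressionMatrix,
    cells_a,
    cells_b,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon + BH DEG table for group A (e.g. old-like) vs
    group B (young-like); log2FC = mean(A) - mean(B) on log2 values."""
    if m.layer != LOGNORM:
        raise ValueError("call_degs expects log-normalized values")
    xa = m.values[:, m.cell_mask(cells_a)]
    xb = m.values[:, m.cell_mask(cells_b)]
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("both groups need >= 2 cells")
    p = rank_sum_genes(xa, xb)
    lfc = group_log2fc(xa, xb)
    fdr = bh_fdr(p)
    keep = (np.abs(lfc) >= lfc_min) & (fdr <= fdr_max)
    tab = pd.DataFrame(
        {
            "gene": m.gene_ids[keep],
            "log2fc": lfc[keep],
            "p": p[keep],
            "fdr": fdr[keep],
            "direction": np.where(lfc[keep] > 0, "up", "down"),
        }
    )
    return tab.sort_values("log2fc", ascending=False, ignore_index=True)


def regress_out_detected(
    m: ExpressionMatrix, groups: np.ndarray | None = None
) -> ExpressionMatrix:
    """Residualize each gene against per-cell global covariates.

    The per-cell mean log-normalized value and detected-gene count are the
    dominant global covariates of scRNA-seq profiles (the classic
    "complexity" PC1); removing them before PCA keeps biological contrasts
    from rotating into that mode. When ``groups`` (donor labels) is given,
    the covariates are centered within each group first: only within-donor
    complexity variance is removed, while between-donor differences — an
    aging program that genuinely shifts the covariates, or a single donor's
    batch shift — are left for the donor-consistency filter to judge.
    """
    x = np.asarray(m.values, dtype=np.float64)
    covs = np.stack([x.mean(axis=0), (x > 0).sum(axis=0).astype(float)], axis=1)
    if groups is None:
        covs = covs - covs.mean(axis=0)
    else:
        groups = np.asarray(groups)
        for g in np.unique(groups):
            sel = groups == g
            covs[sel] -= covs[sel].mean(axis=0)
    if not covs.any():
        return m
    coef, *_ = np.linalg.lstsq(covs, x.T, rcond=None)
    resid = x - (covs @ coef).T
    return ExpressionMatrix(resid, m.gene_ids, m.cell_ids, layer=LOGNORM)


def aging_axis_degs(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    n_components: int = 10,
    max_pc: int = 10,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    regress_detected: bool = True,
    seed: int = 0,
) -> tuple[AgingAxis | None, pd.Series | None, pd.DataFrame | None]:
    """Full per-type procedure: detected-count regression -> PCA -> axis
    selection -> state assignment -> genome-wide DEG calling. Returns
    (axis, states, degs), all None-propagating when no consistent axis
    exists. DEGs are always tested on the unregressed values."""
    sel = meta[meta["cell_type"] == cell_type]
    sub = m.subset_cells(list(sel["cell_id"]))
    if regress_detected:
        donors = sel.set_index("cell_id").loc[list(sub.cell_ids), "donor_id"]
        sub = regress_out_detected(sub, groups=donors.to_numpy())
    pca = fit_pca(sub, n_components=n_components, seed=seed)
    axis = select_age_pc(pca, meta, cell_type=cell_type, max_pc=max_pc)
    if axis is None:
        return None, None, None
    states = assign_age_states(axis, meta)
    old_like = states.index[states == "old-like"]
    young_like = states.index[states == "young-like"]
    if len(old_like) < 2 or len(young_like) < 2:
        return axis, states, None
    degs = call_degs(m, list(old_like), list(young_like),
                     lfc_min=lfc_min, fdr_max=fdr_max)
    return axis, states, degs


def direct_degs(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """DEGs from directly comparing all old vs all young cells of a type."""
    sel = meta[meta["cell_type"] == cell_type]
    old = sel.loc[sel["age_group"] == "old", "cell_id"]
    young = sel.loc[sel["age_group"] == "young", "cell_id"]
    return call_degs(m, list(old), list(young), lfc_min=lfc_min, fdr_max=fdr_max)


def overlap_sets(list_a, list_b) -> tuple[int, int, int, list[str]]:
    """Venn counts: (A-only, shared, B-only, shared gene list)."""
    a, b = set(list_a), set(list_b)
    shared = sorted(a & b)
    return len(a - b), len(shared), len(b - a), shared


def stratified_degs(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    cell_type: str,
    stratum_col: str = "sex",
    **kwargs,
) -> dict[str, pd.DataFrame | None]:
    """Run the full axis -> assign -> DEG pipeline within each stratum
    (default: per sex). Strata missing an age group are skipped with a
    warning and reported as None."""
    out: dict[str, pd.DataFrame | None] = {}
    for level in sorted(meta[stratum_col].dropna().unique()):
        sub_meta = meta[meta[stratum_col] == level].reset_index(drop=True)
        sel = sub_meta[sub_meta["cell_type"] == cell_type]
        if sel["age_group"].nunique() < 2:
            warnings.warn(
                f"stratum {stratum_col}={level!r} lacks an age group; skipped",
                stacklevel=2,
            )
            out[level] = None
            continue
        sub_m = m.subset_cells(list(sub_meta["cell_id"]))
        _, _, degs = aging_axis_degs(sub_m, sub_meta, cell_type, **kwargs)
        out[level] = degs
    return out
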