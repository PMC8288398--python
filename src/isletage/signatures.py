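"""Gene-set level statistics.

Group tests for pathway sets (UPR branches, ERAD, NRF2, apoptosis panels),
single-gene group statistics (aging markers such as CDKN1A/CDKN2A, IAPP,
DDIT3), per-type old-vs-young fold-change matrices for curated lists
(GenAge/SASP-style), hypergeometric overlap enrichment and a gene-permutation
GSEA. All curated lists are user inputs (TSV/GMT); nothing is bundled beyond
illustrative fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aging import call_degs
from .matrix import LOGNORM, ExpressionMatrix
from .stats import bh_fdr, hypergeom_sf, welch_t


@dataclass
class GeneSet:
    name: str
    genes: list[str]
    source: str = ""

    def __post_init__(self):
        self.genes = list(dict.fromkeys(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class SetScoreResult:
    set_name: str
    scores: pd.Series  # cell_id -> mean log-normalized expression over set
    mean_a: float
    mean_b: float
    t: float
    p: float
    genes_used: list[str]


def geneset_group_test(
    m: ExpressionMatrix, geneset: GeneSet, cells_a, cells_b
) -> SetScoreResult:
    """Per-cell set score (mean log-normalized expression over the set's
    genes present in the matrix) compared between two cell groups with a
    Welch two-tailed t-test."""
    if m.layer != LOGNORM:
        raise ValueError("geneset_group_test expects log-normalized values")
    present = [g for g in geneset.genes if m.has_gene(g)]
    if not present:
        raise ValueError(f"no genes of set {geneset.name!r} in matrix")
    sub = m.subset_genes(present)
    score = sub.values.mean(axis=0)
    scores = pd.Series(score, index=pd.Index(m.cell_ids, name="cell_id"))
    a = score[m.cell_mask(cells_a)]
    b = score[m.cell_mask(cells_b)]
    t, p = welch_t(a, b)
    return SetScoreResult(
        geneset.name, scores, float(a.mean()), float(b.mean()), t, p, present
    )


def gene_group_stats(
    m: ExpressionMatrix, gene: str, cells_a, cells_b
) -> tuple[float, float, float]:
    """(log2FC, Welch t, two-tailed p) of one gene between two groups."""
    if m.layer != LOGNORM:
        raise ValueError("gene_group_stats expects log-normalized values")
    v = m.gene_values(gene)
    a = v[m.cell_mask(cells_a)]
    b = v[m.cell_mask(cells_b)]
    t, p = welch_t(a, b)
    return float(a.mean() - b.mean()), t, p


def foldchange_matrix(
    m: ExpressionMatrix,
    genes: list[str],
    meta: pd.DataFrame,
    types: list[str] | None = None,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
) -> pd.DataFrame:
    """Genes x cell types old-vs-young log2FC table for a curated list,
    masked to genes called differential in at least one type (with the DEG
    defaults). Rows are a subset of the input list; empty when nothing is
    differential."""
    meta = meta.set_index("cell_id", drop=False).loc[list(m.cell_ids)]
    if types is None:
        types = sorted(meta["cell_type"].dropna().unique())
    present = [g for g in genes if m.has_gene(g)]
    sub = m.subset_genes(present)
    fc = {}
    differential = pd.Series(False, index=present)
    for t in types:
        sel = meta["cell_type"] == t
        old = meta.loc[sel & (meta["age_group"] == "old"), "cell_id"]
        young = meta.loc[sel & (meta["age_group"] == "young"), "cell_id"]
        if len(old) < 2 or len(young) < 2:
            raise ValueError(f"type {t!r} lacks an age group")
        xa = sub.values[:, sub.cell_mask(list(old))]
        xb = sub.values[:, sub.cell_mask(list(young))]
        fc[t] = xa.mean(axis=1) - xb.mean(axis=1)
        degs = call_degs(sub, list(old), list(young),
                         lfc_min=lfc_min, fdr_max=fdr_max)
        differential.loc[differential.index.isin(degs["gene"])] = True
    out = pd.DataFrame(fc, index=pd.Index(present, name="gene"))
    return out.loc[differential]


def hypergeom_enrichment(
    hits, geneset, universe
) -> tuple[int, float]:
    """Upper-tail hypergeometric overlap test of ``hits`` against a gene set
    within ``universe``. Returns (overlap, p)."""
    uni = set(universe)
    hits = set(hits)
    gs = set(geneset.genes if isinstance(geneset, GeneSet) else geneset)
    if not hits <= uni or not gs <= uni:
        raise ValueError("hits and set must be subsets of the universe")
    overlap = len(hits & gs)
    p = hypergeom_sf(overlap, len(uni), len(gs), len(hits))
    return overlap, p


# ---------------------------------------------------------------------------
def _running_es(order: np.ndarray, weights: np.ndarray, in_set: np.ndarray) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score for a ranked list.

    ``order`` ranks genes best-to-worst; ``weights`` = |ranking score|;
    ``in_set`` flags membership. ES is the maximum deviation (signed) of the
    running sum: hits step up by weight / total-set-weight, misses step down
    by 1 / (N - K).
    """
    w = weights[order]
    s = in_set[order]
    wsum = w[s].sum()
    n_miss = len(order) - s.sum()
    if wsum == 0 or n_miss == 0:
        # degenerate: all weight outside the set or set == universe
        hit = np.where(s, 1.0 / max(s.sum(), 1), 0.0)
    else:
        hit = np.where(s, w / wsum, 0.0)
    miss = np.where(~s, 1.0 / max(n_miss, 1), 0.0)
    running = np.cumsum(hit - miss)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea(
    ranking: pd.Series,
    genesets: list[GeneSet] | GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-permutation null.

    ``ranking`` maps gene -> signed score (e.g. log2FC of a contrast),
    ranked descending internally; weights are |score|. For each set: ES from
    the weighted running sum, null ES from ``n_perm`` random same-size gene
    sets, NES = ES / mean(|null ES| of the same sign), empirical nominal p
    among same-sign nulls, and BH q across the tested sets.
    """
    if isinstance(genesets, GeneSet):
        genesets = [genesets]
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    genes = np.asarray(ranking.index, dtype=object)
    scores = ranking.to_numpy(dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    weights = np.abs(scores)
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows = []
    for gs in genesets:
        members = [gene_pos[g] for g in gs.genes if g in gene_pos]
        if not members:
            raise ValueError(f"set {gs.name!r} does not intersect the ranking")
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[members] = True
        es = _running_es(order, weights, in_set)
        k = len(members)
        null = np.empty(n_perm)
        for i in range(n_perm):
            perm = np.zeros(len(genes), dtype=bool)
            perm[rng.choice(len(genes), size=k, replace=False)] = True
            null[i] = _running_es(order, weights, perm)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same).mean() if same.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else 0.0
        p = (1 + (np.abs(same) >= abs(es)).sum()) / (1 + same.size)
        rows.append({"set": gs.name, "size": k, "es": es, "nes": nes, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
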