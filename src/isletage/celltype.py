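"""Clustering, marker-based annotation and marker-gene discovery.

Cells are embedded with PCA, connected in a k-nearest-neighbour graph and
partitioned by greedy modularity (Clauset-Newman-Moore, via igraph), i.e.
unsupervised: the number of clusters is not fixed in advance. Clusters are
annotated to endocrine types from canonical hormone markers (GCG/INS/SST/PPY
by default) by z-scored mean marker expression, with a tie margin below which
a cluster stays "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph

from .matrix import LOGNORM, ExpressionMatrix
from .stats import bh_fdr, group_log2fc, rank_sum_genes

#: canonical marker -> type mapping of the islet endocrine compartment
CANONICAL_MARKERS = {"GCG": "alpha", "INS": "beta", "SST": "delta", "PPY": "pp"}


@dataclass
class ClusterAssignment:
    labels: pd.Series  # cell_id -> contiguous int label, largest cluster = 0
    n_pcs: int
    params: dict

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def cluster_cells(
    m: ExpressionMatrix,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    resolution: float = 0.1,
    seed: int = 0,
) -> ClusterAssignment:
    """PCA -> symmetric kNN graph (Euclidean) -> modularity communities.

    Modularity is optimized with the Leiden algorithm (greedy local moves
    with refinement), deterministic given the seed, which also controls the
    randomized PCA solver. The default ``resolution`` is low because this
    stage targets major-population granularity (the endocrine cell types);
    finer within-type states (e.g. aging states) are resolved downstream.
    Labels are renumbered by decreasing cluster size, ties broken by the
    lowest member cell index.
    """
    if m.layer != LOGNORM:
        raise ValueError("cluster_cells expects log-normalized values")
    if m.n_cells < 2:
        raise ValueError("need at least 2 cells")
    if n_pcs >= min(m.n_cells, m.n_genes):
        raise ValueError("n_pcs must be below min(n_genes, n_cells)")
    if k_neighbors >= m.n_cells:
        raise ValueError("k_neighbors must be below the number of cells")

    x = np.asarray(m.values.T, dtype=np.float64)  # cells x genes
    scores = PCA(n_components=n_pcs, random_state=seed).fit_transform(x)
    adj = kneighbors_graph(scores, n_neighbors=k_neighbors, mode="connectivity")
    adj = adj.maximum(adj.T).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(adj.row, adj.col) if i < j]
    graph = ig.Graph(n=m.n_cells, edges=edges)
    partition = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    raw = np.asarray(partition.membership)

    # relabel: 0 = largest cluster; ties by lowest member index
    order = sorted(
        range(raw.max() + 1),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = pd.Series(
        [remap[c] for c in raw], index=pd.Index(m.cell_ids, name="cell_id")
    )
    return ClusterAssignment(
        labels, n_pcs,
        {"k_neighbors": k_neighbors, "resolution": resolution, "seed": seed},
    )


def annotate_types(
    m: ExpressionMatrix,
    clusters: ClusterAssignment,
    marker_map: dict[str, str] | None = None,
    tie_margin: float = 0.25,
) -> pd.Series:
    """Assign each cluster the type whose marker z-score is highest.

    For each marker gene, mean log-normalized expression per cluster is
    z-scored *across clusters* (removing scale differences between
    hormones); a cluster whose top-vs-second margin is below ``tie_margin``
    becomes ``"unassigned"``. Returns a cell_id -> cell_type Series.
    """
    marker_map = dict(marker_map or CANONICAL_MARKERS)
    for g in marker_map:
        if not m.has_gene(g):
            raise KeyError(f"marker gene {g!r} absent from matrix")
    label_of = clusters.labels
    n_clusters = clusters.n_clusters
    means = np.zeros((len(marker_map), n_clusters))
    marker_genes = list(marker_map)
    lab_arr = label_of.loc[list(m.cell_ids)].to_numpy()
    for c in range(n_clusters):
        cols = lab_arr == c
        for gi, g in enumerate(marker_genes):
            means[gi, c] = m.gene_values(g)[cols].mean()
    sd = means.std(axis=1, keepdims=True)
    centered = means - means.mean(axis=1, keepdims=True)
    z = np.divide(centered, sd, out=np.zeros_like(centered), where=sd > 0)

    # per-cluster type scores: mean z over that type's markers
    types = sorted(set(marker_map.values()))
    type_scores = np.stack(
        [
            z[[i for i, g in enumerate(marker_genes) if marker_map[g] == t]].mean(axis=0)
            for t in types
        ]
    )  # types x clusters
    cluster_type = {}
    for c in range(n_clusters):
        col = type_scores[:, c]
        order = np.argsort(col)[::-1]
        margin = col[order[0]] - (col[order[1]] if len(col) > 1 else -np.inf)
        cluster_type[c] = types[order[0]] if margin >= tie_margin else "unassigned"
    return label_of.map(cluster_type).rename("cell_type")


def find_markers(
    m: ExpressionMatrix,
    types: pd.Series,
    lfc_min: float = 0.5,
    fdr_max: float = 0.05,
    frac_min: float = 0.25,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon marker table per cell type.

    ``types`` maps cell_id -> cell_type. Per type, each gene is tested
    against all remaining cells (two-sided rank-sum on log-normalized
    values), BH-corrected across genes, and kept when log2FC >= ``lfc_min``,
    FDR <= ``fdr_max`` and expressed in at least ``frac_min`` of the type's
    cells. Rows sorted by type then descending log2FC.
    """
    if m.layer != LOGNORM:
        raise ValueError("find_markers expects log-normalized values")
    lab = types.loc[list(m.cell_ids)].to_numpy()
    out = []
    utypes = [t for t in pd.unique(lab) if t != "unassigned"]
    if len(utypes) < 2:
        raise ValueError("need at least 2 annotated types")
    for t in utypes:
        mask = lab == t
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"type {t!r} has fewer than 2 cells")
        xa, xb = m.values[:, mask], m.values[:, ~mask]
        p = rank_sum_genes(xa, xb)
        lfc = group_log2fc(xa, xb)
        fdr = bh_fdr(p)
        frac_in = (xa > 0).mean(axis=1)
        frac_out = (xb > 0).mean(axis=1)
        keep = (lfc >= lfc_min) & (fdr <= fdr_max) & (frac_in >= frac_min)
        tab = pd.DataFrame(
            {
                "gene": m.gene_ids[keep],
                "cell_type": t,
                "log2fc": lfc[keep],
                "p": p[keep],
                "fdr": fdr[keep],
                "fraction_in": frac_in[keep],
                "fraction_out": frac_out[keep],
            }
        ).sort_values("log2fc", ascending=False)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
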