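"""Ground-truth recovery benchmarks on the synthetic study design.

Each function simulates the named scenario, runs the corresponding pipeline
stage and measures recovery against the planted truth. The acceptance tests
assert on these quantities and ``scripts/acceptance.py`` reports them; both
recompute everything from scratch at run time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .aging import aging_axis_degs, direct_degs
from .celltype import annotate_types, cluster_cells
from .grn import hub_ranking, infer_network
from .interactions import lr_permutation_test
from .io import normalize_log, qc_filter
from .matrix import ExpressionMatrix
from .noise import compare_noise, noise_correlated_genes, transcriptional_noise
from .simdata import (
    DEFAULT_TFS,
    axis_scenario_config,
    default_config,
    generate_dataset,
    hub_scenario_config,
    lr_null_config,
    null_config,
)


def _prepared(config, seed):
    m, meta, truth = generate_dataset(config, seed=seed)
    mq, _ = qc_filter(m)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    return ln, meta, truth


# -- transcriptional noise ---------------------------------------------------
def noise_pattern_pvalues(seeds) -> dict[str, list[float]]:
    """Old-vs-young noise p-value per cell type on the default design
    (dispersion inflated 1.5x in alpha/beta only), one entry per seed."""
    config = default_config()
    out: dict[str, list[float]] = {t: [] for t in ("alpha", "beta", "delta", "pp")}
    for seed in seeds:
        ln, meta, _ = _prepared(config, seed)
        for t in out:
            nv = transcriptional_noise(ln, meta, t)
            _, p, _ = compare_noise(nv)
            out[t].append(p)
    return out


def noise_null_pvalues(n_seeds: int = 200, base_seed: int = 0) -> np.ndarray:
    """Noise-test p-values on no-inflation simulations (one per seed)."""
    config = null_config()
    ps = []
    for i in range(n_seeds):
        m, meta, _ = generate_dataset(config, seed=base_seed + i)
        ln = normalize_log(m)
        nv = transcriptional_noise(ln, meta, "alpha")
        _, p, _ = compare_noise(nv)
        ps.append(p)
    return np.asarray(ps)


def noise_bruteforce_check(seed: int = 0):
    """Compare the vectorized noise statistic and noise-gene correlations
    with naive per-cell / per-gene loops on a 50-gene x 40-cell dataset.

    Returns (max |noise diff|, max |r diff|, passes flags equal?).
    """
    from scipy import stats as sps

    config = null_config(n_cells=40, n_genes=50)
    m, meta, _ = generate_dataset(config, seed=seed)
    ln = normalize_log(m)
    nv = transcriptional_noise(ln, meta, "alpha", frac_min=0.1)

    # brute force: loop over cells, literal distance to own group centroid
    sub = ln.values
    expressed = (sub > 0).mean(axis=1) >= 0.1
    vals = sub[expressed]
    ages = meta["age_group"].to_numpy()
    brute = np.empty(ln.n_cells)
    for i in range(ln.n_cells):
        grp = ages == ages[i]
        centroid = vals[:, grp].mean(axis=1)
        d = np.sqrt(((vals[:, i] - centroid) ** 2).sum())
        brute[i] = d / np.sqrt(vals.shape[0])
    noise_diff = float(np.abs(nv.values.to_numpy() - brute).max())

    table = noise_correlated_genes(ln, nv).set_index("gene")
    r_diff = 0.0
    passes_equal = True
    for gi, g in enumerate(ln.gene_ids):
        x = ln.values[gi]
        if np.all(x == x[0]):
            passes_equal &= not bool(table.loc[g, "defined"])
            continue
        r, p = sps.pearsonr(x, nv.values.to_numpy())
        r_diff = max(r_diff, abs(r - table.loc[g, "r"]))
        expected_pass = (r > 0.6) and bool(table.loc[g, "fdr"] <= 0.05)
        passes_equal &= expected_pass == bool(table.loc[g, "passes"])
    return noise_diff, r_diff, passes_equal


# -- aging axis --------------------------------------------------------------
def axis_recovery(seed: int) -> dict:
    """Planted beta-program scenario: loading cosine vs the planted log2FC
    direction, DEG precision/recall, assignment rate, delta/PP axis = None."""
    config = axis_scenario_config()
    ln, meta, truth = _prepared(config, seed)
    axis, states, degs = aging_axis_degs(ln, meta, "beta")
    res = {"found": axis is not None, "cosine": 0.0,
           "precision": 0.0, "recall": 0.0, "assigned_frac": 0.0,
           "delta_none": None, "pp_none": None}
    if axis is not None:
        planted = truth.aging_degs.query("cell_type == 'beta'")
        direction = {r["gene"]: r["log2fc"] for _, r in planted.iterrows()}
        vec = np.array([direction.get(g, 0.0) for g in axis.loading.index])
        load = axis.loading.to_numpy()
        res["cosine"] = float(
            abs(load @ vec) / (np.linalg.norm(load) * np.linalg.norm(vec))
        )
        res["assigned_frac"] = float((states != "excluded").mean())
        if degs is not None and len(degs):
            found = set(degs["gene"])
            tset = set(planted["gene"])
            res["precision"] = len(found & tset) / len(found)
            res["recall"] = len(found & tset) / len(tset)
    for t, key in (("delta", "delta_none"), ("pp", "pp_none")):
        a, _, _ = aging_axis_degs(ln, meta, t)
        res[key] = a is None
    return res


def axis_type1_count(n_seeds: int = 100, base_seed: int = 0) -> int:
    """Number of no-aging simulations (with donor batch effects) in which a
    fully donor-consistent component is reported."""
    config = null_config(donor_effect_sd=0.2, n_cells=320, n_genes=600)
    found = 0
    for i in range(n_seeds):
        m, meta, _ = generate_dataset(config, seed=base_seed + i)
        ln = normalize_log(m)
        axis, _, _ = aging_axis_degs(ln, meta, "alpha")
        found += axis is not None
    return found


def axis_direct_concordance(seed: int) -> dict[str, float]:
    """Jaccard of up-regulated DEG sets, axis-based vs direct old-vs-young,
    on the default aging design (alpha and beta)."""
    ln, meta, _ = _prepared(default_config(), seed)
    out = {}
    for t in ("alpha", "beta"):
        axis, _, degs = aging_axis_degs(ln, meta, t)
        if axis is None or degs is None:
            out[t] = 0.0
            continue
        direct = direct_degs(ln, meta, t)
        up_axis = set(degs.loc[degs["direction"] == "up", "gene"])
        up_direct = set(direct.loc[direct["direction"] == "up", "gene"])
        union = up_axis | up_direct
        out[t] = len(up_axis & up_direct) / len(union) if union else 0.0
    return out


def confounded_donor_check(seed: int = 7) -> dict:
    """Synthetic single-confounded-donor fixture: one old donor carries a
    pure batch shift on 30 genes (counts scaled 32x post hoc). The direct
    comparison picks up batch genes; the axis procedure must not report a
    donor-consistent component at all."""
    config = default_config(
        aging_program={}, noise_inflation={}, noise_coupling={}, hub=None,
        n_genes=3000, n_cells_total=2500,
    )
    m, meta, _ = generate_dataset(config, seed=seed)
    means = m.values.mean(axis=1)
    generic = [i for i, g in enumerate(m.gene_ids) if str(g).startswith("G0")]
    batch_idx = sorted(generic, key=lambda i: -means[i])[:30]
    batch_genes = [m.gene_ids[i] for i in batch_idx]
    donor = meta.set_index("cell_id").loc[list(m.cell_ids), "donor_id"]
    cols = np.flatnonzero((donor == "O1").to_numpy())
    vals = m.values.copy()
    vals[np.ix_(batch_idx, cols)] *= 32
    m2 = ExpressionMatrix(vals, m.gene_ids, m.cell_ids, layer="raw")
    mq, _ = qc_filter(m2)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    direct = direct_degs(ln, meta, "alpha")
    up = set(direct.loc[direct["direction"] == "up", "gene"])
    axis, _, degs = aging_axis_degs(ln, meta, "alpha")
    axis_genes = set() if degs is None else set(degs["gene"])
    return {
        "batch_in_direct": len(up & set(batch_genes)),
        "axis_found": axis is not None,
        "batch_in_axis": len(axis_genes & set(batch_genes)),
    }


# -- ligand-receptor ---------------------------------------------------------
def lr_null_fraction(seed: int = 0, n_perm: int = 500) -> tuple[float, int]:
    """Fraction of tested combinations with p < 0.05 on a null simulation
    (~1 000 combinations). Returns (fraction, n_tested)."""
    config = lr_null_config()
    m, meta, _ = generate_dataset(config, seed=seed)
    ln = normalize_log(m)
    pairs = pd.DataFrame(
        [{"ligand": p.ligand, "receptor": p.receptor} for p in config.lr_pairs]
    )
    res = lr_permutation_test(ln, meta, pairs, n_perm=n_perm, seed=seed + 1)
    tested = res[res["tested"]]
    return float((tested["p"] < 0.05).mean()), int(len(tested))


def lr_planted_pvalue(seed: int = 0, n_perm: int = 500) -> float:
    """p-value of the planted TTR->DDR1 (alpha->beta) interaction on a
    reduced default design; the floor is 1/(n_perm+1)."""
    config = default_config(n_cells_total=1200, n_genes=2000)
    m, meta, _ = generate_dataset(config, seed=seed)
    mq, _ = qc_filter(m, min_counts=1000)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    pairs = pd.DataFrame(
        [{"ligand": p.ligand, "receptor": p.receptor} for p in config.lr_pairs]
    )
    res = lr_permutation_test(ln, meta, pairs, n_perm=n_perm, seed=seed + 1)
    row = res[
        (res["ligand"] == "TTR") & (res["receptor"] == "DDR1")
        & (res["sender"] == "alpha") & (res["receiver"] == "beta")
    ]
    return float(row["p"].iloc[0])


# -- regulatory network ------------------------------------------------------
def hub_recovery(seed: int = 5) -> dict:
    """Planted 30-target hub: retained hub edges and hub rank."""
    config = hub_scenario_config()
    m, meta, truth = generate_dataset(config, seed=seed)
    ln = normalize_log(m)
    targets = list(truth.hub_edges["target"])
    decoys = [g for g in ln.gene_ids if str(g).startswith("G0")][:70]
    edges = infer_network(ln, list(DEFAULT_TFS), targets + decoys)
    kept = edges[
        (edges["regulator"] == "HSPA5") & edges["target"].isin(set(targets))
    ]
    ranking = hub_ranking(edges)
    top = ranking["regulator"].iloc[0] if len(ranking) else None
    return {"edges_retained": int(len(kept)), "n_targets": len(targets),
            "top_regulator": top}


# -- cell typing -------------------------------------------------------------
def celltyping_scores(ln=None, meta=None, seed: int = 0,
                      cluster_seed: int = 0) -> dict:
    """Clustering ARI and annotation accuracy vs truth types on the default
    design. Pass a prepared (ln, meta) pair to reuse an existing dataset."""
    if ln is None:
        ln, meta, _ = _prepared(default_config(), seed)
    clusters = cluster_cells(ln, seed=cluster_seed)
    true = meta.set_index("cell_id")["cell_type"]
    ari = adjusted_rand_score(true.loc[clusters.labels.index], clusters.labels)
    types = annotate_types(ln, clusters)
    accuracy = float((types.loc[true.index] == true).mean())
    return {"ari": float(ari), "accuracy": accuracy,
            "n_clusters": clusters.n_clusters}
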