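"""End-to-end orchestration with a config file and a run manifest.

``run_pipeline`` executes: simulate (optional) -> qc -> normalize ->
cluster -> annotate -> markers -> noise -> aging_axis -> signatures ->
interactions -> grn, writing TSV outputs per stage plus ``manifest.json``
(package version, fan-out seeds, parameters, counts in/out). A single
config seed fans out deterministically to per-stage seeds through a fixed
counter scheme, so whole runs reproduce while stages stay independent.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aging import aging_axis_degs, direct_degs, overlap_sets, stratified_degs
from .celltype import CANONICAL_MARKERS, annotate_types, cluster_cells, find_markers
from .grn import hub_ranking, infer_network
from .interactions import lr_permutation_test
from .io import (
    normalize_log,
    qc_filter,
    read_gene_list,
    read_gmt,
    read_matrix_bundle,
    write_matrix_bundle,
)
from .noise import compare_noise, noise_correlated_genes, transcriptional_noise
from .signatures import GeneSet, geneset_group_test
from .simdata import DEFAULT_TFS, SimConfig, generate_dataset, write_truth

STAGES = (
    "simulate", "qc", "normalize", "cluster", "annotate", "markers",
    "noise", "aging_axis", "signatures", "interactions", "grn",
)


@dataclass
class PipelineConfig:
    outdir: str = "results/run"
    seed: int = 0
    # input: either a simulation config or a bundle directory
    simulate: SimConfig | None = None
    input_bundle: str | None = None
    # optional resource files
    marker_map: dict[str, str] = field(default_factory=lambda: dict(CANONICAL_MARKERS))
    gene_sets_gmt: str | None = None
    lr_pairs_tsv: str | None = None
    tf_list_tsv: str | None = None
    # stage parameters
    min_genes: int = 1000
    min_counts: int = 10000
    scale: float = 1e5
    n_pcs: int = 50
    k_neighbors: int = 15
    lfc_min: float = 0.5
    fdr_max: float = 0.05
    frac_min: float = 0.25
    noise_frac_min: float = 0.10
    noise_r_min: float = 0.6
    max_pc: int = 10
    n_perm: int = 500
    lr_frac_min: float = 0.10
    weight_quantile: float = 0.90
    sex_stratified: bool = False

    def validate(self) -> None:
        if self.simulate is None and self.input_bundle is None:
            raise ValueError("config needs either simulate: or input_bundle:")
        for name in ("input_bundle", "gene_sets_gmt", "lr_pairs_tsv", "tf_list_tsv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if d.get("simulate") is not None:
            from .simdata import _config_from_dict

            d["simulate"] = _config_from_dict(d["simulate"])
        return cls(**d)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk).

    Any stage failure raises with the stage name attached; outputs written
    before the failure are retained.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "isletage",
        "version": __version__,
        "seed": config.seed,
        "stages": [],
    }
    current = None
    try:
        # -- simulate / load -------------------------------------------------
        current = "simulate"
        if config.simulate is not None:
            m, meta, truth = generate_dataset(
                config.simulate, seed=stage_seed(config.seed, "simulate")
            )
            write_matrix_bundle(m, meta, out / "bundle")
            write_truth(truth, out / "bundle")
            _record(manifest, "simulate", {"n_genes": m.n_genes}, n_cells=m.n_cells)
        else:
            m, meta = read_matrix_bundle(config.input_bundle)
            _record(manifest, "simulate",
                    {"loaded": str(config.input_bundle)}, n_cells=m.n_cells)

        # -- qc + normalize --------------------------------------------------
        current = "qc"
        m, qc = qc_filter(m, config.min_genes, config.min_counts)
        meta = meta[meta["cell_id"].isin(m.cell_ids)].reset_index(drop=True)
        qc.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        _record(manifest, "qc",
                {"min_genes": config.min_genes, "min_counts": config.min_counts},
                n_cells=m.n_cells)

        current = "normalize"
        ln = normalize_log(m, scale=config.scale)
        _record(manifest, "normalize", {"scale": config.scale}, n_cells=ln.n_cells)

        # -- cluster + annotate + markers ------------------------------------
        current = "cluster"
        clusters = cluster_cells(
            ln, n_pcs=config.n_pcs, k_neighbors=config.k_neighbors,
            seed=stage_seed(config.seed, "cluster"),
        )
        clusters.labels.rename("cluster").to_csv(out / "clusters.tsv", sep="\t")
        _record(manifest, "cluster",
                {"n_pcs": config.n_pcs, "k_neighbors": config.k_neighbors,
                 "n_clusters": clusters.n_clusters}, n_cells=ln.n_cells)

        current = "annotate"
        cell_types = annotate_types(ln, clusters, config.marker_map)
        meta = meta.drop(columns=["cell_type"], errors="ignore").merge(
            cell_types.rename("cell_type").reset_index(), on="cell_id"
        )
        meta.to_csv(out / "metadata_annotated.tsv", sep="\t", index=False)
        counts = meta["cell_type"].value_counts().to_dict()
        _record(manifest, "annotate", {"type_counts": counts}, n_cells=len(meta))

        current = "markers"
        markers = find_markers(
            ln, meta.set_index("cell_id")["cell_type"],
            lfc_min=config.lfc_min, fdr_max=config.fdr_max,
            frac_min=config.frac_min,
        )
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        _record(manifest, "markers", {"n_markers": len(markers)}, n_cells=ln.n_cells)

        types = [
            t for t in sorted(set(meta["cell_type"])) if t != "unassigned"
            and (meta.loc[meta["cell_type"] == t]
                 .groupby("age_group")["cell_id"].count().ge(2).sum() == 2)
        ]

        # -- noise -----------------------------------------------------------
        current = "noise"
        noise_rows, noise_series = [], []
        for t in types:
            nv = transcriptional_noise(ln, meta, t, frac_min=config.noise_frac_min)
            tt, p, means = compare_noise(nv)
            noise_rows.append({"cell_type": t, "t": tt, "p": p, **means})
            noise_series.append(nv.values.rename("noise").to_frame()
                                .assign(cell_type=t))
            genes_tab = noise_correlated_genes(
                ln, nv, r_min=config.noise_r_min, fdr_max=config.fdr_max
            )
            genes_tab[genes_tab["passes"]].to_csv(
                out / f"noise_genes_{t}.tsv", sep="\t", index=False
            )
        pd.concat(noise_series).to_csv(out / "noise_per_cell.tsv", sep="\t")
        noise_table = pd.DataFrame(noise_rows)
        noise_table.to_csv(out / "noise_tests.tsv", sep="\t", index=False)
        _record(manifest, "noise", {"frac_min": config.noise_frac_min},
                n_cells=sum(len(s) for s in noise_series))

        # -- aging axis ------------------------------------------------------
        current = "aging_axis"
        axis_rows, deg_tables = [], {}
        for t in types:
            axis, states, degs = aging_axis_degs(
                ln, meta, t, n_components=config.max_pc, max_pc=config.max_pc,
                lfc_min=config.lfc_min, fdr_max=config.fdr_max,
                seed=stage_seed(config.seed, "aging_axis"),
            )
            if axis is None:
                axis_rows.append({"cell_type": t, "pc_index": None, "auc": None,
                                  "status": "not discriminated"})
                continue
            axis_rows.append({"cell_type": t, "pc_index": axis.pc_index,
                              "auc": axis.auc, "status": "selected"})
            states.rename("age_state").to_csv(
                out / f"age_states_{t}.tsv", sep="\t"
            )
            if degs is not None:
                deg_tables[t] = degs
                degs.to_csv(out / f"degs_axis_{t}.tsv", sep="\t", index=False)
            direct = direct_degs(ln, meta, t, lfc_min=config.lfc_min,
                                 fdr_max=config.fdr_max)
            direct.to_csv(out / f"degs_direct_{t}.tsv", sep="\t", index=False)
            if degs is not None:
                up_axis = degs.loc[degs["direction"] == "up", "gene"]
                up_direct = direct.loc[direct["direction"] == "up", "gene"]
                a_only, shared, b_only, _ = overlap_sets(up_axis, up_direct)
                pd.DataFrame(
                    [{"cell_type": t, "axis_only": a_only, "shared": shared,
                      "direct_only": b_only}]
                ).to_csv(out / f"deg_overlap_{t}.tsv", sep="\t", index=False)
            if config.sex_stratified:
                strata = stratified_degs(
                    ln, meta, t, max_pc=config.max_pc,
                    lfc_min=config.lfc_min, fdr_max=config.fdr_max,
                    seed=stage_seed(config.seed, "aging_axis"),
                )
                for sex, table in strata.items():
                    if table is not None:
                        table.to_csv(out / f"degs_axis_{t}_{sex}.tsv",
                                     sep="\t", index=False)
        pd.DataFrame(axis_rows).to_csv(out / "aging_axes.tsv", sep="\t", index=False)
        _record(manifest, "aging_axis", {"max_pc": config.max_pc},
                n_cells=len(meta))

        # -- signatures ------------------------------------------------------
        current = "signatures"
        sig_rows = []
        gene_sets = (
            {name: GeneSet(name, genes)
             for name, genes in read_gmt(config.gene_sets_gmt).items()}
            if config.gene_sets_gmt else {}
        )
        for name, gs in gene_sets.items():
            for t in types:
                sel = meta[meta["cell_type"] == t]
                old = sel.loc[sel["age_group"] == "old", "cell_id"]
                young = sel.loc[sel["age_group"] == "young", "cell_id"]
                res = geneset_group_test(ln, gs, list(old), list(young))
                sig_rows.append(
                    {"set": name, "cell_type": t, "t": res.t, "p": res.p,
                     "mean_old": res.mean_a, "mean_young": res.mean_b}
                )
        pd.DataFrame(
            sig_rows, columns=["set", "cell_type", "t", "p", "mean_old", "mean_young"]
        ).to_csv(out / "signature_tests.tsv", sep="\t", index=False)
        _record(manifest, "signatures", {"n_sets": len(gene_sets)},
                n_cells=len(meta))

        # -- interactions ----------------------------------------------------
        current = "interactions"
        if config.lr_pairs_tsv:
            pairs = pd.read_csv(config.lr_pairs_tsv, sep="\t")
        elif config.simulate is not None and config.simulate.lr_pairs:
            pairs = pd.DataFrame(
                [{"ligand": p.ligand, "receptor": p.receptor}
                 for p in config.simulate.lr_pairs]
            )
        else:
            pairs = pd.DataFrame(columns=["ligand", "receptor"])
        if len(pairs):
            lr = lr_permutation_test(
                ln, meta, pairs, n_perm=config.n_perm,
                frac_min=config.lr_frac_min,
                seed=stage_seed(config.seed, "interactions"),
            )
        else:
            lr = pd.DataFrame(
                columns=["ligand", "receptor", "sender", "receiver",
                         "mean_score", "p", "tested", "reason"]
            )
        lr.to_csv(out / "interactions.tsv", sep="\t", index=False)
        _record(manifest, "interactions",
                {"n_perm": config.n_perm, "n_pairs": len(pairs)},
                n_cells=len(meta))

        # -- grn -------------------------------------------------------------
        current = "grn"
        tfs = (read_gene_list(config.tf_list_tsv) if config.tf_list_tsv
               else list(DEFAULT_TFS))
        grn_edges, grn_summary = [], []
        for t, degs in deg_tables.items():
            cells_t = list(meta.loc[meta["cell_type"] == t, "cell_id"])
            for direction in ("up", "down"):
                genes = degs.loc[degs["direction"] == direction, "gene"].tolist()
                regs = [g for g in genes if g in set(tfs)]
                if not regs or len(genes) < 2:
                    grn_summary.append({"cell_type": t, "direction": direction,
                                        "n_edges": 0, "top_hub": ""})
                    continue
                edges = infer_network(
                    ln, regs, genes, weight_quantile=config.weight_quantile,
                    cells=cells_t,
                )
                ranking = hub_ranking(edges)
                edges.insert(0, "direction", direction)
                edges.insert(0, "cell_type", t)
                grn_edges.append(edges)
                grn_summary.append(
                    {"cell_type": t, "direction": direction,
                     "n_edges": len(edges),
                     "top_hub": ranking["regulator"].iloc[0] if len(ranking) else ""}
                )
        (pd.concat(grn_edges, ignore_index=True) if grn_edges
         else pd.DataFrame(columns=["cell_type", "direction", "regulator",
                                    "target", "weight"])
         ).to_csv(out / "grn_edges.tsv", sep="\t", index=False)
        pd.DataFrame(grn_summary).to_csv(out / "grn_summary.tsv", sep="\t",
                                         index=False)
        _record(manifest, "grn", {"weight_quantile": config.weight_quantile},
                n_cells=len(meta))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _record(manifest: dict, stage: str, params: dict, n_cells: int) -> None:
    manifest["stages"].append(
        {"stage": stage, "seed": stage_seed(manifest["seed"], stage)
         if stage in STAGES else None,
         "params": params, "n_cells": int(n_cells)}
    )


def report(outdir) -> str:
    """Plain-text summary of a completed run, written to ``report.txt``.

    Per-type cell counts and young/old percentages, the noise test table,
    selected axes, DEG counts, top interactions and hub regulators. Missing
    stage outputs are listed rather than fatal; re-running is idempotent.
    """
    out = Path(outdir)
    lines, missing = [], []
    lines.append(f"isletage run report: {out}")

    def _load(name):
        p = out / name
        if not p.exists():
            missing.append(name)
            return None
        return pd.read_csv(p, sep="\t")

    meta = _load("metadata_annotated.tsv")
    if meta is not None:
        lines.append("\n== cell types ==")
        tab = meta.groupby(["cell_type", "age_group"]).size().unstack(fill_value=0)
        pct = (tab.T / tab.sum(axis=1)).T * 100
        for t in tab.index:
            parts = ", ".join(
                f"{g}: {tab.loc[t, g]} ({pct.loc[t, g]:.1f}%)" for g in tab.columns
            )
            lines.append(f"  {t}: {parts}")

    noise = _load("noise_tests.tsv")
    if noise is not None:
        lines.append("\n== transcriptional noise (old vs young, Welch t) ==")
        for _, r in noise.iterrows():
            lines.append(
                f"  {r['cell_type']}: t={r['t']:+.2f} p={r['p']:.3g} "
                f"(old {r['old']:.4f} vs young {r['young']:.4f})"
            )

    axes = _load("aging_axes.tsv")
    if axes is not None:
        lines.append("\n== aging axes ==")
        for _, r in axes.iterrows():
            if r["status"] == "selected":
                lines.append(f"  {r['cell_type']}: PC{int(r['pc_index'])} "
                             f"AUC={r['auc']:.3f}")
            else:
                lines.append(f"  {r['cell_type']}: not discriminated")
        for t in axes["cell_type"]:
            degs = _load(f"degs_axis_{t}.tsv")
            if degs is not None:
                n_up = int((degs["direction"] == "up").sum())
                n_down = int((degs["direction"] == "down").sum())
                lines.append(f"  {t} aging DEGs: {n_up} up / {n_down} down")

    lr = _load("interactions.tsv")
    if lr is not None and len(lr):
        lines.append("\n== top ligand-receptor interactions ==")
        top = lr[lr["tested"]].nsmallest(5, "p")
        for _, r in top.iterrows():
            lines.append(
                f"  {r['ligand']}->{r['receptor']} ({r['sender']}->{r['receiver']}): "
                f"score={r['mean_score']:.2f} p={r['p']:.4g}"
            )

    grn = _load("grn_summary.tsv")
    if grn is not None and len(grn):
        lines.append("\n== regulatory-network hubs ==")
        for _, r in grn.iterrows():
            lines.append(
                f"  {r['cell_type']} {r['direction']}: {r['n_edges']} edges, "
                f"top hub {r['top_hub'] or '-'}"
            )

    if missing:
        lines.append("\n== missing stage outputs ==")
        lines.extend(f"  {name}" for name in missing)
    text = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(text)
    return text
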