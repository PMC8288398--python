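"""Gene-set and single-gene aging signatures in beta-cells.

Scores illustrative UPR-branch / ERAD / chaperone sets (GMT shipped next
to this script; real analyses supply curated lists) old vs young per cell
type, reports single-gene statistics for the classic panel (CDKN1A,
CDKN2A, IAPP, HSP90B1), builds the old/young fold-change matrix over a
curated list, tests DEG overlap against an "ATF6 target"-style set with
the hypergeometric tail, and runs pre-ranked GSEA on the beta contrast.
"""

from pathlib import Path

import pandas as pd

from common import load_dataset, outdir
from isletage.aging import direct_degs
from isletage.io import read_gmt
from isletage.signatures import (
    GeneSet,
    foldchange_matrix,
    gene_group_stats,
    geneset_group_test,
    gsea,
    hypergeom_enrichment,
)
from isletage.stats import group_log2fc

_, ln, meta, truth, _ = load_dataset()
out = outdir("05_signatures")
sets = {name: GeneSet(name, genes)
        for name, genes in read_gmt(Path(__file__).parent / "gene_sets.gmt").items()}

sel = meta[meta["cell_type"] == "beta"]
old = list(sel.loc[sel["age_group"] == "old", "cell_id"])
young = list(sel.loc[sel["age_group"] == "young", "cell_id"])

rows = []
for name, gs in sets.items():
    res = geneset_group_test(ln, gs, old, young)
    rows.append({"set": name, "t": res.t, "p": res.p,
                 "mean_old": res.mean_a, "mean_young": res.mean_b})
    print(f"{name}: old {res.mean_a:.2f} vs young {res.mean_b:.2f} "
          f"(t={res.t:+.1f}, p={res.p:.2g})")
pd.DataFrame(rows).to_csv(out / "set_tests_beta.tsv", sep="\t", index=False)

panel = []
for gene in ("CDKN1A", "CDKN2A", "IAPP", "HSP90B1"):
    lfc, t, p = gene_group_stats(ln, gene, old, young)
    panel.append({"gene": gene, "log2fc": lfc, "t": t, "p": p})
    print(f"{gene}: log2FC {lfc:+.2f}, p={p:.2g}")
pd.DataFrame(panel).to_csv(out / "gene_panel_beta.tsv", sep="\t", index=False)

curated = sets["ER_chaperones"].genes + sets["ERAD"].genes + ["G00010", "G00020"]
fc = foldchange_matrix(ln, curated, meta)
fc.to_csv(out / "foldchange_matrix.tsv", sep="\t")
print(f"fold-change matrix: {len(fc)} of {len(curated)} curated genes "
      f"differential in >= 1 type")

degs = direct_degs(ln, meta, "beta")
up = list(degs.loc[degs["direction"] == "up", "gene"])
atf6_like = [g for g in sets["UPR_ATF6_branch"].genes] + ["G00100", "G00200"]
overlap, p = hypergeom_enrichment(up, GeneSet("atf6", atf6_like),
                                  list(ln.gene_ids))
print(f"up-DEGs vs ATF6-style target set: {overlap}/{len(atf6_like)} "
      f"overlap, hypergeometric p={p:.2g}")

beta = ln.subset_cells(old + young)
ranking = pd.Series(
    group_log2fc(beta.values[:, beta.cell_mask(old)],
                 beta.values[:, beta.cell_mask(young)]),
    index=beta.gene_ids,
)
enr = gsea(ranking, list(sets.values()), n_perm=500, seed=0)
enr.to_csv(out / "gsea_beta.tsv", sep="\t", index=False)
print(enr.round(3).to_string(index=False))
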