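"""Simulate the islet aging study design and record its ground truth.

Sixteen cynomolgus-monkey donors (8 young, 8 old, both sexes), 5 575
endocrine cells of four types, a UPR-flavoured aging program and inflated
overdispersion in alpha/beta cells, planted ligand-receptor pairs and an
HSPA5 hub. Writes the planted-truth tables and a dataset summary; the
counts themselves are regenerated from the seed by the later scripts.
"""

import pandas as pd

from common import load_dataset, outdir
from isletage.simdata import truth_report, write_truth

m, ln, meta, truth, qc = load_dataset()
out = outdir("01_dataset")

write_truth(truth, out)
qc.table.to_csv(out / "qc_report.tsv", sep="\t", index=False)

summary = {
    "cells_simulated": m.n_cells,
    "cells_after_qc": ln.n_cells,
    "genes": m.n_genes,
    "mean_genes_detected": float((m.values > 0).sum(axis=0).mean()),
    "donors": meta["donor_id"].nunique(),
}
pd.Series(summary).to_csv(out / "summary.tsv", sep="\t", header=False)

print(f"simulated {m.n_cells} cells x {m.n_genes} genes from "
      f"{summary['donors']} donors; {summary['cells_after_qc']} kept after QC")
print(f"mean genes detected per cell: {summary['mean_genes_detected']:.0f}")
for name, table in truth_report(truth).items():
    print(f"planted {name}: {len(table)} rows")
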