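"""Aging-axis DEG discovery per cell type, with the direct cross-check.

For each endocrine type: PCA within the type, selection of the component
that separates young from old cells consistently across every donor,
young-like/old-like state assignment along it, and Wilcoxon DEG calling.
delta/PP are expected to report no axis. The axis-based DEG sets are
compared against the plain all-old-vs-all-young contrast, and the beta
analysis is additionally stratified by sex.
"""

import warnings

import pandas as pd

from common import load_dataset, outdir
from isletage.aging import (
    aging_axis_degs,
    direct_degs,
    overlap_sets,
    stratified_degs,
)

_, ln, meta, truth, _ = load_dataset()
out = outdir("04_aging_axis")

axis_rows = []
for cell_type in ("alpha", "beta", "delta", "pp"):
    axis, states, degs = aging_axis_degs(ln, meta, cell_type)
    if axis is None:
        axis_rows.append({"cell_type": cell_type, "pc_index": None,
                          "auc": None, "status": "not discriminated"})
        print(f"{cell_type}: not discriminated (no donor-consistent PC)")
        continue
    axis_rows.append({"cell_type": cell_type, "pc_index": axis.pc_index,
                      "auc": axis.auc, "status": "selected"})
    n_young = int((states == "young-like").sum())
    n_old = int((states == "old-like").sum())
    degs.to_csv(out / f"degs_axis_{cell_type}.tsv", sep="\t", index=False)
    direct = direct_degs(ln, meta, cell_type)
    direct.to_csv(out / f"degs_direct_{cell_type}.tsv", sep="\t", index=False)
    up_axis = degs.loc[degs["direction"] == "up", "gene"]
    up_direct = direct.loc[direct["direction"] == "up", "gene"]
    a_only, shared, b_only, _ = overlap_sets(up_axis, up_direct)
    planted = set(truth.aging_degs.query("cell_type == @cell_type")["gene"])
    recovered = len(set(degs["gene"]) & planted)
    print(f"{cell_type}: PC{axis.pc_index} (AUC {axis.auc:.3f}); "
          f"{n_young} young-like / {n_old} old-like cells; "
          f"{(degs['direction'] == 'up').sum()} up / "
          f"{(degs['direction'] == 'down').sum()} down DEGs "
          f"({recovered}/{len(planted)} planted); "
          f"up-set overlap with direct contrast: {shared} shared, "
          f"{a_only} axis-only, {b_only} direct-only")

pd.DataFrame(axis_rows).to_csv(out / "aging_axes.tsv", sep="\t", index=False)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    strata = stratified_degs(ln, meta, "beta")
for sex, table in strata.items():
    if table is None:
        continue
    table.to_csv(out / f"degs_axis_beta_{sex}.tsv", sep="\t", index=False)
up = {s: set(t.loc[t["direction"] == "up", "gene"])
      for s, t in strata.items() if t is not None}
if len(up) == 2:
    f_only, shared, m_only, _ = overlap_sets(up["F"], up["M"])
    print(f"beta up-DEGs by sex: {shared} shared, {f_only} female-specific, "
          f"{m_only} male-specific")
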