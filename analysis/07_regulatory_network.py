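"""Regulator->target network over beta-cell aging DEGs; hub ranking.

Regulators are the transcription-factor/chaperone list intersected with
the up-regulated DEGs; edges are |Spearman| weights above the 0.9
quantile. The planted HSPA5 hub should rank first by out-degree.
"""

import pandas as pd

from common import load_dataset, outdir
from isletage.aging import direct_degs
from isletage.grn import hub_ranking, infer_network
from isletage.simdata import DEFAULT_TFS

_, ln, meta, truth, _ = load_dataset()
out = outdir("07_grn")

degs = direct_degs(ln, meta, "beta")
up = degs.loc[degs["direction"] == "up", "gene"].tolist()
regulators = [g for g in up if g in set(DEFAULT_TFS)]
cells = list(meta.loc[meta["cell_type"] == "beta", "cell_id"])
edges = infer_network(ln, regulators, up, cells=cells)
ranking = hub_ranking(edges)
edges.to_csv(out / "edges_beta_up.tsv", sep="\t", index=False)
ranking.to_csv(out / "hubs_beta_up.tsv", sep="\t", index=False)

print(f"{len(up)} up-DEGs, {len(regulators)} candidate regulators, "
      f"{len(edges)} retained edges")
print("hub ranking:")
print(ranking.to_string(index=False))
planted_targets = set(truth.hub_edges["target"])
kept = edges[(edges["regulator"] == "HSPA5")
             & edges["target"].isin(planted_targets)]
print(f"planted hub edges retained: {len(kept)}/{len(planted_targets)}")
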