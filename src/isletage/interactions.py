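"""Ligand-receptor interaction scoring with an empirical permutation test.

The score of (ligand, receptor) for an ordered (sender, receiver) type pair
is the arithmetic mean of the ligand's mean log-normalized expression in
sender cells and the receptor's mean in receiver cells. Significance comes
from shuffling cell-type labels across cells (type sizes preserved; one
shared shuffle per iteration for all pairs) with the add-one estimator
p = (1 + #{null >= observed}) / (n_perm + 1). Pairs whose ligand or receptor
falls below an expression-fraction cutoff in the relevant type are reported
untested with the reason.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import LOGNORM, ExpressionMatrix


def lr_score(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    ligand: str,
    receptor: str,
    sender: str,
    receiver: str,
    frac_min: float = 0.10,
) -> tuple[float | None, str | None]:
    """Observed score for one combination, or (None, reason) if filtered."""
    meta = meta.set_index("cell_id", drop=False).loc[list(m.cell_ids)]
    types = meta["cell_type"].to_numpy()
    for t in (sender, receiver):
        if t not in set(types):
            raise KeyError(f"unknown cell type {t!r}")
    lv = m.gene_values(ligand)
    rv = m.gene_values(receptor)
    smask = types == sender
    rmask = types == receiver
    if (lv[smask] > 0).mean() < frac_min:
        return None, f"ligand {ligand} below frac_min in {sender}"
    if (rv[rmask] > 0).mean() < frac_min:
        return None, f"receptor {receptor} below frac_min in {receiver}"
    return float(0.5 * (lv[smask].mean() + rv[rmask].mean())), None


def lr_permutation_test(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
    n_perm: int = 500,
    frac_min: float = 0.10,
    seed: int = 0,
    types: list[str] | None = None,
) -> pd.DataFrame:
    """Score every (pair, sender, receiver) combination and test it against
    a cell-type label-shuffling null.

    ``pairs`` needs columns ligand/receptor (duplicates dropped). Returns
    one row per ordered type combination per pair: mean_score, empirical p
    (NaN when untested) and the filter reason.
    """
    if m.layer != LOGNORM:
        raise ValueError("lr_permutation_test expects log-normalized values")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    pairs = pairs[["ligand", "receptor"]].drop_duplicates().reset_index(drop=True)
    meta = meta.set_index("cell_id", drop=False).loc[list(m.cell_ids)]
    type_arr = meta["cell_type"].to_numpy()
    if types is None:
        types = sorted(pd.unique(type_arr))
    if len(types) < 2:
        raise ValueError("need >= 2 cell types")

    genes = list(dict.fromkeys(pairs["ligand"].tolist() + pairs["receptor"].tolist()))
    for g in genes:
        m.gene_index(g)  # raises on unknown genes
    expr = np.stack([m.gene_values(g) for g in genes])  # genes x cells
    gpos = {g: i for i, g in enumerate(genes)}

    # observed per-type means and expression fractions
    masks = {t: type_arr == t for t in types}
    obs_mean = np.stack([expr[:, masks[t]].mean(axis=1) for t in types], axis=1)
    obs_frac = np.stack([(expr[:, masks[t]] > 0).mean(axis=1) for t in types], axis=1)
    tpos = {t: i for i, t in enumerate(types)}

    combos = []  # (pair_row, sender, receiver, observed, reason)
    for _, row in pairs.iterrows():
        li, ri = gpos[row["ligand"]], gpos[row["receptor"]]
        for s in types:
            for r in types:
                reason = None
                if obs_frac[li, tpos[s]] < frac_min:
                    reason = f"ligand below frac_min in {s}"
                elif obs_frac[ri, tpos[r]] < frac_min:
                    reason = f"receptor below frac_min in {r}"
                score = 0.5 * (obs_mean[li, tpos[s]] + obs_mean[ri, tpos[r]])
                combos.append((row["ligand"], row["receptor"], s, r, score, reason))

    tested = np.array([c[5] is None for c in combos])
    observed = np.array([c[4] for c in combos])
    ge_counts = np.zeros(len(combos), dtype=np.int64)

    # one shared label shuffle per iteration; type sizes preserved
    rng = np.random.default_rng(seed)
    n_cells = m.n_cells
    indicator = np.stack([masks[t].astype(float) for t in types], axis=1)
    sizes = indicator.sum(axis=0)
    li_idx = np.array([gpos[c[0]] for c in combos])
    ri_idx = np.array([gpos[c[1]] for c in combos])
    s_idx = np.array([tpos[c[2]] for c in combos])
    r_idx = np.array([tpos[c[3]] for c in combos])
    for _ in range(n_perm):
        perm = rng.permutation(n_cells)
        null_mean = (expr[:, perm] @ indicator) / sizes[None, :]
        null_scores = 0.5 * (null_mean[li_idx, s_idx] + null_mean[ri_idx, r_idx])
        ge_counts += null_scores >= observed

    p = (1.0 + ge_counts) / (n_perm + 1.0)
    return pd.DataFrame(
        {
            "ligand": [c[0] for c in combos],
            "receptor": [c[1] for c in combos],
            "sender": [c[2] for c in combos],
            "receiver": [c[3] for c in combos],
            "mean_score": observed,
            "p": np.where(tested, p, np.nan),
            "tested": tested,
            "reason": [c[5] or "" for c in combos],
        }
    )
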