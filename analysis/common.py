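"""Shared setup for the numbered analysis scripts.

The study-design dataset (16 donors, 5 575 cells) is regenerated
deterministically from ANALYSIS_SEED by every script instead of being
stored: the count matrix is large, cheap to re-draw, and bit-identical
across scripts. Derived tables land under results/.
"""

from pathlib import Path

from isletage.io import normalize_log, qc_filter
from isletage.simdata import default_config, generate_dataset

ANALYSIS_SEED = 0
RESULTS = Path(__file__).resolve().parent.parent / "results"


def load_dataset():
    """(raw, lognorm, metadata, truth) for the analysis dataset."""
    config = default_config()
    m, meta, truth = generate_dataset(config, seed=ANALYSIS_SEED)
    mq, report = qc_filter(m)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    return m, ln, meta, truth, report


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
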