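import numpy as np
import pandas as pd
import pytest

from isletage.io import normalize_log, qc_filter
from isletage.simdata import default_config, generate_dataset


def simulate_lognorm(config, seed, min_genes=0, min_counts=1):
    """Generate, QC-filter and log-normalize one dataset."""
    m, meta, truth = generate_dataset(config, seed=seed)
    mq, _ = qc_filter(m, min_genes=min_genes, min_counts=min_counts)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    return ln, meta, truth


@pytest.fixture(scope="session")
def default_dataset():
    """One study-design dataset (16 donors, 5 575 cells), shared across
    tests that exercise the full-scale design."""
    config = default_config()
    m, meta, truth = generate_dataset(config, seed=0)
    mq, _ = qc_filter(m)
    ln = normalize_log(mq)
    meta = meta[meta["cell_id"].isin(mq.cell_ids)].reset_index(drop=True)
    return {"raw": m, "lognorm": ln, "meta": meta, "truth": truth,
            "config": config}


@pytest.fixture()
def tiny_matrix():
    """3 genes x 4 cells deterministic count fixture."""
    from isletage.matrix import ExpressionMatrix

    values = np.array(
        [[0, 2, 4, 1],
         [1, 0, 3, 5],
         [2, 2, 0, 0]], dtype=np.int32
    )
    return ExpressionMatrix(
        values, ["g1", "g2", "g3"], ["c1", "c2", "c3", "c4"], layer="raw"
    )


@pytest.fixture()
def tiny_meta():
    return pd.DataFrame(
        {
            "cell_id": ["c1", "c2", "c3", "c4"],
            "donor_id": ["d1", "d1", "d2", "d2"],
            "age_group": ["young", "young", "old", "old"],
            "sex": ["F", "M", "F", "M"],
            "cell_type": ["alpha", "alpha", "alpha", "alpha"],
        }
    )
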