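"""Shared statistical primitives.

All multiple-testing correction in the package goes through :func:`bh_fdr`;
all two-group location tests go through :func:`welch_t` (scalar) or
:func:`rank_sum_genes` (vectorized per-gene Wilcoxon rank-sum). Thin wrappers
around scipy/statsmodels with the degenerate cases pinned down so callers do
not have to special-case them.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up).

    NaN entries propagate as NaN and are excluded from the correction.
    """
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def welch_t(a, b) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test, returning ``(t, p)``.

    Two degenerate groups with equal means (e.g. the same cells in both
    groups) give ``(0.0, 1.0)`` rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (np.inf, 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def rank_sum_genes(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per gene (rows).

    ``xa``/``xb`` are genes x cells blocks for the two groups. Uses the
    tie-corrected normal approximation; a gene constant across both groups
    has an undefined statistic and is assigned p = 1.
    """
    xa = np.atleast_2d(xa)
    xb = np.atleast_2d(xb)
    if xa.shape[1] < 2 or xb.shape[1] < 2:
        raise ValueError("rank_sum_genes needs >= 2 cells per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(
            xa, xb, axis=1, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    const = np.all(xa == xa[:, :1], axis=1) & np.all(xb == xa[:, :1], axis=1)
    p[const | np.isnan(p)] = 1.0
    return p


def group_log2fc(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Per-row difference of group means: mean(A) - mean(B).

    On log2-normalized values this is the log2 fold change of group A over
    group B (means of logs, the convention used throughout).
    """
    return np.atleast_2d(xa).mean(axis=1) - np.atleast_2d(xb).mean(axis=1)


def pearson_vs_vector(x: np.ndarray, y: np.ndarray):
    """Pearson r of every row of ``x`` against the vector ``y``.

    Returns ``(r, p, defined)`` where ``defined`` is False for constant rows
    (or constant ``y``), whose r/p are NaN. Two-sided p from the exact
    t-distribution with n-2 df.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.size
    if x.shape[1] != n:
        raise ValueError("shape mismatch")
    if n < 3:
        raise ValueError("need >= 3 observations for a correlation p-value")
    yc = y - y.mean()
    ynorm = np.linalg.norm(yc)
    xc = x - x.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(xc, axis=1)
    defined = (xnorm > 0) & (ynorm > 0)
    r = np.full(x.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        r[defined] = (xc[defined] @ yc) / (xnorm[defined] * ynorm)
    r = np.clip(r, -1.0, 1.0)
    p = np.full(x.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r[defined] * np.sqrt((n - 2) / np.maximum(1 - r[defined] ** 2, 0))
    p[defined] = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p[defined & (np.abs(r) == 1.0)] = 0.0
    return r, p, defined


def spearman_abs_matrix(xr: np.ndarray, xt: np.ndarray) -> np.ndarray:
    """|Spearman correlation| between every row of ``xr`` and of ``xt``.

    Constant rows get correlation 0 (undefined, treated as no association).
    """
    def _ranked(x):
        x = np.atleast_2d(np.asarray(x, dtype=float))
        rk = sps.rankdata(x, axis=1)
        rk = rk - rk.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(rk, axis=1)
        ok = norm > 0
        rk[ok] = rk[ok] / norm[ok, None]
        rk[~ok] = 0.0
        return rk

    rr = _ranked(xr)
    rt = _ranked(xt)
    return np.abs(np.clip(rr @ rt.T, -1.0, 1.0))


def hypergeom_sf(overlap: int, n_universe: int, n_set: int, n_hits: int) -> float:
    """Upper-tail hypergeometric P(X >= overlap)."""
    return float(sps.hypergeom.sf(overlap - 1, n_universe, n_set, n_hits))


def mannwhitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC of scores for the positive vs negative group (ties count 1/2)."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    u = sps.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return float(u / (pos.size * neg.size))
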