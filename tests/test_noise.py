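"""Transcriptional-noise statistic, group comparison, noise-gene discovery."""

import numpy as np
import pandas as pd
import pytest

from isletage.matrix import ExpressionMatrix
from isletage.noise import (
    bin_cells_by_noise,
    compare_noise,
    noise_correlated_genes,
    transcriptional_noise,
)
from isletage.simdata import default_config
from tests.conftest import simulate_lognorm


def _matrix(values, types=None, ages=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    m = ExpressionMatrix(values, [f"g{i}" for i in range(n_genes)],
                         [f"c{i}" for i in range(n_cells)], layer="lognorm")
    meta = pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "donor_id": ["d1"] * n_cells,
            "age_group": ages or ["young"] * n_cells,
            "sex": ["F"] * n_cells,
            "cell_type": types or ["alpha"] * n_cells,
        }
    )
    return m, meta


def test_midpoint_distance_hand_example():
    """Two cells at (0,0) and (2,2): both sit sqrt(2) from the centroid
    (1,1); scaled by 1/sqrt(2 genes) the noise is exactly 1."""
    m, meta = _matrix([[0, 2], [0, 2], [0, 0], [0, 0]])
    # last two genes stay unexpressed and are dropped by the frac filter
    nv = transcriptional_noise(m, meta, "alpha", frac_min=0.5)
    assert len(nv.genes_used) == 2
    assert np.allclose(nv.values, [1.0, 1.0])


def test_identical_cells_zero_noise():
    m, meta = _matrix(np.tile([[1.0], [2.0]], (1, 6)))
    nv = transcriptional_noise(m, meta, "alpha", frac_min=0)
    assert np.allclose(nv.values, 0.0)


def test_noise_homogeneity_under_doubling():
    rng = np.random.default_rng(0)
    base = rng.uniform(0.5, 3, size=(10, 12))
    m1, meta = _matrix(base)
    m2, _ = _matrix(base * 2)
    n1 = transcriptional_noise(m1, meta, "alpha", frac_min=0)
    n2 = transcriptional_noise(m2, meta, "alpha", frac_min=0)
    assert np.allclose(n2.values, 2 * n1.values)


def test_noise_invariant_to_gene_order_and_subthreshold_genes():
    rng = np.random.default_rng(1)
    base = rng.uniform(1, 3, size=(8, 10))
    m1, meta = _matrix(base)
    n1 = transcriptional_noise(m1, meta, "alpha", frac_min=0.2)
    # permute genes
    perm = m1.subset_genes([f"g{i}" for i in (3, 1, 0, 2, 4, 7, 6, 5)])
    n2 = transcriptional_noise(perm, meta, "alpha", frac_min=0.2)
    assert np.allclose(n1.values, n2.values)
    # append genes expressed in a single cell (below frac_min)
    extra = np.zeros((2, 10))
    extra[:, 0] = 1.0
    m3 = ExpressionMatrix(np.vstack([base, extra]),
                          list(m1.gene_ids) + ["x1", "x2"],
                          m1.cell_ids, layer="lognorm")
    n3 = transcriptional_noise(m3, meta, "alpha", frac_min=0.2)
    assert np.allclose(n1.values, n3.values)


def test_centroids_are_per_age_group():
    """A pure mean shift between age groups must not register as noise."""
    base = np.tile([[1.0], [2.0]], (1, 8))
    shifted = base.copy()
    shifted[:, 4:] += 3.0  # old cells uniformly shifted
    m, meta = _matrix(shifted, ages=["young"] * 4 + ["old"] * 4)
    nv = transcriptional_noise(m, meta, "alpha", frac_min=0)
    assert np.allclose(nv.values, 0.0)


class TestCompareNoise:
    def test_identical_distributions_t_zero(self):
        rng = np.random.default_rng(2)
        base = rng.uniform(1, 3, size=(6, 5))
        values = np.concatenate([base, base], axis=1)  # same cells duplicated
        m, meta = _matrix(values, ages=["young"] * 5 + ["old"] * 5)
        nv = transcriptional_noise(m, meta, "alpha", frac_min=0)
        t, p, means = compare_noise(nv)
        assert t == 0.0 and p == 1.0
        assert means["old"] == pytest.approx(means["young"])

    def test_matches_textbook_welch_on_3v3(self):
        from scipy import stats as sps

        nv_values = pd.Series(
            [0.5, 0.7, 0.6, 1.2, 1.0, 1.4],
            index=pd.Index([f"c{i}" for i in range(6)], name="cell_id"),
        )
        from isletage.noise import NoiseVector

        nv = NoiseVector(
            nv_values, "alpha", ["g0"],
            pd.Series(["young"] * 3 + ["old"] * 3, index=nv_values.index),
        )
        t, p, _ = compare_noise(nv)
        ref = sps.ttest_ind([1.2, 1.0, 1.4], [0.5, 0.7, 0.6], equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_missing_group_is_error(self):
        m, meta = _matrix(np.ones((2, 6)) + np.arange(6))
        nv = transcriptional_noise(m, meta, "alpha", frac_min=0)
        with pytest.raises(ValueError):
            compare_noise(nv)


class TestNoiseGenes:
    def test_sign_rule(self):
        rng = np.random.default_rng(3)
        noise_vals = rng.uniform(0.5, 2.0, 20)
        values = np.vstack([noise_vals, -noise_vals, rng.normal(size=20)])
        m = ExpressionMatrix(values, ["pos", "neg", "rand"],
                             [f"c{i}" for i in range(20)], layer="lognorm")
        from isletage.noise import NoiseVector

        nv = NoiseVector(
            pd.Series(noise_vals, index=pd.Index(m.cell_ids, name="cell_id")),
            "alpha", list(m.gene_ids),
            pd.Series(["young"] * 20, index=pd.Index(m.cell_ids)),
        )
        tab = noise_correlated_genes(m, nv).set_index("gene")
        assert tab.loc["pos", "r"] == pytest.approx(1.0)
        assert bool(tab.loc["pos", "passes"])
        assert tab.loc["neg", "r"] == pytest.approx(-1.0)
        assert not bool(tab.loc["neg", "passes"])  # one-sided rule

    def test_constant_gene_flagged_not_error(self):
        values = np.vstack([np.ones(10), np.arange(10, dtype=float)])
        m = ExpressionMatrix(values, ["flat", "var"],
                             [f"c{i}" for i in range(10)], layer="lognorm")
        from isletage.noise import NoiseVector

        nv = NoiseVector(
            pd.Series(np.arange(10, dtype=float),
                      index=pd.Index(m.cell_ids, name="cell_id")),
            "alpha", list(m.gene_ids),
            pd.Series(["young"] * 10, index=pd.Index(m.cell_ids)),
        )
        tab = noise_correlated_genes(m, nv).set_index("gene")
        assert not bool(tab.loc["flat", "defined"])
        assert not bool(tab.loc["flat", "passes"])

    def test_coupled_genes_recovered_in_simulation(self):
        """Genes whose means track the per-cell dispersion inflation
        correlate with measured noise at the r > 0.6 / FDR < 0.05 defaults
        when the stress axis is strong (2x dispersion in old beta cells)."""
        cfg = default_config(n_cells_total=2500, n_genes=2000,
                             noise_inflation={"alpha": 1.5, "beta": 2.0})
        ln, meta, truth = simulate_lognorm(cfg, seed=6)
        nv = transcriptional_noise(ln, meta, "beta")
        tab = noise_correlated_genes(ln, nv)
        coupled = set(truth.coupled_genes.query("cell_type == 'beta'")["gene"])
        found = set(tab.loc[tab["passes"], "gene"])
        assert len(found & coupled) >= 16, sorted(found & coupled)


class TestBins:
    def _nv(self, values, ages):
        from isletage.noise import NoiseVector

        idx = pd.Index([f"c{i}" for i in range(len(values))], name="cell_id")
        return NoiseVector(pd.Series(values, index=idx), "alpha", ["g0"],
                           pd.Series(ages, index=idx))

    def test_even_split(self):
        nv = self._nv(np.arange(10.0), ["young"] * 10)
        bins = bin_cells_by_noise(nv, 5)
        assert bins.value_counts().tolist() == [2] * 5

    def test_remainder_rule(self):
        nv = self._nv(np.arange(7.0), ["young"] * 7)
        sizes = bin_cells_by_noise(nv, 3).value_counts().sort_index()
        assert sizes.tolist() == [3, 2, 2]

    def test_bin_means_non_decreasing_within_groups(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(size=24)
        ages = ["young"] * 12 + ["old"] * 12
        nv = self._nv(vals, ages)
        bins = bin_cells_by_noise(nv, 4)
        for grp in ("young", "old"):
            sel = nv.age_groups == grp
            means = nv.values[sel].groupby(bins[sel]).mean()
            assert (means.diff().dropna() >= 0).all()

    def test_errors(self):
        nv = self._nv(np.arange(4.0), ["young"] * 4)
        with pytest.raises(ValueError):
            bin_cells_by_noise(nv, 0)
        with pytest.raises(ValueError):
            bin_cells_by_noise(nv, 9)
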