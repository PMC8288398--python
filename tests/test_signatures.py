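"""Gene-set scores, single-gene stats, enrichment and GSEA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from isletage.matrix import ExpressionMatrix
from isletage.signatures import (
    GeneSet,
    _running_es,
    foldchange_matrix,
    gene_group_stats,
    geneset_group_test,
    gsea,
    hypergeom_enrichment,
)
from isletage.simdata import AgingProgram, default_config
from tests.conftest import simulate_lognorm


def _lognorm(values, gene_ids):
    values = np.asarray(values, float)
    return ExpressionMatrix(
        values, gene_ids, [f"c{i}" for i in range(values.shape[1])],
        layer="lognorm",
    )


class TestGenesetGroupTest:
    def test_singleton_set_equals_single_gene(self):
        rng = np.random.default_rng(0)
        m = _lognorm(rng.uniform(0, 3, size=(5, 12)), [f"g{i}" for i in range(5)])
        a, b = list(m.cell_ids[:6]), list(m.cell_ids[6:])
        res = geneset_group_test(m, GeneSet("one", ["g2"]), a, b)
        lfc, t, p = gene_group_stats(m, "g2", a, b)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
        assert np.allclose(res.scores, m.gene_values("g2"))

    def test_identical_groups_t_zero(self):
        rng = np.random.default_rng(1)
        m = _lognorm(rng.uniform(0, 3, size=(4, 6)), list("abcd"))
        cells = list(m.cell_ids[:3])
        res = geneset_group_test(m, GeneSet("s", ["a", "b"]), cells, cells)
        assert res.t == 0.0

    def test_empty_intersection_error(self):
        m = _lognorm(np.ones((2, 4)), ["a", "b"])
        with pytest.raises(ValueError, match="no genes"):
            geneset_group_test(m, GeneSet("s", ["zz"]),
                               list(m.cell_ids[:2]), list(m.cell_ids[2:]))

    def test_planted_set_shift_detected(self):
        """Set genes shifted up in old beta cells give a significant test."""
        genes = {f"SETG{i:02d}": 0.5 for i in range(15)}
        cfg = default_config(
            n_cells_total=1500, n_genes=1000,
            noise_inflation={}, noise_coupling={}, hub=None,
            aging_program={"beta": [AgingProgram(genes)]},
            baseline_boost={g: 10.0 for g in genes},
        )
        ps = []
        for seed in range(3):
            ln, meta, _ = simulate_lognorm(cfg, seed=seed)
            sel = meta[meta["cell_type"] == "beta"]
            old = list(sel.loc[sel["age_group"] == "old", "cell_id"])
            young = list(sel.loc[sel["age_group"] == "young", "cell_id"])
            res = geneset_group_test(ln, GeneSet("upr", list(genes)), old, young)
            assert res.mean_a > res.mean_b
            ps.append(res.p)
        assert np.median(ps) < 0.01


class TestGeneGroupStats:
    def test_no_difference_zero_lfc(self):
        m = _lognorm(np.tile([[1.5]], (1, 8)), ["g"])
        lfc, t, p = gene_group_stats(m, "g", list(m.cell_ids[:4]),
                                     list(m.cell_ids[4:]))
        assert lfc == 0.0 and t == 0.0 and p == 1.0

    def test_swap_negates_lfc_keeps_p(self):
        rng = np.random.default_rng(2)
        m = _lognorm(rng.uniform(0, 2, size=(1, 10)), ["g"])
        a, b = list(m.cell_ids[:5]), list(m.cell_ids[5:])
        l1, _, p1 = gene_group_stats(m, "g", a, b)
        l2, _, p2 = gene_group_stats(m, "g", b, a)
        assert l1 == pytest.approx(-l2)
        assert p1 == pytest.approx(p2)

    def test_hand_computed_2x3_fixture(self):
        vals = np.array([[1.0, 2.0, 3.0, 5.0, 6.0, 7.0]])
        m = _lognorm(vals, ["g"])
        a, b = list(m.cell_ids[3:]), list(m.cell_ids[:3])
        lfc, t, p = gene_group_stats(m, "g", a, b)
        assert lfc == pytest.approx(4.0)
        ref = sps.ttest_ind([5, 6, 7], [1, 2, 3], equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestFoldchangeMatrix:
    def test_rows_subset_of_input_and_planted_signal(self):
        genes = {f"GA{i:02d}": 1.5 for i in range(10)}
        cfg = default_config(
            n_cells_total=1500, n_genes=1000,
            noise_inflation={}, noise_coupling={}, hub=None,
            aging_program={"beta": [AgingProgram(genes)]},
            baseline_boost={g: 10.0 for g in genes},
        )
        ln, meta, _ = simulate_lognorm(cfg, seed=1)
        curated = list(genes) + ["G00001", "G00002"]
        table = foldchange_matrix(ln, curated, meta)
        assert set(table.index) <= set(curated)
        assert len(set(table.index) & set(genes)) >= 8
        assert (table.loc[table.index.isin(genes), "beta"] > 0.5).all()

    def test_no_aging_gives_empty_mask(self):
        cfg = default_config(
            aging_program={}, noise_inflation={}, noise_coupling={}, hub=None,
            n_cells_total=1000, n_genes=500,
        )
        ln, meta, _ = simulate_lognorm(cfg, seed=2)
        table = foldchange_matrix(ln, [f"G{i:05d}" for i in range(1, 40)], meta)
        assert len(table) == 0


class TestHypergeom:
    def test_saturation(self):
        uni = [f"g{i}" for i in range(10)]
        ov, p = hypergeom_enrichment(uni, GeneSet("all", uni), uni)
        assert ov == 10 and p == pytest.approx(1.0)

    def test_extreme_draw_probability(self):
        uni = [f"g{i}" for i in range(20)]
        hits = uni[:5]
        ov, p = hypergeom_enrichment(hits, GeneSet("s", uni[:5]), uni)
        assert ov == 5
        assert p == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_near_one(self):
        uni = [f"g{i}" for i in range(1000)]
        ov, p = hypergeom_enrichment(uni[:3], GeneSet("s", uni[900:903]), uni)
        assert ov == 0 and p > 0.99

    def test_membership_violation(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(["x"], GeneSet("s", ["a"]), ["a", "b"])


class TestGSEA:
    def _ranking(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        scores = np.sort(rng.normal(size=n))[::-1]
        return pd.Series(scores, index=[f"g{i}" for i in range(n)])

    def test_top_k_set_is_extremal(self):
        ranking = self._ranking()
        genes = list(ranking.index)
        k = 5
        es_top = gsea(ranking, GeneSet("top", genes[:k]), n_perm=10)["es"][0]
        assert es_top > 0
        rng = np.random.default_rng(1)
        order = np.argsort(-ranking.to_numpy())
        weights = np.abs(ranking.to_numpy())
        for _ in range(200):
            in_set = np.zeros(len(genes), dtype=bool)
            in_set[rng.choice(len(genes), k, replace=False)] = True
            assert _running_es(order, weights, in_set) <= es_top + 1e-12

    def test_reversed_ranking_negates_es(self):
        ranking = self._ranking()
        gs = GeneSet("s", list(ranking.index[:8]))
        es1 = gsea(ranking, gs, n_perm=5)["es"][0]
        es2 = gsea(-ranking, gs, n_perm=5)["es"][0]
        assert es1 == pytest.approx(-es2)

    def test_relabeling_invariance(self):
        ranking = self._ranking()
        gs = GeneSet("s", list(ranking.index[10:20]))
        out1 = gsea(ranking, gs, n_perm=50, seed=3)
        renamed = ranking.rename(lambda g: f"x_{g}")
        gs2 = GeneSet("s", [f"x_{g}" for g in gs.genes])
        out2 = gsea(renamed, gs2, n_perm=50, seed=3)
        assert out1["es"][0] == pytest.approx(out2["es"][0])
        assert out1["nes"][0] == pytest.approx(out2["nes"][0])

    def test_random_set_p_roughly_uniform(self):
        ranking = self._ranking(n=200, seed=4)
        rng = np.random.default_rng(5)
        ps = []
        for i in range(100):
            genes = list(rng.choice(ranking.index, 15, replace=False))
            ps.append(gsea(ranking, GeneSet(f"s{i}", genes),
                           n_perm=99, seed=i)["p"][0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_disjoint_set_error(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea(self._ranking(), GeneSet("s", ["nope"]), n_perm=5)
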