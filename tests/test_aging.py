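"""PCA aging axis: fitting, selection, state assignment, DEG calling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from isletage.aging import (
    AgingAxis,
    assign_age_states,
    call_degs,
    direct_degs,
    fit_pca,
    overlap_sets,
    select_age_pc,
    stratified_degs,
)
from isletage.matrix import ExpressionMatrix
from isletage.simdata import AgingProgram, default_config, null_config
from tests.conftest import simulate_lognorm


def _lognorm(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, float)
    g, n = values.shape
    return ExpressionMatrix(
        values,
        gene_ids or [f"g{i}" for i in range(g)],
        cell_ids or [f"c{i}" for i in range(n)],
        layer="lognorm",
    )


class TestFitPCA:
    def test_orthonormal_loadings(self):
        rng = np.random.default_rng(0)
        m = _lognorm(rng.uniform(0, 4, size=(20, 30)))
        res = fit_pca(m, n_components=5)
        assert np.allclose(res.loadings.T @ res.loadings, np.eye(5), atol=1e-8)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_rank_one_matrix(self):
        u = np.linspace(0, 1, 15)[None, :]
        v = np.arange(1, 9, dtype=float)[:, None]
        m = _lognorm(v @ u)
        res = fit_pca(m, n_components=3)
        assert res.variance_explained[0] > 0.999

    def test_full_reconstruction(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 3, size=(6, 10))
        m = _lognorm(x)
        res = fit_pca(m, n_components=6)
        centered = x.T - x.T.mean(axis=0)
        recon = res.scores @ res.loadings.T
        assert np.allclose(recon, centered, atol=1e-6)

    def test_too_many_components(self):
        m = _lognorm(np.random.default_rng(2).uniform(size=(4, 5)))
        with pytest.raises(ValueError):
            fit_pca(m, n_components=10)


def _axis_meta(n_young, n_old, donors_per_group=2):
    rows = []
    for i in range(n_young + n_old):
        grp = "young" if i < n_young else "old"
        within = i if grp == "young" else i - n_young
        donor = f"{grp[0].upper()}{within % donors_per_group + 1}"
        rows.append({"cell_id": f"c{i}", "donor_id": donor,
                     "age_group": grp, "sex": "F", "cell_type": "alpha"})
    return pd.DataFrame(rows)


class TestSelectAgePC:
    def _separable(self, seed=0, flip=False):
        rng = np.random.default_rng(seed)
        n = 40
        meta = _axis_meta(20, 20)
        if flip:
            meta["age_group"] = meta["age_group"].map(
                {"young": "old", "old": "young"}
            )
        age_signal = np.r_[np.zeros(20), np.ones(20) * 3]
        values = rng.uniform(0, 1, size=(30, n))
        values[:5] += age_signal  # age axis on 5 genes
        return _lognorm(values), meta

    def test_selects_and_orients(self):
        m, meta = self._separable()
        pca = fit_pca(m, n_components=5)
        axis = select_age_pc(pca, meta, "alpha")
        assert axis is not None and axis.auc > 0.95
        old = meta.set_index("cell_id")["age_group"] == "old"
        assert axis.scores[old.to_numpy()].mean() > axis.scores[(~old).to_numpy()].mean()
        assert axis.donor_medians["consistent"].all()

    def test_flipping_age_labels_flips_orientation_only(self):
        m, meta = self._separable()
        m2, meta_f = self._separable(flip=True)
        pca = fit_pca(m, n_components=5)
        a1 = select_age_pc(pca, meta, "alpha")
        a2 = select_age_pc(pca, meta_f, "alpha")
        assert a1.pc_index == a2.pc_index
        assert a1.orientation == -a2.orientation
        assert np.allclose(a1.scores, -a2.scores)

    def test_no_signal_returns_none(self):
        rng = np.random.default_rng(5)
        meta = _axis_meta(20, 20, donors_per_group=4)
        m = _lognorm(rng.uniform(0, 1, size=(30, 40)))
        pca = fit_pca(m, n_components=5)
        assert select_age_pc(pca, meta, "alpha") is None

    def test_single_donor_warns(self):
        m, meta = self._separable()
        meta["donor_id"] = np.where(meta["age_group"] == "old", "O1", "Y1")
        pca = fit_pca(m, n_components=5)
        with pytest.warns(UserWarning, match="one old donor"):
            select_age_pc(pca, meta, "alpha")


class TestAssignStates:
    def _axis(self, scores, meta):
        idx = pd.Index(meta["cell_id"], name="cell_id")
        return AgingAxis(
            "alpha", 1, 1, pd.Series(scores, index=idx), 1.0,
            pd.DataFrame(), pd.Series(dtype=float),
        )

    def test_perfect_separation_nothing_excluded(self):
        meta = _axis_meta(5, 5)
        axis = self._axis(np.r_[np.zeros(5), np.ones(5) * 4], meta)
        states = assign_age_states(axis, meta)
        assert (states != "excluded").all()
        assert (states.iloc[:5] == "young-like").all()
        assert (states.iloc[5:] == "old-like").all()

    def test_young_donor_cell_above_threshold_excluded(self):
        meta = _axis_meta(5, 5)
        scores = np.r_[np.zeros(4), [5.0], np.ones(5) * 4]  # young outlier
        states = assign_age_states(self._axis(scores, meta), meta)
        assert states.iloc[4] == "excluded"  # never old-like

    def test_no_cross_age_assignment_invariant(self):
        rng = np.random.default_rng(7)
        meta = _axis_meta(30, 30)
        states = assign_age_states(self._axis(rng.normal(size=60), meta), meta)
        age = meta.set_index("cell_id")["age_group"]
        assert (age[states == "old-like"] == "old").all()
        assert (age[states == "young-like"] == "young").all()


class TestCallDegs:
    def test_identical_groups_no_degs(self):
        rng = np.random.default_rng(8)
        m = _lognorm(rng.uniform(0, 3, size=(15, 8)))
        degs = call_degs(m, list(m.cell_ids[:4]), list(m.cell_ids[:4]))
        assert degs.empty

    def test_swap_flips_directions(self):
        rng = np.random.default_rng(9)
        values = rng.uniform(0, 2, size=(10, 12))
        values[0, :6] += 3
        m = _lognorm(values)
        a, b = list(m.cell_ids[:6]), list(m.cell_ids[6:])
        d1 = call_degs(m, a, b).set_index("gene")
        d2 = call_degs(m, b, a).set_index("gene")
        assert set(d1.index) == set(d2.index)
        for g in d1.index:
            assert d1.loc[g, "log2fc"] == pytest.approx(-d2.loc[g, "log2fc"])
            assert d1.loc[g, "direction"] != d2.loc[g, "direction"]

    def test_direction_matches_sign_and_fdr_bounds(self):
        rng = np.random.default_rng(10)
        values = rng.uniform(0, 2, size=(20, 30))
        values[:3, :15] += 2
        values[3:6, 15:] += 2
        m = _lognorm(values)
        degs = call_degs(m, list(m.cell_ids[:15]), list(m.cell_ids[15:]))
        assert ((degs["log2fc"] > 0) == (degs["direction"] == "up")).all()
        assert (degs["fdr"] >= degs["p"] - 1e-12).all()


def test_overlap_sets_arithmetic():
    assert overlap_sets(["a", "b"], ["a", "b"]) == (0, 2, 0, ["a", "b"])
    assert overlap_sets(["a"], ["b"])[:3] == (1, 0, 1)
    assert overlap_sets(["a", "b", "c"], ["b", "c", "d"])[:3] == (1, 2, 1)


class TestStratified:
    def test_single_sex_skipped_with_warning(self, default_dataset):
        ln, meta = default_dataset["lognorm"], default_dataset["meta"]
        only_f = meta[meta["sex"] == "F"].reset_index(drop=True)
        sub = ln.subset_cells(list(only_f["cell_id"]))
        with pytest.warns(UserWarning, match="lacks an age group"):
            out = stratified_degs(
                sub,
                only_f.assign(sex=np.where(
                    only_f["age_group"] == "old", "F", "M")),
                "beta",
            )
        assert None in out.values()

    def test_male_only_program_stays_male_specific(self):
        genes = {f"MPRG{i:02d}": 1.2 for i in range(40)}
        cfg = default_config(
            n_cells_total=2400, n_genes=1500,
            noise_inflation={}, noise_coupling={}, hub=None,
            aging_program={"beta": [AgingProgram(genes, sexes=("M",))]},
            type_proportions={"alpha": 0.3, "beta": 0.7},
            baseline_boost={g: 10.0 for g in genes},
        )
        ln, meta, truth = simulate_lognorm(cfg, seed=3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = stratified_degs(ln, meta, "beta")
        planted = set(genes)
        male = out.get("M")
        assert male is not None
        male_up = set(male.query("direction == 'up'")["gene"])
        assert len(male_up & planted) / len(planted) >= 0.8
        female = out.get("F")
        female_up = (set() if female is None
                     else set(female.query("direction == 'up'")["gene"]))
        assert len(female_up & planted) <= 0.1 * len(planted)


def test_direct_null_calibration():
    """Without aging effects the direct comparison calls few DEGs."""
    cfg = default_config(
        aging_program={}, noise_inflation={}, noise_coupling={}, hub=None,
        n_genes=2000, n_cells_total=1500,
    )
    ln, meta, _ = simulate_lognorm(cfg, seed=12)
    degs = direct_degs(ln, meta, "alpha")
    assert len(degs) <= 0.05 * ln.n_genes
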