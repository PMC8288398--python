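"""Synthetic islet scRNA-seq generator with known ground truth.

Emulates the study design the pipeline targets: four endocrine cell types
(alpha/beta/delta/PP) sampled from 16 cynomolgus-monkey donors (8 young,
8 old, both sexes), ~5 575 cells, UMI counts from a negative-binomial
(gamma-Poisson) hierarchy with log-normal library sizes and per-donor
multiplicative batch effects, plus planted structure every downstream stage
must recover:

* canonical + auxiliary marker genes enriched per cell type,
* an aging expression program (log2 fold changes applied to old donors'
  cells of a type, optionally restricted to one sex),
* age-inflated overdispersion in selected cell types, with per-cell
  heterogeneity so that "noise-coupled" genes can track the realized
  inflation (the Fig-2G-style noise-correlated genes of the study),
* ligand-receptor pairs enriched in sender/receiver types,
* a hub regulator whose latent per-cell activity modulates its targets.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix

CELL_TYPES = ("alpha", "beta", "delta", "pp")

#: canonical hormone marker per endocrine type
HORMONES = {"alpha": "GCG", "beta": "INS", "delta": "SST", "pp": "PPY"}

#: transcription-factor list used by default for regulatory-network inference
DEFAULT_TFS = (
    "HSPA5", "XBP1", "MAFA", "NKX6-1", "IRX2", "FEV", "HHEX", "RXRG", "EHF",
    "TF_01", "TF_02", "TF_03", "TF_04", "TF_05", "TF_06", "TF_07", "TF_08",
)


@dataclass
class AgingProgram:
    """A set of log2 fold changes applied to old donors' cells of one type.

    ``sexes`` restricts the program to old donors of those sexes (both by
    default), which is how sex-specific aging programs are planted.
    """

    log2fc: dict[str, float]
    sexes: tuple[str, ...] = ("F", "M")


@dataclass
class NoiseCoupling:
    """Genes whose mean tracks a cell's realized dispersion inflation.

    For an old cell of an inflated type with per-cell inflation ``lam``, each
    coupled gene's mean is multiplied by ``lam ** strength``; young cells
    (lam = 1) are untouched. This creates genes whose expression correlates
    with measured transcriptional noise, and which are genuinely upregulated
    with age (expected log2FC recorded in the truth tables). Coupled genes
    get their own (tight) negative-binomial dispersion ``theta``: genes that
    track a latent stress factor closely are necessarily low-dispersion
    around it, like the ER chaperones of the aged-islet noise program.
    """

    genes: tuple[str, ...]
    strength: float = 3.0
    theta: float = 8.0


@dataclass
class LRPair:
    ligand: str
    receptor: str
    sender: str = "alpha"
    receiver: str = "beta"
    planted: bool = False
    log2_enrichment: float = 3.0


@dataclass
class HubSpec:
    """A regulator whose latent per-cell activity drives its targets."""

    regulator: str
    targets: tuple[str, ...]
    latent_sd: float = 0.6
    strength: float = 1.0


@dataclass
class SimConfig:
    n_donors_young: int = 8
    n_donors_old: int = 8
    n_cells_total: int = 5575
    type_proportions: dict[str, float] = field(
        default_factory=lambda: {"alpha": 0.50, "beta": 0.20, "delta": 0.15, "pp": 0.15}
    )
    n_genes: int = 6000
    baseline_sigma: float = 1.2  # log-normal spread of relative abundances
    baseline_boost: dict[str, float] = field(default_factory=dict)
    mean_theta: float = 2.0  # NB inverse-dispersion (size) location
    theta_sigma: float = 0.4
    donor_effect_sd: float = 0.2  # log2-scale sd of per-donor batch factors
    type_profile_sd: float = 0.0  # log2-scale sd of genome-wide per-type profile
    marker_spec: dict[str, dict[str, float]] = field(default_factory=dict)
    aging_program: dict[str, list[AgingProgram]] = field(default_factory=dict)
    noise_inflation: dict[str, float] = field(default_factory=dict)
    inflation_shape: float = 1.0  # gamma shape of per-cell inflation spread
    noise_coupling: dict[str, NoiseCoupling] = field(default_factory=dict)
    lr_pairs: list[LRPair] = field(default_factory=list)
    hub: HubSpec | None = None
    library_size_mean: float = 5e4
    library_size_sigma: float = 0.35
    seed: int = 0

    # -- derived -------------------------------------------------------------
    def named_genes(self) -> list[str]:
        """All genes the config refers to explicitly, in deterministic order."""
        out: list[str] = []
        seen = set()

        def add(g):
            if g not in seen:
                seen.add(g)
                out.append(g)

        for t in self.marker_spec:
            for g in self.marker_spec[t]:
                add(g)
        for t in self.aging_program:
            for prog in self.aging_program[t]:
                for g in prog.log2fc:
                    add(g)
        for t in self.noise_coupling:
            for g in self.noise_coupling[t].genes:
                add(g)
        for pair in self.lr_pairs:
            add(pair.ligand)
            add(pair.receptor)
        if self.hub is not None:
            add(self.hub.regulator)
            for g in self.hub.targets:
                add(g)
        for g in self.baseline_boost:
            add(g)
        return out

    def gene_universe(self) -> list[str]:
        """Named genes first, generic fillers (G00001...) up to n_genes."""
        named = self.named_genes()
        generic = (f"G{i:05d}" for i in range(1, self.n_genes + 1))
        fillers = [g for g in generic if g not in set(named)]
        universe = named + fillers[: self.n_genes - len(named)]
        return universe[: self.n_genes]

    def validate(self) -> None:
        total = sum(self.type_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_proportions sum to {total}, not 1")
        if any(p < 0 for p in self.type_proportions.values()):
            raise ValueError("negative type proportion")
        if self.n_donors_young + self.n_donors_old < 2:
            raise ValueError("need at least 2 donors")
        for t, mult in self.noise_inflation.items():
            if mult < 1:
                raise ValueError(f"noise_inflation[{t}] = {mult} < 1")
        universe = set(self.gene_universe())
        missing = [g for g in self.named_genes() if g not in universe]
        if missing:
            raise ValueError(
                f"planted genes outside the {self.n_genes}-gene universe: "
                f"{missing[:5]}"
            )
        counts = _type_counts(self.type_proportions, self.n_cells_total)
        if any(c < 1 for c in counts.values()):
            raise ValueError("fewer than 1 cell for some cell type")

    # -- YAML ----------------------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_to_dict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return _config_from_dict(yaml.safe_load(Path(path).read_text()))


def _config_to_dict(c: SimConfig) -> dict:
    d = {
        k: getattr(c, k)
        for k in (
            "n_donors_young", "n_donors_old", "n_cells_total", "n_genes",
            "baseline_sigma", "mean_theta", "theta_sigma", "donor_effect_sd",
            "type_profile_sd", "inflation_shape", "library_size_mean",
            "library_size_sigma", "seed",
        )
    }
    d["type_proportions"] = dict(c.type_proportions)
    d["baseline_boost"] = dict(c.baseline_boost)
    d["marker_spec"] = {t: dict(v) for t, v in c.marker_spec.items()}
    d["aging_program"] = {
        t: [{"log2fc": dict(p.log2fc), "sexes": list(p.sexes)} for p in progs]
        for t, progs in c.aging_program.items()
    }
    d["noise_inflation"] = dict(c.noise_inflation)
    d["noise_coupling"] = {
        t: {"genes": list(v.genes), "strength": v.strength, "theta": v.theta}
        for t, v in c.noise_coupling.items()
    }
    d["lr_pairs"] = [
        {
            "ligand": p.ligand, "receptor": p.receptor, "sender": p.sender,
            "receiver": p.receiver, "planted": p.planted,
            "log2_enrichment": p.log2_enrichment,
        }
        for p in c.lr_pairs
    ]
    d["hub"] = (
        None
        if c.hub is None
        else {
            "regulator": c.hub.regulator, "targets": list(c.hub.targets),
            "latent_sd": c.hub.latent_sd, "strength": c.hub.strength,
        }
    )
    return d


def _config_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "aging_program" in d:
        d["aging_program"] = {
            t: [AgingProgram(p["log2fc"], tuple(p.get("sexes", ("F", "M")))) for p in progs]
            for t, progs in d["aging_program"].items()
        }
    if "noise_coupling" in d:
        d["noise_coupling"] = {
            t: NoiseCoupling(tuple(v["genes"]), float(v.get("strength", 3.0)),
                             float(v.get("theta", 8.0)))
            for t, v in d["noise_coupling"].items()
        }
    if "lr_pairs" in d:
        d["lr_pairs"] = [LRPair(**p) for p in d["lr_pairs"]]
    if d.get("hub") is not None:
        h = d["hub"]
        d["hub"] = HubSpec(
            h["regulator"], tuple(h["targets"]),
            float(h.get("latent_sd", 0.6)), float(h.get("strength", 1.0)),
        )
    return SimConfig(**d)


# ---------------------------------------------------------------------------
def default_config(**overrides) -> SimConfig:
    """The study-design configuration: 16 donors, 5 575 cells, 4 types,
    aging programs and inflated overdispersion in alpha- and beta-cells,
    UPR-flavoured beta program, planted ligand-receptor pairs and an HSPA5
    hub. Keyword overrides replace fields of the returned config."""
    marker_spec = {
        "alpha": {"GCG": 5.0, "TSPAN12": 2.0, "ARRDC4": 2.0, "IRX2": 2.0, "FEV": 2.0,
                  **{f"MKA_{i:02d}": 2.0 for i in range(1, 11)}},
        "beta": {"INS": 5.0, "IAPP": 3.0, "SLC2A2": 2.0, "ERO1B": 2.0,
                 "TMEM132B": 2.0, "NKX6-1": 2.0, "MAFA": 2.0, "RXRG": 2.0,
                 **{f"MKB_{i:02d}": 2.0 for i in range(1, 8)}},
        "delta": {"SST": 5.0, "HHEX": 2.0, "ANK3": 2.0, "EHF": 2.0,
                  "CSGALNACT1": 2.0, **{f"MKD_{i:02d}": 2.0 for i in range(1, 11)}},
        "pp": {"PPY": 5.0, "UGT2B20": 2.0, **{f"MKP_{i:02d}": 2.0 for i in range(1, 14)}},
    }
    beta_up = [
        "HSP90B1", "HSPA5", "CALR", "PDIA3", "PDIA4", "PDIA5", "PDIA6",
        "DNAJB11", "DNAJB9", "DNAJC3", "HYOU1", "XBP1", "SPP1", "APOD",
        "SERPINA1", "SORL1", "SDF2L1", "SEC61B", "SSR4", "EDEM1",
        "CDKN1A", "CDKN2A",
    ] + [f"AGEB_U{i:02d}" for i in range(23, 51)]
    beta_down = [f"AGEB_D{i:02d}" for i in range(1, 51)]
    alpha_up = ["TTR", "SPP1", "APOD", "SERPINA1", "CDKN1A", "CDKN2A"] + [
        f"AGEA_U{i:02d}" for i in range(7, 41)
    ]
    alpha_down = [f"AGEA_D{i:02d}" for i in range(1, 41)]
    aging_program = {
        "alpha": [AgingProgram({**{g: 1.0 for g in alpha_up},
                                **{g: -1.0 for g in alpha_down}})],
        "beta": [AgingProgram({**{g: 1.0 for g in beta_up},
                               **{g: -1.0 for g in beta_down}})],
    }
    noise_coupling = {
        "alpha": NoiseCoupling(tuple(f"NCA_{i:02d}" for i in range(1, 21))),
        "beta": NoiseCoupling(
            ("CANX", "ERP29", "ERP44", "MANF", "P4HB")
            + tuple(f"NCB_{i:02d}" for i in range(6, 21))
        ),
    }
    lr_pairs = [
        LRPair("TTR", "DDR1", "alpha", "beta", planted=True),
        LRPair("APP", "SORL1", "alpha", "beta", planted=True),
    ] + [
        LRPair(f"LIG{i:02d}", f"REC{i:02d}",
               CELL_TYPES[i % 4], CELL_TYPES[(i + 1) % 4])
        for i in range(1, 9)
    ]
    # targets exclude TF-list genes so the hub is the only regulator that
    # shares the latent activity with its targets
    hub_targets = tuple(g for g in beta_up if g not in set(DEFAULT_TFS))[:30]
    boost = {h: 200.0 for h in HORMONES.values()}
    boost.update({g: 10.0 for g in ("HSP90B1", "HSPA5", "CALR", "PDIA3",
                                    "PDIA4", "P4HB", "CANX", "IAPP", "TTR")})
    for t, spec in marker_spec.items():
        for g in spec:
            boost.setdefault(g, 3.0)
    # aging-program and noise-coupled genes sit at chaperone-like abundance:
    # the study's aging DEGs are well-detected genes, not dropout-dominated
    for genes in (beta_up, beta_down, alpha_up, alpha_down):
        for g in genes:
            boost.setdefault(g, 10.0)
    for nc in noise_coupling.values():
        for g in nc.genes:
            boost.setdefault(g, 10.0)
    for p in lr_pairs:
        boost.setdefault(p.ligand, 4.0)
        boost.setdefault(p.receptor, 4.0)
    for g in DEFAULT_TFS:
        boost.setdefault(g, 4.0)
    cfg = SimConfig(
        marker_spec=marker_spec,
        aging_program=aging_program,
        noise_inflation={"alpha": 1.5, "beta": 1.5},
        noise_coupling=noise_coupling,
        lr_pairs=lr_pairs,
        hub=HubSpec("HSPA5", hub_targets),
        baseline_boost=boost,
        # endocrine types differ genome-wide (hundreds of DE genes per type),
        # not just at the named markers; donor batch effects are milder
        type_profile_sd=0.5,
        donor_effect_sd=0.1,
        # abundance spread and depth calibrated to ~4 389 genes detected/cell
        baseline_sigma=1.6,
        library_size_mean=1e5,
    )
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def axis_scenario_config(**overrides) -> SimConfig:
    """Aging-axis recovery scenario: the study-design config with only the
    aging programs planted (no dispersion inflation, noise coupling or hub,
    which are separate planted structures with their own recovery checks),
    at the 3 000-gene scale used for program-recovery checks."""
    cfg = default_config(
        noise_coupling={}, noise_inflation={}, hub=None, n_genes=3000,
        donor_effect_sd=0.2,
    )
    return replace(cfg, **overrides) if overrides else cfg


def null_config(
    n_cells: int = 240,
    n_genes: int = 400,
    cell_type: str = "alpha",
    donor_effect_sd: float = 0.0,
    **overrides,
) -> SimConfig:
    """Small single-type dataset with no planted structure, for null
    calibrations (uniform p-values, type-I error of the axis search)."""
    cfg = SimConfig(
        n_cells_total=n_cells,
        n_genes=n_genes,
        type_proportions={cell_type: 1.0},
        donor_effect_sd=donor_effect_sd,
        library_size_mean=2e4,
    )
    return replace(cfg, **overrides) if overrides else cfg


def hub_scenario_config(**overrides) -> SimConfig:
    """Hub-recovery scenario: one beta-cell population with an HSPA5 hub
    driving 30 targets through a strong latent activity; no aging program,
    so co-expression alone must reveal the hub."""
    targets = tuple(f"TGT_{i:02d}" for i in range(1, 31))
    boost = {"HSPA5": 10.0}
    boost.update({g: 6.0 for g in targets})
    boost.update({g: 6.0 for g in DEFAULT_TFS})
    cfg = SimConfig(
        n_cells_total=800,
        n_genes=1000,
        type_proportions={"beta": 1.0},
        donor_effect_sd=0.1,
        hub=HubSpec("HSPA5", targets, latent_sd=0.8, strength=1.0),
        baseline_boost=boost,
        library_size_mean=2e4,
    )
    return replace(cfg, **overrides) if overrides else cfg


def lr_null_config(n_pairs: int = 63, **overrides) -> SimConfig:
    """Four balanced cell types with many unplanted ligand-receptor pairs,
    all well expressed, for permutation-test type-I calibration."""
    pairs = [
        LRPair(f"NLIG{i:02d}", f"NREC{i:02d}", CELL_TYPES[i % 4],
               CELL_TYPES[(i + 1) % 4], planted=False)
        for i in range(1, n_pairs + 1)
    ]
    boost = {}
    for p in pairs:
        boost[p.ligand] = 8.0
        boost[p.receptor] = 8.0
    cfg = SimConfig(
        n_cells_total=480,
        n_genes=400,
        type_proportions={t: 0.25 for t in CELL_TYPES},
        donor_effect_sd=0.0,
        lr_pairs=pairs,
        baseline_boost=boost,
        library_size_mean=2e4,
    )
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, as flat tables."""

    cells: pd.DataFrame  # cell_id, donor_id, age_group, sex, cell_type
    gene_ids: list[str]
    markers: pd.DataFrame  # cell_type, gene, log2_enrichment
    aging_degs: pd.DataFrame  # cell_type, gene, log2fc, direction, sexes
    noise_inflation: pd.DataFrame  # cell_type, multiplier
    coupled_genes: pd.DataFrame  # cell_type, gene, strength, expected_log2fc
    lr_pairs: pd.DataFrame  # ligand, receptor, sender, receiver, planted
    hub_edges: pd.DataFrame  # regulator, target, strength

    def aging_genes(self, cell_type: str, direction: str | None = None) -> list[str]:
        t = self.aging_degs[self.aging_degs["cell_type"] == cell_type]
        if direction is not None:
            t = t[t["direction"] == direction]
        return list(t["gene"])


def truth_report(truth: SimTruth) -> dict[str, pd.DataFrame]:
    """Flat tables of everything planted, for test harnesses."""
    return {
        "aging_degs": truth.aging_degs,
        "markers": truth.markers,
        "noise_inflation": truth.noise_inflation,
        "coupled_genes": truth.coupled_genes,
        "lr_pairs": truth.lr_pairs,
        "hub_edges": truth.hub_edges,
    }


def write_truth(truth: SimTruth, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(path / "truth_cells.tsv", sep="\t", index=False)
    for name, table in truth_report(truth).items():
        table.to_csv(path / f"truth_{name}.tsv", sep="\t", index=False)


def _type_counts(props: dict[str, float], total: int) -> dict[str, int]:
    """Largest-remainder apportionment of cells to types."""
    items = list(props.items())
    raw = [total * p for _, p in items]
    base = [int(math.floor(r)) for r in raw]
    rem = total - sum(base)
    order = sorted(range(len(items)), key=lambda i: raw[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return {t: n for (t, _), n in zip(items, base)}


def expected_inflation_pow(mult: float, strength: float, shape: float) -> float:
    """E[(1 + (mult-1) G)^strength] for G ~ Gamma(shape, 1/shape).

    The expected multiplicative effect of noise coupling on an old cell's
    coupled-gene mean; integer strengths use the exact moment expansion.
    """
    if mult <= 1:
        return 1.0
    a = mult - 1.0
    if float(strength).is_integer():
        s = int(strength)
        # E[G^j] for Gamma(k, 1/k)
        total = 0.0
        for j in range(s + 1):
            mom = math.prod((shape + i) for i in range(j)) / shape**j
            total += math.comb(s, j) * a**j * mom
        return total
    from scipy import integrate, stats as sps

    val, _ = integrate.quad(
        lambda g: (1 + a * g) ** strength * sps.gamma.pdf(g, shape, scale=1 / shape),
        0, np.inf,
    )
    return float(val)


# ---------------------------------------------------------------------------
def generate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame, SimTruth]:
    """Draw one dataset: raw UMI counts, cell metadata and the ground truth.

    ``seed`` overrides ``config.seed``; the draw is deterministic given the
    (config, seed) pair.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    genes = config.gene_universe()
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    # donors: alternating sexes within each age group
    donors = []
    for i in range(config.n_donors_young):
        donors.append((f"Y{i + 1}", "young", "F" if i % 2 == 0 else "M"))
    for i in range(config.n_donors_old):
        donors.append((f"O{i + 1}", "old", "F" if i % 2 == 0 else "M"))
    donor_df = pd.DataFrame(donors, columns=["donor_id", "age_group", "sex"])

    # cells: exact per-type counts, shuffled order, donors drawn uniformly
    counts_per_type = _type_counts(config.type_proportions, config.n_cells_total)
    type_labels = np.concatenate(
        [np.repeat(t, n) for t, n in counts_per_type.items()]
    )
    type_labels = type_labels[rng.permutation(config.n_cells_total)]
    donor_idx = rng.integers(0, len(donors), size=config.n_cells_total)
    cells = pd.DataFrame(
        {
            "cell_id": [f"C{i + 1:05d}" for i in range(config.n_cells_total)],
            "donor_id": donor_df["donor_id"].to_numpy()[donor_idx],
            "age_group": donor_df["age_group"].to_numpy()[donor_idx],
            "sex": donor_df["sex"].to_numpy()[donor_idx],
            "cell_type": type_labels,
        }
    )
    t_idx = np.array([CELL_TYPES.index(t) if t in CELL_TYPES else 0
                      for t in type_labels])
    type_names = list(dict.fromkeys(type_labels))

    # per-gene parameters; boosted genes belong to a known abundance class
    # (hormones, chaperones, ...), so their spread is kept narrow
    pi = rng.lognormal(0.0, config.baseline_sigma, n_genes)
    for g, b in config.baseline_boost.items():
        pi[gidx[g]] = b * rng.lognormal(0.0, 0.25)
    theta = np.clip(
        rng.lognormal(np.log(config.mean_theta), config.theta_sigma, n_genes),
        0.2, 50.0,
    )
    for nc in config.noise_coupling.values():
        for g in nc.genes:
            theta[gidx[g]] = nc.theta

    # per-type multipliers (genome-wide profile + markers + LR planting)
    type_mult = np.ones((n_genes, len(CELL_TYPES)), dtype=np.float32)
    if config.type_profile_sd > 0:
        psd = config.type_profile_sd * np.log(2.0)
        type_mult *= rng.lognormal(
            -0.5 * psd * psd, psd, size=(n_genes, len(CELL_TYPES))
        ).astype(np.float32)
    for t, spec in config.marker_spec.items():
        ti = CELL_TYPES.index(t)
        for g, enr in spec.items():
            type_mult[gidx[g], ti] *= 2.0 ** enr
    for pair in config.lr_pairs:
        if pair.planted:
            type_mult[gidx[pair.ligand], CELL_TYPES.index(pair.sender)] *= (
                2.0 ** pair.log2_enrichment
            )
            type_mult[gidx[pair.receptor], CELL_TYPES.index(pair.receiver)] *= (
                2.0 ** pair.log2_enrichment
            )

    # donor batch factors (log-normal, unit mean; sd on the log2 scale,
    # matching the units of every other effect size in the config)
    if config.donor_effect_sd > 0:
        sd = config.donor_effect_sd * np.log(2.0)
        donor_mult = rng.lognormal(
            -0.5 * sd * sd, sd, size=(n_genes, len(donors))
        ).astype(np.float32)
    else:
        donor_mult = np.ones((n_genes, len(donors)), dtype=np.float32)

    # rate matrix
    rate = (pi[:, None] * type_mult[:, t_idx]).astype(np.float32)
    rate *= donor_mult[:, donor_idx]

    old_mask = (cells["age_group"] == "old").to_numpy()

    # aging programs
    for t, progs in config.aging_program.items():
        for prog in progs:
            cols = np.flatnonzero(
                old_mask
                & (type_labels == t)
                & cells["sex"].isin(prog.sexes).to_numpy()
            )
            if cols.size == 0:
                continue
            vec = np.ones(n_genes, dtype=np.float32)
            for g, lfc in prog.log2fc.items():
                vec[gidx[g]] = 2.0 ** lfc
            rate[:, cols] *= vec[:, None]

    # hub latent activity
    if config.hub is not None:
        u = np.exp(rng.normal(0.0, config.hub.latent_sd, config.n_cells_total))
        rate[gidx[config.hub.regulator]] *= u
        tg_rows = np.array([gidx[g] for g in config.hub.targets])
        rate[tg_rows] *= (u[None, :] ** config.hub.strength).astype(np.float32)

    # per-cell dispersion inflation (old cells of flagged types)
    lam = np.ones(config.n_cells_total)
    for t, mult in config.noise_inflation.items():
        cols = np.flatnonzero(old_mask & (type_labels == t))
        if cols.size and mult > 1:
            g = rng.gamma(config.inflation_shape, 1.0 / config.inflation_shape,
                          cols.size)
            lam[cols] = 1.0 + (mult - 1.0) * g

    # noise-coupled genes track realized inflation
    for t, nc in config.noise_coupling.items():
        cols = np.flatnonzero(type_labels == t)
        rows = np.array([gidx[g] for g in nc.genes])
        if cols.size and rows.size:
            rate[np.ix_(rows, cols)] *= (
                lam[cols][None, :] ** nc.strength
            ).astype(np.float32)

    # library sizes; per-cell normalization so totals follow the library
    lib = rng.lognormal(
        np.log(config.library_size_mean) - 0.5 * config.library_size_sigma**2,
        config.library_size_sigma,
        config.n_cells_total,
    )
    col_sums = rate.sum(axis=0)
    mean = rate * (lib / col_sums)[None, :].astype(np.float32)

    # gamma-Poisson draw with per-cell inflated dispersion
    theta_mat = (theta[:, None] / lam[None, :]).astype(np.float32)
    shape_gamma = rng.gamma(theta_mat, mean / theta_mat)
    counts = rng.poisson(shape_gamma).astype(np.int32)

    m = ExpressionMatrix(counts, np.array(genes, dtype=object),
                         cells["cell_id"].to_numpy(), layer="raw")
    truth = _build_truth(config, cells, genes)
    return m, cells.copy(), truth


def _build_truth(config: SimConfig, cells: pd.DataFrame, genes: list[str]) -> SimTruth:
    marker_rows = [
        {"cell_type": t, "gene": g, "log2_enrichment": enr}
        for t, spec in config.marker_spec.items()
        for g, enr in spec.items()
    ]
    deg_rows = []
    for t, progs in config.aging_program.items():
        for prog in progs:
            for g, lfc in prog.log2fc.items():
                deg_rows.append(
                    {"cell_type": t, "gene": g, "log2fc": lfc,
                     "direction": "up" if lfc > 0 else "down",
                     "sexes": "".join(prog.sexes)}
                )
    coupled_rows = []
    for t, nc in config.noise_coupling.items():
        mult = config.noise_inflation.get(t, 1.0)
        eff = expected_inflation_pow(mult, nc.strength, config.inflation_shape)
        lfc = math.log2(eff)
        for g in nc.genes:
            coupled_rows.append(
                {"cell_type": t, "gene": g, "strength": nc.strength,
                 "expected_log2fc": lfc}
            )
            if lfc > 0:
                deg_rows.append(
                    {"cell_type": t, "gene": g, "log2fc": lfc,
                     "direction": "up", "sexes": "FM"}
                )
    lr_rows = [
        {"ligand": p.ligand, "receptor": p.receptor, "sender": p.sender,
         "receiver": p.receiver, "planted": p.planted}
        for p in config.lr_pairs
    ]
    hub_rows = (
        []
        if config.hub is None
        else [
            {"regulator": config.hub.regulator, "target": g,
             "strength": config.hub.strength}
            for g in config.hub.targets
        ]
    )
    empty = lambda cols: pd.DataFrame(columns=cols)  # noqa: E731
    return SimTruth(
        cells=cells.copy(),
        gene_ids=list(genes),
        markers=pd.DataFrame(marker_rows) if marker_rows
        else empty(["cell_type", "gene", "log2_enrichment"]),
        aging_degs=pd.DataFrame(deg_rows) if deg_rows
        else empty(["cell_type", "gene", "log2fc", "direction", "sexes"]),
        noise_inflation=pd.DataFrame(
            [{"cell_type": t, "multiplier": v}
             for t, v in config.noise_inflation.items()]
        ) if config.noise_inflation else empty(["cell_type", "multiplier"]),
        coupled_genes=pd.DataFrame(coupled_rows) if coupled_rows
        else empty(["cell_type", "gene", "strength", "expected_log2fc"]),
        lr_pairs=pd.DataFrame(lr_rows) if lr_rows
        else empty(["ligand", "receptor", "sender", "receiver", "planted"]),
        hub_edges=pd.DataFrame(hub_rows) if hub_rows
        else empty(["regulator", "target", "strength"]),
    )
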