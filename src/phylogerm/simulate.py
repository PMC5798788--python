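"""Synthetic germination datasets with the study's statistical structure.

The generator reproduces the experimental design — 8 species, 2–4
populations each (24 in total), four stratification regimes crossed with
two incubation regimes, four replicate plates of 25 seeds — and draws
germination counts from the same generative model the spike-and-slab GLMM
assumes: phylogenetically correlated species-level coefficient families,
independent population-level effects, per-species inclusion indicators,
a logit link, binomial sampling, and imperfect seed fill (so viability
adjustment is exercised end to end).  Monthly climate series emulate the
southwest-US source sites: mean annual temperatures of roughly 2–16 °C,
annual precipitation of roughly 180–560 mm, and a continuum between
summer-monsoon and winter-precipitation regimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .phylo import relatedness_matrix, write_newick
from .spikeslab import FAMILIES, PARENTS, POPULATION_FAMILIES
from .traits import INCUB_REGIMES, STRAT_REGIMES, PlateRecord, strat_label


def simulate_tree(n_species: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with root depth normalized to 1.

    Tips are labeled ``sp1 ... spN``.  The process starts from the two
    root lineages; waiting times between speciation events are exponential
    with rate proportional to the number of extant lineages.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    birth: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth[child] = 0.0
        active.append(child)
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        node.edge.length = t - birth[node]
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.edge.length = t_end - birth[node]
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = tns.new_taxon(f"sp{i + 1}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t_end
    tree.is_rooted = True
    return tree


def simulate_climate(populations: Sequence[str], seed: int) -> pd.DataFrame:
    """Monthly tmin/tmax/precipitation series for each population.

    Temperature follows a sinusoid peaking in July; precipitation is a
    mixture of a summer-monsoon profile (July–August peak) and a winter
    profile (December–February peak), with the mixture weight varying
    across populations so that precipitation seasonality (BIO15) differs
    between sites.
    """
    rng = np.random.default_rng(seed)
    months = np.arange(12)
    monsoon = np.exp(-0.5 * ((months - 6.5) / 1.2) ** 2)
    monsoon /= monsoon.sum()
    shifted = (months + 6) % 12  # winter peak at Dec-Jan
    winter = np.exp(-0.5 * ((shifted - 6.0) / 2.0) ** 2)
    winter /= winter.sum()
    rows = []
    for pop in populations:
        mat = rng.uniform(2.0, 16.0)
        amp = rng.uniform(8.0, 14.0)
        diurnal = rng.uniform(10.0, 16.0)
        ap = rng.uniform(180.0, 560.0)
        w = rng.uniform(0.0, 1.0)  # monsoon weight
        tavg = mat - amp * np.cos(2 * np.pi * months / 12.0)
        profile = w * monsoon + (1 - w) * winter
        prec = ap * profile
        for m in months:
            rows.append(
                {
                    "population_id": pop,
                    "month": int(m) + 1,
                    "tmin": round(float(tavg[m] - diurnal / 2), 3),
                    "tmax": round(float(tavg[m] + diurnal / 2), 3),
                    "prec": round(float(prec[m]), 3),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and generative-model settings."""

    n_species: int = 8
    populations_per_species: tuple[int, ...] = (4, 3, 3, 4, 2, 2, 4, 2)
    replicates: int = 4
    seeds_per_plate: int = 25
    fill_rate: float = 0.9
    #: per-family inclusion pattern: scalar 0/1, a per-species sequence, or
    #: "prior" to draw from the hierarchical Bernoulli(0.5) prior
    true_delta: Mapping[str, object] = field(default_factory=dict)
    #: per-family coefficient scale (sigma for species-level families, the
    #: N(0, sd) scale for population-level families)
    effect_sd: Mapping[str, float] = field(default_factory=dict)
    intercept_mean: float = 0.0
    #: probability that a germinant germinated during (rather than after)
    #: stratification, by stratification regime label
    strat_germ_frac: Mapping[str, float] = field(
        default_factory=lambda: {"none": 0.0, "3wk/3C": 0.3, "8wk/3C": 0.4, "3wk/30C": 0.6}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.populations_per_species) != self.n_species:
            raise ValueError("populations_per_species length must equal n_species")
        if not (0.0 < self.fill_rate <= 1.0):
            raise ValueError("fill_rate must be in (0, 1]")


@dataclass
class SimulationTruth:
    """Everything sampled by the generator, for recovery checks."""

    tree_newick: str
    A: pd.DataFrame
    delta: dict[str, np.ndarray]
    beta: dict[str, np.ndarray]
    mu: dict[str, np.ndarray]
    sigma: dict[str, float]
    species: list[str]
    populations: list[str]
    cell_probabilities: pd.DataFrame


def _delta_for_family(
    cfg: SimulationConfig, family: str, n_species: int, rng: np.random.Generator, drawn: dict
) -> np.ndarray:
    setting = cfg.true_delta.get(family, "prior")
    if isinstance(setting, str) and setting == "prior":
        d = rng.integers(0, 2, size=n_species).astype(np.int8)
    elif np.isscalar(setting):
        d = np.full(n_species, int(setting), dtype=np.int8)
    else:
        d = np.asarray(setting, dtype=np.int8)
        if d.shape != (n_species,):
            raise ValueError(f"true_delta[{family}] must have one entry per species")
    if family in PARENTS:
        a, b = PARENTS[family]
        d = d * drawn[a] * drawn[b]
    return d


def simulate_germination(
    cfg: SimulationConfig,
    tree: Optional[dendropy.Tree] = None,
) -> tuple[list[PlateRecord], SimulationTruth]:
    """Draw a full plate-level dataset from the GLMM generative model."""
    root = np.random.SeedSequence(cfg.seed)
    s_tree, s_params, s_counts = root.spawn(3)
    if tree is None:
        tree = simulate_tree(cfg.n_species, np.random.default_rng(s_tree).integers(2**31))
    A_df = relatedness_matrix(tree)
    species = list(A_df.index)
    if len(species) != cfg.n_species:
        raise ValueError("tree tip count must equal n_species")
    L = np.linalg.cholesky(A_df.to_numpy() + 1e-10 * np.eye(cfg.n_species))
    populations = [
        f"{sp}_p{k + 1}"
        for sp, npop in zip(species, cfg.populations_per_species)
        for k in range(npop)
    ]
    pop_species = np.repeat(np.arange(cfg.n_species), cfg.populations_per_species)

    sl_levels = sorted({sl for sl, _ in STRAT_REGIMES})
    st_levels = sorted({f"{st:g}" for _, st in STRAT_REGIMES if st is not None})
    it_levels = list(INCUB_REGIMES)
    strat_combos = sorted(
        {(sl, f"{st:g}") for sl, st in STRAT_REGIMES if st is not None}
    )
    slit_combos = sorted({(sl, it) for sl, _ in STRAT_REGIMES for it in it_levels})
    stit_combos = sorted({(st, it) for st in st_levels for it in it_levels})
    level_count = {
        "SL": len(sl_levels),
        "ST": len(st_levels),
        "IT": len(it_levels),
        "P": 1,
        "P:SL": len(sl_levels),
        "P:ST": len(st_levels),
        "P:IT": len(it_levels),
        "SL:ST": len(strat_combos),
        "SL:IT": len(slit_combos),
        "ST:IT": len(stit_combos),
    }

    rng = np.random.default_rng(s_params)
    delta: dict[str, np.ndarray] = {}
    for f in FAMILIES:
        delta[f] = _delta_for_family(cfg, f, cfg.n_species, rng, delta)

    beta: dict[str, np.ndarray] = {}
    mu: dict[str, np.ndarray] = {}
    sigma: dict[str, float] = {}
    # species intercepts: always-included correlated family
    sigma["S"] = float(cfg.effect_sd.get("S", 1.0))
    mu["S"] = np.array([cfg.intercept_mean])
    beta["S"] = (mu["S"][0] + sigma["S"] * (L @ rng.normal(size=cfg.n_species)))[:, None]
    for f in FAMILIES:
        sd = float(cfg.effect_sd.get(f, 1.0))
        nlev = level_count[f]
        if f in POPULATION_FAMILIES:
            beta[f] = rng.normal(0.0, sd, size=(len(populations), nlev))
            sigma[f] = sd
        else:
            sigma[f] = sd
            mu[f] = (
                rng.normal(0.0, 1.0, size=nlev)
                if f in ("SL", "ST", "IT")
                else np.zeros(nlev)
            )
            cols = [mu[f][l] + sd * (L @ rng.normal(size=cfg.n_species)) for l in range(nlev)]
            beta[f] = np.column_stack(cols)

    def lookup(f: str, sp: int, pop: int, sl: int, st: Optional[str], it: str) -> float:
        if delta[f][sp] == 0:
            return 0.0
        if f == "P":
            return beta[f][pop, 0]
        if f == "SL":
            return beta[f][sp, sl_levels.index(sl)]
        if f == "ST":
            return 0.0 if st is None else beta[f][sp, st_levels.index(st)]
        if f == "IT":
            return beta[f][sp, it_levels.index(it)]
        if f == "P:SL":
            return beta[f][pop, sl_levels.index(sl)]
        if f == "P:ST":
            return 0.0 if st is None else beta[f][pop, st_levels.index(st)]
        if f == "P:IT":
            return beta[f][pop, it_levels.index(it)]
        if f == "SL:ST":
            return 0.0 if st is None else beta[f][sp, strat_combos.index((sl, st))]
        if f == "SL:IT":
            return beta[f][sp, slit_combos.index((sl, it))]
        if f == "ST:IT":
            return 0.0 if st is None else beta[f][sp, stit_combos.index((st, it))]
        raise KeyError(f)

    crng = np.random.default_rng(s_counts)
    records: list[PlateRecord] = []
    prob_rows = []
    for pop_i, pop in enumerate(populations):
        sp = int(pop_species[pop_i])
        for sl, st_raw in STRAT_REGIMES:
            st = None if st_raw is None else f"{st_raw:g}"
            regime = strat_label(sl, st_raw)
            frac = float(cfg.strat_germ_frac.get(regime, 0.0))
            for it in it_levels:
                eta = beta["S"][sp, 0] + sum(
                    lookup(f, sp, pop_i, sl, st, it) for f in FAMILIES
                )
                p = 1.0 / (1.0 + np.exp(-eta))
                prob_rows.append(
                    {
                        "species": species[sp],
                        "population": pop,
                        "sl": sl,
                        "st": "none" if st is None else st,
                        "it": it,
                        "eta": float(eta),
                        "p": float(p),
                    }
                )
                for rep in range(1, cfg.replicates + 1):
                    filled = int(crng.binomial(cfg.seeds_per_plate, cfg.fill_rate))
                    germinated = int(crng.binomial(filled, p))
                    germ_strat = int(crng.binomial(germinated, frac))
                    records.append(
                        PlateRecord(
                            species_code=species[sp],
                            population_id=pop,
                            strat_length_weeks=sl,
                            strat_temp_c=st_raw,
                            incub_regime=it,
                            replicate=rep,
                            n_sown=cfg.seeds_per_plate,
                            germ_strat=germ_strat,
                            germ_incub=germinated - germ_strat,
                            filled_ungerminated=filled - germinated,
                        )
                    )
    truth = SimulationTruth(
        tree_newick=write_newick(tree),
        A=A_df,
        delta=delta,
        beta=beta,
        mu=mu,
        sigma=sigma,
        species=species,
        populations=populations,
        cell_probabilities=pd.DataFrame(prob_rows),
    )
    return records, truth
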