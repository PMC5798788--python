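"""Spike-and-slab phylogenetic GLMM: density, sampler and summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

import phylogerm as pg
from phylogerm import spikeslab, traits
from phylogerm.spikeslab import (
    FAMILIES,
    PARENTS,
    POPULATION_FAMILIES,
    MCMCSettings,
    ModelSpec,
    Posterior,
    Priors,
    SpikeSlabModel,
    inclusion_table,
    phylogeny_necessity_check,
)


def _toy_cells(n_species=2, n_pops=1, seed=0, n=25):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_species):
        for j in range(n_pops):
            for sl, st in ((0, "none"), (3, "3"), (8, "3"), (3, "30")):
                for it in ("20/10", "25/15"):
                    rows.append(
                        {
                            "species": f"sp{s + 1}",
                            "population": f"sp{s + 1}_p{j + 1}",
                            "sl": sl,
                            "st": st,
                            "it": it,
                            "y": int(rng.integers(0, n + 1)),
                            "n": n,
                        }
                    )
    return pd.DataFrame(rows)


def _identity_A(labels):
    return pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)


def _symbolic_eta(model, state, cell):
    """Independent term-by-term evaluation of the 11-term linear predictor."""
    s = model.species.index(cell["species"])
    p = model.populations.index(cell["population"])
    sl, st, it = cell["sl"], str(cell["st"]), cell["it"]
    beta, delta = state["beta"], state["delta"]
    eta = beta["S"][s, 0]

    def lvl(levels, key):
        return levels.index(key)

    for f in model.spec.families:
        if delta[f][s] == 0:
            continue
        if f == "P":
            eta += beta["P"][p, 0]
        elif f == "SL":
            eta += beta["SL"][s, lvl(model.sl_levels, sl)]
        elif f == "ST":
            if st != "none":
                eta += beta["ST"][s, lvl(model.st_levels, st)]
        elif f == "IT":
            eta += beta["IT"][s, lvl(model.it_levels, it)]
        elif f == "P:SL":
            eta += beta["P:SL"][p, lvl(model.sl_levels, sl)]
        elif f == "P:ST":
            if st != "none":
                eta += beta["P:ST"][p, lvl(model.st_levels, st)]
        elif f == "P:IT":
            eta += beta["P:IT"][p, lvl(model.it_levels, it)]
        elif f == "SL:ST":
            if st != "none":
                eta += beta["SL:ST"][s, model.level_labels["SL:ST"].index((sl, st))]
        elif f == "SL:IT":
            eta += beta["SL:IT"][s, model.level_labels["SL:IT"].index((sl, it))]
        elif f == "ST:IT":
            if st != "none":
                eta += beta["ST:IT"][s, model.level_labels["ST:IT"].index((st, it))]
    return eta


def test_linear_predictor_gates_closed_is_intercept():
    cells = _toy_cells()
    model = SpikeSlabModel(cells, _identity_A(["sp1", "sp2"]))
    state = model.initial_state(np.random.default_rng(0))
    for f in model.spec.families:
        state["delta"][f][:] = 0
    eta = model.eta(state)
    expected = state["beta"]["S"][model.s_idx, 0]
    np.testing.assert_allclose(eta, expected)


def test_linear_predictor_single_open_gate():
    cells = _toy_cells(n_species=1)
    model = SpikeSlabModel(cells, _identity_A(["sp1"]), spec=ModelSpec(("SL",)))
    state = model.initial_state(np.random.default_rng(0))
    state["beta"]["S"][:] = 0.0
    state["beta"]["SL"][:] = 0.0
    state["beta"]["SL"][0, model.sl_levels.index(8)] = 1.5
    state["delta"]["SL"][:] = 1
    eta = model.eta(state)
    expected = np.where(cells["sl"].to_numpy() == 8, 1.5, 0.0)
    np.testing.assert_allclose(eta, expected)


def test_linear_predictor_matches_symbolic_evaluator():
    cells = _toy_cells(n_species=3, n_pops=2, seed=4)
    model = SpikeSlabModel(cells, _identity_A(["sp1", "sp2", "sp3"]))
    rng = np.random.default_rng(1)
    state = model.initial_state(rng)
    for f in model.spec.families:  # open a random, hierarchy-respecting set
        if f in PARENTS:
            a, b = PARENTS[f]
            state["delta"][f] = (
                state["delta"][a] * state["delta"][b] * rng.integers(0, 2, 3)
            ).astype(np.int8)
    eta = model.eta(state)
    for i, (_, cell) in enumerate(cells.iterrows()):
        assert eta[i] == pytest.approx(_symbolic_eta(model, state, cell), abs=1e-12)


def test_log_joint_empty_data_is_finite_prior():
    cells = _toy_cells(n_species=2)
    cells["y"] = 0
    cells["n"] = 0
    model = SpikeSlabModel(cells, _identity_A(["sp1", "sp2"]))
    state = model.initial_state(np.random.default_rng(2))
    lp = model.log_joint(state)
    assert np.isfinite(lp)
    assert model.loglik(state) == 0.0


def test_log_joint_saturated_cell_limit():
    cells = _toy_cells(n_species=1).iloc[:1].copy()
    cells["y"] = cells["n"]
    model = SpikeSlabModel(cells, _identity_A(["sp1"]), spec=ModelSpec(()))
    state = model.initial_state(np.random.default_rng(0))
    state["beta"]["S"][:] = 30.0  # eta -> +inf: binomial term -> log(1) = 0
    assert model.loglik(state) == pytest.approx(0.0, abs=1e-8)


def test_log_joint_matches_textbook_density_oracle(study_A):
    cells = _toy_cells(n_species=2, seed=6)
    A = study_A.iloc[:2, :2].copy()
    A.index = A.columns = ["sp1", "sp2"]
    A_arr = A.to_numpy() + 1e-10 * np.eye(2)
    priors = Priors()
    model = SpikeSlabModel(cells, A, priors)
    rng = np.random.default_rng(3)
    state = model.initial_state(rng)
    state["delta"]["P:SL"][:] = state["delta"]["P"] * state["delta"]["SL"]
    state["sig2"] = {f: float(rng.uniform(0.5, 2.0)) for f in model.correlated}
    lp = model.log_joint(state)

    # independent assembly from scipy.stats building blocks
    eta = np.array(
        [_symbolic_eta(model, state, cell) for _, cell in cells.iterrows()]
    )
    oracle = float(
        np.sum(stats.binom.logpmf(cells["y"], cells["n"], expit(eta)))
    )
    for f in model.spec.families:  # indicator prior with hierarchy
        d = state["delta"][f]
        if f in PARENTS:
            a, b = PARENTS[f]
            both = (state["delta"][a] == 1) & (state["delta"][b] == 1)
            for s in range(2):
                if both[s]:
                    oracle += math.log(0.5)
                else:
                    assert d[s] == 0
        else:
            oracle += 2 * math.log(0.5)
    for f in model.spec.families:
        if f in POPULATION_FAMILIES:
            oracle += float(np.sum(stats.norm.logpdf(state["beta"][f])))
    for f in model.correlated:
        s2 = state["sig2"][f]
        for l in range(model.shape[f][1]):
            oracle += float(
                stats.multivariate_normal.logpdf(
                    state["beta"][f][:, l],
                    mean=np.full(2, state["mu"][f][l]),
                    cov=s2 * A_arr,
                )
            )
        if f in ("S", "SL", "ST", "IT"):
            oracle += float(np.sum(stats.norm.logpdf(state["mu"][f])))
        lam = 1.0 / s2
        oracle += float(stats.gamma.logpdf(lam, 0.1, scale=10.0)) + 2 * math.log(lam)
    assert lp == pytest.approx(oracle, abs=1e-7)


@pytest.fixture(scope="module")
def short_posterior(study_cells, study_A):
    sub = study_cells[study_cells["species"].isin(["sp1", "sp2", "sp3"])]
    A = study_A.loc[["sp1", "sp2", "sp3"], ["sp1", "sp2", "sp3"]]
    settings = MCMCSettings(
        chains=2, adapt=300, burnin=200, samples_per_chain=1000, thin=1, seed=21
    )
    return spikeslab.run_mcmc(sub, A, settings=settings)


def test_hierarchy_constraint_holds_in_every_draw(short_posterior):
    fams = list(short_posterior.families)
    d = short_posterior.delta
    for child, (a, b) in PARENTS.items():
        ic, ia, ib = fams.index(child), fams.index(a), fams.index(b)
        assert np.all(d[..., ic] <= d[..., ia])
        assert np.all(d[..., ic] <= d[..., ib])


def test_inclusion_table_summaries(short_posterior):
    tab = inclusion_table(short_posterior)
    assert tab.shape == (3, 10)
    assert ((tab.to_numpy() >= 0) & (tab.to_numpy() <= 1)).all()
    assert np.isfinite(tab.attrs["mcse"].to_numpy()).all()
    # interaction probability bounded by parents (up to MC noise)
    for child, (a, b) in PARENTS.items():
        bound = np.minimum(tab[a], tab[b]) + 0.02
        assert (tab[child] <= bound).all()


def test_inclusion_table_trivial_traces(study_cells, study_A):
    model = SpikeSlabModel(study_cells, study_A)
    fams = list(model.spec.families)
    n_draws, S = 600, len(model.species)
    delta = np.zeros((2, n_draws, S, len(fams)), dtype=np.int8)
    delta[..., fams.index("P")] = 1  # constant one
    j = fams.index("SL")
    delta[:, ::2, :, j] = 1  # alternating
    post = Posterior(
        model,
        MCMCSettings(chains=2, samples_per_chain=n_draws, thin=1, adapt=1, burnin=1),
        delta,
        np.ones((2, n_draws, len(model.correlated))),
        np.zeros((2, n_draws, 9)),
        np.zeros((2, n_draws)),
    )
    tab = inclusion_table(post)
    assert (tab["P"] == 1.0).all()
    assert tab["SL"].iloc[0] == pytest.approx(0.5)


def test_phylogeny_necessity_check_trivial(study_cells, study_A):
    model = SpikeSlabModel(study_cells, study_A)
    fams = list(model.spec.families)
    delta = np.zeros((1, 100, 8, len(fams)), dtype=np.int8)
    delta[0, :, 2, fams.index("P")] = 1  # some population predictor always in
    post = Posterior(model, MCMCSettings(), delta, None, None, None)
    assert phylogeny_necessity_check(post) == 0.0
    delta[0, 50:, 2, fams.index("P")] = 0
    assert phylogeny_necessity_check(post) == pytest.approx(0.5)


def test_species_exchangeable_under_identity_relatedness():
    """With A = I and sigma^2 fixed, relabeling species does not change the
    inclusion posterior beyond Monte-Carlo noise."""
    rng = np.random.default_rng(12)
    rows = []
    p_by_species = {"spA": 0.3, "spB": 0.7, "spC": 0.5}
    for sp, base in p_by_species.items():
        for sl in (0, 3, 8):
            for it in ("20/10", "25/15"):
                p = expit(np.log(base / (1 - base)) + (0.8 if sl == 8 else 0.0))
                rows.append(
                    {
                        "species": sp, "population": f"{sp}_p1", "sl": sl,
                        "st": "none" if sl == 0 else "3", "it": it,
                        "y": int(rng.binomial(50, p)), "n": 50,
                    }
                )
    cells = pd.DataFrame(rows)
    priors = Priors(fix_sigma2=1.0)
    spec = ModelSpec(("SL", "IT", "SL:IT"))
    settings = MCMCSettings(chains=2, adapt=300, burnin=200, samples_per_chain=2500, thin=1, seed=5)
    A = _identity_A(["spA", "spB", "spC"])

    post1 = spikeslab.run_mcmc(cells, A, priors, settings, spec)
    tab1 = inclusion_table(post1)

    relabel = {"spA": "spC", "spB": "spA", "spC": "spB"}
    cells2 = cells.copy()
    cells2["species"] = cells2["species"].map(relabel)
    cells2["population"] = cells2["species"] + "_p1"
    post2 = spikeslab.run_mcmc(
        cells2, A, priors, MCMCSettings(**{**settings.__dict__, "seed": 6}), spec
    )
    tab2 = inclusion_table(post2)

    for sp in p_by_species:
        for fam in spec.families:
            a, b = tab1.loc[sp, fam], tab2.loc[relabel[sp], fam]
            mcse = math.hypot(
                tab1.attrs["mcse"].loc[sp, fam], tab2.attrs["mcse"].loc[relabel[sp], fam]
            )
            assert abs(a - b) <= 3 * max(mcse, 0.01), (sp, fam, a, b)


def test_simulation_based_calibration_of_intercept():
    """Ranks of the true intercept within posterior draws are uniform."""
    n_reps = 150
    bins = 8
    counts = np.zeros(bins)
    spec = ModelSpec(())
    priors = Priors(fix_sigma2=1.0, fix_hypermean=0.0)
    A = _identity_A(["sp1"])
    master = np.random.default_rng(2024)
    for _ in range(n_reps):
        beta_true = master.normal()
        y = master.binomial(40, expit(beta_true))
        cells = pd.DataFrame(
            [{"species": "sp1", "population": "sp1_p1", "sl": 0, "st": "none",
              "it": "20/10", "y": int(y), "n": 40}]
        )
        settings = MCMCSettings(
            chains=1, adapt=100, burnin=100, samples_per_chain=320, thin=4,
            seed=int(master.integers(2**31)), store_beta=True,
        )
        post = spikeslab.run_mcmc(cells, A, priors, settings, spec)
        draws = post.beta[0, :, 0]
        rank = int(np.sum(draws < beta_true))
        counts[min(rank * bins // (len(draws) + 1), bins - 1)] += 1
    expected = n_reps / bins
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    # chi-square test with bins-1 dof, alpha = 0.01
    assert chi2 < stats.chi2.ppf(0.99, bins - 1), counts


def test_stratification_response_refit_runs(study_records, study_A):
    cells = traits.design_cells(study_records, "stratification", per_plate=False)
    spec = ModelSpec(("P", "SL", "ST", "P:SL", "P:ST", "SL:ST"))
    settings = MCMCSettings(chains=2, adapt=150, burnin=100, samples_per_chain=500, thin=1, seed=8)
    post = spikeslab.run_mcmc(cells, study_A, settings=settings, spec=spec)
    tab = inclusion_table(post)
    assert tab.shape == (8, 6)
    assert np.isfinite(post.logpost).all()


def test_settings_and_input_validation(study_cells, study_A):
    with pytest.raises(ValueError, match="positive"):
        MCMCSettings(chains=0)
    with pytest.raises(ValueError, match="parents"):
        ModelSpec(("P:SL",))
    bad = study_cells.copy()
    bad.loc[0, "y"] = bad.loc[0, "n"] + 1
    with pytest.raises(ValueError, match="0 <= y <= n"):
        SpikeSlabModel(bad, study_A)
    with pytest.raises(ValueError, match="absent"):
        SpikeSlabModel(study_cells.assign(species="zz"), study_A)
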