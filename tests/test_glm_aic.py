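"""Binomial GLM fitting, stepwise-AIC search and AIC tables."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from phylogerm import glm_aic, traits
from phylogerm.glm_aic import (
    ModelFormula,
    aic_table,
    design_matrix,
    fit_binomial_glm,
    good_candidates,
    maximal_formula,
    stepwise_aic,
)


def _cells(n_pops=2, sl_levels=(0, 3, 8), seed=0, p_fn=None, reps=2, n=25):
    """Small factorial dataset; st follows the non-crossed study design."""
    rng = np.random.default_rng(seed)
    st_of = {0: ["none"], 3: ["3", "30"], 8: ["3"]}
    rows = []
    for j in range(n_pops):
        for sl in sl_levels:
            for st in st_of.get(sl, ["3"]):
                for it in ("20/10", "25/15"):
                    for _ in range(reps):
                        p = 0.5 if p_fn is None else p_fn(j, sl, st, it)
                        rows.append(
                            {
                                "species": "sp",
                                "population": f"p{j}",
                                "sl": sl,
                                "st": st,
                                "it": it,
                                "y": int(rng.binomial(n, p)),
                                "n": n,
                            }
                        )
    return pd.DataFrame(rows)


def test_formula_hierarchy_enforced():
    with pytest.raises(ValueError, match="parents"):
        ModelFormula(("P", "SL:IT"))
    f = ModelFormula(("SL", "P", "P:SL"))
    assert str(f) == "P+SL+P:SL"


def test_intercept_only_closed_form():
    data = pd.DataFrame(
        {
            "species": "sp", "population": "p0", "sl": [0, 0], "st": "none",
            "it": "20/10", "y": [30, 30], "n": [50, 50],
        }
    )
    fit = fit_binomial_glm(ModelFormula(()), data)
    assert fit.k == 1
    assert fit.params.iloc[0] == pytest.approx(np.log(60 / 40), abs=1e-10)


def test_saturated_model_reproduces_observed_proportions():
    data = _cells(n_pops=1, sl_levels=(0, 3), seed=1)
    data = data.groupby(["species", "population", "sl", "st", "it"], as_index=False)[
        ["y", "n"]
    ].sum()
    fit = fit_binomial_glm(ModelFormula(("SL", "ST", "IT", "SL:ST", "SL:IT", "ST:IT")), data)
    assert fit.k == len(data)  # one parameter per observed cell
    np.testing.assert_allclose(fit.fitted, data["y"] / data["n"], atol=1e-8)


def _newton_oracle_llf(X, y, n):
    """Independent maximum-likelihood value by generic optimization."""
    const = float(np.sum(gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)))

    def nll(b):
        eta = X @ b
        return -(np.sum(y * eta - n * np.logaddexp(0, eta)) + const)

    def grad(b):
        return -(X.T @ (y - n * expit(X @ b)))

    res = minimize(nll, np.zeros(X.shape[1]), jac=grad, method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 500})
    return -res.fun


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_loglik_matches_generic_optimizer(seed):
    def p_fn(j, sl, st, it):
        return expit(0.3 * j - 0.1 * sl + (0.4 if it == "25/15" else 0.0))

    data = _cells(n_pops=3, seed=seed, p_fn=p_fn)
    formula = ModelFormula(("P", "SL", "ST", "IT"))
    fit = fit_binomial_glm(formula, data)
    X = design_matrix(formula, data).to_numpy()
    oracle = _newton_oracle_llf(X, data["y"].to_numpy(float), data["n"].to_numpy(float))
    assert fit.llf == pytest.approx(oracle, abs=1e-6)
    assert fit.aic == pytest.approx(-2 * oracle + 2 * fit.k, abs=1e-6)


@pytest.mark.parametrize(
    "terms,n_pops,scope,expected_k",
    [
        # final-germination structures: the printed parameter counts force
        # ST to be a 3-level factor with data-aliased columns dropped
        (("P", "SL", "ST", "IT", "P:ST", "P:IT", "SL:IT", "ST:IT"), 4, "total", 20),
        (("P", "SL", "ST", "IT", "P:SL", "P:ST", "P:IT", "SL:ST", "SL:IT", "ST:IT"), 4, "total", 23),
        (("P", "SL", "ST", "IT", "P:SL", "P:ST", "P:IT"), 3, "total", 15),
        (("SL", "ST", "IT", "SL:IT", "ST:IT"), 3, "total", 8),
        # during-stratification structures (stratified treatments only)
        (("P", "SL"), 2, "stratification", 3),
        (("P", "SL", "ST", "P:SL", "P:ST"), 4, "stratification", 12),
        (("P", "SL", "ST", "P:ST"), 2, "stratification", 5),
    ],
)
def test_design_rank_matches_study_parameter_counts(terms, n_pops, scope, expected_k):
    sl_levels = (0, 3, 8) if scope == "total" else (3, 8)
    data = _cells(n_pops=n_pops, sl_levels=sl_levels, seed=3)
    fit = fit_binomial_glm(ModelFormula(terms, scope), data)
    assert fit.k == expected_k


def test_stepwise_recovers_population_effect():
    def p_fn(j, sl, st, it):
        return expit(-1.0 + 2.0 * j)

    data = _cells(n_pops=3, seed=5, p_fn=p_fn, reps=4)
    evaluated = stepwise_aic(data, maximal_formula("total"))
    best = min(evaluated.values(), key=lambda f: f.aic)
    assert "P" in best.formula.terms


def test_stepwise_intercept_only_maximal():
    data = _cells(seed=6)
    evaluated = stepwise_aic(data, ModelFormula(()))
    assert len(evaluated) == 1


def test_stepwise_reaches_exhaustive_minimum_on_small_space():
    def p_fn(j, sl, st, it):
        return expit(0.8 * j - 0.15 * sl)

    data = _cells(n_pops=2, seed=7, p_fn=p_fn, reps=4)
    maximal = ModelFormula(("P", "SL", "IT", "P:SL"))
    evaluated = stepwise_aic(data, maximal)
    best = min(f.aic for f in evaluated.values())
    # exhaustive enumeration over all hierarchical subsets
    exhaustive = []
    for r in range(5):
        for combo in itertools.combinations(maximal.terms, r):
            try:
                f = ModelFormula(combo)
            except ValueError:
                continue
            exhaustive.append(fit_binomial_glm(f, data).aic)
    assert best == pytest.approx(min(exhaustive), abs=1e-9)


def test_nesting_monotonicity_of_loglik():
    data = _cells(n_pops=2, seed=8, reps=4)
    evaluated = stepwise_aic(data, maximal_formula("total"))
    fits = list(evaluated.values())
    for a in fits:
        for b in fits:
            if set(a.formula.terms) < set(b.formula.terms):
                assert b.llf >= a.llf - 1e-6


def test_aic_table_weights():
    data = _cells(seed=9)
    f1 = fit_binomial_glm(ModelFormula(()), data)
    tab1 = aic_table([f1])
    assert tab1["weight"].iloc[0] == pytest.approx(1.0)

    f2 = fit_binomial_glm(ModelFormula(()), data)
    tab2 = aic_table([f1, f2])  # equal AIC -> equal weights
    np.testing.assert_allclose(tab2["weight"], [0.5, 0.5])
    assert tab2["dAIC"].iloc[0] == 0.0

    evaluated = stepwise_aic(data, maximal_formula("total"))
    tab = aic_table(evaluated)
    assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)
    assert tab["AIC"].is_monotonic_increasing
    assert (good_candidates(tab)["dAIC"] < 2).all()


def test_species_tables_from_study_data(study_records):
    cells = traits.design_cells(study_records, "stratification", stratified_only=True)
    one = cells[cells["species"].isin(["sp5", "sp6"])]
    tables = glm_aic.species_aic_tables(one, "stratification")
    assert set(tables) == {"sp5", "sp6"}
    for tab in tables.values():
        assert tab["weight"].sum() == pytest.approx(1.0)
        assert tab["dAIC"].iloc[0] == 0.0
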