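"""Per-species binomial GLMs with stepwise-AIC model selection.

Each species' plate counts are modeled as binomial with a logit link over
population (P) and treatment factors: stratification length (SL),
stratification temperature (ST) and incubation temperature (IT), plus
pairwise interactions.  Model search is greedy bidirectional stepwise AIC
from a common maximal model; every model evaluated along the way enters the
candidate set, which is summarized as an AIC table with Akaike weights
w_i = exp(-dAIC_i / 2) / sum_j exp(-dAIC_j / 2).

Factor coding follows the R ``glm`` convention: treatment contrasts with the
alphabetically first level as reference, stratification temperature a
three-level factor {"3", "30", "none"}, and design columns that are aliased
in the observed (non-crossed) design dropped left to right, so the reported
``k`` is the rank of the design matrix.  The log-likelihood includes the
binomial coefficient term log C(n, y), making AIC comparable to values
computed by R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

MAIN_TERMS = ("P", "SL", "ST", "IT")
INTERACTION_TERMS = ("P:SL", "P:ST", "P:IT", "SL:ST", "SL:IT", "ST:IT")
TERM_ORDER = MAIN_TERMS + INTERACTION_TERMS

_FACTOR_COLUMN = {"P": "population", "SL": "sl", "ST": "st", "IT": "it"}


@dataclass(frozen=True)
class ModelFormula:
    """An ordered, hierarchy-respecting set of model terms."""

    terms: tuple[str, ...]
    scope: Literal["total", "stratification"] = "total"

    def __post_init__(self) -> None:
        seen = set()
        for t in self.terms:
            if t not in TERM_ORDER:
                raise ValueError(f"unknown term {t!r}")
            if t in seen:
                raise ValueError(f"duplicate term {t!r}")
            seen.add(t)
        for t in self.terms:
            if ":" in t:
                a, b = t.split(":")
                if a not in seen or b not in seen:
                    raise ValueError(f"interaction {t} requires both parents in the model")
        object.__setattr__(self, "terms", tuple(sorted(self.terms, key=TERM_ORDER.index)))

    def __str__(self) -> str:
        return "+".join(self.terms) if self.terms else "1"

    def with_term(self, term: str) -> "ModelFormula":
        return ModelFormula(self.terms + (term,), self.scope)

    def without_term(self, term: str) -> "ModelFormula":
        return ModelFormula(tuple(t for t in self.terms if t != term), self.scope)


@dataclass
class GLMFit:
    formula: ModelFormula
    params: pd.Series
    llf: float
    k: int
    aic: float
    converged: bool
    n_iter: int
    fitted: np.ndarray = field(repr=False)
    dispersion: float = float("nan")  # Pearson chi^2 / residual df


def _dummies(values: pd.Series) -> pd.DataFrame:
    """Treatment-contrast dummies: one 0/1 column per non-reference level."""
    levels = sorted(values.astype(str).unique())
    cols = {}
    for lev in levels[1:]:
        cols[lev] = (values.astype(str) == lev).astype(float)
    return pd.DataFrame(cols, index=values.index)


def design_matrix(formula: ModelFormula, data: pd.DataFrame) -> pd.DataFrame:
    """Full-rank design matrix for one species' cells.

    Columns are assembled in term order (intercept first) and any column
    linearly dependent on the preceding ones — including structural aliasing
    from the non-crossed stratification design — is dropped, mirroring how R
    reports NA coefficients and counts only estimable parameters.
    """
    blocks: list[pd.DataFrame] = [pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)]
    factor_dummies = {t: _dummies(data[_FACTOR_COLUMN[t]]) for t in MAIN_TERMS}
    for term in formula.terms:
        if ":" not in term:
            d = factor_dummies[term]
            d = d.rename(columns=lambda lev, t=term: f"{t}[{lev}]")
            blocks.append(d)
        else:
            a, b = term.split(":")
            da, db = factor_dummies[a], factor_dummies[b]
            cols = {}
            for la in da.columns:
                for lb in db.columns:
                    cols[f"{a}[{la}]:{b}[{lb}]"] = da[la] * db[lb]
            blocks.append(pd.DataFrame(cols, index=data.index))
    X = pd.concat(blocks, axis=1)

    # sequential rank filter (Gram-Schmidt), keeping earlier columns
    keep: list[str] = []
    Q: list[np.ndarray] = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            continue
        r = v.copy()
        for q in Q:
            r -= (q @ v) * q
        if np.linalg.norm(r) > 1e-8 * nv:
            keep.append(col)
            Q.append(r / np.linalg.norm(r))
    return X[keep]


def fit_binomial_glm(formula: ModelFormula, data: pd.DataFrame) -> GLMFit:
    """Fit one binomial logit GLM by IRLS.

    ``data`` needs columns ``population``, ``sl``, ``st``, ``it``, ``y``
    (germinated) and ``n`` (viable); rows are plates (or pooled cells).
    """
    X = design_matrix(formula, data)
    y = data["y"].to_numpy(dtype=float)
    n = data["n"].to_numpy(dtype=float)
    endog = np.column_stack([y, n - y])
    model = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(maxiter=100, tol=1e-10)
        except Exception as exc:
            raise RuntimeError(f"GLM fit failed for {formula}: {exc}") from exc
    converged = bool(getattr(res, "converged", True))
    params = pd.Series(res.params, index=X.columns)
    if np.any(np.abs(params) > 15):
        converged = False
        warnings.warn(
            f"possible separation in {formula}: some |coefficients| > 15", stacklevel=2
        )
    k = X.shape[1]
    llf = float(res.llf)
    fitted = np.asarray(res.fittedvalues)
    resid_df = len(data) - k
    pearson = float(res.pearson_chi2) / resid_df if resid_df > 0 else float("nan")
    return GLMFit(
        formula=formula,
        params=params,
        llf=llf,
        k=k,
        aic=-2.0 * llf + 2.0 * k,
        converged=converged,
        n_iter=int(getattr(res, "fit_history", {}).get("iteration", 0) or 0),
        fitted=fitted,
        dispersion=pearson,
    )


def _neighbors(formula: ModelFormula, universe: Sequence[str]) -> list[ModelFormula]:
    """Single-term additions and deletions that respect the hierarchy."""
    out = []
    present = set(formula.terms)
    for t in formula.terms:
        # a main term can only leave if none of its interactions is present
        if ":" not in t and any(t in i.split(":") for i in present if ":" in i):
            continue
        out.append(formula.without_term(t))
    for t in universe:
        if t in present:
            continue
        if ":" in t:
            a, b = t.split(":")
            if a not in present or b not in present:
                continue
        out.append(formula.with_term(t))
    return out


def stepwise_aic(
    data: pd.DataFrame,
    maximal: ModelFormula,
) -> dict[tuple[str, ...], GLMFit]:
    """Greedy bidirectional stepwise AIC search from the maximal model.

    At each step every hierarchy-respecting single-term deletion and
    addition (within the maximal model's term universe) is evaluated; the
    search moves to the lowest-AIC neighbor and stops when no neighbor
    improves.  Returns every model evaluated along the way, keyed by its
    term tuple — this is the candidate set for the AIC table.
    """
    universe = maximal.terms
    evaluated: dict[tuple[str, ...], GLMFit] = {}

    def fit(f: ModelFormula) -> GLMFit | None:
        key = f.terms
        if key in evaluated:
            return evaluated[key]
        try:
            g = fit_binomial_glm(f, data)
        except RuntimeError as exc:
            warnings.warn(f"skipping candidate {f}: {exc}", stacklevel=2)
            return None
        evaluated[key] = g
        return g

    current = fit(maximal)
    if current is None:
        raise RuntimeError(f"maximal model {maximal} failed to fit")
    while True:
        best_move = None
        for nb in _neighbors(current.formula, universe):
            g = fit(nb)
            if g is not None and (best_move is None or g.aic < best_move.aic):
                best_move = g
        if best_move is None or best_move.aic >= current.aic - 1e-9:
            break
        current = best_move
    return evaluated


def aic_table(candidates: Iterable[GLMFit] | Mapping[tuple[str, ...], GLMFit]) -> pd.DataFrame:
    """Candidate-model table with k, AIC, delta AIC and Akaike weights."""
    if isinstance(candidates, Mapping):
        fits = list(candidates.values())
    else:
        fits = list(candidates)
    if not fits:
        raise ValueError("no successful fits to tabulate")
    rows = pd.DataFrame(
        {
            "model": [str(f.formula) for f in fits],
            "k": [f.k for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    rows["dAIC"] = rows["AIC"] - rows["AIC"].min()
    rel = np.exp(-rows["dAIC"] / 2.0)
    rows["weight"] = rel / rel.sum()
    rows = rows.sort_values(["AIC", "model"], kind="mergesort").reset_index(drop=True)
    return rows


def good_candidates(table: pd.DataFrame, max_delta: float = 2.0) -> pd.DataFrame:
    """Reporting view: candidate models with delta AIC below ``max_delta``."""
    return table[table["dAIC"] < max_delta].reset_index(drop=True)


def maximal_formula(scope: Literal["total", "stratification"]) -> ModelFormula:
    """The common maximal model for the stepwise search.

    Final germination uses all four factors and their six pairwise
    interactions; germination during stratification (fitted on the three
    stratified treatments only) uses population, stratification length and
    stratification temperature.
    """
    if scope == "total":
        return ModelFormula(TERM_ORDER, scope)
    return ModelFormula(("P", "SL", "ST", "P:SL", "P:ST", "SL:ST"), scope)


def species_aic_tables(
    cells: pd.DataFrame,
    scope: Literal["total", "stratification"] = "total",
    pool_candidates: bool = False,
) -> dict[str, pd.DataFrame]:
    """Stepwise-AIC candidate tables for every species in a cell table.

    ``cells`` is the output of :func:`phylogerm.traits.design_cells` (for
    ``scope="stratification"`` build it with ``response="stratification"``
    and ``stratified_only=True``).  With ``pool_candidates=True`` the
    Akaike weights are renormalized over the union of candidate model
    structures visited across all species.
    """
    maximal = maximal_formula(scope)
    per_species: dict[str, dict[tuple[str, ...], GLMFit]] = {}
    for sp, grp in cells.groupby("species", sort=True):
        per_species[sp] = stepwise_aic(grp.reset_index(drop=True), maximal)
    if not pool_candidates:
        return {sp: aic_table(fits) for sp, fits in per_species.items()}
    # pooled mode: every model structure visited for any species becomes a
    # candidate for every species
    structures = sorted({key for fits in per_species.values() for key in fits})
    out = {}
    for sp, grp in cells.groupby("species", sort=True):
        fits = dict(per_species[sp])
        for key in structures:
            if key in fits:
                continue
            try:
                fits[key] = fit_binomial_glm(ModelFormula(key, scope), grp.reset_index(drop=True))
            except RuntimeError:
                continue
        out[sp] = aic_table(fits)
    return out
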