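"""Bayesian spike-and-slab binomial GLMM with phylogenetically correlated
coefficients.

Germinated counts are binomial with a logit link.  For the *j*th population
of species *i* under stratification length *sl*, stratification temperature
*st* and incubation regime *it*::

    logit p = bS_i + dP_i * bP_ij + dSL_i * bSL_{i,sl} + dST_i * bST_{i,st}
            + dIT_i * bIT_{i,it} + (six pairwise interaction terms,
              each gated by its own per-species indicator)

Binary indicators ``d`` (one per species and predictor family) switch whole
coefficient blocks in or out of the model; each has prior P(d = 1) = 0.5,
with interaction indicators conditioned on the inclusion of both of their
parent factors.  Population-dependent coefficients have independent N(0, 1)
priors.  The remaining (species-level) coefficient families are multivariate
normal across species with covariance sigma^2 * A — A the phylogenetic
relatedness (correlation) matrix — a hypermean sampled from N(0, 1) for main
effects (fixed at 0 for interactions), and a separate sigma^2 per family
with 1/sigma^2 ~ Gamma(0.1, 0.1).  Stratification temperature has no level
for the unstratified control: ST-bearing terms contribute 0 to those cells.

Posterior sampling is Metropolis-within-Gibbs: adaptive random-walk
Metropolis blocks for coefficients; conjugate Gibbs for hypermeans and
variances plus a non-centered scale move for the variance funnel;
reversible indicator flips whose turn-on proposals come from a Laplace
approximation of the block's conditional posterior; and a likelihood-
invariant recentering move that resolves the exact ridges of the
overparameterized factor coding.  The posterior mean of each indicator is
the probability that the predictor belongs in the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

FAMILIES = ("P", "SL", "ST", "IT", "P:SL", "P:ST", "P:IT", "SL:ST", "SL:IT", "ST:IT")
PARENTS = {
    "P:SL": ("P", "SL"),
    "P:ST": ("P", "ST"),
    "P:IT": ("P", "IT"),
    "SL:ST": ("SL", "ST"),
    "SL:IT": ("SL", "IT"),
    "ST:IT": ("ST", "IT"),
}
#: families whose coefficients vary by population (independent N(0,1) priors)
POPULATION_FAMILIES = frozenset({"P", "P:SL", "P:ST", "P:IT"})
#: species-level families carrying the sigma^2 * A prior ("S" is the
#: always-included species intercept)
CORRELATED_FAMILIES = ("S", "SL", "ST", "IT", "SL:ST", "SL:IT", "ST:IT")
#: correlated families whose hypermean is sampled (interactions fixed at 0)
MAIN_CORRELATED = ("S", "SL", "ST", "IT")

_LOG2 = math.log(2.0)


@dataclass(frozen=True)
class ModelSpec:
    """Which gated predictor families enter the model."""

    families: tuple[str, ...] = FAMILIES

    def __post_init__(self) -> None:
        for f in self.families:
            if f not in FAMILIES:
                raise ValueError(f"unknown family {f!r}")
            if f in PARENTS:
                a, b = PARENTS[f]
                if a not in self.families or b not in self.families:
                    raise ValueError(f"family {f} requires both parents in the spec")


@dataclass(frozen=True)
class Priors:
    """Prior constants of the GLMM."""

    p_include: float = 0.5
    coef_sd: float = 1.0  # sd of population-level and hypermean priors
    gamma_shape: float = 0.1
    gamma_rate: float = 0.1
    fix_sigma2: Optional[float] = None  # fix all family variances (no Gibbs)
    fix_hypermean: Optional[float] = None  # fix all hypermeans (no Gibbs)


@dataclass(frozen=True)
class MCMCSettings:
    chains: int = 4
    adapt: int = 5000
    burnin: int = 5000
    samples_per_chain: int = 50000
    thin: int = 10
    seed: int = 0
    store_beta: bool = False

    def __post_init__(self) -> None:
        for f in ("chains", "adapt", "burnin", "samples_per_chain", "thin"):
            if getattr(self, f) < (1 if f in ("chains", "samples_per_chain", "thin") else 0):
                raise ValueError(f"{f} must be positive")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _norm_logpdf(x: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return -0.5 * ((x - mean) / sd) ** 2 - np.log(sd) - 0.5 * math.log(2 * math.pi)


class SpikeSlabModel:
    """Design bookkeeping, joint density, and the MCMC sampler.

    ``cells`` is a DataFrame with columns ``species``, ``population``,
    ``sl`` (int weeks), ``st`` (``"none"`` or a temperature string), ``it``,
    ``y`` and ``n``.  ``A`` is the species relatedness matrix (unit
    diagonal), indexed by species code; every species in the data must be a
    row of A.  Cells with ``n = 0`` contribute nothing to the likelihood, so
    a design of empty cells yields the prior.
    """

    def __init__(
        self,
        cells: pd.DataFrame,
        A: pd.DataFrame,
        priors: Priors = Priors(),
        spec: ModelSpec = ModelSpec(),
    ) -> None:
        self.priors = priors
        self.spec = spec
        self.species = sorted(cells["species"].unique())
        missing = [s for s in self.species if s not in A.index]
        if missing:
            raise ValueError(f"species absent from relatedness matrix: {missing}")
        self.A = A.loc[self.species, self.species].to_numpy(dtype=float)
        w = np.linalg.eigvalsh(self.A)
        if w.min() < -1e-8:
            raise ValueError(f"relatedness matrix is not PSD (min eigenvalue {w.min():.3g})")
        Aj = self.A + 1e-10 * np.eye(len(self.species))
        self.chol_A = np.linalg.cholesky(Aj)
        self.Ainv = np.linalg.inv(Aj)
        self.logdet_A = float(np.linalg.slogdet(Aj)[1])

        self.populations = sorted(cells["population"].unique())
        pop_sp = cells.drop_duplicates("population").set_index("population")["species"]
        self.pop_species = np.array(
            [self.species.index(pop_sp[p]) for p in self.populations]
        )
        self.n_species = len(self.species)
        self.n_pops = len(self.populations)

        s_idx = cells["species"].map({s: i for i, s in enumerate(self.species)}).to_numpy()
        p_idx = cells["population"].map(
            {p: i for i, p in enumerate(self.populations)}
        ).to_numpy()
        sl = cells["sl"].to_numpy()
        st = cells["st"].astype(str).to_numpy()
        it = cells["it"].astype(str).to_numpy()
        self.y = cells["y"].to_numpy(dtype=float)
        self.n = cells["n"].to_numpy(dtype=float)
        if np.any(self.y < 0) or np.any(self.y > self.n):
            raise ValueError("need 0 <= y <= n in every cell")
        self.s_idx = s_idx
        self.ncells = len(cells)
        self.binom_const = float(
            np.sum(gammaln(self.n + 1) - gammaln(self.y + 1) - gammaln(self.n - self.y + 1))
        )

        self.sl_levels = sorted(set(sl.tolist()))
        self.st_levels = sorted(l for l in set(st.tolist()) if l != "none")
        self.it_levels = sorted(set(it.tolist()))
        strat = st != "none"
        slst = sorted({(a, b) for a, b in zip(sl[strat].tolist(), st[strat].tolist())})
        slit = sorted({(a, b) for a, b in zip(sl.tolist(), it.tolist())})
        stit = sorted({(a, b) for a, b in zip(st[strat].tolist(), it[strat].tolist())})

        def idx_of(levels, values):
            lut = {l: i for i, l in enumerate(levels)}
            return np.array([lut.get(v, -1) for v in values])

        sl_i = idx_of(self.sl_levels, sl.tolist())
        st_i = idx_of(self.st_levels, st.tolist())  # -1 for "none"
        it_i = idx_of(self.it_levels, it.tolist())
        slst_i = idx_of(slst, list(zip(sl.tolist(), st.tolist())))
        slit_i = idx_of(slit, list(zip(sl.tolist(), it.tolist())))
        stit_i = idx_of(stit, list(zip(st.tolist(), it.tolist())))

        #: per family: (number of unit rows, number of level columns)
        self.shape: dict[str, tuple[int, int]] = {"S": (self.n_species, 1)}
        self.level_labels: dict[str, list] = {"S": ["(intercept)"]}
        fam_level_idx = {
            "P": (np.zeros(self.ncells, dtype=int), ["(population)"]),
            "SL": (sl_i, self.sl_levels),
            "ST": (st_i, self.st_levels),
            "IT": (it_i, self.it_levels),
            "P:SL": (sl_i, self.sl_levels),
            "P:ST": (st_i, self.st_levels),
            "P:IT": (it_i, self.it_levels),
            "SL:ST": (slst_i, slst),
            "SL:IT": (slit_i, slit),
            "ST:IT": (stit_i, stit),
        }
        self.ptr: dict[str, np.ndarray] = {"S": s_idx.copy()}
        for f in self.spec.families:
            lvl_idx, labels = fam_level_idx[f]
            nlev = len(labels)
            unit = p_idx if f in POPULATION_FAMILIES else s_idx
            nunit = self.n_pops if f in POPULATION_FAMILIES else self.n_species
            ptr = np.where(lvl_idx >= 0, unit * nlev + lvl_idx, -1)
            self.ptr[f] = ptr
            self.shape[f] = (nunit, nlev)
            self.level_labels[f] = list(labels)
        self.correlated = ["S"] + [
            f for f in self.spec.families if f not in POPULATION_FAMILIES
        ]
        self.pop_families = [f for f in self.spec.families if f in POPULATION_FAMILIES]

        # cell index lists used by the sampler
        self.cells_of_fam = {f: np.flatnonzero(self.ptr[f] >= 0) for f in self.ptr}
        self.cells_of_col = {
            f: [
                np.flatnonzero((self.ptr[f] >= 0) & (self.ptr[f] % self.shape[f][1] == l))
                for l in range(self.shape[f][1])
            ]
            for f in self.ptr
        }
        self.cells_of_sp_fam = {
            f: [
                np.flatnonzero((self.ptr[f] >= 0) & (s_idx == s))
                for s in range(self.n_species)
            ]
            for f in self.spec.families
        }
        self.pops_of_species = [
            np.flatnonzero(self.pop_species == s) for s in range(self.n_species)
        ]
        # local (within-species-block) coefficient index per cell, for the
        # Laplace flip proposals
        pop_pos = np.full(self.n_pops, -1)
        for s in range(self.n_species):
            for j, u in enumerate(self.pops_of_species[s]):
                pop_pos[u] = j
        self.block_loc: dict[str, list[tuple[np.ndarray, int]]] = {}
        for f in self.spec.families:
            nlev = self.shape[f][1]
            per_s = []
            for s in range(self.n_species):
                cells = self.cells_of_sp_fam[f][s]
                ptr = self.ptr[f][cells]
                lev = ptr % nlev
                if f in POPULATION_FAMILIES:
                    loc = pop_pos[ptr // nlev] * nlev + lev
                    nloc = len(self.pops_of_species[s]) * nlev
                else:
                    loc = lev
                    nloc = nlev
                per_s.append((loc, nloc))
            self.block_loc[f] = per_s
        self.children = {
            f: [c for c in self.spec.families if c in PARENTS and f in PARENTS[c]]
            for f in self.spec.families
        }
        # per-species coefficient layout for the likelihood-invariant
        # recentering move: all of a species' coefficients (intercept, its
        # populations' coefficients, and its species-level blocks) stacked
        # into one vector, with the cell -> coefficient incidence pattern.
        # Only cells with n > 0 constrain the move — empty cells carry no
        # likelihood, so their coefficients are freely redrawn.
        observed = self.n > 0
        self.fiber_cells = [
            np.flatnonzero((s_idx == s) & observed) for s in range(self.n_species)
        ]
        self.fiber_layout: list[tuple[list, int]] = []
        for s in range(self.n_species):
            pos = {c: i for i, c in enumerate(self.fiber_cells[s])}
            entries = [
                ("S", 0, 1, np.arange(len(pos)), np.zeros(len(pos), dtype=int))
            ]
            off = 1
            for f in self.spec.families:
                loc, nloc = self.block_loc[f][s]
                keep = [i for i, c in enumerate(self.cells_of_sp_fam[f][s]) if c in pos]
                rows = np.array([pos[self.cells_of_sp_fam[f][s][i]] for i in keep], dtype=int)
                entries.append((f, off, nloc, rows, loc[keep]))
                off += nloc
            self.fiber_layout.append((entries, off))

    # -- state ------------------------------------------------------------

    def initial_state(self, rng: np.random.Generator) -> dict:
        beta = {}
        for f, (nu, nl) in self.shape.items():
            beta[f] = rng.normal(0.0, self.priors.coef_sd, size=(nu, nl))
        delta = {}
        for f in self.spec.families:
            if f in PARENTS:
                delta[f] = np.zeros(self.n_species, dtype=np.int8)
            else:
                delta[f] = rng.integers(0, 2, size=self.n_species).astype(np.int8)
        mu = {
            f: np.full(
                self.shape[f][1],
                0.0 if self.priors.fix_hypermean is None else self.priors.fix_hypermean,
            )
            for f in self.correlated
        }
        s2 = 1.0 if self.priors.fix_sigma2 is None else self.priors.fix_sigma2
        sig2 = {f: s2 for f in self.correlated}
        return {"beta": beta, "delta": delta, "mu": mu, "sig2": sig2}

    # -- densities --------------------------------------------------------

    def eta(self, state: dict, idx: np.ndarray | slice = slice(None)) -> np.ndarray:
        beta, delta = state["beta"], state["delta"]
        out = beta["S"].ravel()[self.ptr["S"][idx]].copy()
        s = self.s_idx[idx]
        for f in self.spec.families:
            ptr = self.ptr[f][idx]
            valid = ptr >= 0
            vals = beta[f].ravel()[np.where(valid, ptr, 0)]
            out += np.where(valid, vals, 0.0) * delta[f][s]
        return out

    def loglik(self, state: dict, include_const: bool = True) -> float:
        eta = self.eta(state)
        ll = float(np.sum(self.y * eta - self.n * _softplus(eta)))
        return ll + (self.binom_const if include_const else 0.0)

    def log_delta_prior(self, delta: dict) -> float:
        lp = 0.0
        for f in self.spec.families:
            d = delta[f]
            if f not in PARENTS:
                lp += self.n_species * math.log(self.priors.p_include)
                continue
            a, b = PARENTS[f]
            both = (delta[a] == 1) & (delta[b] == 1)
            for s in range(self.n_species):
                if both[s]:
                    lp += math.log(self.priors.p_include)
                elif d[s] != 0:
                    return -math.inf
        return lp

    def log_joint(self, state: dict) -> float:
        """Full log posterior density (up to no constant: all normalizers kept)."""
        lp = self.loglik(state) + self.log_delta_prior(state["delta"])
        if not np.isfinite(lp):
            return lp
        beta, mu, sig2 = state["beta"], state["mu"], state["sig2"]
        S = self.n_species
        sd0 = self.priors.coef_sd
        for f in self.pop_families:
            b = beta[f].ravel()
            lp += float(
                -0.5 * np.sum(b * b) / sd0**2 - b.size * (0.5 * math.log(2 * math.pi) + math.log(sd0))
            )
        for f in self.correlated:
            s2 = sig2[f]
            nl = self.shape[f][1]
            for l in range(nl):
                r = beta[f][:, l] - mu[f][l]
                quad = float(r @ self.Ainv @ r)
                lp += -0.5 * (
                    S * math.log(2 * math.pi * s2) + self.logdet_A + quad / s2
                )
            if f in MAIN_CORRELATED and self.priors.fix_hypermean is None:
                m = mu[f]
                lp += float(
                    -0.5 * np.sum(m * m) / sd0**2
                    - nl * (0.5 * math.log(2 * math.pi) + math.log(sd0))
                )
            if self.priors.fix_sigma2 is None:
                lam = 1.0 / s2
                a0, b0 = self.priors.gamma_shape, self.priors.gamma_rate
                # density of sigma^2 induced by 1/sigma^2 ~ Gamma(a0, b0)
                lp += float(
                    a0 * math.log(b0) - gammaln(a0) + (a0 - 1) * math.log(lam) - b0 * lam
                    + 2 * math.log(lam)  # Jacobian |d lambda / d sigma^2|
                )
        return float(lp)

    # -- sampling ---------------------------------------------------------

    def run(self, settings: MCMCSettings) -> "Posterior":
        seeds = np.random.SeedSequence(settings.seed).spawn(settings.chains)
        chains = [self._run_chain(np.random.default_rng(s), settings) for s in seeds]
        delta = np.stack([c["delta"] for c in chains])
        sig2 = np.stack([c["sig2"] for c in chains])
        mu = np.stack([c["mu"] for c in chains])
        logpost = np.stack([c["logpost"] for c in chains])
        beta = np.stack([c["beta"] for c in chains]) if settings.store_beta else None
        return Posterior(self, settings, delta, sig2, mu, logpost, beta)

    def _conditional_prior(
        self, state: dict, f: str, s: int, l: int
    ) -> tuple[float, float]:
        """Mean and sd of beta[f][s, l] given the other species (correlated f)."""
        mu_l = state["mu"][f][l]
        s2 = state["sig2"][f]
        col = state["beta"][f][:, l]
        row = self.Ainv[s]
        resid = col - mu_l
        # exclude own entry from the weighted sum
        num = float(row @ resid - row[s] * resid[s])
        mean = mu_l - num / row[s]
        sd = math.sqrt(s2 / row[s])
        return mean, sd

    def _laplace_block(
        self,
        cells: np.ndarray,
        loc: np.ndarray,
        nloc: int,
        m0: np.ndarray,
        sd_0: np.ndarray,
        eta_rest: np.ndarray,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian approximation to a block's conditional posterior.

        Each cell carries exactly one block coefficient, so the penalized
        binomial Newton iteration is diagonal: a few scalar updates per
        coefficient.  Coefficients with no observed cells keep their exact
        conditional prior (so the Hastings terms cancel for them).
        """
        y, n = self.y[cells], self.n[cells]
        v0 = sd_0**2
        b = m0.copy()
        hess = np.full(nloc, -1.0) / v0
        for _ in range(3):
            e = eta_rest + b[loc]
            p = expit(e)
            grad = np.bincount(loc, weights=y - n * p, minlength=nloc) - (b - m0) / v0
            hess = -np.bincount(loc, weights=n * p * (1.0 - p), minlength=nloc) - 1.0 / v0
            b = b - grad / hess
        sd = np.sqrt(-1.0 / hess)
        counts = np.bincount(loc, minlength=nloc)
        observed = counts > 0
        # mild inflation for robustness of the t-like tails
        sd = np.where(observed, 1.15 * sd, sd_0)
        b = np.where(observed, b, m0)
        return b, sd

    def _fiber_move(
        self, state: dict, s: int, rng: np.random.Generator, eta: np.ndarray
    ) -> None:
        """Likelihood-invariant resampling of one species' coefficients.

        The overparameterized factor coding leaves exact ridges in the
        posterior (a block's mean is collinear with the species intercept,
        interaction means with their parents, ...).  This move redraws all
        of the species' coefficients from their joint Gaussian prior
        conditioned on the per-cell linear predictor staying fixed — a
        Gibbs update of the unidentified fiber coordinates — so redundant
        structure flows between blocks the way the prior expects instead of
        by slow random-walk diffusion.  Coefficients of gated-out blocks
        are unconstrained and come back as fresh conditional-prior draws.
        """
        beta, delta = state["beta"], state["delta"]
        entries, d = self.fiber_layout[s]
        cells_s = self.fiber_cells[s]
        nc = cells_s.size
        m = np.empty(d)
        sd = np.empty(d)
        x = np.empty(d)
        M = np.zeros((nc, d))
        for f, off, ncoef, rows, colloc in entries:
            if f == "S":
                m[off], sd[off] = self._conditional_prior(state, "S", s, 0)
                x[off] = beta["S"][s, 0]
                M[rows, off] = 1.0
                continue
            if f in POPULATION_FAMILIES:
                m[off : off + ncoef] = 0.0
                sd[off : off + ncoef] = self.priors.coef_sd
                x[off : off + ncoef] = beta[f][self.pops_of_species[s]].ravel()
            else:
                pm, psd = self._block_prior(state, f, s)
                m[off : off + ncoef] = pm
                sd[off : off + ncoef] = psd
                x[off : off + ncoef] = beta[f][s]
            if delta[f][s]:
                M[rows, off + colloc] = 1.0
        var = sd**2
        xp = m + sd * rng.normal(size=d)
        if nc:
            v = M @ x
            K = (M * var) @ M.T
            w, *_ = np.linalg.lstsq(K, v - M @ xp, rcond=1e-10)
            xn = xp + var * (M.T @ w)
        else:  # nothing observed: unconstrained prior redraw
            xn = xp
        for f, off, ncoef, rows, colloc in entries:
            if f == "S":
                beta["S"][s, 0] = xn[off]
            elif f in POPULATION_FAMILIES:
                beta[f][self.pops_of_species[s]] = xn[off : off + ncoef].reshape(
                    len(self.pops_of_species[s]), -1
                )
            else:
                beta[f][s] = xn[off : off + ncoef]
        if nc:
            eta[cells_s] = M @ xn  # equals v up to float round-off

    def _scale_move(
        self, state: dict, f: str, rng: np.random.Generator, eta: np.ndarray
    ) -> None:
        """Non-centered update of a family's variance.

        Proposes a fresh precision from its Gamma prior while holding the
        standardized coefficients z = (beta - mu) / sigma fixed; the prior
        and Jacobian terms cancel exactly, so the move accepts on the
        likelihood ratio alone.  This jumps across scales the conjugate
        Gibbs step cannot reach (the classic variance funnel) and, with no
        data, samples sigma^2 from its prior exactly.
        """
        beta, delta, mu, sig2 = state["beta"], state["delta"], state["mu"], state["sig2"]
        lam_new = rng.gamma(self.priors.gamma_shape, 1.0 / self.priors.gamma_rate)
        s2_new = 1.0 / lam_new
        factor = math.sqrt(s2_new / sig2[f])
        cells = self.cells_of_fam[f]
        nlev = self.shape[f][1]
        mu_row = mu[f][None, :]
        if cells.size:
            ptr = self.ptr[f][cells]
            vals_old = beta[f].ravel()[ptr]
            mu_cell = mu[f][ptr % nlev]
            gate = 1.0 if f == "S" else delta[f][self.s_idx[cells]]
            d_eta = gate * (factor - 1.0) * (vals_old - mu_cell)
            e_old = eta[cells]
            e_new = e_old + d_eta
            dlik = float(
                np.sum(
                    self.y[cells] * d_eta
                    - self.n[cells] * (_softplus(e_new) - _softplus(e_old))
                )
            )
        else:
            dlik = 0.0
        if rng.random() < math.exp(min(0.0, dlik)):
            beta[f] = mu_row + factor * (beta[f] - mu_row)
            sig2[f] = s2_new
            if cells.size:
                eta[cells] = e_new

    def _block_prior(self, state: dict, f: str, s: int) -> tuple[np.ndarray, np.ndarray]:
        """Conditional-prior means and sds of species ``s``'s block in family ``f``."""
        nlev = self.shape[f][1]
        m = np.empty(nlev)
        sd = np.empty(nlev)
        for l in range(nlev):
            m[l], sd[l] = self._conditional_prior(state, f, s, l)
        return m, sd

    def _run_chain(self, rng: np.random.Generator, settings: MCMCSettings) -> dict:
        state = self.initial_state(rng)
        beta, delta, mu, sig2 = (
            state["beta"],
            state["delta"],
            state["mu"],
            state["sig2"],
        )
        # adaptation runs with every indicator on (the full model), so that
        # proposal scales and pseudo-priors are fitted for every block;
        # indicator flips begin at burn-in
        for f in self.spec.families:
            delta[f][:] = 1
        eta = self.eta(state)
        y, n = self.y, self.n

        # proposal scales, adapted during the adapt phase only
        log_scale = {f: np.zeros(self.shape[f][1]) for f in self.ptr}
        target = {f: (0.23 if f in self.correlated else 0.44) for f in self.ptr}


        n_iter = settings.adapt + settings.burnin + settings.samples_per_chain
        n_keep = settings.samples_per_chain // settings.thin
        famlist = list(self.spec.families)
        rec_delta = np.empty((n_keep, self.n_species, len(famlist)), dtype=np.int8)
        rec_sig2 = np.empty((n_keep, len(self.correlated)))
        n_mu = sum(self.shape[f][1] for f in MAIN_CORRELATED if f in self.correlated)
        rec_mu = np.empty((n_keep, n_mu))
        rec_logpost = np.empty(n_keep)
        n_beta = sum(v.size for v in beta.values())
        rec_beta = np.empty((n_keep, n_beta)) if settings.store_beta else None
        kept = 0

        sd0 = self.priors.coef_sd
        one = np.ones(self.n_species)
        Ainv_one = self.Ainv @ one
        one_Ainv_one = float(one @ Ainv_one)

        for it in range(n_iter):
            adapting = it < settings.adapt
            gamma = min(0.25, 5.0 / math.sqrt(it + 10.0)) if adapting else 0.0

            # --- correlated species-level coefficient columns (block RW)
            for f in self.correlated:
                nlev = self.shape[f][1]
                gate = None if f == "S" else delta[f]
                for l in range(nlev):
                    scale = math.exp(log_scale[f][l])
                    cur = beta[f][:, l]
                    step = scale * (self.chol_A @ rng.normal(size=self.n_species))
                    prop = cur + step
                    r_cur = cur - mu[f][l]
                    r_prop = prop - mu[f][l]
                    dprior = -0.5 / sig2[f] * float(
                        r_prop @ self.Ainv @ r_prop - r_cur @ self.Ainv @ r_cur
                    )
                    cells = self.cells_of_col[f][l]
                    if cells.size:
                        g = 1.0 if gate is None else gate[self.s_idx[cells]]
                        d_eta = g * step[self.s_idx[cells]]
                        e_old = eta[cells]
                        e_new = e_old + d_eta
                        dlik = float(
                            np.sum(y[cells] * d_eta - n[cells] * (_softplus(e_new) - _softplus(e_old)))
                        )
                    else:
                        dlik = 0.0
                        e_new = None
                    log_alpha = dprior + dlik
                    if not np.isfinite(log_alpha) and log_alpha > 0:
                        raise RuntimeError("divergent proposal: non-finite log density")
                    acc = min(1.0, math.exp(min(0.0, log_alpha)))
                    if rng.random() < acc:
                        beta[f][:, l] = prop
                        if cells.size:
                            eta[cells] = e_new
                    if adapting:
                        log_scale[f][l] += gamma * (acc - target[f])

            # --- population-level coefficient columns (per-unit RW)
            for f in self.pop_families:
                nlev = self.shape[f][1]
                gate = delta[f]
                for l in range(nlev):
                    scale = math.exp(log_scale[f][l])
                    cur = beta[f][:, l]
                    step = scale * rng.normal(size=self.n_pops)
                    cells = self.cells_of_col[f][l]
                    dlik_u = np.zeros(self.n_pops)
                    if cells.size:
                        unit = self.ptr[f][cells] // nlev
                        g = gate[self.s_idx[cells]]
                        d_eta = g * step[unit]
                        e_old = eta[cells]
                        e_new = e_old + d_eta
                        contrib = y[cells] * d_eta - n[cells] * (_softplus(e_new) - _softplus(e_old))
                        dlik_u = np.bincount(unit, weights=contrib, minlength=self.n_pops)
                    prop = cur + step
                    dprior_u = -0.5 * (prop**2 - cur**2) / sd0**2
                    log_alpha = dprior_u + dlik_u
                    acc_p = np.minimum(1.0, np.exp(np.minimum(0.0, log_alpha)))
                    accepted = rng.random(self.n_pops) < acc_p
                    beta[f][accepted, l] = prop[accepted]
                    if cells.size and accepted.any():
                        m = accepted[unit]
                        eta[cells[m]] = e_new[m]
                    if adapting:
                        log_scale[f][l] += gamma * (float(acc_p.mean()) - target[f])

            # --- indicator flips with fresh block draws (skipped while the
            # adaptation phase holds the full model)
            for s in range(self.n_species if not adapting else 0):
                for f in famlist:
                    d_cur = int(delta[f][s])
                    if f in PARENTS:
                        a, b = PARENTS[f]
                        if d_cur == 0 and not (delta[a][s] and delta[b][s]):
                            continue  # prior forbids turning on
                        dprior_delta = 0.0
                    else:
                        kids = [
                            c
                            for c in self.children[f]
                            if delta[[p for p in PARENTS[c] if p != f][0]][s]
                        ]
                        if d_cur == 1 and any(delta[c][s] for c in self.children[f]):
                            continue  # prior forbids removing a parent in use
                        dprior_delta = (len(kids) * _LOG2) * (1 if d_cur == 1 else -1)

                    # conditional-prior parameters of the species' block
                    if f in POPULATION_FAMILIES:
                        sel: np.ndarray | int = self.pops_of_species[s]
                        old_block = beta[f][sel].copy()
                        m0 = np.zeros(old_block.size)
                        sd_0 = np.full(old_block.size, sd0)
                    else:
                        sel = s
                        old_block = beta[f][s].copy()
                        m0, sd_0 = self._block_prior(state, f, s)
                    flat_old = old_block.ravel()
                    cells = self.cells_of_sp_fam[f][s]
                    loc, nloc = self.block_loc[f][s]

                    if cells.size:
                        e_old = eta[cells]
                        eta_rest = e_old - flat_old[loc] if d_cur == 1 else e_old

                    # turn-on proposals draw the block from a Laplace
                    # (one-block IRLS) approximation of its conditional
                    # posterior given the rest of the linear predictor, with
                    # the exact Hastings correction; a 20% share of plain
                    # conditional-prior flips keeps exploring
                    extra = 0.0
                    use_laplace = cells.size > 0 and rng.random() < 0.8
                    if use_laplace:
                        mhat, sdhat = self._laplace_block(
                            cells, loc, nloc, m0, sd_0, eta_rest
                        )
                    if d_cur == 0:
                        if use_laplace:
                            flat_new = mhat + sdhat * rng.normal(size=nloc)
                            extra = float(
                                np.sum(
                                    _norm_logpdf(flat_new, m0, sd_0)
                                    - _norm_logpdf(flat_new, mhat, sdhat)
                                )
                            )
                        else:
                            flat_new = m0 + sd_0 * rng.normal(size=nloc)
                        e_new = eta_rest + flat_new[loc] if cells.size else None
                    else:
                        flat_new = m0 + sd_0 * rng.normal(size=nloc)
                        if use_laplace:  # reverse (turn-on) move draws from Laplace
                            extra = float(
                                np.sum(
                                    _norm_logpdf(flat_old, mhat, sdhat)
                                    - _norm_logpdf(flat_old, m0, sd_0)
                                )
                            )
                        e_new = eta_rest if cells.size else None
                    if cells.size:
                        dlik = float(
                            np.sum(
                                y[cells] * (e_new - e_old)
                                - n[cells] * (_softplus(e_new) - _softplus(e_old))
                            )
                        )
                    else:
                        dlik = 0.0
                    log_alpha = dlik + dprior_delta + extra
                    if rng.random() < math.exp(min(0.0, log_alpha)):
                        delta[f][s] = 1 - d_cur
                        beta[f][sel] = flat_new.reshape(old_block.shape)
                        if cells.size:
                            eta[cells] = e_new

            # --- likelihood-invariant recentering along the coding ridges
            for s in range(self.n_species):
                self._fiber_move(state, s, rng, eta)

            # --- hypermeans (conjugate normal) and variances (conjugate gamma)
            if self.priors.fix_hypermean is None:
                for f in MAIN_CORRELATED:
                    if f not in self.correlated:
                        continue
                    for l in range(self.shape[f][1]):
                        prec = 1.0 / sd0**2 + one_Ainv_one / sig2[f]
                        mean = float(Ainv_one @ beta[f][:, l]) / sig2[f] / prec
                        mu[f][l] = rng.normal(mean, math.sqrt(1.0 / prec))
            if self.priors.fix_sigma2 is None:
                for f in self.correlated:
                    nlev = self.shape[f][1]
                    quad = 0.0
                    for l in range(nlev):
                        r = beta[f][:, l] - mu[f][l]
                        quad += float(r @ self.Ainv @ r)
                    shape = self.priors.gamma_shape + 0.5 * self.n_species * nlev
                    rate = self.priors.gamma_rate + 0.5 * quad
                    sig2[f] = 1.0 / rng.gamma(shape, 1.0 / rate)
                    self._scale_move(state, f, rng, eta)

            # periodic refresh against float drift
            if (it + 1) % 1000 == 0:
                eta = self.eta(state)

            post_warm = it - settings.adapt - settings.burnin
            if post_warm >= 0 and (post_warm + 1) % settings.thin == 0 and kept < n_keep:
                for j, f in enumerate(famlist):
                    rec_delta[kept, :, j] = delta[f]
                rec_sig2[kept] = [sig2[f] for f in self.correlated]
                rec_mu[kept] = np.concatenate(
                    [mu[f] for f in MAIN_CORRELATED if f in self.correlated]
                )
                lp = self.log_joint(state)
                if not np.isfinite(lp):
                    raise RuntimeError("chain diverged: non-finite log joint density")
                rec_logpost[kept] = lp
                if rec_beta is not None:
                    rec_beta[kept] = np.concatenate([beta[f].ravel() for f in beta])
                kept += 1

        return {
            "delta": rec_delta[:kept],
            "sig2": rec_sig2[:kept],
            "mu": rec_mu[:kept],
            "logpost": rec_logpost[:kept],
            "beta": rec_beta[:kept] if rec_beta is not None else None,
        }


@dataclass
class Posterior:
    """Thinned post-burnin draws from all chains."""

    model: SpikeSlabModel
    settings: MCMCSettings
    delta: np.ndarray  # (chains, draws, species, families)
    sig2: np.ndarray  # (chains, draws, correlated families)
    mu: np.ndarray  # (chains, draws, hypermean columns)
    logpost: np.ndarray  # (chains, draws)
    beta: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def families(self) -> tuple[str, ...]:
        return self.model.spec.families

    @property
    def n_draws(self) -> int:
        return self.delta.shape[0] * self.delta.shape[1]


def _split_rhat(x: np.ndarray) -> float:
    """Split-R-hat of a (chains, draws) array; 1.0 for constant traces."""
    c, d = x.shape
    if d < 4:
        return float("nan")
    half = d // 2
    parts = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m = parts.mean(axis=1)
    v = parts.var(axis=1, ddof=1)
    W = v.mean()
    B = parts.shape[1] * m.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else float("inf")
    var_hat = (parts.shape[1] - 1) / parts.shape[1] * W + B / parts.shape[1]
    return float(math.sqrt(var_hat / W))


def _ess(x: np.ndarray) -> float:
    """Effective sample size via arviz (falls back to n for constant traces)."""
    import arviz as az

    if np.allclose(x, x.ravel()[0]):
        return float(x.size)
    with np.errstate(all="ignore"):
        e = float(az.ess(x))  # arviz treats a 2-D array as (chain, draw)
    return e if np.isfinite(e) else float(x.size)


def inclusion_table(post: Posterior, rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Species × predictor posterior inclusion probabilities.

    The returned frame carries per-entry Monte-Carlo standard errors and
    split-R-hat diagnostics in ``.attrs["mcse"]`` and ``.attrs["rhat"]``;
    ``.attrs["converged"]`` is False if any indicator's R-hat exceeds the
    threshold.
    """
    if post.n_draws < 1000:
        raise ValueError("need at least 1000 retained draws for an inclusion table")
    species = post.model.species
    fams = list(post.families)
    prob = post.delta.mean(axis=(0, 1))
    mcse = np.empty_like(prob, dtype=float)
    rhat = np.empty_like(prob, dtype=float)
    for i in range(len(species)):
        for j in range(len(fams)):
            trace = post.delta[:, :, i, j].astype(float)
            rhat[i, j] = _split_rhat(trace)
            ess = _ess(trace)
            mcse[i, j] = math.sqrt(max(trace.var(), 0.0) / max(ess, 1.0))
    table = pd.DataFrame(prob, index=species, columns=fams)
    table.attrs["mcse"] = pd.DataFrame(mcse, index=species, columns=fams)
    table.attrs["rhat"] = pd.DataFrame(rhat, index=species, columns=fams)
    table.attrs["converged"] = bool(np.nanmax(rhat) <= rhat_threshold)
    return table


def phylogeny_necessity_check(post: Posterior) -> float:
    """Posterior probability that no species includes the population factor.

    A value of 0 means at least one population predictor was always in the
    model — the observed variation is never attributed to phylogeny alone.
    """
    if "P" not in post.families:
        raise ValueError("model has no population family")
    j = list(post.families).index("P")
    none_included = (post.delta[:, :, :, j] == 0).all(axis=2)
    return float(none_included.mean())


def run_mcmc(
    cells: pd.DataFrame,
    A: pd.DataFrame,
    priors: Priors = Priors(),
    settings: MCMCSettings = MCMCSettings(),
    spec: ModelSpec = ModelSpec(),
) -> Posterior:
    """Fit the spike-and-slab GLMM by MCMC and return posterior draws."""
    return SpikeSlabModel(cells, A, priors, spec).run(settings)


def log_joint(
    state: dict,
    cells: pd.DataFrame,
    A: pd.DataFrame,
    priors: Priors = Priors(),
    spec: ModelSpec = ModelSpec(),
) -> float:
    """Joint log density of a full parameter state given the data."""
    return SpikeSlabModel(cells, A, priors, spec).log_joint(state)
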