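"""Distance matrices and Mantel permutation tests.

The Mantel statistic is the Pearson correlation between the strictly
lower-triangular entries of two labeled distance matrices.  Significance
comes from jointly permuting the rows and columns of the second matrix;
the one-tailed upper p-value uses the add-one permutational convention
p = (1 + #{r_perm >= r_obs}) / (1 + n_permutations).  For small matrices an
exhaustive mode enumerates all n! relabelings and returns the exact p.

Species-level phylogenetic distances are compared against population-level
trait matrices either by expanding the species matrix to population pairs
(conspecific distance 0) or by averaging traits to species level first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

DEFAULT_SEED = 20150801


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_one_tailed: float
    n_permutations: int
    seed: int | None
    exhaustive: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        mode = "exhaustive" if self.exhaustive else f"{self.n_permutations} permutations"
        return f"Mantel r = {self.r:.4g}, one-tailed p = {self.p_one_tailed:.4g} ({mode})"


def euclidean_distances(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Euclidean (L2) distances between the rows of a table."""
    if table.isna().any().any():
        bad = [
            f"({idx}, {col})"
            for idx, row in table.isna().iterrows()
            for col, isna in row.items()
            if isna
        ]
        raise ValueError(f"missing values in cells: {', '.join(bad)}")
    D = squareform(pdist(table.to_numpy(dtype=float), metric="euclidean"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


def expand_species_distances(
    d_species: pd.DataFrame, population_map: Mapping[str, str]
) -> pd.DataFrame:
    """Expand a species × species distance matrix to population pairs.

    ``population_map`` maps population id -> species code.  Conspecific
    populations get distance 0.
    """
    pops = sorted(population_map)
    unmapped = [p for p in pops if population_map[p] not in d_species.index]
    if unmapped:
        raise ValueError(f"populations mapped to species absent from matrix: {unmapped}")
    sp = [population_map[p] for p in pops]
    D = d_species.loc[sp, sp].to_numpy(dtype=float)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=pops, columns=pops)


def species_mean_traits(traits: pd.DataFrame, population_map: Mapping[str, str]) -> pd.DataFrame:
    """Average a population × trait table to species level."""
    sp = pd.Series({p: population_map[p] for p in traits.index}, name="species")
    return traits.groupby(sp).mean()


def _check_pair(d1: pd.DataFrame, d2: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if list(d1.index) != list(d1.columns) or list(d2.index) != list(d2.columns):
        raise ValueError("distance matrices must have identical row and column labels")
    if set(d1.index) != set(d2.index):
        raise ValueError("matrices have different label sets")
    d2 = d2.loc[d1.index, d1.index]
    m1 = d1.to_numpy(dtype=float)
    m2 = d2.to_numpy(dtype=float)
    for name, m in (("first", m1), ("second", m2)):
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError(f"{name} matrix is not symmetric")
    return m1, m2


def _triangle_corr(v1: np.ndarray, v2: np.ndarray) -> float:
    s1, s2 = v1.std(), v2.std()
    if s1 == 0 or s2 == 0:
        raise ValueError("degenerate matrix: zero variance among distances")
    return float(np.corrcoef(v1, v2)[0, 1])


def mantel_test(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    n_permutations: int = 10000,
    seed: int | None = DEFAULT_SEED,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel permutation test between two labeled distance matrices.

    ``exhaustive=True`` enumerates all n! joint row/column relabelings of
    the second matrix (feasible for n <= 8) and returns the exact one-tailed
    p (the identity permutation is part of the enumeration, so p >= 1/n!).
    Otherwise ``n_permutations`` Monte-Carlo draws are used with the +1
    correction.
    """
    m1, m2 = _check_pair(d1, d2)
    n = m1.shape[0]
    if n < 4:
        raise ValueError("need at least 4 labels for a Mantel test")
    iu = np.tril_indices(n, k=-1)
    v1 = m1[iu]
    r_obs = _triangle_corr(v1, m2[iu])

    if exhaustive:
        if n > 8:
            raise ValueError("exhaustive mode is limited to n <= 8 labels")
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.array(perm)
            r_perm = _triangle_corr(v1, m2[np.ix_(p, p)][iu])
            # >= with a float tolerance so the identity permutation counts
            if r_perm >= r_obs - 1e-12:
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, total, None, exhaustive=True)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(n)
        r_perm = _triangle_corr(v1, m2[np.ix_(p, p)][iu])
        if r_perm >= r_obs - 1e-12:
            count += 1
    p_val = (1 + count) / (1 + n_permutations)
    return MantelResult(r_obs, p_val, n_permutations, seed)
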