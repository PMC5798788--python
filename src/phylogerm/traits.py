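"""Plate-level germination records and viability-adjusted trait matrices.

The germination experiment exposes each population to four stratification
regimes (none; 3 weeks at 3 °C; 8 weeks at 3 °C; 3 weeks at 30 °C) crossed
with two alternating incubation regimes (20/10 °C and 25/15 °C day/night),
with four replicate plates of 25 seeds per treatment.  Germination is
viability-adjusted: the denominator for every plate is the number of seeds
that germinated plus the number of ungerminated seeds judged filled (viable)
by a cut test at the end of the trial.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The four (stratification length in weeks, stratification temperature in
#: °C) treatments applied in the study design.  ``None`` temperature marks
#: the unstratified control.
STRAT_REGIMES: tuple[tuple[int, Optional[float]], ...] = (
    (0, None),
    (3, 3.0),
    (8, 3.0),
    (3, 30.0),
)

#: Day/night incubation temperature regimes (°C).
INCUB_REGIMES: tuple[str, str] = ("20/10", "25/15")

Scope = Literal["total", "stratification"]


def strat_label(length_weeks: int, temp_c: Optional[float]) -> str:
    """Human-readable label for a stratification regime, e.g. ``"3wk/3C"``."""
    if length_weeks == 0:
        return "none"
    return f"{length_weeks}wk/{temp_c:g}C"


def treatment_label(length_weeks: int, temp_c: Optional[float], incub: str) -> str:
    return f"{strat_label(length_weeks, temp_c)}|{incub}"


#: Column order of the 8-trait (total germination) matrix.
TOTAL_COLUMNS: tuple[str, ...] = tuple(
    treatment_label(sl, st, it) for sl, st in STRAT_REGIMES for it in INCUB_REGIMES
)

#: Column order of the 3-trait (germination during stratification) matrix:
#: the three regimes with a nonzero stratification period.
STRAT_COLUMNS: tuple[str, ...] = tuple(
    strat_label(sl, st) for sl, st in STRAT_REGIMES if sl > 0
)


@dataclass(frozen=True)
class PlateRecord:
    """One petri plate's counts under one stratification × incubation treatment."""

    species_code: str
    population_id: str
    strat_length_weeks: int
    strat_temp_c: Optional[float]  # None iff strat_length_weeks == 0
    incub_regime: str
    replicate: int
    n_sown: int
    germ_strat: int
    germ_incub: int
    filled_ungerminated: int

    def __post_init__(self) -> None:
        for field in ("n_sown", "germ_strat", "germ_incub", "filled_ungerminated"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be >= 0, got {getattr(self, field)}")
        total = self.germ_strat + self.germ_incub + self.filled_ungerminated
        if total > self.n_sown:
            raise ValueError(
                f"germ_strat + germ_incub + filled_ungerminated = {total} "
                f"exceeds n_sown = {self.n_sown} for plate {self.population_id}"
            )
        if (self.strat_temp_c is None) != (self.strat_length_weeks == 0):
            raise ValueError(
                "strat_temp_c must be None exactly when strat_length_weeks == 0"
            )
        if (self.strat_length_weeks, self.strat_temp_c) not in STRAT_REGIMES:
            raise ValueError(
                f"unknown stratification regime "
                f"({self.strat_length_weeks} wk, {self.strat_temp_c} °C)"
            )
        if self.incub_regime not in INCUB_REGIMES:
            raise ValueError(f"unknown incubation regime {self.incub_regime!r}")


def viable_count(plate: PlateRecord) -> int:
    """Number of viable seeds on a plate.

    Germinated seeds are viable by definition; viability of ungerminated
    seeds comes from the end-of-trial cut test (filled, intact embryo).
    """
    return plate.germ_strat + plate.germ_incub + plate.filled_ungerminated


def adjusted_proportion(
    plate: PlateRecord,
    scope: Scope = "total",
    include_warm_strat_in_total: bool = True,
) -> float:
    """Viability-adjusted germination proportion for one plate.

    ``scope="total"`` counts seeds germinated during stratification and
    incubation; ``scope="stratification"`` counts only those that germinated
    during the stratification period.  A plate with zero viable seeds yields
    ``nan`` (with a logged warning) so that replicate averaging can skip it.

    ``include_warm_strat_in_total=False`` excludes germinants of the warm
    (30 °C) stratification period from the total-germination numerator.
    """
    viable = viable_count(plate)
    if viable == 0:
        logger.warning(
            "plate %s rep %d (%s) has zero viable seeds; proportion is missing",
            plate.population_id,
            plate.replicate,
            treatment_label(plate.strat_length_weeks, plate.strat_temp_c, plate.incub_regime),
        )
        return math.nan
    if scope == "stratification":
        return plate.germ_strat / viable
    if scope != "total":
        raise ValueError(f"unknown scope {scope!r}")
    germ = plate.germ_strat + plate.germ_incub
    if not include_warm_strat_in_total and plate.strat_temp_c == 30.0:
        germ = plate.germ_incub
    return germ / viable


def build_trait_matrix(
    records: Iterable[PlateRecord],
    scope: Scope = "total",
    include_warm_strat_in_total: bool = True,
) -> pd.DataFrame:
    """Population × treatment matrix of mean viability-adjusted proportions.

    Cells are the arithmetic mean of per-plate proportions over replicates
    (mean of proportions, not pooled counts).  ``scope="total"`` yields the
    8-column matrix over all stratification × incubation treatments;
    ``scope="stratification"`` yields the 3-column matrix over the three
    stratified regimes (plates from both incubation regimes are averaged,
    since germination during stratification precedes incubation).

    Raises ``ValueError`` listing the holes if any population lacks every
    replicate of some treatment.
    """
    records = list(records)
    if scope == "total":
        columns: Sequence[str] = TOTAL_COLUMNS
        key = lambda r: treatment_label(r.strat_length_weeks, r.strat_temp_c, r.incub_regime)
        wanted = lambda r: True
    elif scope == "stratification":
        columns = STRAT_COLUMNS
        key = lambda r: strat_label(r.strat_length_weeks, r.strat_temp_c)
        wanted = lambda r: r.strat_length_weeks > 0
    else:
        raise ValueError(f"unknown scope {scope!r}")

    pops = sorted({r.population_id for r in records})
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    for r in records:
        if not wanted(r):
            continue
        p = adjusted_proportion(r, scope, include_warm_strat_in_total)
        if math.isnan(p):
            continue
        cell = (r.population_id, key(r))
        sums[cell] = sums.get(cell, 0.0) + p
        counts[cell] = counts.get(cell, 0) + 1

    holes = [
        (pop, col) for pop in pops for col in columns if counts.get((pop, col), 0) == 0
    ]
    if holes:
        listing = ", ".join(f"{pop}×{col}" for pop, col in holes)
        raise ValueError(f"population × treatment cells with no usable plate: {listing}")

    mat = pd.DataFrame(
        [[sums[(pop, col)] / counts[(pop, col)] for col in columns] for pop in pops],
        index=pd.Index(pops, name="population_id"),
        columns=list(columns),
    )
    mat.attrs["scope"] = scope
    return mat


# ---------------------------------------------------------------------------
# I/O and downstream reshaping

_CSV_COLUMNS = [
    "species_code",
    "population_id",
    "strat_length_weeks",
    "strat_temp_c",
    "incub_regime",
    "replicate",
    "n_sown",
    "germ_strat",
    "germ_incub",
    "filled_ungerminated",
]


def _record_from_row(row: pd.Series) -> PlateRecord:
    raw_temp = row["strat_temp_c"]
    if isinstance(raw_temp, str) and raw_temp.strip().lower() in ("none", "na", ""):
        temp: Optional[float] = None
    elif pd.isna(raw_temp):
        temp = None
    else:
        temp = float(raw_temp)
    return PlateRecord(
        species_code=str(row["species_code"]),
        population_id=str(row["population_id"]),
        strat_length_weeks=int(row["strat_length_weeks"]),
        strat_temp_c=temp,
        incub_regime=str(row["incub_regime"]),
        replicate=int(row["replicate"]),
        n_sown=int(row["n_sown"]),
        germ_strat=int(row["germ_strat"]),
        germ_incub=int(row["germ_incub"]),
        filled_ungerminated=int(row["filled_ungerminated"]),
    )


def read_plates_csv(path) -> list[PlateRecord]:
    """Read plate records from a UTF-8 CSV with the canonical header."""
    df = pd.read_csv(path, dtype={"strat_temp_c": str})
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    return [_record_from_row(row) for _, row in df.iterrows()]


def read_plates_xlsx(path, sheet: int | str = 0) -> list[PlateRecord]:
    """Convenience importer for a one-sheet XLSX laid out like the plate CSV."""
    df = pd.read_excel(path, sheet_name=sheet)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate sheet missing columns: {sorted(missing)}")
    return [_record_from_row(row) for _, row in df.iterrows()]


def plates_to_frame(records: Iterable[PlateRecord]) -> pd.DataFrame:
    """Plate records as a tidy DataFrame using the canonical CSV layout."""
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in _CSV_COLUMNS}
        d["strat_temp_c"] = "none" if r.strat_temp_c is None else f"{r.strat_temp_c:g}"
        rows.append(d)
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def write_plates_csv(records: Iterable[PlateRecord], path) -> None:
    plates_to_frame(records).to_csv(path, index=False)


def design_cells(
    records: Iterable[PlateRecord],
    response: Scope = "total",
    per_plate: bool = True,
    stratified_only: bool = False,
) -> pd.DataFrame:
    """Binomial response cells for the GLMM / GLM stages.

    One row per plate (default) or per population × treatment cell
    (``per_plate=False``, counts pooled), with columns ``species``,
    ``population``, ``sl`` (weeks), ``st`` ("3"/"30"/"none"), ``it``,
    ``y`` (germinated, scope-dependent) and ``n`` (viable seeds).
    ``stratified_only`` drops the unstratified control plates, as used by
    the during-stratification GLMs.
    """
    rows = []
    for r in records:
        if stratified_only and r.strat_length_weeks == 0:
            continue
        n = viable_count(r)
        y = r.germ_strat if response == "stratification" else r.germ_strat + r.germ_incub
        rows.append(
            {
                "species": r.species_code,
                "population": r.population_id,
                "sl": r.strat_length_weeks,
                "st": "none" if r.strat_temp_c is None else f"{r.strat_temp_c:g}",
                "it": r.incub_regime,
                "replicate": r.replicate,
                "y": y,
                "n": n,
            }
        )
    df = pd.DataFrame(rows)
    if not per_plate:
        df = (
            df.groupby(["species", "population", "sl", "st", "it"], as_index=False)[["y", "n"]]
            .sum()
        )
    return df
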