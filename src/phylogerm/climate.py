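"""Bioclimatic variables from monthly climate, and climate variable subsets.

Seven standard bioclim summaries describe each seed source site:

====  =======================================  =========
BIO1  mean annual temperature                  °C
BIO2  mean diurnal range (tmax − tmin)         °C
BIO4  temperature seasonality (sd × 100)       °C × 100
BIO8  mean temperature of the wettest quarter  °C
BIO12 annual precipitation                     mm
BIO15 precipitation seasonality (CV)           %
BIO18 precipitation of the warmest quarter     mm
====  =======================================  =========

Quarters are consecutive 3-month windows with December–January wrap-around
(12 candidate windows); ties between equally wettest/warmest quarters go to
the earliest window.  Standard deviations use the population (n) denominator
and BIO15 divides by 1 + mean monthly precipitation, matching the convention
of the widely used ``biovars`` implementation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BIOCLIM_COLUMNS = ["bio1", "bio2", "bio4", "bio8", "bio12", "bio15", "bio18"]

TEMPERATURE_VARS = ["bio1", "bio2", "bio4", "bio8"]
PRECIPITATION_VARS = ["bio12", "bio15", "bio18"]


def _validate_monthly(tmin, tmax, prec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    prec = np.asarray(prec, dtype=float)
    for name, arr in (("tmin", tmin), ("tmax", tmax), ("prec", prec)):
        if arr.shape != (12,):
            raise ValueError(f"{name} must have exactly 12 monthly values")
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin in some month")
    if np.any(prec < 0):
        raise ValueError("negative precipitation")
    return tmin, tmax, prec


def _quarter_sums(x: np.ndarray) -> np.ndarray:
    """Sums of the 12 wrap-around consecutive 3-month windows."""
    ext = np.concatenate([x, x[:2]])
    return np.array([ext[m : m + 3].sum() for m in range(12)])


def compute_bioclim_row(tmin, tmax, prec) -> dict[str, float]:
    """The seven bioclim variables for one site's 12-month series."""
    tmin, tmax, prec = _validate_monthly(tmin, tmax, prec)
    tavg = (tmin + tmax) / 2.0
    wet = _quarter_sums(prec)
    warm_t = _quarter_sums(tavg) / 3.0  # mean temperature per window
    wettest = int(np.argmax(wet))  # argmax takes the earliest tie
    warmest = int(np.argmax(warm_t))
    tavg_ext = np.concatenate([tavg, tavg[:2]])
    prec_ext = np.concatenate([prec, prec[:2]])
    return {
        "bio1": float(tavg.mean()),
        "bio2": float((tmax - tmin).mean()),
        "bio4": float(tavg.std(ddof=0) * 100.0),
        "bio8": float(tavg_ext[wettest : wettest + 3].mean()),
        "bio12": float(prec.sum()),
        "bio15": float(100.0 * prec.std(ddof=0) / (1.0 + prec.mean())),
        "bio18": float(prec_ext[warmest : warmest + 3].sum()),
    }


def compute_bioclim(monthly: pd.DataFrame) -> pd.DataFrame:
    """Bioclim table for a set of populations from monthly climate.

    ``monthly`` is tidy with columns ``population_id``, ``month`` (1–12),
    ``tmin``, ``tmax``, ``prec``; returns one row per population with the
    seven bioclim columns.
    """
    required = {"population_id", "month", "tmin", "tmax", "prec"}
    if not required <= set(monthly.columns):
        raise ValueError(f"monthly table missing columns: {sorted(required - set(monthly.columns))}")
    rows = {}
    for pop, grp in monthly.groupby("population_id", sort=True):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"population {pop}: months must be exactly 1..12")
        rows[pop] = compute_bioclim_row(
            grp["tmin"].to_numpy(), grp["tmax"].to_numpy(), grp["prec"].to_numpy()
        )
    table = pd.DataFrame.from_dict(rows, orient="index", columns=BIOCLIM_COLUMNS)
    table.index.name = "population_id"
    return table


def log_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Natural-log transform of a bioclim table, to even out scales.

    Temperatures can be zero or negative, so any column whose minimum is
    <= 0 is first shifted by ``1 - min`` (the smallest value maps to
    log(1) = 0); the shift is logged loudly since it is a convention, not
    an identity.
    """
    out = table.copy().astype(float)
    for col in out.columns:
        colmin = out[col].min()
        if not np.isfinite(colmin):
            raise ValueError(f"column {col} contains non-finite values")
        if colmin <= 0:
            offset = 1.0 - colmin
            logger.warning(
                "log_transform: column %s has min %.4g <= 0; shifting by +%.4g before log",
                col,
                colmin,
                offset,
            )
            out[col] = out[col] + offset
        out[col] = np.log(out[col])
    return out


def subset_variables(table: pd.DataFrame, which: str) -> pd.DataFrame:
    """Select bioclim columns: ``all``, ``temperature``, ``precipitation``
    or a single variable name such as ``bio15``."""
    which = which.lower()
    if which == "all":
        cols = [c for c in BIOCLIM_COLUMNS if c in table.columns]
    elif which == "temperature":
        cols = TEMPERATURE_VARS
    elif which == "precipitation":
        cols = PRECIPITATION_VARS
    elif which in BIOCLIM_COLUMNS:
        cols = [which]
    else:
        raise ValueError(f"unknown variable selector {which!r}")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"requested columns absent from table: {missing}")
    return table[cols].copy()
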