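"""Life tables of expected (background) mortality.

A life table is a grid of annual hazard rates lambda_P*(age, year[, stratum])
from which excess-hazard models read the expected mortality of the general
population.  Attained age and calendar year both advance continuously with
follow-up time (a diagonal path through the Lexis diagram); rates are
piecewise constant on 1-year x 1-year cells, which makes every cumulative
hazard an exact piecewise-linear function of follow-up time.

Lookups beyond the tabulated age or year range carry the boundary cell
forward rather than raising: simulated or real subjects routinely outlive
the last tabulated age.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LifeTable",
    "AlphaSchedule",
    "expected_hazard",
    "cumulative_expected_hazard",
    "build_complete_table",
    "read_life_table",
    "write_life_table",
    "load_us_male_1990",
]


class LifeTableError(ValueError):
    """Malformed life-table input (holes, negative rates, bad stratum)."""


@dataclass(frozen=True)
class LifeTable:
    """Grid of annual expected hazard rates.

    Parameters
    ----------
    ages, years
        Contiguous integer grids (step 1 year).
    rates
        Array of shape ``(n_ages, n_years)`` or ``(n_ages, n_years,
        n_strata)``; non-negative annual hazards (units 1/year).
    strata
        Optional stratum labels (e.g. ``("male", "female")``).
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    strata: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or years.ndim != 1:
            raise LifeTableError("age and year grids must be 1-d")
        if np.any(np.diff(ages) != 1):
            raise LifeTableError("age grid must be contiguous with step 1")
        if len(years) > 1 and np.any(np.diff(years) != 1):
            raise LifeTableError("year grid must be contiguous with step 1")
        expected_shape = (len(ages), len(years))
        if self.strata is not None:
            expected_shape += (len(self.strata),)
        if rates.shape != expected_shape:
            raise LifeTableError(
                f"rates shape {rates.shape} does not match grid {expected_shape}"
            )
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise LifeTableError("all rates must be finite and >= 0")

    def stratum_index(self, stratum: str | None) -> int | None:
        if self.strata is None:
            if stratum is not None:
                raise LifeTableError(
                    f"table has no strata but stratum {stratum!r} requested"
                )
            return None
        if stratum is None:
            if len(self.strata) == 1:
                return 0
            raise LifeTableError(
                f"stratum required; available strata: {list(self.strata)}"
            )
        try:
            return self.strata.index(str(stratum))
        except ValueError:
            raise LifeTableError(
                f"unknown stratum {stratum!r}; available strata: {list(self.strata)}"
            ) from None

    def rate_grid(self, stratum: str | None = None) -> np.ndarray:
        """2-d (age x year) rate grid for one stratum."""
        s = self.stratum_index(stratum)
        return self.rates if s is None else self.rates[:, :, s]


@dataclass(frozen=True)
class AlphaSchedule:
    """Age-segment multipliers on the expected hazard.

    ``breakpoints`` are attained ages splitting the age axis into B+1
    left-closed right-open segments ``[eps_{b-1}, eps_b)``; ``multipliers``
    has one row per level of the additional variable and B+1 columns of
    strictly positive factors alpha_mb.
    """

    breakpoints: tuple[float, ...]
    multipliers: np.ndarray  # shape (M, B + 1)

    def __post_init__(self) -> None:
        bps = tuple(float(e) for e in self.breakpoints)
        mult = np.atleast_2d(np.asarray(self.multipliers, dtype=float))
        object.__setattr__(self, "breakpoints", bps)
        object.__setattr__(self, "multipliers", mult)
        if any(b2 <= b1 for b1, b2 in zip(bps, bps[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if mult.shape[1] != len(bps) + 1:
            raise ValueError(
                f"need {len(bps) + 1} multipliers per level, got {mult.shape[1]}"
            )
        if not np.all(mult > 0):
            raise ValueError("all multipliers must be > 0")

    def segment_of(self, attained_age: float) -> int:
        return int(np.searchsorted(self.breakpoints, attained_age, side="right"))

    def weight(self, attained_age: float, level: int) -> float:
        return float(self.multipliers[level, self.segment_of(attained_age)])


# ---------------------------------------------------------------------------
# Lookup and exact piecewise integration along the Lexis diagonal
# ---------------------------------------------------------------------------


def expected_hazard(
    table: LifeTable,
    attained_age: float,
    year: float,
    stratum: str | None = None,
) -> float:
    """Annual expected hazard of the cell containing (age, year).

    Cell membership is by ``floor`` of each coordinate; coordinates beyond
    the grid are clamped to the boundary cell (carry-forward).
    """
    if attained_age < 0:
        raise ValueError("attained age must be >= 0")
    grid = table.rate_grid(stratum)
    i = int(np.clip(np.floor(attained_age) - table.ages[0], 0, len(table.ages) - 1))
    j = int(np.clip(np.floor(year) - table.years[0], 0, len(table.years) - 1))
    return float(grid[i, j])


def _diagonal_path(
    table: LifeTable,
    age: float,
    year: float,
    t_max: float,
    stratum: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Knots and per-piece rates of the hazard path u -> lambda_P*(age+u, year+u).

    Returns ``(knots, rates)`` with ``knots`` of length J+1 spanning
    ``[0, t_max]`` and ``rates`` of length J, the constant hazard on each
    piece.  Pieces break wherever attained age or calendar year crosses an
    integer boundary; the hazard between knots is evaluated at the piece
    midpoint (exact for piecewise-constant rates).
    """
    if t_max < 0:
        raise ValueError("t must be >= 0")
    grid = table.rate_grid(stratum)
    if t_max == 0:
        return np.array([0.0]), np.array([])
    # integer crossings of age + u and year + u within (0, t_max); rounding
    # merges age and year crossings that coincide, and the final clip keeps
    # the endpoint knot exact so no partial piece is ever dropped
    cuts: list[float] = [0.0, float(t_max)]
    for start in (age, year):
        first = np.floor(start) + 1.0
        if first - start < t_max:
            cuts.extend(np.arange(first - start, t_max, 1.0))
    knots = np.unique(np.round(np.asarray(cuts), 12))
    knots = np.unique(np.clip(knots, 0.0, float(t_max)))
    mids = (knots[:-1] + knots[1:]) / 2.0
    i = np.clip(np.floor(age + mids).astype(int) - table.ages[0], 0, len(table.ages) - 1)
    j = np.clip(np.floor(year + mids).astype(int) - table.years[0], 0, len(table.years) - 1)
    return knots, grid[i, j]


def cumhaz_path(
    table: LifeTable,
    age: float,
    year: float,
    t_max: float,
    stratum: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear cumulative expected hazard over ``[0, t_max]``.

    Returns ``(knots, cumvals)``: the cumulative hazard at each knot; it is
    linear in between.  Used for exact likelihood precomputation and for
    inverse-transform sampling of other-cause death times.
    """
    knots, rates = _diagonal_path(table, age, year, t_max, stratum)
    cum = np.concatenate([[0.0], np.cumsum(rates * np.diff(knots))])
    return knots, cum


def _cum_between(knots: np.ndarray, cum: np.ndarray, u0: float, u1: float) -> float:
    """Cumulative hazard accrued on [u0, u1] from a piecewise-linear path."""
    if u1 <= u0:
        return 0.0
    return float(np.interp(u1, knots, cum) - np.interp(u0, knots, cum))


def cumulative_expected_hazard(
    table: LifeTable,
    age: float,
    diag_year: float,
    t: float,
    stratum: str | None = None,
    schedule: AlphaSchedule | None = None,
    level: int = 0,
) -> float:
    """Integral of the (optionally alpha-weighted) expected hazard over follow-up.

    Computes ``int_0^t w(age + u) lambda_P*(age + u, diag_year + u) du`` with
    ``w == 1`` when no schedule is given and ``w(a) = alpha_{level, b(a)}``
    otherwise.  Exact piecewise integration across every age cell, year cell
    and breakpoint crossing.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    knots, cum = cumhaz_path(table, age, diag_year, t, stratum)
    if schedule is None:
        return float(cum[-1])
    total = 0.0
    seg_edges = [0.0] + [max(0.0, e - age) for e in schedule.breakpoints] + [t]
    seg_edges = np.clip(np.asarray(seg_edges), 0.0, t)
    for b in range(len(schedule.breakpoints) + 1):
        u0, u1 = seg_edges[b], seg_edges[b + 1]
        total += schedule.multipliers[level, b] * _cum_between(knots, cum, u0, u1)
    return total


def segment_cumhaz(
    table: LifeTable,
    age: float,
    diag_year: float,
    t: float,
    breakpoints: Sequence[float],
    stratum: str | None = None,
) -> np.ndarray:
    """Unweighted cumulative expected hazard split by attained-age segment.

    Element b is the portion of the cumulative hazard over ``[0, t]`` accrued
    while the attained age lay in segment b of ``breakpoints``; summing the
    vector gives the total cumulative expected hazard.
    """
    knots, cum = cumhaz_path(table, age, diag_year, t, stratum)
    edges = np.clip([0.0] + [max(0.0, e - age) for e in breakpoints] + [t], 0.0, t)
    out = np.empty(len(breakpoints) + 1)
    for b in range(len(out)):
        out[b] = _cum_between(knots, cum, edges[b], edges[b + 1])
    return out


# ---------------------------------------------------------------------------
# Complete-table construction under a mismatch scenario
# ---------------------------------------------------------------------------


def build_complete_table(
    incomplete: LifeTable,
    scenario,
    labels: tuple[str, ...] | None = None,
) -> LifeTable:
    """Stratify an incomplete table by the additional variable.

    ``scenario`` is either a sequence of per-level multiplier callables
    ``age -> factor`` or any object with a ``multipliers`` attribute holding
    such a sequence (a simulation scenario).  The complete table has one
    stratum per level with ``rate(age, year, m) = mult_m(age) * rate(age,
    year)``; the no-mismatch case (all multipliers identically 1) returns a
    cell-for-cell copy of the incomplete table per level.
    """
    mults: Sequence[Callable[[float], float]]
    mults = getattr(scenario, "multipliers", scenario)
    if incomplete.strata is not None:
        raise LifeTableError("incomplete table must be unstratified")
    n_lev = len(mults)
    factors = np.empty((len(incomplete.ages), n_lev))
    for m, f in enumerate(mults):
        factors[:, m] = [float(f(a)) for a in incomplete.ages]
    if np.any(factors <= 0) or not np.all(np.isfinite(factors)):
        bad = np.argwhere(~(factors > 0))
        age, m = incomplete.ages[bad[0][0]], bad[0][1]
        raise LifeTableError(
            f"non-positive multiplier for level {m} at age {age}"
        )
    rates = incomplete.rates[:, :, None] * factors[:, None, :]
    if labels is None:
        labels = tuple(str(m) for m in range(n_lev))
    return LifeTable(incomplete.ages, incomplete.years, rates, strata=labels)


# ---------------------------------------------------------------------------
# File I/O: long-format delimited tables
# ---------------------------------------------------------------------------


def read_life_table(
    path: str | Path,
    dialect: str = "rate",
    stratum_col: str | None = None,
) -> LifeTable:
    """Read a long-format delimited life table.

    Expected columns: ``age``, ``year``, optionally a stratum column, and
    ``rate`` (annual hazard) or ``qx`` (annual death probability, converted
    via ``-log(1 - q)`` when ``dialect='qx'``).  The (age, year[, stratum])
    grid must be complete; holes, negative rates and q >= 1 are errors that
    name the offending cell.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    value_col = "qx" if dialect == "qx" else "rate"
    if value_col not in df.columns:
        raise LifeTableError(f"missing column {value_col!r} in {path}")
    if stratum_col is None and "sex" in df.columns:
        stratum_col = "sex"
    key_cols = ["age", "year"] + ([stratum_col] if stratum_col else [])
    for c in key_cols:
        if c not in df.columns:
            raise LifeTableError(f"missing column {c!r} in {path}")

    ages = np.arange(df["age"].min(), df["age"].max() + 1)
    years = np.arange(df["year"].min(), df["year"].max() + 1)
    strata = (
        tuple(str(s) for s in pd.unique(df[stratum_col])) if stratum_col else None
    )
    shape = (len(ages), len(years)) + ((len(strata),) if strata else ())
    rates = np.full(shape, np.nan)

    vals = df[value_col].to_numpy(dtype=float)
    if dialect == "qx":
        bad = np.where((vals >= 1) | (vals < 0))[0]
        if bad.size:
            row = df.iloc[bad[0]]
            raise LifeTableError(
                f"invalid qx={row[value_col]} at age={row['age']}, year={row['year']}"
            )
        vals = -np.log1p(-vals)
    elif np.any(vals < 0):
        row = df.iloc[int(np.where(vals < 0)[0][0])]
        raise LifeTableError(
            f"negative rate at age={row['age']}, year={row['year']}"
        )

    i = df["age"].to_numpy(int) - ages[0]
    j = df["year"].to_numpy(int) - years[0]
    if strata:
        k = np.array([strata.index(str(s)) for s in df[stratum_col]])
        rates[i, j, k] = vals
    else:
        rates[i, j] = vals
    if np.any(np.isnan(rates)):
        hole = np.argwhere(np.isnan(rates))[0]
        msg = f"age={ages[hole[0]]}, year={years[hole[1]]}"
        if strata:
            msg += f", {stratum_col}={strata[hole[2]]}"
        raise LifeTableError(f"life table has a hole at {msg}")
    return LifeTable(ages, years, rates, strata=strata)


def write_life_table(
    table: LifeTable, path: str | Path, stratum_col: str = "sex"
) -> None:
    """Write a life table in the long format `read_life_table` accepts."""
    recs = []
    for i, a in enumerate(table.ages):
        for j, y in enumerate(table.years):
            if table.strata is None:
                recs.append({"age": a, "year": y, "rate": table.rates[i, j]})
            else:
                for k, s in enumerate(table.strata):
                    recs.append(
                        {"age": a, "year": y, stratum_col: s, "rate": table.rates[i, j, k]}
                    )
    pd.DataFrame(recs).to_csv(path, index=False)


def load_us_male_1990() -> LifeTable:
    """US male 1990 annual expected-mortality rates, ages 0-109.

    Annualized from the daily hazards of the R `survival` package's
    `survexp.us` ratetable (see docs for the one-line export recipe).
    """
    with resources.as_file(
        resources.files("exhaz.data").joinpath("us_male_1990.csv")
    ) as p:
        return read_life_table(p)
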