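"""Breakpoint-location search by AIC over a decile grid.

The attained-age range is divided into 10 segments by its interior decile
boundaries, giving 9 candidate breakpoint locations; with B breakpoints
there are C(9, B) candidate location sets.  The correction model is fitted
at every set and the one with the lowest AIC is selected.  Choosing by AIC
between the best single-breakpoint and best two-breakpoint fits is the
automatic model ("model 4" in the package's simulation reports).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .models import (
    CohortDesign,
    EmptySegmentError,
    ExcessModelSpec,
    FitResult,
    ParameterVector,
    fit,
)

__all__ = [
    "BreakpointScan",
    "candidate_grid",
    "enumerate_location_sets",
    "scan_breakpoints",
    "select_model4",
]


def candidate_grid(data: pd.DataFrame, n_segments: int = 10) -> np.ndarray:
    """Interior decile boundaries of the attained-age distribution.

    Attained age is taken at end of follow-up (age at diagnosis plus
    follow-up time) for every subject.  Returns the 10%..90% quantiles,
    deduplicated; fewer than 2 distinct candidates is an error.
    """
    attained = (data["age"] + data["t"]).to_numpy(float)
    if len(np.unique(attained)) < n_segments:
        raise ValueError(
            f"need >= {n_segments} distinct attained ages, got {len(np.unique(attained))}"
        )
    qs = np.quantile(attained, np.linspace(0, 1, n_segments + 1)[1:-1])
    out = np.unique(qs)
    if out.size < 2:
        raise ValueError("fewer than 2 distinct breakpoint candidates")
    return out


def enumerate_location_sets(n_candidates: int, n_breakpoints: int) -> list[tuple[int, ...]]:
    """All C(n, B) strictly increasing B-tuples of candidate indices.

    Lexicographic order; B = 0 yields the single empty tuple.
    """
    if n_breakpoints < 0:
        raise ValueError("number of breakpoints must be >= 0")
    if n_breakpoints > n_candidates:
        raise ValueError("more breakpoints than candidates")
    return list(itertools.combinations(range(n_candidates), n_breakpoints))


@dataclass
class BreakpointScan:
    """Result of fitting the correction model at every candidate location set."""

    candidates: np.ndarray
    n_breakpoints: int
    results: pd.DataFrame  # columns: locations, aic, loglik, converged, skipped
    selected: FitResult | None
    selected_locations: tuple[float, ...] | None

    @property
    def n_sets(self) -> int:
        return len(self.results)


def scan_breakpoints(
    data: pd.DataFrame,
    table: LifeTable,
    n_breakpoints: int,
    spec: ExcessModelSpec,
    candidates: np.ndarray | None = None,
    warm_start: bool = True,
) -> BreakpointScan:
    """Fit the breakpoint model at every candidate location set; select by AIC.

    ``spec`` supplies cuts, covariates and level count; its ``breakpoints``
    are replaced by each candidate set in turn (B = 0 degenerates to a
    single proportional-correction fit).  Sets leaving a (level, segment)
    cell without person-time are skipped and recorded.  Ties on AIC break
    toward the earlier (lexicographically smaller) location tuple.  The scan
    is deterministic.
    """
    if candidates is None:
        candidates = candidate_grid(data)
    candidates = np.asarray(candidates, float)
    if n_breakpoints == 0:
        base = replace(spec, kind="touraine", breakpoints=())
        res = fit(data, table, base)
        results = pd.DataFrame(
            [{"locations": (), "aic": res.aic, "loglik": res.loglik,
              "converged": res.converged, "skipped": False}]
        )
        return BreakpointScan(candidates, 0, results, res, ())

    rows = []
    best: FitResult | None = None
    best_locs: tuple[float, ...] | None = None
    init = None
    for idx_set in enumerate_location_sets(len(candidates), n_breakpoints):
        locs = tuple(float(candidates[i]) for i in idx_set)
        cand_spec = replace(spec, kind="breakpoint", breakpoints=locs)
        try:
            res = fit(data, table, cand_spec, init=init)
        except EmptySegmentError:
            rows.append({"locations": locs, "aic": np.nan, "loglik": np.nan,
                         "converged": False, "skipped": True})
            continue
        if warm_start and init is None and res.converged:
            # reuse (beta, tau) from the first converged fit as warm start
            init = ParameterVector(
                res.params.beta, res.params.tau, np.zeros(cand_spec.alpha_shape)
            )
        rows.append({"locations": locs, "aic": res.aic, "loglik": res.loglik,
                     "converged": res.converged, "skipped": False})
        if res.converged and (best is None or res.aic < best.aic):
            best, best_locs = res, locs
    if best is None:
        raise EmptySegmentError(
            "every candidate location set was skipped or failed to converge"
        )
    return BreakpointScan(candidates, n_breakpoints, pd.DataFrame(rows), best, best_locs)


def select_model4(scan1: BreakpointScan, scan2: BreakpointScan) -> FitResult:
    """AIC choice between the best single- and two-breakpoint fits.

    Lower selected AIC wins; an exact tie (and any scan whose competitor
    produced no fit) resolves to the fewer-breakpoint fit, which is the more
    parsimonious model.
    """
    f1, f2 = scan1.selected, scan2.selected
    if f2 is None:
        if f1 is None:
            raise ValueError("neither scan produced a fit")
        return f1
    if f1 is None:
        return f2
    return f2 if f2.aic < f1.aic else f1
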