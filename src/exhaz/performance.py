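"""Replicate-level performance summaries: bias, coverage, RMSE, AIC shares.

Given the estimate store produced by `exhaz.simulate.run_replicates`, these
helpers compute the usual Monte-Carlo criteria for an estimator -- bias,
relative bias (bias / true value), empirical coverage rate of the 95%
intervals, and root mean squared error -- and the percentage of replicates
in which each model of a comparison set attains the lowest AIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PerformanceSummary",
    "summarize_estimates",
    "summarize_store",
    "aic_selection_frequency",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Monte-Carlo criteria for one (model, parameter) pair."""

    bias: float
    relative_bias: float | None
    ecr: float  # percent of CIs containing the truth
    rmse: float
    n_replicates: int

    def as_dict(self) -> dict:
        return {
            "bias": self.bias, "relative_bias": self.relative_bias,
            "ecr": self.ecr, "rmse": self.rmse, "n": self.n_replicates,
        }


def summarize_estimates(
    estimates: np.ndarray,
    true_value: float,
    lo: np.ndarray | None = None,
    hi: np.ndarray | None = None,
) -> PerformanceSummary:
    """bias / relative bias / ECR / RMSE of replicate estimates.

    ``lo``/``hi`` are the per-replicate 95% interval bounds; when omitted
    the ECR is reported as NaN.  Relative bias is undefined at a true value
    of zero and reported as None.
    """
    est = np.asarray(estimates, float)
    if est.size == 0:
        raise ValueError("need at least one converged replicate")
    bias = float(est.mean() - true_value)
    rel = None if true_value == 0 else bias / true_value
    rmse = float(np.sqrt(np.mean((est - true_value) ** 2)))
    if lo is None or hi is None:
        ecr = float("nan")
    else:
        lo = np.asarray(lo, float)
        hi = np.asarray(hi, float)
        ecr = float(100.0 * np.mean((lo <= true_value) & (true_value <= hi)))
    return PerformanceSummary(bias, rel, ecr, rmse, int(est.size))


def summarize_store(
    store: pd.DataFrame, model: str, term: str, true_value: float
) -> PerformanceSummary:
    """Summary for one model/parameter from a `run_replicates` store.

    Non-converged replicates are excluded; estimates are on the log scale
    (beta or log alpha), so ``true_value`` must be too.
    """
    sub = store[
        (store["model"] == model) & (store["term"] == term) & store["converged"]
    ]
    return summarize_estimates(
        sub["estimate"].to_numpy(), true_value,
        sub["lo"].to_numpy(), sub["hi"].to_numpy(),
    )


def aic_selection_frequency(
    aic_table: pd.DataFrame, comparison_set: Sequence[str]
) -> dict[str, float]:
    """Percent of replicates in which each model has the lowest AIC.

    ``aic_table`` has one row per replicate and one column per model (AIC
    values); only replicates with finite AICs for the whole comparison set
    count.  Ties resolve to the model listed first in ``comparison_set``
    (list fewer-breakpoint models first to mirror the parsimony rule).
    """
    cols = list(comparison_set)
    sub = aic_table[cols].dropna()
    if sub.empty:
        raise ValueError("no replicates with AICs for the full comparison set")
    arr = sub.to_numpy(float)
    winners = np.argmin(arr, axis=1)  # argmin takes the first minimum: tie rule
    pct = {m: float(100.0 * np.mean(winners == j)) for j, m in enumerate(cols)}
    return pct


def aic_table_from_store(store: pd.DataFrame) -> pd.DataFrame:
    """Pivot a `run_replicates` store into a replicate x model AIC table."""
    sub = store[store["converged"]].drop_duplicates(["replicate", "model"])
    return sub.pivot(index="replicate", columns="model", values="aic")
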