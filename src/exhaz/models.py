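"""Excess-hazard regression models with background-mortality correction.

The observed hazard of a cohort member is split additively into an excess
(disease-related) hazard and an expected (population) hazard read from a
life table:

    lambda_O(t | z) = lambda_E(t | z) + w(a + t) * lambda_P*(a + t | z_D)

The excess hazard is piecewise-constant in follow-up time with proportional
covariate effects, lambda_E(t|z) = exp(tau_k(t)) * exp(beta' z).  The weight
``w`` on the life-table hazard distinguishes the three model families:

* ``esteve``      -- w == 1 (the life table is trusted);
* ``touraine``    -- w = alpha_m, one multiplier per level m of an
                     additional categorical variable x missing from the
                     life table (proportional mismatch);
* ``breakpoint``  -- w = alpha_mb, the multiplier additionally changes at
                     attained-age breakpoints (piecewise-proportional
                     mismatch).

All three share one log-likelihood, maximized jointly over
psi = (beta, tau, log alpha); the Estève model is the alpha == 1 fixed
case and the proportional model is the zero-breakpoint case, so the
nesting equalities hold exactly.

Two conventions exist for the survival part of the likelihood when
follow-up crosses a breakpoint: weighting each age segment's share of the
cumulative population hazard by its own alpha (``cumulative='segment'``,
the default, which makes the survival term the exact integral of the
hazard), or applying the final segment's alpha to the whole cumulative
hazard (``cumulative='literal'``, kept as a compatibility switch).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .life_tables import LifeTable, cumhaz_path, expected_hazard

__all__ = [
    "SubjectRecord",
    "ExcessModelSpec",
    "ParameterVector",
    "FitResult",
    "EmptySegmentError",
    "default_cuts",
    "excess_hazard",
    "cumulative_excess_hazard",
    "log_likelihood",
    "score_vector",
    "fit",
    "wald_summary",
]

Z975 = 1.959963984540054  # normal 97.5% quantile for Wald intervals


class EmptySegmentError(ValueError):
    """A baseline interval or (level, segment) cell has no person-time."""


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member.

    ``t`` follow-up time in years (> 0), ``delta`` death indicator,
    ``age`` age at diagnosis, ``diag_year`` calendar year of diagnosis,
    ``x`` level of the additional variable (0-based), ``covariates``
    named covariate values entering the excess-hazard linear predictor.
    """

    t: float
    delta: int
    age: float
    diag_year: int
    x: int = 0
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.t > 0:
            raise ValueError("follow-up time must be > 0")
        if self.delta not in (0, 1):
            raise ValueError("death indicator must be 0 or 1")


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"t": r.t, "delta": r.delta, "age": r.age,
               "diag_year": r.diag_year, "x": r.x}
        row.update(r.covariates)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ExcessModelSpec:
    """Identifies a model: baseline cuts, covariates, correction scheme.

    ``kind`` is one of ``esteve`` (no correction), ``touraine`` (per-level
    multipliers, no breakpoints) or ``breakpoint`` (per-level multipliers
    changing at the attained ages in ``breakpoints``).  ``n_levels`` is the
    number of levels of the additional variable; ``stratum_col`` names the
    cohort column used for life-table stratum lookup (demographic variables
    only -- never the additional variable).
    """

    cuts: tuple[float, ...]
    covariates: tuple[str, ...]
    kind: str = "esteve"
    breakpoints: tuple[float, ...] = ()
    n_levels: int = 1
    cumulative: str = "segment"  # or "literal"
    stratum_col: str | None = None

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        object.__setattr__(self, "cuts", cuts)
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(
            self, "breakpoints", tuple(float(b) for b in self.breakpoints)
        )
        if self.kind not in ("esteve", "touraine", "breakpoint"):
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(cuts) < 2 or cuts[0] != 0.0:
            raise ValueError("cuts must start at 0 and define >= 1 interval")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError("cuts must be strictly increasing")
        if self.kind == "touraine" and self.breakpoints:
            raise ValueError("touraine model takes no breakpoints")
        if self.kind == "breakpoint" and any(
            b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])
        ):
            raise ValueError("breakpoints must be strictly increasing")
        if self.cumulative not in ("segment", "literal"):
            raise ValueError("cumulative must be 'segment' or 'literal'")

    @property
    def n_intervals(self) -> int:
        return len(self.cuts) - 1

    @property
    def n_segments(self) -> int:
        return len(self.breakpoints) + 1 if self.kind == "breakpoint" else 1

    @property
    def alpha_shape(self) -> tuple[int, int]:
        if self.kind == "esteve":
            return (0, 0)
        return (self.n_levels, self.n_segments)

    @property
    def n_params(self) -> int:
        m, s = self.alpha_shape
        return len(self.covariates) + self.n_intervals + m * s


@dataclass(frozen=True)
class ParameterVector:
    """psi = (beta, tau, alpha_tilde); alpha = exp(alpha_tilde) > 0."""

    beta: np.ndarray
    tau: np.ndarray
    alpha_tilde: np.ndarray  # shape (M, B + 1); empty for esteve

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, float))
        object.__setattr__(self, "tau", np.asarray(self.tau, float))
        at = np.asarray(self.alpha_tilde, float)
        if at.ndim == 1 and at.size:
            at = at[:, None]
        object.__setattr__(self, "alpha_tilde", at.reshape(at.shape if at.ndim == 2 else (0, 0)))

    @property
    def alpha(self) -> np.ndarray:
        return np.exp(self.alpha_tilde)

    def pack(self) -> np.ndarray:
        return np.concatenate([self.beta, self.tau, self.alpha_tilde.ravel()])

    @classmethod
    def unpack(cls, theta: np.ndarray, spec: ExcessModelSpec) -> "ParameterVector":
        p, k = len(spec.covariates), spec.n_intervals
        m, s = spec.alpha_shape
        theta = np.asarray(theta, float)
        if theta.size != p + k + m * s:
            raise ValueError(
                f"parameter vector of length {theta.size}, spec needs {p + k + m * s}"
            )
        return cls(theta[:p], theta[p : p + k],
                   theta[p + k :].reshape(m, s) if m else np.empty((0, 0)))


# ---------------------------------------------------------------------------
# Excess-hazard evaluation
# ---------------------------------------------------------------------------


def _interval_index(t, cuts: Sequence[float]):
    """Index k(t) of the baseline interval with t_{k-1} < t <= t_k (t=0 -> 0)."""
    t = np.asarray(t, float)
    if np.any(t > cuts[-1] + 1e-12) or np.any(t < 0):
        raise ValueError(f"t outside [0, {cuts[-1]}] (last baseline cut)")
    k = np.searchsorted(cuts, t, side="left") - 1
    return np.clip(k, 0, len(cuts) - 2)


def _linpred(z, covariates: Sequence[str], beta: np.ndarray) -> float:
    if isinstance(z, Mapping):
        zv = np.array([float(z[c]) for c in covariates])
    else:
        zv = np.atleast_1d(np.asarray(z, float))
    return float(zv @ beta) if len(beta) else 0.0


def excess_hazard(t, z, spec: ExcessModelSpec, psi: ParameterVector) -> float:
    """lambda_E(t | z) = exp(tau_k(t)) * exp(beta' z), in 1/year."""
    k = int(_interval_index(t, spec.cuts))
    return float(np.exp(psi.tau[k] + _linpred(z, spec.covariates, psi.beta)))


def cumulative_excess_hazard(t, z, spec: ExcessModelSpec, psi: ParameterVector) -> float:
    """Lambda_E(t | z) = sum_k exp(tau_k) t_k(t) * exp(beta' z)."""
    t = float(t)
    _interval_index(t, spec.cuts)  # range check
    cuts = np.asarray(spec.cuts)
    t_k = np.clip(t, cuts[:-1], cuts[1:]) - cuts[:-1]
    return float((t_k @ np.exp(psi.tau)) * np.exp(_linpred(z, spec.covariates, psi.beta)))


# ---------------------------------------------------------------------------
# Precomputed design: everything in the likelihood that does not depend on psi
# ---------------------------------------------------------------------------


class CohortDesign:
    """Per-subject quantities entering the likelihood, computed once.

    The population cumulative-hazard path of each subject along the Lexis
    diagonal is piecewise linear and parameter-free, so it is precomputed;
    any set of attained-age breakpoints then splits it by interpolation
    without re-reading the life table (`with_breakpoints`).
    """

    def __init__(self, data: pd.DataFrame, table: LifeTable, spec: ExcessModelSpec):
        self.spec = spec
        self.n = len(data)
        if self.n == 0:
            raise ValueError("empty cohort")
        self.t = data["t"].to_numpy(float)
        self.delta = data["delta"].to_numpy(int)
        self.age = data["age"].to_numpy(float)
        self.year = data["diag_year"].to_numpy(float)
        if not np.all(self.t > 0):
            raise ValueError("all follow-up times must be > 0")
        if self.delta.sum() < 1:
            raise ValueError("cohort has no deaths; model not identifiable")

        p = len(spec.covariates)
        self.Z = (
            data[list(spec.covariates)].to_numpy(float)
            if p else np.empty((self.n, 0))
        )
        m_levels = spec.alpha_shape[0]
        if m_levels and "x" in data.columns:
            self.x = data["x"].to_numpy(int)
            if self.x.min() < 0 or self.x.max() >= spec.n_levels:
                raise ValueError("additional-variable level outside 0..M-1")
        else:
            self.x = np.zeros(self.n, dtype=int)

        cuts = np.asarray(spec.cuts)
        if cuts[-1] < self.t.max() - 1e-12:
            raise ValueError(
                f"last baseline cut {cuts[-1]} < max follow-up {self.t.max()}"
            )
        self.t_ki = np.clip(self.t[:, None], cuts[:-1], cuts[1:]) - cuts[:-1]
        self.k_idx = _interval_index(self.t, spec.cuts)

        strat = (
            data[spec.stratum_col].astype(str).to_numpy()
            if spec.stratum_col and spec.stratum_col in data.columns
            else np.full(self.n, None)
        )
        self._paths = []
        self.lamP_end = np.empty(self.n)
        for i in range(self.n):
            knots, cum = cumhaz_path(
                table, self.age[i], self.year[i], self.t[i], strat[i]
            )
            self._paths.append((knots, cum))
            self.lamP_end[i] = expected_hazard(
                table, self.age[i] + self.t[i], self.year[i] + self.t[i], strat[i]
            )
        self.LamP_total = np.array([c[-1] for _, c in self._paths])
        # default segmentation for the spec's own breakpoints
        self.set_breakpoints(spec.breakpoints if spec.kind == "breakpoint" else ())

    def set_breakpoints(self, breakpoints: Sequence[float]) -> None:
        """(Re)compute segment splits for a set of attained-age breakpoints."""
        bps = tuple(float(b) for b in breakpoints)
        self.breakpoints = bps
        n_seg = len(bps) + 1
        self.b_end = np.searchsorted(bps, self.age + self.t, side="right")
        self.LamP_seg = np.empty((self.n, n_seg))
        self.pt_seg = np.empty((self.n, n_seg))
        for i, (knots, cum) in enumerate(self._paths):
            edges = np.clip(
                [0.0] + [e - self.age[i] for e in bps] + [self.t[i]],
                0.0, self.t[i],
            )
            cum_at = np.interp(edges, knots, cum)
            self.LamP_seg[i] = np.diff(cum_at)
            self.pt_seg[i] = np.diff(edges)

    def check_identifiable(self) -> None:
        empty_k = np.where(self.t_ki.sum(axis=0) <= 0)[0]
        if empty_k.size:
            raise EmptySegmentError(
                f"baseline interval(s) without person-time: {empty_k.tolist()}"
            )
        m, s = self.spec.alpha_shape
        if m:
            bad = []
            for lev in range(m):
                pt = self.pt_seg[self.x == lev].sum(axis=0)
                bad += [(lev, b) for b in np.where(pt <= 0)[0]]
            if bad:
                raise EmptySegmentError(
                    f"(level, segment) cell(s) without person-time: {bad}"
                )

    # -- likelihood pieces ---------------------------------------------------

    def _parts(self, psi: ParameterVector):
        spec = self.spec
        eta = self.Z @ psi.beta if psi.beta.size else np.zeros(self.n)
        e_eta = np.exp(eta)
        e_tau = np.exp(psi.tau)
        lamE = e_tau[self.k_idx] * e_eta
        LamE = (self.t_ki @ e_tau) * e_eta
        if spec.kind == "esteve":
            alpha = np.ones((1, len(self.breakpoints) + 1))
        else:
            alpha = psi.alpha
        a_end = alpha[self.x, self.b_end]
        lamO = lamE + a_end * self.lamP_end
        if spec.cumulative == "segment":
            LamP_w = (alpha[self.x] * self.LamP_seg).sum(axis=1)
        else:
            LamP_w = a_end * self.LamP_total
        return eta, e_eta, lamE, LamE, alpha, a_end, lamO, LamP_w

    def loglik_terms(self, psi: ParameterVector) -> np.ndarray:
        # overflow at extreme parameters yields non-finite terms, which the
        # callers turn into an error (public API) or a rejected step (fit)
        with np.errstate(over="ignore", invalid="ignore"):
            _, _, _, LamE, _, _, lamO, LamP_w = self._parts(psi)
            log_lamO = np.where(self.delta == 1, np.log(lamO), 0.0)
            return -LamE - LamP_w + self.delta * log_lamO

    def loglik(self, psi: ParameterVector) -> float:
        return float(self.loglik_terms(psi).sum())

    def score(self, psi: ParameterVector) -> np.ndarray:
        spec = self.spec
        _, e_eta, lamE, LamE, alpha, a_end, lamO, _ = self._parts(psi)
        d_ratio = np.where(self.delta == 1, self.delta / lamO, 0.0)
        g_beta = self.Z.T @ (-LamE + d_ratio * lamE)
        e_tau = np.exp(psi.tau)
        death_k = np.zeros((self.n, spec.n_intervals))
        death_k[np.arange(self.n), self.k_idx] = d_ratio * lamE
        g_tau = (-(self.t_ki * e_eta[:, None]) * e_tau).sum(axis=0) + death_k.sum(axis=0)
        m, s = spec.alpha_shape
        if m == 0:
            return np.concatenate([g_beta, g_tau])
        g_alpha = np.zeros((m, s))
        death_a = d_ratio * a_end * self.lamP_end
        for lev in range(m):
            mask = self.x == lev
            if spec.cumulative == "segment":
                g_alpha[lev] = -alpha[lev] * self.LamP_seg[mask].sum(axis=0)
            else:
                surv = alpha[lev, self.b_end[mask]] * self.LamP_total[mask]
                np.add.at(g_alpha[lev], self.b_end[mask], -surv)
            np.add.at(g_alpha[lev], self.b_end[mask], death_a[mask])
        return np.concatenate([g_beta, g_tau, g_alpha.ravel()])


# ---------------------------------------------------------------------------
# Public likelihood / score / fit
# ---------------------------------------------------------------------------


def default_cuts(data: pd.DataFrame, k: int = 5) -> tuple[float, ...]:
    """Baseline cuts at quantiles of observed death times (equal-events).

    Returns ``(0, q_{1/k}, ..., q_{(k-1)/k}, max follow-up)`` over death
    times, deduplicated; stabilizes the piecewise-constant baseline by
    giving every interval a comparable number of events.
    """
    deaths = data.loc[data["delta"] == 1, "t"].to_numpy(float)
    if deaths.size == 0:
        raise ValueError("no deaths; cannot place baseline cuts")
    qs = np.quantile(deaths, np.linspace(0, 1, k + 1)[1:-1])
    top = float(data["t"].max())
    interior = sorted({float(q) for q in qs if 0.0 < q < top})
    return (0.0, *interior, top)


def _design(data, table, spec) -> CohortDesign:
    return CohortDesign(data, table, spec)


def log_likelihood(
    data: pd.DataFrame, table: LifeTable, spec: ExcessModelSpec, psi: ParameterVector
) -> float:
    """Joint log-likelihood of the cohort under ``spec`` at ``psi``."""
    terms = _design(data, table, spec).loglik_terms(psi)
    if not np.all(np.isfinite(terms)):
        i = int(np.where(~np.isfinite(terms))[0][0])
        raise ValueError(f"non-finite log-likelihood contribution for subject {i}")
    return float(terms.sum())


def score_vector(
    data: pd.DataFrame, table: LifeTable, spec: ExcessModelSpec, psi: ParameterVector
) -> np.ndarray:
    """Analytic gradient of the log-likelihood over (beta, tau, alpha_tilde)."""
    g = _design(data, table, spec).score(psi)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite score; check parameters and data")
    return g


@dataclass
class FitResult:
    """Maximum-likelihood fit: estimates, covariance, information criteria."""

    spec: ExcessModelSpec
    params: ParameterVector
    cov: np.ndarray
    loglik: float
    aic: float
    converged: bool
    message: str
    n_subjects: int
    n_deaths: int
    n_params: int
    n_restarts: int = 0

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))


def _numerical_hessian(fun_grad, theta: np.ndarray) -> np.ndarray:
    """Central-difference Jacobian of the analytic score (observed information)."""
    p = theta.size
    h = 1e-5 * (1.0 + np.abs(theta))
    H = np.empty((p, p))
    for j in range(p):
        e = np.zeros(p)
        e[j] = h[j]
        H[:, j] = (fun_grad(theta + e) - fun_grad(theta - e)) / (2 * h[j])
    return (H + H.T) / 2.0


def fit(
    data: pd.DataFrame,
    table: LifeTable,
    spec: ExcessModelSpec,
    init: ParameterVector | None = None,
    gtol: float = 1e-6,
    max_restarts: int = 3,
    rng: np.random.Generator | None = None,
) -> FitResult:
    """Fit an excess-hazard model by maximum likelihood.

    Quasi-Newton (BFGS) maximization with the analytic score; the
    covariance is the inverse of the numerically differentiated observed
    information at the optimum.  Non-convergence is flagged on the result,
    not raised; an unidentifiable design (a baseline interval or a
    (level, segment) cell without person-time) raises `EmptySegmentError`.
    """
    design = CohortDesign(data, table, spec)
    design.check_identifiable()
    if init is None:
        # crude per-interval death rates as tau starting values
        e_rate = np.empty(spec.n_intervals)
        for k in range(spec.n_intervals):
            pt = design.t_ki[:, k].sum()
            dk = design.delta[design.k_idx == k].sum()
            e_rate[k] = max(dk / pt if pt > 0 else 0.0, 1e-4)
        init = ParameterVector(
            np.zeros(len(spec.covariates)), np.log(e_rate),
            np.zeros(spec.alpha_shape),
        )
    theta0 = init.pack()

    def neg_ll(theta):
        terms = design.loglik_terms(ParameterVector.unpack(theta, spec))
        val = terms.sum()
        return np.inf if not np.isfinite(val) else -val

    def neg_grad(theta):
        g = design.score(ParameterVector.unpack(theta, spec))
        return np.where(np.isfinite(g), -g, 0.0)

    rng = rng or np.random.default_rng(0)
    best = None
    n_restarts = 0
    for attempt in range(max_restarts + 1):
        start = theta0 if attempt == 0 else theta0 + rng.normal(0, 0.1, theta0.size)
        res = optimize.minimize(
            neg_ll, start, jac=neg_grad, method="BFGS",
            options={"gtol": gtol, "maxiter": 500},
        )
        ok = np.isfinite(res.fun) and np.max(np.abs(res.jac)) < max(gtol * 10, 1e-4)
        if best is None or res.fun < best[0].fun:
            best = (res, ok)
        if ok:
            break
        n_restarts = attempt + 1 if attempt < max_restarts else n_restarts
    res, converged = best

    psi_hat = ParameterVector.unpack(res.x, spec)
    H = _numerical_hessian(lambda th: design.score(ParameterVector.unpack(th, spec)), res.x)
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-H)
        converged = False
    cov = (cov + cov.T) / 2.0
    # guard against a saddle: require positive variances
    if np.any(np.diag(cov) < 0):
        converged = False
    ll = -res.fun
    n_par = spec.n_params
    return FitResult(
        spec=spec, params=psi_hat, cov=cov, loglik=float(ll),
        aic=float(2 * n_par - 2 * ll), converged=bool(converged),
        message=str(res.message), n_subjects=design.n,
        n_deaths=int(design.delta.sum()), n_params=n_par,
        n_restarts=n_restarts,
    )


def wald_summary(result: FitResult) -> pd.DataFrame:
    """EHR and alpha estimates with 95% Wald intervals on the exp scale.

    One row per covariate (``kind='EHR'``, exp(beta)) and per (level,
    segment) multiplier (``kind='alpha'``, exp(alpha_tilde)); intervals are
    exponentiated Wald intervals on the log scale.
    """
    spec, psi = result.spec, result.params
    se = result.se
    p, k = len(spec.covariates), spec.n_intervals
    rows = []
    for j, name in enumerate(spec.covariates):
        b, s = psi.beta[j], se[j]
        rows.append({
            "term": name, "kind": "EHR", "log_estimate": b, "se": s,
            "estimate": np.exp(b),
            "lo": np.exp(b - Z975 * s), "hi": np.exp(b + Z975 * s),
        })
    m, n_seg = spec.alpha_shape
    for lev in range(m):
        for b_idx in range(n_seg):
            j = p + k + lev * n_seg + b_idx
            a, s = psi.alpha_tilde[lev, b_idx], se[j]
            rows.append({
                "term": f"alpha[x={lev},seg={b_idx}]", "kind": "alpha",
                "log_estimate": a, "se": s, "estimate": np.exp(a),
                "lo": np.exp(a - Z975 * s), "hi": np.exp(a + Z975 * s),
            })
    return pd.DataFrame(rows)
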