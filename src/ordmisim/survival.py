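"""Survival-analysis core: Nelson-Aalen hazards, Cox regression, Rubin pooling.

The Cox model is the analysis model of the whole pipeline: log hazard ratios
of the ordinal ECOG performance status (categories 1-4 against reference 0)
adjusted for the registry covariates.  The partial likelihood is maximised by
Newton-Raphson with the Efron correction for tied event times -- ties are
ubiquitous because survival is recorded in whole months.

Per-imputation Cox estimates are combined with Rubin's rules: pooled point
``Qbar``, within-variance ``W``, between-variance ``B``, total variance
``T = W + (1 + 1/m) B``, and Barnard-Rubin small-sample degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import ECOG_TERMS, analysis_design


class SurvivalError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------

def nelson_aalen(times, events) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated at each subject's own time.

    H(t) = sum_{event times t_i <= t} d_i / n_i with d_i events and n_i
    subjects at risk at t_i; tied times are grouped.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=float)
    if t.ndim != 1 or t.shape != e.shape:
        raise SurvivalError("times and events must be 1-d and equal length")
    if (t <= 0).any():
        raise SurvivalError("all survival times must be positive")
    n = len(t)
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    uniq, start = np.unique(ts, return_index=True)
    d = np.add.reduceat(es, start)                      # deaths per unique time
    at_risk = n - start                                 # risk set size at t_j
    H_step = np.cumsum(d / at_risk)                     # H at each unique time
    return H_step[np.searchsorted(uniq, t)]


# ---------------------------------------------------------------------------
# Cox proportional hazards (Efron ties)
# ---------------------------------------------------------------------------

@dataclass
class CoxEstimate:
    """Fitted Cox model: log-HR coefficients, covariance, Wald 95% CIs."""

    params: pd.Series
    cov: pd.DataFrame
    ci_lower: pd.Series
    ci_upper: pd.Series
    n: int = 0
    n_events: int = 0
    converged: bool = False
    failed: bool = False
    failure_reason: str | None = None
    dropped_terms: list = field(default_factory=list)

    @property
    def df_complete(self) -> int:
        """Complete-data degrees of freedom: events minus parameters."""
        return max(self.n_events - len(self.params), 1)

    @classmethod
    def failure(cls, reason: str, names) -> "CoxEstimate":
        nan = pd.Series(np.nan, index=names)
        return cls(params=nan, cov=pd.DataFrame(np.nan, index=names, columns=names),
                   ci_lower=nan.copy(), ci_upper=nan.copy(),
                   failed=True, failure_reason=reason)


def _newton_cox(X, time, event, init=None, tol=1e-12, max_iter=60):
    from ._cox import efron_quantities

    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    ts = time[order]
    es = np.ascontiguousarray(event[order], dtype=np.float64)
    _, start = np.unique(ts, return_index=True)
    start = start.astype(np.int64)
    d_group = np.add.reduceat(es, start)
    beta = np.zeros(p) if init is None else np.array(init, dtype=float)
    eta = np.clip(Xs @ beta, -500, 500)
    ll, grad, hess = efron_quantities(Xs, eta, start, d_group, es)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return beta, None, False
        # step-halving line search on the partial log-likelihood
        for half in range(30):
            cand = beta + step
            eta = np.clip(Xs @ cand, -500, 500)
            ll_new, grad_new, hess_new = efron_quantities(Xs, eta, start,
                                                          d_group, es)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step *= 0.5
        else:
            return beta, hess, False
        delta = ll_new - ll
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # quadratic convergence makes |delta| the sharp criterion; the
        # gradient check is a loose scale-aware safeguard (float noise in the
        # risk-set sums grows with |ll|)
        if abs(delta) < tol and np.abs(grad).max() < 1e-4 * (1.0 + abs(ll)):
            return beta, hess, True
    return beta, hess, False


def fit_cox(cohort: pd.DataFrame, terms: str = "adjusted",
            warm_start: pd.Series | None = None) -> CoxEstimate:
    """Fit the analysis Cox model on a cohort complete in every analysis term.

    ``terms`` selects the adjusted model (ECOG contrasts + all baseline
    covariates, the default) or ``"ecog_only"``.  An empty ECOG category or a
    non-converged fit yields a structured failure record instead of an
    exception, so the simulation bookkeeping can carry it forward.
    Adjuster dummies that are constant in the sample (an unpopulated category)
    are merged into the reference level and reported in ``dropped_terms``.
    """
    if terms == "adjusted":
        X, names = analysis_design(cohort, include_ecog=True)
    elif terms == "ecog_only":
        from ._design import ecog_dummies
        X, names = ecog_dummies(cohort["ecog"].to_numpy()), list(ECOG_TERMS)
    else:
        raise SurvivalError(f"unknown term specification {terms!r}")

    ecog = cohort["ecog"].to_numpy()
    present = np.unique(ecog)
    missing_cats = [k for k in range(5) if k not in present]
    if missing_cats:
        return CoxEstimate.failure(
            f"ECOG categories {missing_cats} absent from the sample", names)

    time = cohort["time"].to_numpy(dtype=float)
    event = cohort["event"].to_numpy(dtype=float)
    if (time <= 0).any():
        raise SurvivalError("all survival times must be positive")

    # drop constant (all-zero or all-one) adjuster columns: unpopulated levels
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = [nm for nm, k in zip(names, keep) if not k]
    if any(nm in ECOG_TERMS for nm in dropped):  # cannot drop the estimand
        return CoxEstimate.failure(
            f"degenerate ECOG contrast column(s): {dropped}", names)
    Xk = X[:, keep]
    kept = [nm for nm, k in zip(names, keep) if k]

    init = None
    if warm_start is not None:
        init = warm_start.reindex(kept).fillna(0.0).to_numpy()

    beta, hess, ok = _newton_cox(Xk, time, event, init=init)
    if hess is None or not ok:
        return CoxEstimate.failure("Cox partial likelihood did not converge", names)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return CoxEstimate.failure("singular information matrix", names)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = stats.norm.ppf(0.975)
    params = pd.Series(beta, index=kept).reindex(names)
    sef = pd.Series(se, index=kept).reindex(names)
    covf = pd.DataFrame(cov, index=kept, columns=kept).reindex(
        index=names, columns=names)
    return CoxEstimate(
        params=params, cov=covf,
        ci_lower=params - z * sef, ci_upper=params + z * sef,
        n=len(cohort), n_events=int(event.sum()), converged=True,
        dropped_terms=dropped)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

@dataclass
class PooledEstimate:
    """Rubin-pooled coefficients with total variance and 95% CI."""

    names: list
    q: np.ndarray            # pooled point estimates Qbar
    W: np.ndarray            # within-imputation variance
    B: np.ndarray            # between-imputation variance
    T: np.ndarray            # total variance W + (1 + 1/m) B
    df: np.ndarray           # CI degrees of freedom (Barnard-Rubin when available)
    df_old: np.ndarray       # classical (m-1)(1 + W/((1+1/m)B))^2
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    m: int


def rubin_pool(estimates, covariances, names=None,
               df_complete: float | None = None) -> PooledEstimate:
    """Pool m point estimates and covariance matrices with Rubin's rules.

    ``estimates`` is (m, k); ``covariances`` is (m, k, k) or (m, k) variance
    vectors.  ``df_complete`` enables the Barnard-Rubin small-sample df; when
    omitted the classical large-sample formula is used for the CI.  With
    m = 1 the single fit passes through (B undefined, normal-quantile CI).
    """
    Q = np.atleast_2d(np.asarray(estimates, dtype=float))
    m, k = Q.shape
    U = np.asarray(covariances, dtype=float)
    if U.ndim == 3:
        if U.shape != (m, k, k):
            raise SurvivalError("covariance stack shape mismatch")
        Uv = np.einsum("mkk->mk", U)
    elif U.shape == (m, k):
        Uv = U
    else:
        raise SurvivalError("covariance stack shape mismatch")
    if names is None:
        names = [f"b{j}" for j in range(k)]

    qbar = Q.mean(axis=0)
    W = Uv.mean(axis=0)
    if m == 1:
        B = np.full(k, np.nan)
        T = W.copy()
        df = np.full(k, np.inf)
        df_old = np.full(k, np.inf)
        half = stats.norm.ppf(0.975) * np.sqrt(T)
        return PooledEstimate(list(names), qbar, W, B, T, df, df_old,
                              qbar - half, qbar + half, m)

    B = Q.var(axis=0, ddof=1)
    T = W + (1 + 1 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (1 + 1 / m) * B
        df_old = np.where(B > 0, (m - 1) * (1 + W / rel) ** 2, np.inf)
        if df_complete is not None:
            lam = np.where(T > 0, rel / T, 0.0)
            nu_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
            df = np.where(np.isinf(df_old), nu_obs,
                          1.0 / (1.0 / df_old + 1.0 / nu_obs))
        else:
            df = df_old
    tq = np.where(np.isinf(df), stats.norm.ppf(0.975),
                  stats.t.ppf(0.975, np.clip(df, 1e-3, None)))
    half = tq * np.sqrt(T)
    return PooledEstimate(list(names), qbar, W, B, T, df, df_old,
                          qbar - half, qbar + half, m)
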