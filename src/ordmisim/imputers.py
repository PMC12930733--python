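"""Multiple-imputation engines for a single incomplete ordinal variable.

Five engines share one predictor-construction contract (the imputation model
of the replication design: all analysis covariates plus the Nelson-Aalen
cumulative-hazard estimate and the event indicator in place of the survival
time) and one output contract: m completed cohorts in which every imputed
ECOG value lies in {0,...,4} and observed cells are untouched.

With exactly one incomplete variable, chained-equations imputation collapses
to repeated draws from a single univariate imputation model, so the engines
implement the corresponding univariate defaults directly: m = 5 imputations,
PMM with 5 donors and type-1 matching, 10 trees for the random forest, and a
latent-normal joint model with 500 burn-in and 500 between-imputation Gibbs
updates.  POLR and POLYREG propagate parameter uncertainty by one
nonparametric bootstrap refit per imputation; PMM draws its linear-stage
parameters from their approximate normal posterior.  A small ridge penalty
(1e-4) keeps the ordinal and multinomial fits finite under the separation
that rare top categories readily produce in small samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from ._design import (MISSING, PREDICTOR_TERMS, _adjuster_matrix,
                      ADJUSTER_TERMS, validate_complete)
from .survival import nelson_aalen

logger = logging.getLogger(__name__)

DEFAULT_M = 5


class ImputationError(RuntimeError):
    pass


@dataclass
class ImputationResult:
    """m completed cohorts produced by one engine."""

    method: str
    m: int
    datasets: list
    imputed_mask: np.ndarray
    diagnostics: list = field(default_factory=list)
    seed: object = None


# ---------------------------------------------------------------------------
# predictor construction
# ---------------------------------------------------------------------------

def build_predictors(cohort: pd.DataFrame) -> pd.DataFrame:
    """Imputation-model design matrix (everything except ECOG itself).

    Column order is fixed and documented in ``PREDICTOR_TERMS``; categorical
    variables are expanded against the reference levels of the code book
    ("no therapy reported" and peers).  Any missing non-ECOG cell violates
    the univariate-missingness design and raises.
    """
    validate_complete(cohort, allow_missing_ecog=True)
    adj = pd.DataFrame(_adjuster_matrix(cohort), columns=ADJUSTER_TERMS,
                       index=cohort.index)
    adj["nelson_aalen"] = nelson_aalen(cohort["time"].to_numpy(),
                                       cohort["event"].to_numpy())
    adj["event"] = cohort["event"].to_numpy(dtype=float)
    return adj[PREDICTOR_TERMS]


def _prepare(cohort, predictors):
    if predictors is None:
        predictors = build_predictors(cohort)
    y = cohort["ecog"].to_numpy()
    miss = y == MISSING
    X = np.ascontiguousarray(predictors.to_numpy(dtype=float))
    return y, miss, X


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _assemble(cohort, miss, method, imputed, m, seed) -> ImputationResult:
    y_obs = cohort["ecog"].to_numpy()[~miss]
    mean_obs = float(y_obs.mean()) if len(y_obs) else np.nan
    datasets, diags = [], []
    for values in imputed:
        ds = cohort.copy()
        if miss.any():
            col = ds["ecog"].to_numpy().copy()
            col[miss] = values
            ds["ecog"] = col
        datasets.append(ds)
        diags.append({
            "mean_imp": float(np.mean(values)) if len(values) else np.nan,
            "mean_obs": mean_obs,
        })
    return ImputationResult(method=method, m=m, datasets=datasets,
                            imputed_mask=miss.copy(), diagnostics=diags,
                            seed=seed)


def _identity_result(cohort, miss, method, m, seed) -> ImputationResult:
    return _assemble(cohort, miss, method,
                     [np.empty(0, dtype=np.int64)] * m, m, seed)


def _scale_columns(*arrays):
    """Standardise design columns (fit-time conditioning for the likelihood
    optimisers); the first array defines the location/scale."""
    ref = arrays[0]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0)
    sd[sd == 0] = 1.0
    return tuple((a - mu) / sd for a in arrays)


def _sample_categories(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Row-wise categorical draw from a (n, K) probability matrix."""
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(len(probs))
    return (u[:, None] > cum).sum(axis=1).astype(np.int64)


# ---------------------------------------------------------------------------
# PMM
# ---------------------------------------------------------------------------

def impute_pmm(cohort, predictors=None, m=DEFAULT_M, donors=5, seed=None):
    """Predictive mean matching, type-1: Bayesian linear regression of the
    (numerically coded) ECOG on the predictors; missing rows get predictions
    under a posterior parameter draw, observed rows under the point estimate,
    and each missing row receives the observed value of one donor sampled
    uniformly from its ``donors`` nearest predictions."""
    y, miss, X = _prepare(cohort, predictors)
    rng = _rng(seed)
    if not miss.any():
        return _identity_result(cohort, miss, "pmm", m, seed)

    Xo = np.column_stack([np.ones((~miss).sum()), X[~miss]])
    Xm = np.column_stack([np.ones(miss.sum()), X[miss]])
    yo = y[~miss].astype(float)
    n_obs, p = Xo.shape
    if n_obs < p + 2:
        raise ImputationError(
            f"pmm: {n_obs} observed rows cannot support {p} regression "
            "parameters (posterior undefined)")
    if n_obs < donors:
        logger.warning("pmm: shrinking donor pool from %d to %d", donors, n_obs)
        donors = n_obs

    A = Xo.T @ Xo + 1e-8 * np.eye(p)
    Lc = np.linalg.cholesky(A)
    beta_hat = cho_solve((Lc, True), Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n_obs - p, 1)
    sse = float(resid @ resid)
    yhat_obs = Xo @ beta_hat
    # type-1 matching is one-dimensional: sort the observed predictions once
    # and search each missing prediction's donor window
    order = np.argsort(yhat_obs, kind="stable")
    sorted_yhat = yhat_obs[order]
    y_sorted = yo[order]
    n_mis = len(Xm)
    offsets = np.arange(-donors, donors)

    imputed = []
    for _ in range(m):
        sigma2 = sse / rng.chisquare(df)
        g = rng.standard_normal(p)
        beta_star = beta_hat + solve_triangular(Lc.T, g) * np.sqrt(sigma2)
        yhat_mis = Xm @ beta_star
        pos = np.searchsorted(sorted_yhat, yhat_mis)
        cand = np.clip(pos[:, None] + offsets[None, :], 0, n_obs - 1)
        d = np.abs(sorted_yhat[cand] - yhat_mis[:, None])
        sel = np.argpartition(d, donors - 1, axis=1)[:, :donors]
        pool = cand[np.arange(n_mis)[:, None], sel]
        pick = pool[np.arange(n_mis), rng.integers(0, donors, n_mis)]
        imputed.append(y_sorted[pick].astype(np.int64))
    return _assemble(cohort, miss, "pmm", imputed, m, seed)


# ---------------------------------------------------------------------------
# POLR (cumulative-logit / proportional-odds)
# ---------------------------------------------------------------------------

def _polr_nll_grad(params, X, k, K, ridge):
    p = X.shape[1]
    beta = params[:p]
    t0 = params[p]
    if K > 2:
        zeta = t0 + np.concatenate([[0.0], np.cumsum(np.exp(params[p + 1:]))])
    else:
        zeta = np.array([t0])
    eta = X @ beta
    up = np.where(k <= K - 2, zeta[np.minimum(k, K - 2)] - eta, np.inf)
    lo = np.where(k >= 1, zeta[np.maximum(k - 1, 0)] - eta, -np.inf)
    u = np.where(np.isinf(up), 1.0, expit(up))
    l = np.where(np.isinf(lo), 0.0, expit(lo))
    P = np.clip(u - l, 1e-12, None)
    nll = -np.log(P).sum() + 0.5 * ridge * beta @ beta

    fu = np.where(np.isinf(up), 0.0, u * (1.0 - u))
    fl = np.where(np.isinf(lo), 0.0, l * (1.0 - l))
    invP = 1.0 / P
    g_beta = X.T @ ((fu - fl) * invP) + ridge * beta
    g_cut = (np.bincount(k, weights=-fu * invP, minlength=K)[: K - 1]
             + np.bincount(np.maximum(k - 1, 0),
                           weights=np.where(k >= 1, fl * invP, 0.0),
                           minlength=K)[: K - 1])
    g_t0 = g_cut.sum()
    if K > 2:
        tail = np.cumsum(g_cut[::-1])[::-1]
        g_d = np.exp(params[p + 1:]) * tail[1:]
        grad = np.concatenate([g_beta, [g_t0], g_d])
    else:
        grad = np.concatenate([g_beta, [g_t0]])
    return nll, grad


def _polr_start(X, k, K):
    p = X.shape[1]
    freq = np.bincount(k, minlength=K) + 0.5
    cum = np.cumsum(freq)[:-1] / freq.sum()
    zeta = np.log(cum / (1.0 - cum))
    start = np.zeros(p + K - 1)
    start[p] = zeta[0]
    if K > 2:
        start[p + 1:] = np.log(np.clip(np.diff(zeta), 1e-3, None))
    return start


def _fit_polr(X, k, K, ridge=1e-4, start=None):
    x0 = _polr_start(X, k, K) if start is None else start
    res = minimize(_polr_nll_grad, x0, args=(X, k, K, ridge), jac=True,
                   method="L-BFGS-B", options={"maxiter": 400, "ftol": 1e-10})
    if not res.success and np.abs(res.jac).max() > 1e-2 * max(1, len(k)) ** 0.5:
        res = minimize(_polr_nll_grad, _polr_start(X, k, K),
                       args=(X, k, K, ridge), jac=True, method="L-BFGS-B",
                       options={"maxiter": 800, "ftol": 1e-12})
        if not res.success and np.abs(res.jac).max() > 0.1 * max(1, len(k)) ** 0.5:
            raise ImputationError("polr: cumulative-logit fit did not converge")
    return res.x


def _polr_probs(params, X, K):
    p = X.shape[1]
    beta = params[:p]
    if K > 2:
        zeta = params[p] + np.concatenate([[0.0], np.cumsum(np.exp(params[p + 1:]))])
    else:
        zeta = params[p: p + 1]
    eta = X @ beta
    F = expit(zeta[None, :] - eta[:, None])
    F = np.column_stack([np.zeros(len(X)), F, np.ones(len(X))])
    return np.diff(F, axis=1)


def impute_polr(cohort, predictors=None, m=DEFAULT_M, seed=None, ridge=1e-4):
    """Proportional-odds (cumulative-logit) imputation: maximum-likelihood
    fit on the observed rows with ordered thresholds and a ridge penalty;
    one nonparametric bootstrap refit per imputation carries the parameter
    uncertainty; missing rows are drawn from the implied category
    probabilities."""
    y, miss, X = _prepare(cohort, predictors)
    rng = _rng(seed)
    if not miss.any():
        return _identity_result(cohort, miss, "polr", m, seed)

    yo = y[~miss]
    Xo, Xm = _scale_columns(X[~miss], X[miss])
    levels = np.unique(yo)
    if len(levels) < 2:
        # degenerate: a single observed category, impute it everywhere
        imputed = [np.full(miss.sum(), levels[0], dtype=np.int64)] * m
        return _assemble(cohort, miss, "polr", imputed, m, seed)
    if len(levels) < 5:
        logger.warning("polr: observed categories %s only; empty categories "
                       "merged out of the threshold set", levels.tolist())
    base = _fit_polr(Xo, np.searchsorted(levels, yo), len(levels), ridge)

    imputed = []
    for _ in range(m):
        idx = rng.integers(0, len(yo), len(yo))
        yb = yo[idx]
        blev = np.unique(yb)
        kb = np.searchsorted(blev, yb)
        start = base if len(blev) == len(levels) else None
        params = _fit_polr(Xo[idx], kb, len(blev), ridge, start=start)
        probs = _polr_probs(params, Xm, len(blev))
        imputed.append(blev[_sample_categories(probs, rng)])
    return _assemble(cohort, miss, "polr", imputed, m, seed)


# ---------------------------------------------------------------------------
# POLYREG (multinomial logit)
# ---------------------------------------------------------------------------

def impute_polyreg(cohort, predictors=None, m=DEFAULT_M, seed=None, ridge=1e-4):
    """Multinomial-logit (softmax) imputation over the five categories with a
    small ridge penalty; bootstrap parameter draw per imputation; categories
    sampled from the predicted probabilities.  A category absent from the
    observed rows receives zero predicted probability (logged)."""
    y, miss, X = _prepare(cohort, predictors)
    rng = _rng(seed)
    if not miss.any():
        return _identity_result(cohort, miss, "polyreg", m, seed)

    yo = y[~miss]
    Xo, Xm = _scale_columns(X[~miss], X[miss])
    absent = sorted(set(range(5)) - set(np.unique(yo)))
    if absent:
        logger.warning("polyreg: categories %s unobserved; their predicted "
                       "probability is zero", absent)

    imputed = []
    for _ in range(m):
        idx = rng.integers(0, len(yo), len(yo))
        yb = yo[idx]
        if len(np.unique(yb)) < 2:
            imputed.append(np.full(miss.sum(), yb[0], dtype=np.int64))
            continue
        est = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=500,
                                 tol=1e-4)
        with warnings.catch_warnings():
            # near-separation is expected for rare top categories; the weak
            # ridge keeps coefficients finite and the probabilities usable
            warnings.simplefilter("ignore", ConvergenceWarning)
            est.fit(Xo[idx], yb)
        probs = np.zeros((len(Xm), 5))
        probs[:, est.classes_.astype(int)] = est.predict_proba(Xm)
        probs /= probs.sum(axis=1, keepdims=True)
        imputed.append(_sample_categories(probs, rng))
    return _assemble(cohort, miss, "polyreg", imputed, m, seed)


# ---------------------------------------------------------------------------
# RF (tree-ensemble donor draw)
# ---------------------------------------------------------------------------

def impute_rf(cohort, predictors=None, m=DEFAULT_M, ntree=10, seed=None):
    """Random-forest imputation in the mice style: ``ntree`` classification
    trees grown on bootstrap samples of the observed rows; each missing row
    is routed down one uniformly chosen tree and receives the ECOG value of
    one training observation drawn uniformly from the reached leaf."""
    y, miss, X = _prepare(cohort, predictors)
    rng = _rng(seed)
    if not miss.any():
        return _identity_result(cohort, miss, "rf", m, seed)

    yo = y[~miss]
    Xo, Xm = X[~miss], X[miss]
    n_obs, n_mis = len(yo), int(miss.sum())
    if len(np.unique(yo)) == 1:
        imputed = [np.full(n_mis, yo[0], dtype=np.int64)] * m
        return _assemble(cohort, miss, "rf", imputed, m, seed)

    imputed = []
    for _ in range(m):
        values = np.empty(n_mis, dtype=np.int64)
        assignment = rng.integers(0, ntree, n_mis)
        for t in range(ntree):
            rows = np.flatnonzero(assignment == t)
            boot = rng.integers(0, n_obs, n_obs)
            tree = DecisionTreeClassifier(
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(Xo[boot], yo[boot])
            if len(rows) == 0:
                continue
            # donor pool = every observed row routed to the same leaf, not
            # only the in-bag rows the leaf was grown on; out-of-bag rows
            # dilute rare-category leaves with majority-class donors, the
            # documented class-imbalance behaviour of this engine
            train_leaves = tree.apply(Xo)
            target_leaves = tree.apply(Xm[rows])
            order = np.argsort(train_leaves, kind="stable")
            sorted_leaves = train_leaves[order]
            left = np.searchsorted(sorted_leaves, target_leaves, side="left")
            right = np.searchsorted(sorted_leaves, target_leaves, side="right")
            empty = right == left
            if empty.any():  # in-bag rows populate every leaf; guard anyway
                logger.warning("rf: empty leaf fallback to root distribution")
                left[empty], right[empty] = 0, n_obs
            pick = left + (rng.random(len(rows)) * (right - left)).astype(np.int64)
            values[rows] = yo[order[pick]]
        imputed.append(values)
    return _assemble(cohort, miss, "rf", imputed, m, seed)


# ---------------------------------------------------------------------------
# JM (latent-normal joint model, Gibbs)
# ---------------------------------------------------------------------------

def impute_jm(cohort, predictors=None, m=DEFAULT_M, burnin=500, between=500,
              seed=None, ridge=1.0, keep_trace=False, estimate_cov=False):
    """Latent-normal joint-model imputation of the 5-category ECOG.

    Four latent normal scores (category = argmax against 0) are regressed on
    the predictor matrix; a Gibbs sampler cycles truncated-normal latent
    draws for the observed rows and a conjugate matrix-normal draw of the
    coefficients.  With a single categorical variable the latent residual
    covariance is not identified, so it stays fixed at the standard
    identification constraint (unit diagonal, 1/2 off-diagonal);
    ``estimate_cov=True`` adds the inverse-Wishart covariance update of the
    general multivariate model (trace-normalised, and slow-mixing here).
    The first completed dataset is taken after ``burnin`` updates,
    subsequent ones every ``between`` updates; missing rows get an
    unconstrained latent draw mapped through the argmax rule."""
    from ._jm import run_chain

    y, miss, X = _prepare(cohort, predictors)
    rng = _rng(seed)
    if not miss.any():
        return _identity_result(cohort, miss, "jm", m, seed)

    yo = y[~miss].astype(np.int64)
    Xs_o, Xs_m = _scale_columns(X[~miss], X[miss])
    Xo = np.column_stack([np.ones((~miss).sum()), Xs_o])
    Xm = np.column_stack([np.ones(miss.sum()), Xs_m])

    chain_seed = int(rng.integers(0, 2**31 - 1))
    try:
        draws, trace = run_chain(Xo, Xm, yo, m, burnin, between,
                                 float(ridge), chain_seed, estimate_cov)
    except Exception as exc:  # pragma: no cover - degenerate covariance draws
        raise ImputationError(f"jm: Gibbs chain failed ({exc})") from exc
    imputed = [draws[l] for l in range(m)]

    result = _assemble(cohort, miss, "jm", imputed, m, seed)
    if keep_trace:
        for d in result.diagnostics:
            d["trace"] = trace
    return result


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

@dataclass
class CompleteCaseResult:
    """Complete-case cohort plus a failure flag for the replicate ledger."""

    cohort: pd.DataFrame
    failed: bool = False
    reason: str | None = None


def complete_cases(cohort: pd.DataFrame) -> CompleteCaseResult:
    """Drop rows with a missing ECOG (the only analysis-model variable that
    can be missing in this design).  The result is flagged as failed when no
    rows remain or when an ECOG category present before deletion has been
    emptied, mirroring the single unproducible complete-case replicate the
    evaluation bookkeeping must tolerate."""
    y = cohort["ecog"].to_numpy()
    kept = cohort.loc[y != MISSING].copy()
    if len(kept) == 0:
        return CompleteCaseResult(kept, failed=True, reason="no complete cases")
    present = set(int(v) for v in np.unique(y) if v != MISSING)
    missing_cats = set(range(5)) - present
    if missing_cats:
        return CompleteCaseResult(
            kept, failed=True,
            reason=f"ECOG categories {sorted(missing_cats)} have no complete cases")
    return CompleteCaseResult(kept)


#: engine registry; ``cca`` is handled specially by the pipeline (no pooling)
ENGINES = {
    "pmm": impute_pmm,
    "polr": impute_polr,
    "polyreg": impute_polyreg,
    "rf": impute_rf,
    "jm": impute_jm,
}

METHODS = list(ENGINES) + ["cca"]
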