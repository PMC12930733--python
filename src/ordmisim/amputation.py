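"""Weighted-sum-score amputation of the ECOG column.

Controlled deletion of a single complete variable: each row receives a
weighted sum score over (column-standardised) covariates, scores are pushed
through a right-tailed logistic whose intercept is solved so that the mean
missingness probability equals the target proportion, and independent
Bernoulli draws delete the ECOG value.  The three mechanisms differ only in
the weights:

* MCAR -- all weights zero, so every row has the same probability;
* MAR  -- weights on observed covariates (by default the signed coefficients
  of a logistic missingness model, which may include the Nelson-Aalen
  cumulative-hazard estimate and the event indicator, making the mechanism
  outcome-dependent);
* MNAR -- weight 1 on ECOG itself, all others zero.

Only the ECOG column is ever touched; the realized missing fraction is
stochastic (continuous-probability deletion, not exact-count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import brentq
from scipy.special import expit

from ._design import MISSING
from .survival import nelson_aalen

logger = logging.getLogger(__name__)

MECHANISMS = ("MCAR", "MAR", "MNAR")

#: candidate predictors of the missingness model (numeric codes)
_CANDIDATE_COLUMNS = ["age", "sex", "diagnosis_year", "grading", "stage",
                      "topography", "morphology", "radiotherapy", "intention",
                      "residual", "systemic", "nelson_aalen", "event"]


class AmputationError(ValueError):
    pass


def mcar_weights() -> dict:
    """MCAR preset: all weights zero."""
    return {}


def mnar_weights() -> dict:
    """MNAR preset: weight 1 on the ECOG value itself."""
    return {"ecog": 1.0}


def default_mar_weights() -> dict:
    """Shipped MAR weight vector with a plausible sign structure
    (death and high cumulative hazard, higher stage and age increase the
    odds of a missing ECOG; curative treatment intention decreases them).
    Fully overridable; a data-derived vector comes from
    :func:`derive_mar_weights`."""
    return {"event": 0.5, "nelson_aalen": 0.5, "stage": 0.3,
            "age": 0.2, "intention": -0.3}


@dataclass
class AmputationConfig:
    mechanism: str = "MCAR"
    proportion: float = 0.3
    weights: dict | None = None
    seed: int | np.random.Generator | None = None

    def resolved_weights(self) -> dict:
        if self.weights is not None:
            return dict(self.weights)
        if self.mechanism == "MCAR":
            return mcar_weights()
        if self.mechanism == "MNAR":
            return mnar_weights()
        return default_mar_weights()

    def validate(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise AmputationError(f"mechanism must be one of {MECHANISMS}")
        if not 0.0 < self.proportion < 1.0:
            raise AmputationError("missingness proportion must lie strictly "
                                  "between 0 and 1")


class AmputedCohort(NamedTuple):
    cohort: pd.DataFrame
    realized_proportion: float
    probabilities: np.ndarray


def _column_values(cohort: pd.DataFrame, name: str) -> np.ndarray:
    if name == "nelson_aalen":
        return nelson_aalen(cohort["time"].to_numpy(), cohort["event"].to_numpy())
    if name not in cohort.columns:
        raise AmputationError(f"weighted variable {name!r} not in cohort")
    v = cohort[name].to_numpy(dtype=float)
    if (v == MISSING).any():
        raise AmputationError(f"weighted variable {name!r} contains missing values")
    return v


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def weighted_sum_scores(cohort: pd.DataFrame, weights: dict) -> np.ndarray:
    """Per-row score sum_j w_j z_ij over column-standardised variables.

    Categorical variables enter as their numeric codes; an all-zero weight
    vector yields all-zero scores (the MCAR construction).
    """
    scores = np.zeros(len(cohort))
    for name, w in weights.items():
        if w == 0:
            continue
        scores += w * _standardize(_column_values(cohort, name))
    return scores


def ampute(cohort: pd.DataFrame, config: AmputationConfig) -> AmputedCohort:
    """Delete ECOG values under the configured mechanism and proportion.

    Row i is deleted with probability ``logistic(b + s_i)`` where ``s_i`` is
    the standardised weighted sum score and the intercept ``b`` is solved by
    bisection so the mean probability equals the target proportion; under
    MCAR this reduces to a constant probability.  Nelson-Aalen scores are
    computed on the complete cohort before any deletion.  Returns the
    amputed table and the realized missing fraction.
    """
    config.validate()
    if (cohort["ecog"].to_numpy() == MISSING).any():
        raise AmputationError("cohort must be complete in ECOG before amputation")

    weights = config.resolved_weights()
    scores = weighted_sum_scores(cohort, weights)
    n = len(cohort)
    target = config.proportion

    if scores.std() == 0:
        probs = np.full(n, target)
    else:
        s = _standardize(scores)

        def mean_prob(b: float) -> float:
            return float(expit(b + s).mean()) - target

        try:
            b = brentq(mean_prob, -20.0, 20.0, xtol=1e-10)
            probs = expit(b + s)
            if abs(probs.mean() - target) > 1e-8:
                raise AmputationError("intercept solution insufficiently precise")
        except (ValueError, AmputationError):
            logger.warning("degenerate score distribution; falling back to "
                           "constant-probability (MCAR-like) deletion")
            probs = np.full(n, target)

    rng = (config.seed if isinstance(config.seed, np.random.Generator)
           else np.random.default_rng(config.seed))
    deleted = rng.random(n) < probs
    out = cohort.copy()
    out.loc[deleted, "ecog"] = MISSING
    realized = float(deleted.mean())
    logger.debug("amputation %s: target %.3f realized %.3f",
                 config.mechanism, target, realized)
    return AmputedCohort(out, realized, probs)


def derive_mar_weights(cohort: pd.DataFrame, indicator, alpha: float = 0.05) -> dict:
    """Estimate MAR weights from an observed missingness indicator.

    Fits one logistic regression of the indicator on all standardised
    candidate predictors (covariate codes, the Nelson-Aalen estimate and the
    event indicator) and returns the coefficients whose Wald p-value is below
    ``alpha``, signs preserved; all other weights are zero.  ``alpha >= 1``
    returns every coefficient verbatim.
    """
    y = np.asarray(indicator, dtype=float)
    if y.shape != (len(cohort),):
        raise AmputationError("indicator length must match the cohort")
    if y.min() == y.max():
        raise AmputationError("indicator must contain both classes")

    Z = np.column_stack([_standardize(_column_values(cohort, c))
                         for c in _CANDIDATE_COLUMNS])
    X = sm.add_constant(Z)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.bse)):
            raise AmputationError("non-finite standard errors")
    except Exception as exc:  # noqa: BLE001 -- statsmodels raises various types
        raise AmputationError(
            "logistic missingness model failed (possible perfect separation); "
            "refit with a penalised logistic regression or reduce the "
            f"candidate set: {exc}") from exc

    coefs = fit.params[1:]
    pvals = fit.pvalues[1:]
    if alpha >= 1.0:
        keep = np.ones(len(coefs), dtype=bool)
    else:
        keep = pvals < alpha
    return {name: float(c) for name, c, k in
            zip(_CANDIDATE_COLUMNS, coefs, keep) if k}
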