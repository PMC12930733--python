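"""Survival core: Nelson-Aalen, Cox/Efron engine, Rubin's rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ordmisim as om
from ordmisim.survival import SurvivalError, _newton_cox


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------

def test_nelson_aalen_risk_set_arithmetic():
    H = om.nelson_aalen([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(H, [1 / 3, 1 / 3 + 1 / 2, 1 / 3 + 1 / 2 + 1])


def test_nelson_aalen_no_events_is_zero():
    assert (om.nelson_aalen([3.0, 1.0, 7.0], [0, 0, 0]) == 0).all()


def test_nelson_aalen_single_event():
    np.testing.assert_allclose(om.nelson_aalen([5.0], [1]), [1.0])


def test_nelson_aalen_rejects_nonpositive_times():
    with pytest.raises(SurvivalError):
        om.nelson_aalen([0.0, 1.0], [1, 1])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.tuples(st.integers(1, 20), st.booleans()),
                min_size=1, max_size=40))
def test_nelson_aalen_monotone_in_time(data):
    t = np.array([d[0] for d in data], dtype=float)
    e = np.array([d[1] for d in data], dtype=float)
    H = om.nelson_aalen(t, e)
    order = np.argsort(t)
    assert (np.diff(H[order]) >= -1e-12).all()


def test_nelson_aalen_matches_lifelines(cohort_5k):
    from lifelines import NelsonAalenFitter

    t = cohort_5k["time"].to_numpy()
    e = cohort_5k["event"].to_numpy()
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
    ours = om.nelson_aalen(t, e)
    ref = naf.cumulative_hazard_["NA_estimate"]
    np.testing.assert_allclose(ours, ref.loc[t].to_numpy(), atol=1e-10)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_two_group_exponential_recovery():
    """Groups with hazard ratio 2 -> coefficient near log 2."""
    rng = np.random.default_rng(0)
    n = 2000
    g = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / np.where(g == 1, 2.0, 1.0))
    beta, hess, ok = _newton_cox(g[:, None].astype(float), t, np.ones(n))
    assert ok
    se = np.sqrt(np.linalg.inv(hess)[0, 0])
    assert abs(beta[0] - np.log(2)) < 3 * se


def test_cox_null_covariate():
    rng = np.random.default_rng(1)
    n = 2000
    x = rng.normal(size=n)
    t = rng.exponential(1.0, n)
    beta, hess, ok = _newton_cox(x[:, None], t, np.ones(n))
    se = np.sqrt(np.linalg.inv(hess)[0, 0])
    assert abs(beta[0]) < 3 * se


def test_cox_tied_fixture_matches_lifelines():
    """Worked fixture with tied event times: agreement to 1e-6."""
    df = pd.DataFrame({
        "t": [4.0, 4.0, 6.0, 6.0, 8.0, 10.0],
        "e": [1, 1, 1, 0, 1, 1],
        "x": [0.5, -0.2, 1.0, 0.0, -1.0, 0.3],
        "z": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0],
    })
    from lifelines import CoxPHFitter

    ref = CoxPHFitter().fit(df, "t", "e",
                            fit_options=dict(precision=1e-12)).params_.to_numpy()
    beta, _, ok = _newton_cox(df[["x", "z"]].to_numpy(),
                              df["t"].to_numpy(), df["e"].to_numpy(float))
    assert ok
    np.testing.assert_allclose(beta, ref, atol=1e-6)


def test_fit_cox_full_model(cohort_5k):
    fit = om.fit_cox(cohort_5k)
    assert fit.converged and not fit.failed
    assert list(fit.params.index) == om.ANALYSIS_TERMS
    assert (fit.ci_lower <= fit.params).all() and (fit.params <= fit.ci_upper).all()
    cov = fit.cov.to_numpy()
    np.testing.assert_allclose(cov, cov.T, atol=1e-10)
    assert (np.diag(cov) >= 0).all()
    # hazard increases across ECOG contrasts by construction
    assert fit.params["ecog_4"] > fit.params["ecog_1"]


def test_fit_cox_ecog_only_switch(cohort_5k):
    fit = om.fit_cox(cohort_5k, terms="ecog_only")
    assert list(fit.params.index) == om.ECOG_TERMS
    assert fit.converged


def test_fit_cox_missing_category_is_structured_failure(cohort_5k):
    reduced = cohort_5k[cohort_5k["ecog"] != 4].reset_index(drop=True)
    fit = om.fit_cox(reduced)
    assert fit.failed and not fit.converged
    assert "4" in fit.failure_reason
    assert fit.params.isna().all()


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def test_rubin_hand_arithmetic():
    pooled = om.rubin_pool(np.array([[0.1], [0.2], [0.3]]),
                           np.array([[0.04], [0.04], [0.04]]))
    assert pooled.q[0] == pytest.approx(0.2, abs=1e-12)
    assert pooled.W[0] == pytest.approx(0.04, abs=1e-12)
    assert pooled.B[0] == pytest.approx(0.01, abs=1e-12)
    assert pooled.T[0] == pytest.approx(0.04 + (4 / 3) * 0.01, abs=1e-12)
    assert pooled.df_old[0] == pytest.approx(32.0, abs=1e-10)


def test_rubin_total_variance_identity(amputed_5k, predictors_5k, cohort_5k):
    res = om.impute_pmm(amputed_5k, predictors=predictors_5k, seed=3)
    truth = om.fit_cox(cohort_5k)
    fits = [om.fit_cox(ds, warm_start=truth.params) for ds in res.datasets]
    est = np.stack([f.params[om.ECOG_TERMS].to_numpy() for f in fits])
    cov = np.stack([f.cov.loc[om.ECOG_TERMS, om.ECOG_TERMS].to_numpy()
                    for f in fits])
    pooled = om.rubin_pool(est, cov, names=om.ECOG_TERMS,
                           df_complete=fits[0].df_complete)
    np.testing.assert_allclose(pooled.T, pooled.W + (1 + 1 / 5) * pooled.B,
                               atol=1e-12)
    assert (pooled.B > 0).all()
    assert (pooled.df <= pooled.df_old).all()


def test_rubin_identical_estimates_collapse():
    est = np.tile([[0.5, -0.2]], (4, 1))
    var = np.tile([[0.09, 0.04]], (4, 1))
    pooled = om.rubin_pool(est, var)
    np.testing.assert_allclose(pooled.q, [0.5, -0.2])
    np.testing.assert_allclose(pooled.B, 0.0, atol=1e-15)
    np.testing.assert_allclose(pooled.T, pooled.W)
    assert np.isinf(pooled.df_old).all()
    # CI falls back to the normal quantile
    np.testing.assert_allclose(pooled.ci_upper - pooled.q,
                               1.959963984540054 * np.sqrt(pooled.T))


def test_rubin_single_fit_passthrough():
    pooled = om.rubin_pool(np.array([[1.0]]), np.array([[0.25]]))
    assert pooled.m == 1
    assert np.isnan(pooled.B[0])
    assert pooled.T[0] == 0.25
    assert pooled.ci_upper[0] == pytest.approx(1.0 + 1.96 * 0.5, abs=1e-3)


def test_rubin_permutation_invariance():
    rng = np.random.default_rng(4)
    est = rng.normal(size=(5, 3))
    cov = rng.random((5, 3)) + 0.1
    a = om.rubin_pool(est, cov, df_complete=100)
    perm = rng.permutation(5)
    b = om.rubin_pool(est[perm], cov[perm], df_complete=100)
    np.testing.assert_allclose(a.q, b.q)
    np.testing.assert_allclose(a.T, b.T)
    np.testing.assert_allclose(a.df, b.df)


def test_rubin_dimension_mismatch():
    with pytest.raises(SurvivalError):
        om.rubin_pool(np.ones((3, 2)), np.ones((3, 4)))
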