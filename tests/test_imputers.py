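"""Imputation-engine contracts: validity, distribution match, engine quirks."""

import numpy as np
import pandas as pd
import pytest

import ordmisim as om
from ordmisim._design import MISSING, PREDICTOR_TERMS
from ordmisim.imputers import (ImputationError, _fit_polr, _polr_probs,
                               _sample_categories)

MI_ENGINES = ["pmm", "polr", "polyreg", "rf", "jm"]


def _mini_cohort(n=40, seed=0, missing=0):
    rng = np.random.default_rng(seed)
    pop = om.generate_population(om.GeneratorConfig(population_size=n,
                                                    seed=seed))
    if missing:
        idx = rng.choice(n, missing, replace=False)
        col = pop["ecog"].to_numpy().copy()
        col[idx] = MISSING
        pop["ecog"] = col
    return pop


# ---------------------------------------------------------------------------
# predictor construction
# ---------------------------------------------------------------------------

def test_predictor_columns_and_determinism(amputed_5k):
    a = om.build_predictors(amputed_5k)
    b = om.build_predictors(amputed_5k)
    assert list(a.columns) == PREDICTOR_TERMS
    assert a.shape[1] == 36
    pd.testing.assert_frame_equal(a, b)
    assert not a.isna().any().any()


def test_predictors_no_events_gives_zero_hazard():
    cohort = _mini_cohort(30, seed=3)
    cohort["event"] = 0
    pred = om.build_predictors(cohort)
    assert (pred["nelson_aalen"] == 0).all()
    assert (pred["event"] == 0).all()


def test_predictors_reject_missing_covariates(amputed_5k):
    broken = amputed_5k.copy()
    broken.loc[broken.index[0], "age"] = np.nan
    with pytest.raises(ValueError):
        om.build_predictors(broken)


# ---------------------------------------------------------------------------
# shared engine contracts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("engine", MI_ENGINES)
def test_zero_missing_is_identity(engine, cohort_5k):
    sub = cohort_5k.iloc[:400].reset_index(drop=True)
    res = om.ENGINES[engine](sub, seed=1)
    assert res.m == 5
    for ds in res.datasets:
        pd.testing.assert_frame_equal(ds, sub)


@pytest.fixture(scope="module")
def mcar_replicates(population_50k):
    """50 independent N=5,000 / MCAR 20% replicates imputed by every engine;
    the distribution-match material for the validity checks below."""
    out = {e: [] for e in MI_ENGINES}
    deep = []
    for rep in range(50):
        cohort = om.sample_population(population_50k, 5000, seed=1000 + rep)
        amp, _, _ = om.ampute(cohort, om.AmputationConfig("MCAR", 0.2,
                                                          seed=2000 + rep))
        pred = om.build_predictors(amp)
        observed = amp.loc[amp["ecog"] != MISSING, "ecog"].to_numpy()
        for engine in MI_ENGINES:
            res = om.ENGINES[engine](amp, predictors=pred, seed=3000 + rep)
            diag = om.diagnose_imputations(res, observed)
            out[engine].append(diag)
            if rep == 0:
                deep.append((engine, amp, res))
    return out, deep


@pytest.mark.parametrize("engine", MI_ENGINES)
def test_imputed_values_plausible_and_observed_untouched(engine,
                                                         mcar_replicates):
    _, deep = mcar_replicates
    engine_, amp, res = next(x for x in deep if x[0] == engine)
    observed_mask = ~res.imputed_mask
    for ds in res.datasets:
        vals = ds["ecog"].to_numpy()
        assert vals[res.imputed_mask].min() >= 0
        assert vals[res.imputed_mask].max() <= 4
        assert (vals[observed_mask] == amp["ecog"].to_numpy()[observed_mask]).all()
        others = [c for c in amp.columns if c != "ecog"]
        pd.testing.assert_frame_equal(ds[others], amp[others])


@pytest.mark.parametrize("engine", MI_ENGINES)
def test_between_imputation_variability(engine, mcar_replicates):
    _, deep = mcar_replicates
    _, amp, res = next(x for x in deep if x[0] == engine)
    stacks = np.stack([ds["ecog"].to_numpy()[res.imputed_mask]
                       for ds in res.datasets])
    assert (stacks.std(axis=0) > 0).any()


@pytest.mark.parametrize("engine", MI_ENGINES)
def test_mcar_distribution_match(engine, mcar_replicates):
    """Under MCAR the imputed and observed distributions coincide: the mean
    difference averaged over 50 replicates stays within 0.1 (RF is allowed
    its documented negative offset within that band)."""
    diags, _ = mcar_replicates
    mean_diffs = [d["mean_diff"].mean() for d in diags[engine]]
    assert abs(np.mean(mean_diffs)) <= 0.1


def test_pmm_mean_difference_tight(mcar_replicates):
    diags, _ = mcar_replicates
    mean_diffs = [d["mean_diff"].mean() for d in diags["pmm"]]
    assert abs(np.mean(mean_diffs)) <= 0.05


# ---------------------------------------------------------------------------
# PMM specifics
# ---------------------------------------------------------------------------

def test_pmm_unique_donor_identity():
    """A missing row whose prediction matches exactly one observed row gets
    that donor's value with donors=1."""
    n = 30
    cohort = _mini_cohort(n, seed=5)
    y = np.arange(n) % 5
    cohort["ecog"] = y
    col = cohort["ecog"].to_numpy().copy()
    col[0] = MISSING
    target = cohort.copy()
    target["ecog"] = col
    # predictor equals the (numeric) ECOG of the donor rows; row 0 mirrors row 1
    pred = pd.DataFrame({"x": np.where(np.arange(n) == 0, y[1], y).astype(float)})
    res = om.impute_pmm(target, predictors=pred, m=3, donors=1, seed=9)
    for ds in res.datasets:
        assert ds["ecog"].iloc[0] == y[1]


def test_pmm_insufficient_rows_error():
    cohort = _mini_cohort(40, seed=6, missing=30)
    with pytest.raises(ImputationError):
        om.impute_pmm(cohort, seed=1)


# ---------------------------------------------------------------------------
# POLR specifics
# ---------------------------------------------------------------------------

def test_polr_null_model_matches_marginal():
    """With a predictor unrelated to the outcome the fitted category
    probabilities approach the observed marginal distribution."""
    rng = np.random.default_rng(2)
    n = 5000
    X = rng.normal(size=(n, 1))
    probs = np.array([0.25, 0.49, 0.16, 0.07, 0.03])
    y = rng.choice(5, size=n, p=probs)
    params = _fit_polr(X, y, 5)
    fitted = _polr_probs(params, X, 5).mean(axis=0)
    np.testing.assert_allclose(fitted, np.bincount(y, minlength=5) / n,
                               atol=0.02)


def test_polr_matches_reference_ordinal_regression():
    """Dual route: the in-package cumulative-logit ML fit agrees with the
    statsmodels ordered model on a moderate problem."""
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    rng = np.random.default_rng(7)
    n = 1500
    X = rng.normal(size=(n, 2))
    eta = X @ np.array([0.8, -0.5])
    cuts = np.array([-1.0, 0.2, 1.0, 2.0])
    u = rng.logistic(size=n)
    y = (eta[:, None] + u[:, None] > cuts[None, :]).sum(axis=1)
    params = _fit_polr(X, y, 5, ridge=1e-8)
    ref = OrderedModel(y, X, distr="logit").fit(method="bfgs", disp=0)
    np.testing.assert_allclose(params[:2], ref.params[:2], atol=5e-3)


def test_polr_extreme_rows_get_extreme_categories():
    """Deterministic ordinal structure: missing rows at extreme predictor
    values draw almost surely from the extreme categories."""
    n = 200
    x = np.linspace(-3, 3, n)
    y = np.digitize(x, [-1.8, -0.6, 0.6, 1.8])
    pop = _mini_cohort(n, seed=11)
    pop["ecog"] = y
    col = pop["ecog"].to_numpy().copy()
    lo_rows = np.arange(5)
    hi_rows = np.arange(n - 5, n)
    col[lo_rows] = MISSING
    col[hi_rows] = MISSING
    pop["ecog"] = col
    pred = pd.DataFrame({"x": x})
    res = om.impute_polr(pop, predictors=pred, m=10, seed=13)
    draws = np.stack([ds["ecog"].to_numpy()[res.imputed_mask]
                      for ds in res.datasets])
    lo_draws = draws[:, :5]
    hi_draws = draws[:, 5:]
    assert (lo_draws == 0).mean() >= 0.8
    assert (hi_draws == 4).mean() >= 0.8


# ---------------------------------------------------------------------------
# POLYREG specifics
# ---------------------------------------------------------------------------

def test_polyreg_constant_predictors_follow_frequencies():
    rng = np.random.default_rng(3)
    n = 5000
    probs = np.array([0.25, 0.49, 0.16, 0.07, 0.03])
    pop = _mini_cohort(n, seed=15)
    pop["ecog"] = rng.choice(5, size=n, p=probs)
    col = pop["ecog"].to_numpy().copy()
    miss = rng.choice(n, 1000, replace=False)
    observed = np.delete(pop["ecog"].to_numpy(), miss)
    col[miss] = MISSING
    pop["ecog"] = col
    pred = pd.DataFrame({"c": np.ones(n)})
    res = om.impute_polyreg(pop, predictors=pred, m=5, seed=17)
    draws = np.concatenate([ds["ecog"].to_numpy()[res.imputed_mask]
                            for ds in res.datasets])
    freq = np.bincount(draws, minlength=5) / len(draws)
    obs_freq = np.bincount(observed, minlength=5) / len(observed)
    np.testing.assert_allclose(freq, obs_freq, atol=0.02)


def test_polyreg_separable_toy_stays_finite():
    """Perfect separation: ridge keeps the softmax finite and the predicted
    class matches the true class nearly everywhere."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(19)
    n = 300
    x = np.repeat([0.0, 5.0, 10.0], n // 3) + rng.normal(scale=0.1, size=n)
    y = np.repeat([0, 1, 2], n // 3)
    est = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
    est.fit(x[:, None], y)
    assert np.isfinite(est.coef_).all()
    assert (est.predict(x[:, None]) == y).mean() >= 0.95


# ---------------------------------------------------------------------------
# RF specifics
# ---------------------------------------------------------------------------

def test_rf_constant_observed_imputes_constant():
    pop = _mini_cohort(60, seed=21, missing=10)
    col = pop["ecog"].to_numpy().copy()
    col[col != MISSING] = 2
    pop["ecog"] = col
    res = om.impute_rf(pop, seed=23)
    for ds in res.datasets:
        assert (ds["ecog"].to_numpy()[res.imputed_mask] == 2).all()


def test_rf_pulls_imputed_means_below_regression_engines(population_50k):
    """The class-imbalance pull of the tree engine: on the skewed ECOG
    distribution under outcome-dependent MAR, RF's imputed mean sits below
    PMM's on the same amputed cohort in at least 80% of replicates (the
    direction of the majority-class bias, measured relative to a
    regression-based engine)."""
    lower = 0
    reps = 20
    for rep in range(reps):
        cohort = om.sample_population(population_50k, 5000, seed=5000 + rep)
        amp, _, _ = om.ampute(cohort, om.AmputationConfig("MAR", 0.3,
                                                          seed=6000 + rep))
        pred = om.build_predictors(amp)
        observed = amp.loc[amp["ecog"] != MISSING, "ecog"].to_numpy()
        md = {}
        for engine in ("rf", "pmm"):
            res = om.ENGINES[engine](amp, predictors=pred, seed=7000 + rep)
            md[engine] = om.diagnose_imputations(res, observed)["mean_diff"].mean()
        lower += md["rf"] < md["pmm"]
    assert lower >= 0.8 * reps


# ---------------------------------------------------------------------------
# JM specifics
# ---------------------------------------------------------------------------

def test_jm_intercept_only_matches_marginal(population_50k):
    """Stationary check: with no informative predictors the imputed category
    frequencies reproduce the observed marginal within 0.03."""
    cohort = om.sample_population(population_50k, 5000, seed=31)
    amp, _, _ = om.ampute(cohort, om.AmputationConfig("MCAR", 0.2, seed=33))
    pred = pd.DataFrame({"c": np.zeros(len(amp))})
    res = om.impute_jm(amp, predictors=pred, seed=35)
    draws = np.concatenate([ds["ecog"].to_numpy()[res.imputed_mask]
                            for ds in res.datasets])
    freq = np.bincount(draws, minlength=5) / len(draws)
    observed = amp.loc[amp["ecog"] != MISSING, "ecog"].to_numpy()
    obs_freq = np.bincount(observed, minlength=5) / len(observed)
    np.testing.assert_allclose(freq, obs_freq, atol=0.03)


def test_jm_chain_mixes(population_50k):
    """Split-chain potential scale reduction of every latent-mean trace
    stays below 1.1 after burn-in.  Rare-category components carry high
    between-sweep autocorrelation, so the diagnostic monitors a long chain
    rather than the five short between-imputation segments."""
    import arviz as az

    cohort = om.sample_population(population_50k, 1000, seed=41)
    amp, _, _ = om.ampute(cohort, om.AmputationConfig("MCAR", 0.2, seed=43))
    res = om.impute_jm(amp, predictors=om.build_predictors(amp), seed=45,
                       keep_trace=True, m=2, between=20_000)
    trace = res.diagnostics[0]["trace"][500:]   # post burn-in
    for c in range(4):
        x = trace[:, c]
        half = len(x) // 2
        rhat = az.rhat(np.stack([x[:half], x[half:2 * half]]))
        assert float(rhat.to_array().max() if hasattr(rhat, "to_array")
                     else rhat) < 1.1


# ---------------------------------------------------------------------------
# CCA
# ---------------------------------------------------------------------------

def test_complete_cases_drops_missing_rows():
    pop = _mini_cohort(5, seed=51)
    col = pop["ecog"].to_numpy().copy()
    col[:2] = MISSING
    pop["ecog"] = col
    cc = om.complete_cases(pop)
    assert len(cc.cohort) == 3


def test_complete_cases_identity_when_complete():
    pop = _mini_cohort(20, seed=53)
    # make sure every category is present so the result is not flagged
    pop.loc[:4, "ecog"] = [0, 1, 2, 3, 4]
    cc = om.complete_cases(pop)
    assert not cc.failed
    pd.testing.assert_frame_equal(cc.cohort, pop)


def test_complete_cases_flags_emptied_category(cohort_5k):
    amp = cohort_5k.copy()
    col = amp["ecog"].to_numpy().copy()
    col[col == 4] = MISSING
    amp["ecog"] = col
    cc = om.complete_cases(amp)
    assert cc.failed
    assert "4" in cc.reason
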