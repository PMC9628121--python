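import numpy as np
import pytest
from scipy import stats

from survbench.synthetic_registry import (
    CalibrationError,
    CovariateSpec,
    OutcomeSpec,
    SpecError,
    expected_event_fraction,
    generate_covariates,
    generate_outcomes,
    linear_predictor,
    make_nacc_like,
    make_prompt_like,
)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def test_independent_latents_have_near_zero_correlation():
    spec = CovariateSpec(n_binary=2, n_continuous=3, correlation=0.0)
    X, _ = generate_covariates(spec, 10_000, seed=1)
    corr = np.corrcoef(X.to_numpy(), rowvar=False)
    off = corr[~np.eye(5, dtype=bool)]
    assert np.all(np.abs(off) < 0.05)


def test_binary_prevalence_calibrated():
    n = 10_000
    spec = CovariateSpec(n_binary=1, n_continuous=1, binary_prevalences=[0.5])
    X, _ = generate_covariates(spec, n, seed=2)
    mc_se = np.sqrt(0.25 / n)
    assert abs(X["x1"].mean() - 0.5) < 3 * mc_se


def test_binary_pair_matches_bivariate_normal_orthant():
    """With latent correlation 0.3 the joint prevalence of two thresholded
    binaries must match the bivariate-normal orthant probability computed
    by numeric integration."""
    rho, p1, p2, n = 0.3, 0.4, 0.3, 40_000
    spec = CovariateSpec(
        n_binary=2, n_continuous=0, correlation=rho, binary_prevalences=[p1, p2]
    )
    X, _ = generate_covariates(spec, n, seed=3)
    a, b = stats.norm.ppf(1 - p1), stats.norm.ppf(1 - p2)
    # P(Z1 > a, Z2 > b) by brute-force integration of the bivariate density
    mvn = stats.multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    joint = 1 - stats.norm.cdf(a) - stats.norm.cdf(b) + mvn.cdf([a, b])
    emp = float(np.mean((X["x1"] == 1) & (X["x2"] == 1)))
    mc_se = np.sqrt(joint * (1 - joint) / n)
    assert abs(emp - joint) < 3 * mc_se


def test_continuous_columns_standardized():
    spec = CovariateSpec(n_binary=0, n_continuous=4, correlation=0.2)
    X, _ = generate_covariates(spec, 20_000, seed=4)
    assert np.all(np.abs(X.mean()) < 0.03)
    assert np.all(np.abs(X.std() - 1) < 0.03)


def test_ordinal_levels_and_types():
    spec = CovariateSpec(n_binary=1, n_continuous=1, n_ordinal=2, ordinal_levels=[3, 5])
    X, col_types = generate_covariates(spec, 5000, seed=5)
    assert set(col_types.values()) == {"binary", "continuous", "ordinal"}
    assert set(np.unique(X["x3"])) <= set(range(3))
    assert set(np.unique(X["x4"])) <= set(range(5))


def test_deterministic_given_seed():
    spec = CovariateSpec(n_binary=2, n_continuous=2)
    X1, _ = generate_covariates(spec, 100, seed=6)
    X2, _ = generate_covariates(spec, 100, seed=6)
    assert X1.equals(X2)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(n_binary=0, n_continuous=0),
        dict(n_binary=1, n_continuous=1, correlation=1.2),
        dict(n_binary=1, n_continuous=1, correlation=-0.1),
        dict(n_binary=2, n_continuous=0, binary_prevalences=[0.5]),
        dict(n_binary=1, n_continuous=0, binary_prevalences=[1.5]),
        dict(n_binary=0, n_continuous=0, n_ordinal=1, ordinal_levels=[1]),
    ],
)
def test_invalid_covariate_specs_rejected(kwargs):
    with pytest.raises(SpecError):
        CovariateSpec(**kwargs)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def test_null_model_weibull_median():
    """With zero coefficients and no censoring the empirical median
    survival time matches the closed form lambda * ln(2)^(1/k)."""
    n, k, lam = 10_000, 1.5, 2.0
    spec = OutcomeSpec(
        weibull_shape=k,
        weibull_scale=lam,
        linear_coefs=np.zeros(2),
        target_event_rate=None,
        horizon_tau=np.inf,
    )
    X, _ = generate_covariates(CovariateSpec(n_binary=1, n_continuous=1), n, seed=7)
    time, event = generate_outcomes(X, spec, seed=8)
    assert np.all(event == 1)
    med_true = lam * np.log(2) ** (1 / k)
    # SE of the sample median: 1 / (2 f(median) sqrt(n))
    f_med = stats.weibull_min.pdf(med_true, k, scale=lam)
    se = 1 / (2 * f_med * np.sqrt(n))
    assert abs(np.median(time) - med_true) < 3 * se


def test_event_fraction_hits_target():
    n = 10_000
    spec = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=np.array([0.5, -0.4, 0.3]),
        target_event_rate=0.40,
        horizon_tau=3.0,
    )
    from survbench.synthetic_registry import _calibrate_censor_mix

    X, _ = generate_covariates(CovariateSpec(n_binary=1, n_continuous=2), n, seed=9)
    q = _calibrate_censor_mix(linear_predictor(X, spec), spec)
    expected = expected_event_fraction(X, spec, censor_mix=q)
    time, event = generate_outcomes(X, spec, seed=10)
    assert 0.38 <= event.mean() <= 0.42
    assert abs(expected - 0.40) < 0.01


def test_hazard_ratio_recovery():
    """A single binary predictor with coefficient beta yields a fitted
    proportional-hazards ratio within 10% of exp(beta) at n = 10^4."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    beta = np.log(2.0)
    spec = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=np.array([beta]),
        target_event_rate=0.4,
        horizon_tau=3.0,
    )
    X, _ = generate_covariates(
        CovariateSpec(n_binary=1, n_continuous=0, binary_prevalences=[0.5]), 10_000, seed=11
    )
    time, event = generate_outcomes(X, spec, seed=12)
    est = CoxPHSurvivalAnalysis().fit(
        X.to_numpy(), Surv.from_arrays(event.astype(bool), time)
    )
    hr = np.exp(est.coef_[0])
    assert abs(hr - 2.0) / 2.0 < 0.10


def test_linear_coefficient_recovery_bias():
    """Fitting the true functional form to a large cohort recovers the
    generating coefficients with small absolute bias."""
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    beta = np.array([0.5, -0.4, 0.3, 0.2])
    spec = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=beta,
        target_event_rate=0.4,
        horizon_tau=3.0,
    )
    X, _ = generate_covariates(
        CovariateSpec(n_binary=0, n_continuous=4, correlation=0.2), 10_000, seed=13
    )
    time, event = generate_outcomes(X, spec, seed=14)
    est = CoxPHSurvivalAnalysis().fit(
        X.to_numpy(), Surv.from_arrays(event.astype(bool), time)
    )
    assert np.max(np.abs(est.coef_ - beta)) < 0.05


def test_interaction_and_nonlinear_terms_change_the_hazard():
    spec_cov = CovariateSpec(n_binary=0, n_continuous=3)
    X, _ = generate_covariates(spec_cov, 1000, seed=15)
    base = OutcomeSpec(
        weibull_shape=1.2, weibull_scale=3.0, linear_coefs=np.array([0.5, 0.0, 0.0])
    )
    rich = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=3.0,
        linear_coefs=np.array([0.5, 0.0, 0.0]),
        interaction_terms=[((0, 1), 0.4)],
        nonlinear_terms=[(2, "square", 0.3)],
    )
    eta0 = linear_predictor(X, base)
    eta1 = linear_predictor(X, rich)
    assert not np.allclose(eta0, eta1)


def test_unreachable_event_rate_raises_with_range():
    spec = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=50.0,  # events essentially never happen inside 3 years
        linear_coefs=np.zeros(2),
        target_event_rate=0.9,
        horizon_tau=3.0,
    )
    X, _ = generate_covariates(CovariateSpec(n_binary=1, n_continuous=1), 500, seed=16)
    with pytest.raises(CalibrationError, match="achievable"):
        generate_outcomes(X, spec, seed=17)


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(weibull_shape=-1.0, weibull_scale=2.0, linear_coefs=np.zeros(2)),
        dict(weibull_shape=1.0, weibull_scale=2.0, linear_coefs=np.zeros(2), target_event_rate=1.5),
        dict(
            weibull_shape=1.0,
            weibull_scale=2.0,
            linear_coefs=np.zeros(2),
            interaction_terms=[((0, 5), 0.1)],
        ),
        dict(
            weibull_shape=1.0,
            weibull_scale=2.0,
            linear_coefs=np.zeros(2),
            nonlinear_terms=[(0, "cube", 0.1)],
        ),
    ],
)
def test_invalid_outcome_specs_rejected(kwargs):
    with pytest.raises(SpecError):
        OutcomeSpec(**kwargs)


# ---------------------------------------------------------------------------
# registry presets
# ---------------------------------------------------------------------------


def test_preset_shapes(prompt_cohort):
    assert prompt_cohort.n == 273
    assert prompt_cohort.p == 30
    nacc = make_nacc_like(11)
    assert nacc.n == 967
    assert nacc.p == 35


def test_preset_determinism(prompt_cohort):
    again = make_prompt_like(11)
    assert prompt_cohort.X.equals(again.X)
    assert np.array_equal(prompt_cohort.time, again.time)
    assert np.array_equal(prompt_cohort.event, again.event)


def test_preset_event_rate_across_seeds():
    fracs = [make_prompt_like(s).event_fraction for s in range(200)]
    assert 0.38 <= np.mean(fracs) <= 0.42


def test_preset_outcome_invariants(prompt_cohort):
    assert np.all(prompt_cohort.time > 0)
    assert np.all(prompt_cohort.time <= prompt_cohort.tau)
    assert np.all(prompt_cohort.time[prompt_cohort.event == 1] <= 3.0)
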