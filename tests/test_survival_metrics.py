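import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survbench.dgp_engine import SurvivalCurveSet
from survbench.survival_metrics import (
    CalibrationFit,
    ConcordanceUndefinedError,
    DegeneratePredictionsError,
    MetricError,
    censoring_km,
    fit_calibration,
    harrell_cindex,
    ici,
    integrated_brier,
    rcs_basis,
)
from survbench.synthetic_registry import (
    CovariateSpec,
    OutcomeSpec,
    generate_covariates,
    generate_outcomes,
    true_failure_prob,
)


# ---------------------------------------------------------------------------
# Harrell's c-index
# ---------------------------------------------------------------------------


def brute_force_cindex(time, event, risk):
    """Direct enumeration of all ordered pairs (independent oracle)."""
    conc = comp = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                comp += 1
                if risk[i] > risk[j]:
                    conc += 1
                elif risk[i] == risk[j]:
                    conc += 0.5
    if comp == 0:
        raise ZeroDivisionError
    return conc / comp


def test_perfect_ranking_gives_one():
    assert harrell_cindex([1, 2, 3], [1, 1, 1], [3, 2, 1]) == 1.0


def test_all_tied_risks_give_half():
    assert harrell_cindex([1, 2, 3, 4], [1, 1, 0, 1], [2, 2, 2, 2]) == 0.5


def test_matches_brute_force_on_worked_example():
    time = np.array([2.0, 1.0, 4.0, 3.0])
    event = np.array([1, 0, 1, 1])
    risk = np.array([0.6, 0.1, 0.2, 0.4])
    expected = brute_force_cindex(time, event, risk)
    assert harrell_cindex(time, event, risk) == pytest.approx(expected)
    assert expected == 1.0  # frozen from the enumeration above


def test_all_censored_raises():
    with pytest.raises(ConcordanceUndefinedError):
        harrell_cindex([1, 2, 3], [0, 0, 0], [1, 2, 3])


def test_reordering_invariance():
    rng = np.random.default_rng(4)
    time = rng.exponential(2, 60)
    event = (rng.random(60) < 0.6).astype(int)
    risk = rng.normal(size=60)
    c = harrell_cindex(time, event, risk)
    perm = rng.permutation(60)
    assert harrell_cindex(time[perm], event[perm], risk[perm]) == pytest.approx(c)


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000), st.integers(min_value=4, max_value=50))
def test_cindex_equals_pair_enumeration(seed, n):
    """Property: the blocked implementation equals direct pair enumeration,
    including tied times, tied risks, and heavy censoring."""
    rng = np.random.default_rng(seed)
    time = rng.integers(1, 8, n).astype(float)  # many ties
    event = (rng.random(n) < 0.7).astype(int)
    risk = rng.integers(0, 5, n).astype(float)
    if not np.any(event[time < time.max()] == 1):
        event[np.argmin(time)] = 1
    assert harrell_cindex(time, event, risk) == pytest.approx(
        brute_force_cindex(time, event, risk)
    )


# ---------------------------------------------------------------------------
# censoring Kaplan-Meier
# ---------------------------------------------------------------------------


def test_no_censoring_gives_unit_G():
    G = censoring_km([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.all(G.evaluate([0.5, 1.5, 3.5]) == 1.0)


def test_product_limit_by_hand():
    # subjects: times 1,2,2,3,4 with censorings at 2 (x1) and 3 (x1)
    time = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
    event = np.array([1, 0, 1, 0, 1])
    G = censoring_km(time, event)
    # at t=2: risk set 4, one censoring -> G = 3/4
    # at t=3: risk set 2, one censoring -> G = 3/4 * 1/2 = 3/8
    assert G.evaluate([1.0])[0] == 1.0
    assert G.evaluate([2.0])[0] == pytest.approx(0.75)
    assert G.evaluate([3.5])[0] == pytest.approx(0.375)
    # left limits used inside IPCW weights
    assert G.evaluate_left([2.0])[0] == 1.0
    assert G.evaluate_left([3.0])[0] == pytest.approx(0.75)


def test_matches_lifelines_flipped_km():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(9)
    time = rng.exponential(2, 200).round(2) + 0.01
    event = (rng.random(200) < 0.5).astype(int)
    G = censoring_km(time, event)
    km = KaplanMeierFitter().fit(time, 1 - event)
    pts = np.quantile(time, [0.1, 0.3, 0.5, 0.7, 0.9])
    ours = G.evaluate(pts)
    theirs = km.survival_function_at_times(pts).to_numpy()
    np.testing.assert_allclose(ours, theirs, atol=1e-12)


def test_G_monotone_nonincreasing():
    rng = np.random.default_rng(12)
    for _ in range(5):
        time = rng.exponential(1, 50)
        event = (rng.random(50) < 0.4).astype(int)
        G = censoring_km(time, event)
        assert np.all(np.diff(G.values) <= 1e-12)
        assert np.all((G.values >= 0) & (G.values <= 1))


# ---------------------------------------------------------------------------
# integrated Brier score
# ---------------------------------------------------------------------------


def _curves(grid, S, tau):
    return SurvivalCurveSet(grid=np.asarray(grid, float), S=np.asarray(S, float), tau=tau)


def test_single_subject_worked_example():
    # event at t=2, no censoring, evaluation grid {1, 3}:
    # at t*=1 subject still at risk -> (1 - S(1))^2 = 0.04
    # at t*=3 subject has failed   -> S(3)^2 = 0.16
    # average = 0.10
    curves = _curves([1.0, 3.0], [[0.8, 0.4]], tau=3.0)
    val = integrated_brier(curves, [2.0], [1], times=[1.0, 3.0])
    assert val == pytest.approx(0.10)


def test_perfect_oracle_prediction_scores_zero():
    # S jumps 1 -> 0 exactly at each subject's event time
    time = np.array([1.0, 2.0, 3.0])
    grid = np.array([1.0, 2.0, 3.0])
    S = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0]])
    val = integrated_brier(_curves(grid, S, 3.0), time, [1, 1, 1])
    assert val == pytest.approx(0.0)


def test_constant_half_prediction_scores_quarter():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    S = np.full((4, 4), 0.5)
    val = integrated_brier(_curves([1.0, 2.0, 3.0, 4.0], S, 5.0), time, [1, 1, 1, 1])
    assert val == pytest.approx(0.25)


def naive_ibs_no_censoring(grid, S, time, event):
    """Double-loop mean squared prediction error (independent oracle)."""
    total = 0.0
    n, T = S.shape
    for i in range(n):
        for j in range(T):
            if time[i] <= grid[j] and event[i] == 1:
                total += S[i, j] ** 2
            elif time[i] > grid[j]:
                total += (1 - S[i, j]) ** 2
    return total / (n * T)


def test_no_censoring_equals_naive_double_loop():
    rng = np.random.default_rng(3)
    n = 40
    time = rng.exponential(2, n) + 0.05
    event = np.ones(n, dtype=int)
    grid = np.unique(time[time <= 3.0])
    S = np.sort(rng.random((n, len(grid))))[:, ::-1]
    curves = _curves(grid, S, tau=3.0)
    expected = naive_ibs_no_censoring(grid, curves.evaluate(grid), time, event)
    assert integrated_brier(curves, time, event) == pytest.approx(expected, abs=1e-12)


def test_zero_weight_raises_with_time_point():
    # the last subject is censored, so G drops to 0 at its time; under the
    # literal weighting that subject's own 1/G(t_i) weight is undefined
    time = np.array([1.0, 2.0, 3.0])
    event = np.array([0, 1, 0])
    curves = _curves([1.0, 2.0], np.full((3, 2), 0.7), tau=3.0)
    with pytest.raises(MetricError, match="undefined"):
        integrated_brier(curves, time, event, weighting="literal")


def test_literal_weighting_variant_differs():
    rng = np.random.default_rng(8)
    n = 60
    time = np.round(rng.exponential(2, n), 2) + 0.05
    event = (rng.random(n) < 0.7).astype(int)
    time[event == 0] = np.minimum(time[event == 0], 2.0)
    grid = np.unique(time[event == 1])
    S = np.sort(rng.random((n, len(grid))))[:, ::-1]
    curves = _curves(grid, S, tau=time.max() + 1)
    graf = integrated_brier(curves, time, event, weighting="graf")
    literal = integrated_brier(curves, time, event, weighting="literal")
    assert graf >= 0 and literal >= 0
    assert graf != pytest.approx(literal)


def test_ibs_reordering_invariance():
    rng = np.random.default_rng(21)
    n = 30
    time = rng.exponential(2, n) + 0.05
    event = (rng.random(n) < 0.6).astype(int)
    grid = np.unique(time[event == 1])
    S = np.sort(rng.random((n, len(grid))))[:, ::-1]
    val = integrated_brier(_curves(grid, S, 4.0), time, event)
    perm = rng.permutation(n)
    val_p = integrated_brier(_curves(grid, S[perm], 4.0), time[perm], event[perm])
    assert val_p == pytest.approx(val)


# ---------------------------------------------------------------------------
# integrated calibration index
# ---------------------------------------------------------------------------


def test_ici_identity_is_zero():
    p = np.linspace(0.05, 0.9, 20)
    fit = CalibrationFit(p_unique=p, p_observed=p.copy(), knots=np.zeros(3), t_star=3.0, clip=1e-6)
    assert ici(fit) == 0.0


def test_ici_constant_offset():
    p = np.linspace(0.1, 0.7, 25)
    fit = CalibrationFit(p_unique=p, p_observed=p + 0.1, knots=np.zeros(3), t_star=3.0, clip=1e-6)
    assert ici(fit) == pytest.approx(0.1)


def test_rcs_basis_linear_beyond_boundary_knots():
    knots = np.array([-1.0, 0.0, 1.0])
    x = np.array([1.5, 2.5, 3.5])
    b = rcs_basis(x, knots)
    # second differences of each basis column vanish on the linear tail
    assert np.allclose(np.diff(b, n=2, axis=0), 0.0, atol=1e-9)


def _calibration_data(n, seed, shift=0.0):
    """Outcomes from a known Weibull PH model plus predictions whose
    cloglog is shifted by a constant (0 = perfectly calibrated)."""
    cov = CovariateSpec(n_binary=0, n_continuous=3, correlation=0.0)
    out = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=np.array([0.6, -0.5, 0.4]),
        target_event_rate=0.4,
        horizon_tau=3.0,
    )
    X, _ = generate_covariates(cov, n, seed)
    time, event = generate_outcomes(X, out, seed + 1)
    p_true = true_failure_prob(X, out, 3.0)
    p_pred = 1.0 - (1.0 - p_true) ** np.exp(shift)  # cloglog(p_pred) = cloglog(p_true) + shift
    return p_pred, p_true, time, event


def test_perfectly_calibrated_predictions_recovered():
    p_pred, _, time, event = _calibration_data(5000, seed=50)
    fit = fit_calibration(p_pred, time, event, t_star=3.0)
    assert np.max(np.abs(fit.p_observed - fit.p_unique)) < 0.03
    assert ici(fit) < 0.03


def test_shifted_cloglog_miscalibration_detected():
    shift = 0.5
    p_pred, p_true, time, event = _calibration_data(5000, seed=60, shift=shift)
    fit = fit_calibration(p_pred, time, event, t_star=3.0)
    # smoothed observed probabilities recover the unshifted truth
    order = np.argsort(p_pred)
    truth_at_unique = np.interp(fit.p_unique, p_pred[order], p_true[order])
    assert np.max(np.abs(fit.p_observed - truth_at_unique)) < 0.03
    # and the ICI approximates the analytic mean absolute miscalibration
    analytic = np.mean(np.abs(p_pred - p_true))
    assert ici(fit) == pytest.approx(analytic, abs=0.02)


def test_degenerate_predictions_rejected():
    time = np.linspace(0.1, 3.0, 50)
    event = np.ones(50, dtype=int)
    with pytest.raises(DegeneratePredictionsError):
        fit_calibration(np.full(50, 0.4), time, event, t_star=3.0)
    with pytest.raises(DegeneratePredictionsError):
        fit_calibration(np.tile([0.3, 0.6], 25), time, event, t_star=3.0)


def test_predictions_outside_unit_interval_rejected():
    with pytest.raises(MetricError):
        fit_calibration([0.2, 0.5, 1.3], [1.0, 2.0, 3.0], [1, 1, 1], t_star=3.0)
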