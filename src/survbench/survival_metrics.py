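"""Discrimination and calibration metrics for right-censored predictions.

Implements the three scores used throughout the benchmark:

* :func:`harrell_cindex` — Harrell's concordance index. A pair (i, j) is
  comparable when ``time_i < time_j`` and subject i had the event; the
  pair is concordant when the earlier failure carries the higher
  predicted risk, with ties in risk counting 1/2.

* :func:`ici` / :func:`fit_calibration` — the integrated calibration
  index at a fixed horizon t*: predicted failure probabilities are
  mapped to the complementary log-log scale, smoothed against the
  observed outcomes with a proportional-hazards model on a restricted
  cubic spline basis (3 knots), and the ICI is the mean absolute gap
  between predicted and smoothed-observed probabilities over the unique
  predictions.

* :func:`integrated_brier` — the integrated Brier score: squared error
  between event status and predicted survival, averaged over subjects
  and the unique event times up to the horizon, reweighted by the
  inverse of the Kaplan–Meier estimate of the censoring distribution
  (:func:`censoring_km`). The default weighting follows Graf's
  convention — events before t* are weighted by 1/G(t_i^-), survivors
  by 1/G(t*) — with a ``weighting="literal"`` variant that divides both
  terms by G(t_i) for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetricError",
    "ConcordanceUndefinedError",
    "DegeneratePredictionsError",
    "CensorKM",
    "CalibrationFit",
    "harrell_cindex",
    "censoring_km",
    "integrated_brier",
    "fit_calibration",
    "ici",
    "rcs_basis",
]


class MetricError(ValueError):
    """A metric could not be computed on the given inputs."""


class ConcordanceUndefinedError(MetricError):
    """No comparable pairs: the c-index is undefined."""


class DegeneratePredictionsError(MetricError):
    """Too little spread in the predictions for spline calibration."""


def _as_1d(name, x):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise MetricError(f"{name} must be one-dimensional")
    return x


def _check_outcome(time, event):
    time = _as_1d("time", time)
    event = np.asarray(event)
    if len(event) != len(time):
        raise MetricError("time and event have different lengths")
    if not np.isin(event, (0, 1)).all():
        raise MetricError("event indicator must be 0 or 1")
    return time, event.astype(int)


# ---------------------------------------------------------------------------
# Harrell's concordance index
# ---------------------------------------------------------------------------


def harrell_cindex(time, event, risk) -> float:
    """Harrell's c-index for risk scores (larger score = earlier failure).

    Processes subjects in row blocks so the pairwise comparison stays
    vectorised without materialising an n^2 matrix for large cohorts.
    """
    time, event = _check_outcome(time, event)
    risk = _as_1d("risk", risk)
    if len(risk) != len(time):
        raise MetricError("risk and time have different lengths")
    n = len(time)
    concordant = 0.0
    comparable = 0
    block = 512
    for start in range(0, n, block):
        sl = slice(start, min(start + block, n))
        # pair (i, j) comparable iff time_i < time_j and subject i failed
        comp = (time[sl, None] < time[None, :]) & (event[sl, None] == 1)
        ri = risk[sl, None]
        rj = risk[None, :]
        concordant += np.sum((ri > rj) & comp) + 0.5 * np.sum((ri == rj) & comp)
        comparable += int(comp.sum())
    if comparable == 0:
        raise ConcordanceUndefinedError(
            "no comparable pairs (all subjects censored or tied); "
            "the c-index is undefined"
        )
    return float(concordant / comparable)


# ---------------------------------------------------------------------------
# censoring-distribution Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class CensorKM:
    """Product-limit estimate G(t) of the censoring distribution.

    ``times`` are the distinct censoring times; ``values`` the
    right-continuous step values of G just after each time. G(0) = 1.
    """

    times: np.ndarray
    values: np.ndarray

    def evaluate(self, t) -> np.ndarray:
        """G(t): right-continuous step evaluation."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        vals = np.concatenate(([1.0], self.values))
        return vals[idx + 1]

    def evaluate_left(self, t) -> np.ndarray:
        """G(t-): left limit, the value just before t."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="left") - 1
        vals = np.concatenate(([1.0], self.values))
        return vals[idx + 1]


def censoring_km(time, event) -> CensorKM:
    """Kaplan–Meier estimate of the censoring distribution.

    The event indicator is flipped: censorings are the 'events', actual
    failures are treated as censored observations of the censoring time.
    """
    time, event = _check_outcome(time, event)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    cens_sorted = 1 - event[order]
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    n = len(time)
    values = []
    g = 1.0
    for k, t_k in enumerate(uniq):
        at_risk = n - first_idx[k]
        end = first_idx[k + 1] if k + 1 < len(uniq) else n
        d = int(cens_sorted[first_idx[k]:end].sum())
        if d > 0:
            g *= 1.0 - d / at_risk
        values.append(g)
    return CensorKM(times=uniq, values=np.asarray(values))


# ---------------------------------------------------------------------------
# integrated Brier score
# ---------------------------------------------------------------------------


def integrated_brier(
    curves,
    time,
    event,
    G: CensorKM | None = None,
    weighting: str = "graf",
    times=None,
) -> float:
    """Censoring-weighted integrated Brier score over unique event times.

    ``curves`` is a :class:`~survbench.dgp_engine.SurvivalCurveSet`
    aligned with (time, event); the evaluation grid is the unique
    observed event times not exceeding the curve horizon tau (or the
    explicit ``times`` when given). With ``weighting="graf"`` events
    before t* are weighted by 1/G(t_i^-) and survivors by 1/G(t*);
    ``weighting="literal"`` divides both terms by G(t_i).
    """
    time, event = _check_outcome(time, event)
    if weighting not in ("graf", "literal"):
        raise MetricError(f"unknown weighting {weighting!r}")
    if G is None:
        G = censoring_km(time, event)

    if times is not None:
        grid = np.asarray(times, dtype=float)
    else:
        grid = np.unique(time[event == 1])
        grid = grid[grid <= curves.tau]
    if len(grid) == 0:
        raise MetricError("no event times at or below the horizon")
    S = curves.evaluate(grid)  # n x T
    if S.shape[0] != len(time):
        raise MetricError("curve set not aligned with (time, event)")

    is_event_before = (time[:, None] <= grid[None, :]) & (event[:, None] == 1)
    is_survivor = time[:, None] > grid[None, :]

    if weighting == "graf":
        w_event = np.zeros_like(S)
        g_left = G.evaluate_left(time)
        _check_positive_weights(g_left, time, np.any(is_event_before, axis=1))
        w_event = np.where(is_event_before, 1.0 / g_left[:, None], 0.0)
        g_grid = G.evaluate(grid)
        needed = np.any(is_survivor, axis=0)
        if np.any(needed & (g_grid <= 0)):
            bad = grid[needed & (g_grid <= 0)][0]
            raise MetricError(
                f"censoring survival G is zero at evaluation time {bad:g}; "
                "the IPCW weight is undefined there"
            )
        w_surv = np.where(is_survivor, 1.0 / np.where(g_grid > 0, g_grid, 1.0), 0.0)
    else:  # literal: both terms divided by G at the subject's own time
        g_own = G.evaluate(time)
        used = np.any(is_event_before | is_survivor, axis=1)
        _check_positive_weights(g_own, time, used)
        g_own = np.where(g_own > 0, g_own, 1.0)
        w_event = np.where(is_event_before, 1.0 / g_own[:, None], 0.0)
        w_surv = np.where(is_survivor, 1.0 / g_own[:, None], 0.0)

    loss = S**2 * w_event + (1.0 - S) ** 2 * w_surv
    return float(loss.sum() / (S.shape[0] * S.shape[1]))


def _check_positive_weights(g, time, needed):
    bad = needed & (np.asarray(g) <= 0)
    if np.any(bad):
        t_bad = np.asarray(time)[bad][0]
        raise MetricError(
            f"censoring survival G is zero at time {t_bad:g}; "
            "the IPCW weight is undefined there"
        )


# ---------------------------------------------------------------------------
# integrated calibration index
# ---------------------------------------------------------------------------


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted (natural) cubic spline basis, linear beyond the
    boundary knots. For three knots k1 < k2 < k3 the basis has two
    columns: x itself and one restricted cubic term."""
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3:
        raise MetricError("restricted cubic splines need at least 3 knots")
    t1, tk, tk1 = knots[0], knots[-1], knots[-2]
    span2 = (tk - t1) ** 2

    def pos3(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            pos3(x - tj)
            - pos3(x - tk1) * (tk - tj) / (tk - tk1)
            + pos3(x - tk) * (tk1 - tj) / (tk - tk1)
        ) / span2
        cols.append(term)
    return np.column_stack(cols)


@dataclass
class CalibrationFit:
    """Smoothed-calibration intermediate at horizon ``t_star``.

    ``p_unique`` holds the unique predicted failure probabilities (after
    clipping to ``(clip, 1-clip)`` and rounding to 12 significant
    digits); ``p_observed`` the spline-smoothed observed failure
    probabilities evaluated at those predictions; ``knots`` the spline
    knots on the cloglog scale.
    """

    p_unique: np.ndarray
    p_observed: np.ndarray
    knots: np.ndarray
    t_star: float
    clip: float


def _round_sig(x, digits=12):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    nz = x != 0
    mag = np.floor(np.log10(np.abs(x[nz])))
    out[nz] = np.round(x[nz] / 10.0**mag, digits - 1) * 10.0**mag
    return out


def _cloglog(p):
    return np.log(-np.log1p(-p))


def fit_calibration(pred_probs, time, event, t_star, clip: float = 1e-6) -> CalibrationFit:
    """Smooth observed against predicted failure probabilities at t*.

    Fits a proportional-hazards model whose only covariate is a
    3-knot restricted cubic spline of cloglog(predicted probability)
    (knots at the 10th/50th/90th percentiles), then reads off the
    model's predicted failure probability at t* for every unique
    prediction.
    """
    from lifelines import CoxPHFitter

    time, event = _check_outcome(time, event)
    p = _as_1d("pred_probs", pred_probs)
    if len(p) != len(time):
        raise MetricError("predictions and outcomes have different lengths")
    if np.any(p < 0) or np.any(p > 1):
        raise MetricError("predicted probabilities must lie in [0, 1]")
    if not t_star > 0:
        raise MetricError("t_star must be positive")

    p = np.clip(p, clip, 1.0 - clip)
    p = _round_sig(p, 12)
    uniq = np.unique(p)
    if len(uniq) < 3:
        raise DegeneratePredictionsError(
            f"spline calibration needs at least 3 distinct predicted "
            f"probabilities, got {len(uniq)}"
        )

    z = _cloglog(p)
    knots = np.percentile(_cloglog(uniq), [10, 50, 90])
    if len(np.unique(knots)) < 3:
        raise DegeneratePredictionsError(
            "spline knots coincide: predictions have too little spread"
        )
    basis = rcs_basis(z, knots)
    df = pd.DataFrame(basis, columns=[f"s{i}" for i in range(basis.shape[1])])
    df["time"] = time
    df["event"] = event
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        # lifelines warns about low-variance spline columns whenever the
        # predictions cluster; that is exactly the regime the degenerate
        # guards above are for, so the warning adds no information here
        warnings.simplefilter("ignore")
        cph.fit(df, duration_col="time", event_col="event")

    basis_u = pd.DataFrame(
        rcs_basis(_cloglog(uniq), knots), columns=[f"s{i}" for i in range(basis.shape[1])]
    )
    surv = cph.predict_survival_function(basis_u, times=[t_star])
    p_obs = 1.0 - surv.iloc[0].to_numpy()
    return CalibrationFit(
        p_unique=uniq, p_observed=p_obs, knots=knots, t_star=float(t_star), clip=clip
    )


def ici(fit: CalibrationFit) -> float:
    """Integrated calibration index: mean |observed - predicted| over the
    unique predictions. 0 = perfectly calibrated."""
    if len(fit.p_unique) != len(fit.p_observed):
        raise MetricError("calibration fit is inconsistent")
    return float(np.mean(np.abs(fit.p_observed - fit.p_unique)))
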