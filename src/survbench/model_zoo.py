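"""Nine survival prediction models behind one fit/predict contract.

The roster mirrors the families most often compared in time-to-event
prediction work: unpenalized Cox regression; ridge-, lasso- and
elastic-net-penalized Cox; a survival tree; a random survival forest;
a survival support vector machine (regression formulation); a
feed-forward survival neural network with a Cox partial-likelihood
loss; and extreme gradient boosting with a proportional-hazards
objective.

Every adapter exposes ``fit(cohort)``, ``predict_risk(X, t_star)``
(larger = higher failure risk by t*) and, where the model produces
survival curves, ``predict_survival(X)``. The SSVM predicts a survival
time score and carries no curve, so ``supports_curves`` is False and
``predict_survival`` raises :class:`CapabilityError`. The neural
adapter needs the optional ``torch`` dependency and reports itself
unavailable otherwise.

:func:`tune` runs the random grid search used to pick hyperparameters:
points sampled uniformly from the spaces declared in
``search_spaces.yaml``, each scored by mean 5-fold event-stratified
cross-validated Harrell c-index.
"""

from __future__ import annotations

import logging
import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .dgp_engine import SurvivalCurveSet
from .survival_metrics import harrell_cindex

__all__ = [
    "SurvModelAdapter",
    "TunedConfig",
    "AdapterError",
    "FitError",
    "NotFittedError",
    "CapabilityError",
    "MissingDependencyError",
    "TuningError",
    "make_adapter",
    "available_adapters",
    "load_search_spaces",
    "tune",
    "ADAPTER_NAMES",
]

logger = logging.getLogger(__name__)


class AdapterError(RuntimeError):
    """Base class for adapter failures."""


class FitError(AdapterError):
    """The underlying fit failed; carries adapter name and hyperparameters."""


class NotFittedError(AdapterError):
    """Prediction requested before fitting."""


class CapabilityError(AdapterError):
    """The adapter does not support the requested output type."""


class MissingDependencyError(AdapterError):
    """An optional dependency of this adapter is not installed."""


class TuningError(AdapterError):
    """Invalid tuning request."""


def _surv_y(cohort: Cohort):
    from sksurv.util import Surv

    return Surv.from_arrays(cohort.event.astype(bool), cohort.time)


class SurvModelAdapter(ABC):
    """Uniform contract over heterogeneous survival models."""

    name: str = "abstract"
    supports_curves: bool = True

    def __init__(self, seed: int = 0, **hyperparams):
        self.seed = int(seed)
        self.hyperparams = dict(hyperparams)
        self.fitted = False
        self._columns: tuple | None = None
        self._tau: float | None = None

    # -- contract ---------------------------------------------------------

    def fit(self, cohort: Cohort) -> "SurvModelAdapter":
        if cohort.n_events < 2:
            raise FitError(
                f"{self.name}: cohort has {cohort.n_events} events (need >= 2)"
            )
        self._columns = tuple(cohort.X.columns)
        self._tau = cohort.tau
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self._fit(cohort)
        except AdapterError:
            raise
        except Exception as exc:
            raise FitError(
                f"{self.name} fit failed with hyperparameters "
                f"{self.hyperparams}: {exc}"
            ) from exc
        self.fitted = True
        return self

    def predict_survival(self, X: pd.DataFrame) -> SurvivalCurveSet:
        self._check_ready(X)
        if not self.supports_curves:
            raise CapabilityError(
                f"{self.name} does not produce survival curves; "
                "only predict_risk is available"
            )
        with warnings.catch_warnings():
            # extreme margins under-/overflow to S in {0, 1}; harmless here
            warnings.simplefilter("ignore", RuntimeWarning)
            return self._predict_survival(np.asarray(X, dtype=float))

    def predict_risk(self, X: pd.DataFrame, t_star: float) -> np.ndarray:
        """Risk of failure by t*: 1 - S(t*) for curve models."""
        self._check_ready(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            risk = self._predict_risk(np.asarray(X, dtype=float), t_star)
        if not np.all(np.isfinite(risk)):
            raise AdapterError(f"{self.name} produced non-finite risk scores")
        return risk

    # -- hooks --------------------------------------------------------------

    @abstractmethod
    def _fit(self, cohort: Cohort) -> None: ...

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        raise CapabilityError(f"{self.name} has no survival-curve route")

    def _predict_risk(self, X: np.ndarray, t_star: float) -> np.ndarray:
        curves = self._predict_survival(X)
        return 1.0 - curves.evaluate([t_star])[:, 0]

    def _check_ready(self, X) -> None:
        if not self.fitted:
            raise NotFittedError(f"{self.name} adapter is not fitted")
        if isinstance(X, pd.DataFrame) and tuple(X.columns) != self._columns:
            raise AdapterError(
                f"{self.name}: covariate columns do not match training columns"
            )

    def _curveset(self, grid, S) -> SurvivalCurveSet:
        # numerical jitter from ensemble averaging can leave tiny increases
        S = np.minimum.accumulate(np.clip(S, 0.0, 1.0), axis=1)
        return SurvivalCurveSet(grid=np.asarray(grid, dtype=float), S=S, tau=self._tau)


# ---------------------------------------------------------------------------
# Cox-family adapters
# ---------------------------------------------------------------------------


class CoxAdapter(SurvModelAdapter):
    """Unpenalized Cox proportional hazards (Breslow baseline)."""

    name = "cox"

    def _fit(self, cohort: Cohort) -> None:
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        self._est = CoxPHSurvivalAnalysis(
            alpha=self.hyperparams.get("alpha", 0.0), n_iter=200
        )
        self._est.fit(cohort.X.to_numpy(), _surv_y(cohort))
        if not np.all(np.isfinite(self._est.coef_)):
            raise FitError(f"{self.name}: non-finite coefficients (no convergence)")

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        S = self._est.predict_survival_function(X, return_array=True)
        return self._curveset(self._est.unique_times_, S)

    @property
    def coef_(self) -> np.ndarray:
        return self._est.coef_


class RidgeCoxAdapter(CoxAdapter):
    """Cox regression with an L2 (ridge) penalty."""

    name = "ridge_cox"

    def __init__(self, seed: int = 0, alpha: float = 1.0, **kw):
        super().__init__(seed=seed, alpha=alpha, **kw)


class _CoxnetAdapter(SurvModelAdapter):
    """Elastic-net-penalized Cox via coordinate descent."""

    l1_ratio_default = 0.5

    def _fit(self, cohort: Cohort) -> None:
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        alpha = float(self.hyperparams.get("alpha", 0.1))
        l1_ratio = float(self.hyperparams.get("l1_ratio", self.l1_ratio_default))
        self._est = CoxnetSurvivalAnalysis(
            alphas=[alpha], l1_ratio=l1_ratio, fit_baseline_model=True
        )
        self._est.fit(cohort.X.to_numpy(), _surv_y(cohort))

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        fns = self._est.predict_survival_function(X)
        grid = fns[0].x
        S = np.vstack([fn(grid) for fn in fns])
        return self._curveset(grid, S)

    @property
    def coef_(self) -> np.ndarray:
        return self._est.coef_[:, 0]


class LassoCoxAdapter(_CoxnetAdapter):
    """Cox regression with an L1 (lasso) penalty."""

    name = "lasso_cox"
    l1_ratio_default = 1.0

    def __init__(self, seed: int = 0, alpha: float = 0.1, **kw):
        super().__init__(seed=seed, alpha=alpha, l1_ratio=1.0, **kw)


class ENCoxAdapter(_CoxnetAdapter):
    """Cox regression with an elastic-net penalty."""

    name = "en_cox"

    def __init__(self, seed: int = 0, alpha: float = 0.1, l1_ratio: float = 0.5, **kw):
        super().__init__(seed=seed, alpha=alpha, l1_ratio=l1_ratio, **kw)


# ---------------------------------------------------------------------------
# tree-based adapters
# ---------------------------------------------------------------------------


class SurvivalTreeAdapter(SurvModelAdapter):
    """Single survival tree (log-rank splitting)."""

    name = "surv_tree"

    def __init__(self, seed: int = 0, max_depth: int = 5, min_samples_leaf: int = 20, **kw):
        super().__init__(seed=seed, max_depth=max_depth, min_samples_leaf=min_samples_leaf, **kw)

    def _fit(self, cohort: Cohort) -> None:
        from sksurv.tree import SurvivalTree

        self._est = SurvivalTree(
            max_depth=self.hyperparams["max_depth"],
            min_samples_leaf=self.hyperparams["min_samples_leaf"],
            random_state=self.seed,
        )
        self._est.fit(cohort.X.to_numpy(), _surv_y(cohort))

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        S = self._est.predict_survival_function(X, return_array=True)
        return self._curveset(self._est.unique_times_, S)


class RSFAdapter(SurvModelAdapter):
    """Random survival forest; curves via exp(-ensemble cumulative hazard)."""

    name = "rsf"

    def __init__(
        self,
        seed: int = 0,
        n_estimators: int = 100,
        min_samples_leaf: int = 25,
        max_features="sqrt",
        **kw,
    ):
        super().__init__(
            seed=seed,
            n_estimators=n_estimators,
            min_samples_leaf=min_samples_leaf,
            max_features=max_features,
            **kw,
        )

    def _fit(self, cohort: Cohort) -> None:
        from sksurv.ensemble import RandomSurvivalForest

        self._est = RandomSurvivalForest(
            n_estimators=int(self.hyperparams["n_estimators"]),
            min_samples_leaf=int(self.hyperparams["min_samples_leaf"]),
            max_features=self.hyperparams["max_features"],
            random_state=self.seed,
            n_jobs=1,
        )
        self._est.fit(cohort.X.to_numpy(), _surv_y(cohort))

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        chf = self._est.predict_cumulative_hazard_function(X, return_array=True)
        return self._curveset(self._est.unique_times_, np.exp(-chf))


# ---------------------------------------------------------------------------
# margin-based adapters (risk scores; curves via a Breslow baseline)
# ---------------------------------------------------------------------------


class SSVMAdapter(SurvModelAdapter):
    """Survival support vector machine, regression formulation.

    Predicts a (log) survival-time score; risk is its negation. No
    survival curve is available.
    """

    name = "ssvm"
    supports_curves = False

    def __init__(self, seed: int = 0, alpha: float = 1.0, **kw):
        super().__init__(seed=seed, alpha=alpha, **kw)

    def _fit(self, cohort: Cohort) -> None:
        from sksurv.svm import FastSurvivalSVM

        self._est = FastSurvivalSVM(
            alpha=float(self.hyperparams["alpha"]),
            rank_ratio=0.0,
            fit_intercept=True,
            max_iter=100,
            random_state=self.seed,
        )
        self._est.fit(cohort.X.to_numpy(), _surv_y(cohort))

    def _predict_risk(self, X: np.ndarray, t_star: float) -> np.ndarray:
        # larger predicted survival time = lower risk
        return -self._est.predict(X)


class XGBoostAdapter(SurvModelAdapter):
    """Gradient-boosted trees with a Cox proportional-hazards objective.

    The booster produces a log-hazard-ratio margin per subject; survival
    curves attach a Breslow baseline hazard estimated on the training
    cohort to those margins.
    """

    name = "xgboost"

    def __init__(
        self,
        seed: int = 0,
        max_depth: int = 3,
        learning_rate: float = 0.1,
        n_rounds: int = 100,
        subsample: float = 1.0,
        **kw,
    ):
        super().__init__(
            seed=seed,
            max_depth=max_depth,
            learning_rate=learning_rate,
            n_rounds=n_rounds,
            subsample=subsample,
            **kw,
        )

    def _fit(self, cohort: Cohort) -> None:
        import xgboost as xgb
        from sksurv.linear_model.coxph import BreslowEstimator

        # survival:cox encodes censoring as negative labels
        label = np.where(cohort.event == 1, cohort.time, -cohort.time)
        dtrain = xgb.DMatrix(cohort.X.to_numpy(), label=label)
        params = {
            "objective": "survival:cox",
            "max_depth": int(self.hyperparams["max_depth"]),
            "eta": float(self.hyperparams["learning_rate"]),
            "subsample": float(self.hyperparams["subsample"]),
            "seed": self.seed,
            "nthread": 1,
        }
        self._booster = xgb.train(
            params, dtrain, num_boost_round=int(self.hyperparams["n_rounds"])
        )
        margin = self._booster.predict(dtrain, output_margin=True)
        self._breslow = BreslowEstimator().fit(
            margin, cohort.event.astype(bool), cohort.time
        )
        self._grid = np.unique(cohort.time[cohort.event == 1])

    def _margin(self, X: np.ndarray) -> np.ndarray:
        import xgboost as xgb

        return self._booster.predict(xgb.DMatrix(X), output_margin=True)

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        fns = self._breslow.get_survival_function(self._margin(X))
        S = np.vstack([fn(self._grid) for fn in fns])
        return self._curveset(self._grid, S)


class SurvivalNeuralNetAdapter(SurvModelAdapter):
    """Feed-forward neural network trained on the Cox partial likelihood.

    A small multilayer perceptron maps standardized covariates to a
    log-hazard-ratio; training minimizes the negative Breslow partial
    likelihood with dropout regularization and Adam. Survival curves
    attach a Breslow baseline to the trained margins. Requires the
    optional ``torch`` dependency.
    """

    name = "snn"

    def __init__(
        self,
        seed: int = 0,
        n_hidden: int = 32,
        n_layers: int = 2,
        dropout: float = 0.2,
        lr: float = 1e-3,
        n_epochs: int = 256,
        **kw,
    ):
        super().__init__(
            seed=seed,
            n_hidden=n_hidden,
            n_layers=n_layers,
            dropout=dropout,
            lr=lr,
            n_epochs=n_epochs,
            **kw,
        )

    @staticmethod
    def available() -> bool:
        try:
            import torch  # noqa: F401

            return True
        except ImportError:
            return False

    @staticmethod
    def _require_torch():
        try:
            import torch

            return torch
        except ImportError as exc:
            raise MissingDependencyError(
                "the survival neural network adapter requires the optional "
                "'torch' dependency (pip install survbench[neural])"
            ) from exc

    def _fit(self, cohort: Cohort) -> None:
        torch = self._require_torch()
        from sksurv.linear_model.coxph import BreslowEstimator

        torch.manual_seed(self.seed)
        X = cohort.X.to_numpy(dtype=float)
        self._mu = X.mean(axis=0)
        self._sd = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = torch.tensor((X - self._mu) / self._sd, dtype=torch.float32)

        order = np.argsort(cohort.time)  # ascending; risk set = suffix
        Xs = Xs[order]
        ev = torch.tensor(cohort.event[order].astype(np.float32))

        layers: list = []
        width_in = X.shape[1]
        for _ in range(int(self.hyperparams["n_layers"])):
            layers += [
                torch.nn.Linear(width_in, int(self.hyperparams["n_hidden"])),
                torch.nn.ReLU(),
                torch.nn.Dropout(float(self.hyperparams["dropout"])),
            ]
            width_in = int(self.hyperparams["n_hidden"])
        layers.append(torch.nn.Linear(width_in, 1))
        net = torch.nn.Sequential(*layers)
        opt = torch.optim.Adam(net.parameters(), lr=float(self.hyperparams["lr"]))

        for _ in range(int(self.hyperparams["n_epochs"])):
            opt.zero_grad()
            eta = net(Xs).squeeze(-1)
            # Breslow partial likelihood: risk set of subject i is everyone
            # with time >= t_i, i.e. a suffix after ascending sort
            log_risk = torch.flip(
                torch.logcumsumexp(torch.flip(eta, (0,)), dim=0), (0,)
            )
            loss = -((eta - log_risk) * ev).sum() / ev.sum()
            loss.backward()
            opt.step()

        net.eval()
        self._net = net
        with torch.no_grad():
            margin = net(Xs).squeeze(-1).numpy()
        self._breslow = BreslowEstimator().fit(
            margin, cohort.event[order].astype(bool), cohort.time[order]
        )
        self._grid = np.unique(cohort.time[cohort.event == 1])

    def _margin(self, X: np.ndarray) -> np.ndarray:
        torch = self._require_torch()
        with torch.no_grad():
            Xs = torch.tensor((X - self._mu) / self._sd, dtype=torch.float32)
            return self._net(Xs).squeeze(-1).numpy()

    def _predict_survival(self, X: np.ndarray) -> SurvivalCurveSet:
        fns = self._breslow.get_survival_function(self._margin(X))
        S = np.vstack([fn(self._grid) for fn in fns])
        return self._curveset(self._grid, S)


# ---------------------------------------------------------------------------
# registry and tuning
# ---------------------------------------------------------------------------

_ADAPTERS: dict[str, type[SurvModelAdapter]] = {
    cls.name: cls
    for cls in (
        CoxAdapter,
        RidgeCoxAdapter,
        LassoCoxAdapter,
        ENCoxAdapter,
        SurvivalTreeAdapter,
        RSFAdapter,
        SSVMAdapter,
        SurvivalNeuralNetAdapter,
        XGBoostAdapter,
    )
}

ADAPTER_NAMES = tuple(_ADAPTERS)


def make_adapter(name: str, seed: int = 0, **hyperparams) -> SurvModelAdapter:
    if name not in _ADAPTERS:
        raise AdapterError(f"unknown adapter {name!r}; available: {sorted(_ADAPTERS)}")
    return _ADAPTERS[name](seed=seed, **hyperparams)


def available_adapters() -> tuple[str, ...]:
    """Adapter names whose dependencies are importable right now."""
    names = []
    for name in ADAPTER_NAMES:
        if name == "snn" and not SurvivalNeuralNetAdapter.available():
            continue
        names.append(name)
    return tuple(names)


def load_search_spaces() -> dict:
    text = resources.files("survbench").joinpath("search_spaces.yaml").read_text()
    return yaml.safe_load(text)


def _sample_point(space: dict, rng: np.random.Generator) -> dict:
    point = {}
    for param, cfg in space.items():
        kind = cfg["type"]
        if kind == "loguniform":
            point[param] = float(
                np.exp(rng.uniform(np.log(cfg["low"]), np.log(cfg["high"])))
            )
        elif kind == "uniform":
            point[param] = float(rng.uniform(cfg["low"], cfg["high"]))
        elif kind == "int_uniform":
            point[param] = int(rng.integers(cfg["low"], cfg["high"] + 1))
        elif kind == "choice":
            point[param] = cfg["values"][int(rng.integers(len(cfg["values"])))]
        else:
            raise TuningError(f"unknown search-space type {kind!r} for {param!r}")
    return point


def point_in_space(point: dict, space: dict) -> bool:
    for param, value in point.items():
        cfg = space.get(param)
        if cfg is None:
            return False
        kind = cfg["type"]
        if kind in ("loguniform", "uniform", "int_uniform"):
            if not cfg["low"] <= value <= cfg["high"]:
                return False
        elif kind == "choice" and value not in cfg["values"]:
            return False
    return True


@dataclass
class TunedConfig:
    """Outcome of a random grid search for one adapter."""

    name: str
    hyperparams: dict
    mean_cindex: float
    n_evals: int
    seed: int
    failures: int = 0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "hyperparams": dict(self.hyperparams),
            "mean_cindex": float(self.mean_cindex),
            "n_evals": self.n_evals,
            "seed": self.seed,
            "failures": self.failures,
        }


def tune(
    name: str,
    cohort: Cohort,
    n_evals: int,
    seed: int,
    t_star: float | None = None,
    space: dict | None = None,
    n_folds: int = 5,
) -> TunedConfig:
    """Random grid search scored by event-stratified k-fold CV c-index.

    Samples ``n_evals`` hyperparameter points uniformly from the
    adapter's declared space and returns the best by mean out-of-fold
    Harrell c-index; ties go to the earliest-sampled point. Candidates
    whose fit fails on any fold score -inf and are logged.
    """
    from sklearn.model_selection import StratifiedKFold

    if name == "cox":
        raise TuningError("unpenalized Cox regression has no hyperparameters to tune")
    if n_evals < 1:
        raise TuningError("n_evals must be >= 1")
    if space is None:
        spaces = load_search_spaces()
        if name not in spaces:
            raise TuningError(f"no declared search space for adapter {name!r}")
        space = spaces[name]
    t_star = cohort.tau if t_star is None else t_star

    rng = np.random.default_rng(seed)
    points = [_sample_point(space, rng) for _ in range(n_evals)]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    folds = list(skf.split(cohort.X, cohort.event))

    best_score, best_idx, n_failures = -np.inf, None, 0
    for idx, point in enumerate(points):
        scores = []
        try:
            for train_idx, test_idx in folds:
                adapter = make_adapter(name, seed=seed, **point)
                adapter.fit(cohort.subset(train_idx))
                test = cohort.subset(test_idx)
                risk = adapter.predict_risk(test.X, t_star)
                scores.append(harrell_cindex(test.time, test.event, risk))
            score = float(np.mean(scores))
        except Exception as exc:
            logger.warning("tune(%s): candidate %d failed: %s", name, idx, exc)
            n_failures += 1
            score = -np.inf
        if score > best_score:
            best_score, best_idx = score, idx
    if best_idx is None:
        raise TuningError(f"every candidate failed while tuning {name!r}")
    return TunedConfig(
        name=name,
        hyperparams=points[best_idx],
        mean_cindex=best_score,
        n_evals=n_evals,
        seed=seed,
        failures=n_failures,
    )
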