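"""Orchestration of the full Monte Carlo model comparison.

A *study* is a grid of conditions (registry preset x data-generating
process) replicated many times: per condition a synthetic seed cohort
is drawn, the DGP base model is fitted to it and per-subject survival
curves extracted; each replicate then simulates fresh outcomes from
those curves, splits the replicate into event-stratified folds, fits
every requested model on the training folds, and scores pooled
out-of-fold predictions with Harrell's c-index, the integrated
calibration index and the integrated Brier score.

Seeds derive from a master seed through a (condition, replicate, model)
hash tree, so reruns are bit-identical and adding models or replicates
never perturbs existing records. Studies are resumable from their
long-format results table.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .dgp_engine import DGPModel, SurvivalCurveSet, fit_dgp, predict_curves, simulate_cohort
from .model_zoo import CapabilityError, TunedConfig, make_adapter, tune
from .survival_metrics import (
    MetricError,
    fit_calibration,
    harrell_cindex,
    ici,
    integrated_brier,
)
from .synthetic_registry import make_nacc_like, make_prompt_like

__all__ = [
    "SimCondition",
    "ConditionContext",
    "StudyIntegrityError",
    "prepare_condition",
    "run_replicate",
    "run_study",
    "summarize",
    "METRICS",
    "RECORD_KEY",
]

logger = logging.getLogger(__name__)

METRICS = ("cindex", "ici", "ibs")
RECORD_KEY = ["condition", "dgp", "replicate", "model", "metric"]
_PRESET_MAKERS = {"prompt_like": make_prompt_like, "nacc_like": make_nacc_like}


class StudyIntegrityError(RuntimeError):
    """Conflicting or duplicated records in a study table."""


@dataclass
class SimCondition:
    """One cell of the simulation grid."""

    preset: str
    dgp: str
    n_replications: int = 50
    n_folds: int = 3
    t_star: float = 3.0

    def __post_init__(self) -> None:
        if self.preset not in _PRESET_MAKERS:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.dgp not in ("cox", "rsf"):
            raise ValueError(f"unknown DGP kind {self.dgp!r}")
        if self.n_replications < 1:
            raise ValueError("n_replications must be >= 1")
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")
        if not self.t_star > 0:
            raise ValueError("horizon t_star must be positive")

    @property
    def cid(self) -> str:
        return f"{self.preset}-{self.dgp}"


def _sub_seed(*parts) -> int:
    """Stable 31-bit seed from a path of labels under the master seed."""
    entropy = [zlib.crc32(str(p).encode()) & 0x7FFFFFFF for p in parts]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass
class ConditionContext:
    """Everything fixed across the replicates of one condition."""

    condition: SimCondition
    seed_cohort: Cohort
    dgp_model: DGPModel
    curves: SurvivalCurveSet
    tuned: dict[str, TunedConfig] = field(default_factory=dict)

    def hyperparams_for(self, model: str) -> dict:
        cfg = self.tuned.get(model)
        return dict(cfg.hyperparams) if cfg is not None else {}


def prepare_condition(
    condition: SimCondition,
    master_seed: int,
    models: tuple[str, ...] = (),
    tune_evals: int = 0,
) -> ConditionContext:
    """Draw the seed cohort, fit the DGP, and (optionally) tune models.

    Tuning happens once per condition on a pilot replicate simulated
    from the DGP, and the chosen hyperparameters are reused across all
    replicates. ``tune_evals=0`` skips tuning (library defaults apply).
    """
    cohort = _PRESET_MAKERS[condition.preset](
        _sub_seed(master_seed, condition.cid, "cohort")
    )
    dgp_model = fit_dgp(
        cohort, condition.dgp, seed=_sub_seed(master_seed, condition.cid, "dgp")
    )
    curves = predict_curves(dgp_model, cohort.X)
    ctx = ConditionContext(
        condition=condition, seed_cohort=cohort, dgp_model=dgp_model, curves=curves
    )
    if tune_evals > 0:
        pilot = simulate_cohort(
            curves,
            cohort.X,
            seed=_sub_seed(master_seed, condition.cid, "pilot"),
            col_types=cohort.col_types,
        )
        for model in models:
            if model == "cox":
                continue  # nothing to tune
            try:
                ctx.tuned[model] = tune(
                    model,
                    pilot,
                    n_evals=tune_evals,
                    seed=_sub_seed(master_seed, condition.cid, "tune", model),
                    t_star=condition.t_star,
                )
            except Exception as exc:
                logger.warning(
                    "tuning %s for %s failed (%s); using defaults",
                    model,
                    condition.cid,
                    exc,
                )
    return ctx


def _model_metrics(
    adapter_name: str,
    hyperparams: dict,
    sim: Cohort,
    folds,
    t_star: float,
    seed: int,
    fold_agg: str,
) -> dict[str, float | str | None]:
    """Fit one model across CV folds and compute the three metrics."""
    n = sim.n
    grid = np.unique(sim.time[sim.event == 1])
    grid = grid[grid <= t_star]
    risk = np.full(n, np.nan)
    p_tau = np.full(n, np.nan)
    S_pool = np.full((n, len(grid)), np.nan)
    has_curves = True

    per_fold: dict[str, list[float]] = {m: [] for m in METRICS}
    for train_idx, test_idx in folds:
        adapter = make_adapter(adapter_name, seed=seed, **hyperparams)
        adapter.fit(sim.subset(train_idx))
        test = sim.subset(test_idx)
        risk[test_idx] = adapter.predict_risk(test.X, t_star)
        if adapter.supports_curves:
            cs = adapter.predict_survival(test.X)
            S_pool[test_idx] = cs.evaluate(grid)
            p_tau[test_idx] = 1.0 - cs.evaluate([t_star])[:, 0]
        else:
            has_curves = False
        if fold_agg == "per_fold":
            per_fold["cindex"].append(
                harrell_cindex(test.time, test.event, risk[test_idx])
            )
            if adapter.supports_curves:
                fold_curves = SurvivalCurveSet(
                    grid=grid, S=S_pool[test_idx], tau=t_star
                )
                per_fold["ibs"].append(
                    integrated_brier(fold_curves, test.time, test.event)
                )
                per_fold["ici"].append(
                    ici(fit_calibration(p_tau[test_idx], test.time, test.event, t_star))
                )

    out: dict[str, float | str | None] = {}
    if fold_agg == "per_fold":
        out["cindex"] = float(np.mean(per_fold["cindex"]))
        if has_curves:
            out["ibs"] = float(np.mean(per_fold["ibs"]))
            out["ici"] = float(np.mean(per_fold["ici"]))
    else:
        out["cindex"] = harrell_cindex(sim.time, sim.event, risk)
        if has_curves:
            pooled = SurvivalCurveSet(grid=grid, S=S_pool, tau=t_star)
            out["ibs"] = integrated_brier(pooled, sim.time, sim.event)
            try:
                out["ici"] = ici(fit_calibration(p_tau, sim.time, sim.event, t_star))
            except MetricError as exc:
                out["ici"] = f"ici failed: {exc}"
    if not has_curves:
        reason = "no survival curves: only discrimination is defined"
        out["ibs"] = reason
        out["ici"] = reason
    return out


def run_replicate(
    ctx: ConditionContext,
    replicate: int,
    models: tuple[str, ...],
    master_seed: int,
    fold_agg: str = "pooled",
) -> list[dict]:
    """Simulate one replicate cohort and score every model on it.

    Returns one record per (model, metric); a model failure flags its
    records as missing with the reason and the replicate continues.
    """
    if fold_agg not in ("pooled", "per_fold"):
        raise ValueError(f"unknown fold aggregation {fold_agg!r}")
    from sklearn.model_selection import StratifiedKFold

    cond = ctx.condition
    sim = simulate_cohort(
        ctx.curves,
        ctx.seed_cohort.X,
        seed=_sub_seed(master_seed, cond.cid, "rep", replicate),
        col_types=ctx.seed_cohort.col_types,
    )
    skf = StratifiedKFold(
        n_splits=cond.n_folds,
        shuffle=True,
        random_state=_sub_seed(master_seed, cond.cid, "folds", replicate) % (2**32),
    )
    folds = list(skf.split(sim.X, sim.event))

    records = []
    for model in models:
        seed_m = _sub_seed(master_seed, cond.cid, "rep", replicate, "model", model)
        try:
            results = _model_metrics(
                model,
                ctx.hyperparams_for(model),
                sim,
                folds,
                cond.t_star,
                seed_m,
                fold_agg,
            )
        except Exception as exc:
            logger.warning(
                "%s replicate %d: model %s failed: %s", cond.cid, replicate, model, exc
            )
            results = {m: f"model failed: {exc}" for m in METRICS}
        for metric in METRICS:
            value = results.get(metric)
            failed = isinstance(value, str) or value is None
            records.append(
                {
                    "condition": cond.preset,
                    "dgp": cond.dgp,
                    "replicate": replicate,
                    "model": model,
                    "metric": metric,
                    "value": np.nan if failed else float(value),
                    "seed": seed_m,
                    "fold_agg": fold_agg,
                    "error": value if failed else "",
                }
            )
    return records


def _persist_tuned_configs(ctx: ConditionContext, out: Path) -> None:
    """Append the condition's chosen hyperparameters to a provenance file."""
    import yaml

    path = out.with_suffix(".tuned.yaml")
    record = {}
    if path.exists():
        record = yaml.safe_load(path.read_text()) or {}
    record[ctx.condition.cid] = {
        name: cfg.to_dict() for name, cfg in ctx.tuned.items()
    }
    path.write_text(yaml.safe_dump(record, sort_keys=True))


def _check_table(table: pd.DataFrame) -> None:
    if table.duplicated(subset=RECORD_KEY).any():
        dup = table[table.duplicated(subset=RECORD_KEY, keep=False)]
        raise StudyIntegrityError(
            f"duplicate records for keys:\n{dup[RECORD_KEY].drop_duplicates()}"
        )
    cind = table.loc[table["metric"] == "cindex", "value"].dropna()
    if ((cind < 0) | (cind > 1)).any():
        raise StudyIntegrityError("c-index records outside [0, 1]")
    others = table.loc[table["metric"].isin(("ici", "ibs")), "value"].dropna()
    if (others < 0).any():
        raise StudyIntegrityError("negative ICI/IBS records")


def run_study(
    conditions,
    models: tuple[str, ...],
    master_seed: int,
    out: str | Path | None = None,
    tune_evals: int = 50,
    fold_agg: str = "pooled",
    resume: bool = True,
) -> pd.DataFrame:
    """Run the full replication study and return the long-format table.

    If ``out`` exists and ``resume`` is true, records already present
    are kept and only missing (condition, replicate) cells are computed;
    the deterministic seed tree makes regenerated records identical to
    what a fresh run would have produced.
    """
    existing = pd.DataFrame(columns=RECORD_KEY + ["value", "seed", "fold_agg", "error"])
    if out is not None and Path(out).exists() and resume:
        existing = pd.read_csv(out, keep_default_na=False)
        existing["value"] = pd.to_numeric(existing["value"], errors="coerce")
        _check_table(existing)

    all_records = [existing] if len(existing) else []
    for cond in conditions:
        done = set()
        if len(existing):
            mask = (existing["condition"] == cond.preset) & (existing["dgp"] == cond.dgp)
            done = set(
                existing.loc[mask]
                .groupby("replicate")["model"]
                .agg(lambda s: frozenset(s))
                .loc[lambda s: s >= frozenset(models)]
                .index
            )
        todo = [r for r in range(cond.n_replications) if r not in done]
        if not todo:
            continue
        ctx = prepare_condition(cond, master_seed, models, tune_evals)
        if out is not None and ctx.tuned:
            _persist_tuned_configs(ctx, Path(out))
        for rep in todo:
            recs = run_replicate(ctx, rep, models, master_seed, fold_agg)
            all_records.append(pd.DataFrame(recs))
            if out is not None:
                partial = pd.concat(all_records, ignore_index=True)
                partial.to_csv(out, index=False)

    table = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else existing
    )
    _check_table(table)
    if out is not None:
        table.to_csv(out, index=False)
    return table


def summarize(table: pd.DataFrame, outdir: str | Path | None = None):
    """Per (condition, dgp, model, metric) summary, plus boxplot figures.

    Returns the summary frame; when ``outdir`` is given, writes
    ``summary.csv`` and one four-panel boxplot figure per metric
    (rows = registry preset, columns = DGP kind).
    """
    if len(table) == 0:
        raise ValueError("cannot summarize an empty table")
    grouped = table.groupby(["condition", "dgp", "model", "metric"])["value"]
    summary = grouped.agg(
        mean="mean",
        median="median",
        q25=lambda s: s.quantile(0.25),
        q75=lambda s: s.quantile(0.75),
        n_replicates=lambda s: int(s.notna().sum()),
    ).reset_index()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "summary.csv", index=False)
        _boxplot_figures(table, outdir)
    return summary


def _boxplot_figures(table: pd.DataFrame, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    presets = sorted(table["condition"].unique())
    dgps = sorted(table["dgp"].unique())
    models = sorted(table["model"].unique())
    for metric in table["metric"].unique():
        fig, axes = plt.subplots(
            len(presets),
            len(dgps),
            figsize=(5 * len(dgps), 3.5 * len(presets)),
            squeeze=False,
        )
        for i, preset in enumerate(presets):
            for j, dgp in enumerate(dgps):
                ax = axes[i][j]
                sub = table[
                    (table["condition"] == preset)
                    & (table["dgp"] == dgp)
                    & (table["metric"] == metric)
                ]
                data = [
                    sub.loc[sub["model"] == m, "value"].dropna().to_numpy()
                    for m in models
                ]
                ax.boxplot(data, tick_labels=models)
                ax.set_title(f"{preset}, {dgp} DGP")
                ax.set_ylabel(metric)
                ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        fig.savefig(outdir / f"{metric}_boxplots.png", dpi=120)
        plt.close(fig)
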