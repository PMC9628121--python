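"""Right-censored cohort container and its on-disk format.

A :class:`Cohort` holds one row per subject: an id, a mixed-type baseline
predictor matrix, an observed follow-up time in years, an event indicator
(1 = converted to dementia, 0 = right-censored) and the administrative
horizon ``tau`` (3 years by default throughout the package).

On disk a cohort is a delimited table ``id, x1..xp, time, event`` plus a
YAML sidecar carrying the horizon and per-column type metadata, so the
round trip is lossless to well beyond 12 significant digits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["Cohort", "CohortError"]

VALID_COL_TYPES = {"binary", "continuous", "ordinal"}


class CohortError(ValueError):
    """Raised when a cohort violates its structural invariants."""


@dataclass
class Cohort:
    """One row per subject: predictors plus a right-censored outcome."""

    X: pd.DataFrame
    time: np.ndarray
    event: np.ndarray
    tau: float
    subject_ids: np.ndarray | None = None
    col_types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = pd.DataFrame(self.X)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.subject_ids is None:
            self.subject_ids = np.arange(1, len(self.X) + 1)
        self.subject_ids = np.asarray(self.subject_ids)
        if not self.col_types:
            self.col_types = {c: "continuous" for c in self.X.columns}
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        n = len(self.X)
        if n == 0:
            raise CohortError("cohort is empty")
        if len(self.time) != n or len(self.event) != n or len(self.subject_ids) != n:
            raise CohortError(
                f"length mismatch: X has {n} rows, time {len(self.time)}, "
                f"event {len(self.event)}, ids {len(self.subject_ids)}"
            )
        if len(np.unique(self.subject_ids)) != n:
            raise CohortError("subject ids are not unique")
        if self.X.isna().any().any():
            raise CohortError("predictor matrix contains missing values")
        if np.any(~np.isfinite(self.time)) or np.any(self.time <= 0):
            raise CohortError("all observed times must be finite and positive")
        if not np.isin(self.event, (0, 1)).all():
            raise CohortError("event indicator must be 0 or 1")
        if not self.tau > 0:
            raise CohortError(f"horizon tau must be positive, got {self.tau}")
        # administrative censoring at the horizon bounds every observed time
        if np.isfinite(self.tau) and np.any(self.time > self.tau + 1e-12):
            raise CohortError("observed times exceed the administrative horizon tau")
        bad = set(self.col_types) - set(self.X.columns)
        if bad or set(self.X.columns) - set(self.col_types):
            raise CohortError("col_types does not match predictor columns")
        unknown = set(self.col_types.values()) - VALID_COL_TYPES
        if unknown:
            raise CohortError(f"unknown column types: {sorted(unknown)}")

    # -- conveniences ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.X)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @property
    def event_fraction(self) -> float:
        return float(self.event.mean())

    def subset(self, idx) -> "Cohort":
        idx = np.asarray(idx)
        return Cohort(
            X=self.X.iloc[idx].reset_index(drop=True),
            time=self.time[idx],
            event=self.event[idx],
            tau=self.tau,
            subject_ids=self.subject_ids[idx],
            col_types=dict(self.col_types),
        )

    # -- I/O -------------------------------------------------------------

    def to_files(self, table_path: str | Path, meta_path: str | Path | None = None) -> None:
        table_path = Path(table_path)
        if meta_path is None:
            meta_path = table_path.with_suffix(".meta.yaml")
        df = self.X.copy()
        df.insert(0, "id", self.subject_ids)
        df["time"] = self.time
        df["event"] = self.event
        df.to_csv(table_path, index=False, float_format="%.17g")
        meta = {
            "tau": float(self.tau),
            "col_types": dict(self.col_types),
        }
        Path(meta_path).write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def from_files(cls, table_path: str | Path, meta_path: str | Path | None = None) -> "Cohort":
        table_path = Path(table_path)
        if meta_path is None:
            meta_path = table_path.with_suffix(".meta.yaml")
        meta = yaml.safe_load(Path(meta_path).read_text())
        df = pd.read_csv(table_path)
        xcols = [c for c in df.columns if c not in ("id", "time", "event")]
        return cls(
            X=df[xcols],
            time=df["time"].to_numpy(),
            event=df["event"].to_numpy(),
            tau=float(meta["tau"]),
            subject_ids=df["id"].to_numpy(),
            col_types=dict(meta["col_types"]),
        )
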