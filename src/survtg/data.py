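"""Right-censored survival data: container, delimited-text I/O, Kaplan-Meier anchor.

The central container is :class:`SurvivalDataset`, a thin column-oriented
wrapper around numpy arrays holding, per subject, the observed follow-up time
``X_i = min(T_i, C_i)``, the event indicator ``delta_i = 1{T_i <= C_i}`` and a
covariate vector ``z_i``.  Simulated datasets may additionally carry the
latent (uncensored) event times, which downstream generators use to apply
censoring mechanisms or contamination without re-simulating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalRecord",
    "SurvivalDataset",
    "read_dataset",
    "write_dataset",
    "kaplan_meier",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """One subject: follow-up time, event indicator and covariate vector."""

    time: float
    event: int
    covariates: tuple[float, ...]
    group: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"time must be a finite non-negative real, got {self.time!r}")
        if self.event not in (0, 1):
            raise ValueError(f"event indicator must be 0 or 1, got {self.event!r}")


@dataclass
class SurvivalDataset:
    """Column-oriented right-censored survival data.

    Parameters
    ----------
    times : observed follow-up times, shape (n,)
    events : event indicators in {0, 1}, shape (n,)
    covariates : covariate matrix, shape (n, p); may have p = 0
    covariate_names : labels for the p covariate columns
    groups : optional per-subject categorical labels (e.g. treatment arm)
    true_times : optional latent event times (simulation only)
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    groups: np.ndarray | None = None
    true_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.events = np.asarray(self.events)
        self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if self.covariates.shape[0] != self.times.shape[0] and self.covariates.size == 0:
            self.covariates = np.empty((self.times.shape[0], 0))
        n = self.times.shape[0]
        if n < 2:
            raise ValueError("a survival dataset needs at least 2 subjects")
        if self.events.shape[0] != n or self.covariates.shape[0] != n:
            raise ValueError("times, events and covariates must have one row per subject")
        if np.any(self.times < 0) or not np.all(np.isfinite(self.times)):
            bad = int(np.flatnonzero((self.times < 0) | ~np.isfinite(self.times))[0])
            raise ValueError(f"non-finite or negative time in row {bad}")
        if not np.isin(self.events, (0, 1)).all():
            bad = int(np.flatnonzero(~np.isin(self.events, (0, 1)))[0])
            raise ValueError(f"event indicator outside {{0,1}} in row {bad}")
        self.events = self.events.astype(int)
        if not self.covariate_names:
            self.covariate_names = [f"z{j}" for j in range(self.covariates.shape[1])]
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length must match covariate columns")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape[0] != n:
                raise ValueError("groups must have one entry per subject")

    @property
    def n(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[SurvivalRecord]:
        for i in range(self.n):
            yield SurvivalRecord(
                time=float(self.times[i]),
                event=int(self.events[i]),
                covariates=tuple(self.covariates[i]),
                group=None if self.groups is None else self.groups[i],
            )

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        """Row subset / resample (used by the bootstrap)."""
        return SurvivalDataset(
            times=self.times[idx],
            events=self.events[idx],
            covariates=self.covariates[idx],
            covariate_names=list(self.covariate_names),
            groups=None if self.groups is None else self.groups[idx],
            true_times=None if self.true_times is None else self.true_times[idx],
        )

    def copy(self) -> "SurvivalDataset":
        return SurvivalDataset(
            times=self.times.copy(),
            events=self.events.copy(),
            covariates=self.covariates.copy(),
            covariate_names=list(self.covariate_names),
            groups=None if self.groups is None else self.groups.copy(),
            true_times=None if self.true_times is None else self.true_times.copy(),
        )

    def to_dataframe(self, time_col: str = "time", event_col: str = "event") -> pd.DataFrame:
        df = pd.DataFrame({time_col: self.times, event_col: self.events})
        for j, name in enumerate(self.covariate_names):
            df[name] = self.covariates[:, j]
        if self.groups is not None:
            df["group"] = self.groups
        return df


def read_dataset(
    path,
    time_col: str = "time",
    event_col: str = "event",
    covariate_cols: Sequence[str] | None = None,
    delimiter: str = ",",
    group_col: str | None = None,
) -> SurvivalDataset:
    """Read a delimited-text survival dataset (one row per subject).

    Missing values in any used column are an error: silent imputation would
    change the estimand.  Row numbers in error messages are 1-based data rows
    (header excluded).
    """
    df = pd.read_csv(path, sep=delimiter)
    if covariate_cols is None:
        reserved = {time_col, event_col, group_col}
        covariate_cols = [c for c in df.columns if c not in reserved]
    needed = [time_col, event_col, *covariate_cols] + ([group_col] if group_col else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"column(s) {missing} not found in {path}; available: {list(df.columns)}")

    used = df[needed]
    if used.isna().any().any():
        row = int(used.isna().any(axis=1).idxmax()) + 1
        raise ValueError(f"missing value in a used column at row {row}")

    times = pd.to_numeric(df[time_col], errors="coerce")
    if times.isna().any() or (times < 0).any():
        row = int((times.isna() | (times < 0)).idxmax()) + 1
        raise ValueError(f"non-numeric or negative time value at row {row}")
    events = pd.to_numeric(df[event_col], errors="coerce")
    if events.isna().any() or ~events.isin((0, 1)).all():
        row = int((events.isna() | ~events.isin((0, 1))).idxmax()) + 1
        raise ValueError(f"event indicator outside {{0,1}} at row {row}")

    return SurvivalDataset(
        times=times.to_numpy(float),
        events=events.to_numpy(int),
        covariates=df[list(covariate_cols)].to_numpy(float)
        if covariate_cols
        else np.empty((len(df), 0)),
        covariate_names=list(covariate_cols),
        groups=df[group_col].to_numpy() if group_col else None,
    )


def write_dataset(
    dataset: SurvivalDataset,
    path,
    time_col: str = "time",
    event_col: str = "event",
    delimiter: str = ",",
) -> None:
    """Write the dataset as delimited text (inverse of :func:`read_dataset`)."""
    dataset.to_dataframe(time_col, event_col).to_csv(path, sep=delimiter, index=False)


def kaplan_meier(dataset: SurvivalDataset, t_star):
    """Product-limit estimate of the marginal survival probability S(t*).

    ``t_star`` may be a scalar or an array of times (the estimator is fitted
    once either way).  Right-continuous convention: events at exactly
    ``t_star`` are counted.  With tied death and censoring times the deaths
    precede the censorings, as in the conventional estimator.  Beyond the
    largest observed time the last value is carried forward (with a logged
    warning) so the marginal anchor pi0(t) stays defined for any
    user-requested time.
    """
    scalar = np.isscalar(t_star)
    ts = np.atleast_1d(np.asarray(t_star, dtype=float))
    if np.any(ts < 0):
        raise ValueError(f"t_star must be non-negative, got {t_star}")
    if dataset.n_events == 0 and ts.max() >= dataset.times.min():
        raise ValueError("cannot estimate survival: dataset has no events")
    km = KaplanMeierFitter().fit(dataset.times, dataset.events)
    if ts.max() > dataset.times.max():
        logger.warning(
            "kaplan_meier: t*=%g exceeds the last observed time %g; carrying the last value forward",
            ts.max(),
            dataset.times.max(),
        )
    values = km.predict(ts)
    out = np.atleast_1d(np.asarray(values, dtype=float))
    return float(out[0]) if scalar else out
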