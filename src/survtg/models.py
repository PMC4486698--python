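"""Fitted survival models exposing the two quantities the TG machinery needs.

Every predictor supplies, for a compatible dataset,

* a per-subject *prognostic index* (PI) — for a Cox model the linear
  predictor ``beta' z_i`` — used only through its ranks, and
* predicted survival probabilities ``S(t | z_i)`` at requested times.

Two concrete predictors are provided: a Cox proportional-hazards fit
(wrapping :class:`lifelines.CoxPHFitter`, Efron tie handling, Breslow-type
baseline) and a saturated per-group Weibull fit for arm-structured data with
possibly crossing hazards, parameterised through the cumulative hazard
``H(t) = scale * t**shape``.
"""

from __future__ import annotations

import warnings
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy.optimize import minimize_scalar

from .data import SurvivalDataset

__all__ = [
    "SurvivalPredictor",
    "CoxPredictor",
    "WeibullArmFit",
    "GroupWeibullPredictor",
    "fit_cox",
    "fit_group_weibull",
    "predict_survival_matrix",
]


class SurvivalPredictor(ABC):
    """Contract for a fitted survival model."""

    meta: dict

    @abstractmethod
    def prognostic_index(self, dataset: SurvivalDataset) -> np.ndarray:
        """Per-subject prognostic index, aligned with record order."""

    @abstractmethod
    def predict_survival(self, dataset: SurvivalDataset, times) -> np.ndarray:
        """S(t | z_i) for each subject; shape (n,) for scalar t, else (n, len(times))."""


def _check_times(times):
    scalar = np.isscalar(times)
    ts = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(ts < 0):
        raise ValueError(f"evaluation times must be non-negative, got {times}")
    return scalar, ts


class CoxPredictor(SurvivalPredictor):
    """Cox proportional-hazards model ``h(t|z) = h0(t) exp(beta'z)``.

    Predictions use the Breslow-type baseline cumulative hazard, so
    ``S(t|z) = S0(t) ** exp(beta'z)``; the prognostic index is ``beta'z``.
    """

    def __init__(self, fitter: CoxPHFitter, covariate_names: list[str]):
        self._fitter = fitter
        self._names = list(covariate_names)
        self.beta = fitter.params_.to_numpy()
        self.meta = {
            "model": "cox",
            "coef": dict(zip(self._names, map(float, self.beta))),
            "log_likelihood": float(fitter.log_likelihood_),
            "baseline": "breslow cumulative hazard",
        }
        # Baseline survival on the linear-predictor scale: lifelines centers
        # covariates internally, so fold the centering back out once.
        bch = fitter.baseline_cumulative_hazard_
        self._bch_times = bch.index.to_numpy(float)
        offset = float(np.dot(fitter._norm_mean.to_numpy(), self.beta))
        self._bch_values = bch.iloc[:, 0].to_numpy(float) * np.exp(-offset)

    def prognostic_index(self, dataset: SurvivalDataset) -> np.ndarray:
        self._check_compat(dataset)
        return dataset.covariates @ self.beta

    def _check_compat(self, dataset: SurvivalDataset) -> None:
        if dataset.covariates.shape[1] != len(self._names):
            raise ValueError(
                f"dataset has {dataset.covariates.shape[1]} covariates, model expects {len(self._names)}"
            )

    def _baseline_cumhaz(self, ts: np.ndarray) -> np.ndarray:
        # right-continuous step function, 0 before the first event time
        idx = np.searchsorted(self._bch_times, ts, side="right") - 1
        out = np.where(idx >= 0, self._bch_values[np.clip(idx, 0, None)], 0.0)
        return out

    def predict_survival(self, dataset: SurvivalDataset, times) -> np.ndarray:
        scalar, ts = _check_times(times)
        pi = self.prognostic_index(dataset)
        h0 = self._baseline_cumhaz(ts)  # (k,)
        surv = np.exp(-np.outer(np.exp(pi), h0))  # (n, k)
        return surv[:, 0] if scalar else surv


def fit_cox(dataset: SurvivalDataset) -> CoxPredictor:
    """Maximum partial likelihood Cox fit (Efron tie correction).

    Raises on degenerate inputs: fewer than two events, a constant covariate
    column, or non-convergence (including monotone likelihood under perfect
    separation, which lifelines reports as a convergence failure).
    """
    if dataset.covariates.shape[1] == 0:
        raise ValueError("fit_cox requires at least one covariate")
    if dataset.n_events < 2:
        raise ValueError("fit_cox requires at least 2 events")
    sd = dataset.covariates.std(axis=0)
    if np.any(sd == 0):
        j = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"covariate {dataset.covariate_names[j]!r} is constant")

    df = dataset.to_dataframe("__time", "__event")
    df = df[["__time", "__event", *dataset.covariate_names]]
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="__time", event_col="__event")
    except ConvergenceError as err:
        raise RuntimeError(f"Cox partial-likelihood maximisation failed: {err}") from err
    return CoxPredictor(fitter, dataset.covariate_names)


@dataclass(frozen=True)
class WeibullArmFit:
    """Weibull fit for one arm, with cumulative hazard H(t) = scale * t**shape."""

    arm: str
    scale: float
    shape: float

    def survival(self, times) -> np.ndarray:
        ts = np.asarray(times, dtype=float)
        return np.exp(-self.scale * ts**self.shape)


def _fit_weibull_mle(
    times: np.ndarray, events: np.ndarray, fix_shape: float | None = None
) -> tuple[float, float]:
    """Right-censored MLE of (scale, shape) for H(t) = scale * t**shape.

    The scale maximising the likelihood at fixed shape rho is
    d / sum(t_i**rho), so only a one-dimensional profile search over the
    shape is needed.
    """
    d = int(events.sum())
    if d == 0:
        raise ValueError("cannot fit a Weibull model to an arm with no events")
    t = np.asarray(times, dtype=float)
    if np.any(t[events == 1] <= 0):
        raise ValueError("event times must be strictly positive for a Weibull fit")
    t_pos = np.clip(t, np.finfo(float).tiny, None)
    log_t_events = np.log(t[events == 1]).sum()

    def neg_profile_loglik(log_rho: float) -> float:
        rho = np.exp(log_rho)
        s = np.sum(t_pos**rho)
        scale = d / s
        return -(d * np.log(scale) + d * np.log(rho) + (rho - 1.0) * log_t_events - d)

    if fix_shape is not None:
        rho = float(fix_shape)
    else:
        res = minimize_scalar(
            neg_profile_loglik, bounds=(np.log(1e-3), np.log(1e3)), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success:
            raise RuntimeError(f"Weibull shape optimisation failed: {res.message}")
        rho = float(np.exp(res.x))
    scale = d / float(np.sum(t_pos**rho))
    return scale, rho


class GroupWeibullPredictor(SurvivalPredictor):
    """Saturated per-group Weibull model for arm-structured data.

    Each group gets its own (scale, shape), so the implied hazard ratio
    between arms is free to vary (and cross) over time.  The prognostic
    index is the lexicographic rank of the group label — with two arms TG is
    invariant to which arm ranks first, so the order is fixed but arbitrary.
    """

    def __init__(self, fits: dict[str, WeibullArmFit]):
        self.fits = fits
        self._order = {g: i for i, g in enumerate(sorted(fits, key=str))}
        self.meta = {
            "model": "weibull-by-group",
            "arms": {str(g): {"scale": f.scale, "shape": f.shape} for g, f in fits.items()},
        }

    def prognostic_index(self, dataset: SurvivalDataset) -> np.ndarray:
        groups = self._groups_of(dataset)
        return np.array([self._order[g] for g in groups], dtype=float)

    def _groups_of(self, dataset: SurvivalDataset):
        if dataset.groups is None:
            raise ValueError("dataset has no group labels; fit/predict requires them")
        unknown = set(dataset.groups) - set(self.fits)
        if unknown:
            raise ValueError(f"dataset contains unfitted group(s): {sorted(map(str, unknown))}")
        return dataset.groups

    def predict_survival(self, dataset: SurvivalDataset, times) -> np.ndarray:
        scalar, ts = _check_times(times)
        groups = self._groups_of(dataset)
        out = np.empty((dataset.n, ts.size))
        for g, fit in self.fits.items():
            mask = groups == g
            out[mask] = fit.survival(ts)[None, :]
        return out[:, 0] if scalar else out


def fit_group_weibull(
    dataset: SurvivalDataset, fix_shape: float | None = None
) -> GroupWeibullPredictor:
    """Per-group right-censored Weibull MLE, S(t) = exp(-scale * t**shape).

    ``fix_shape=1`` gives the exponential sub-case, whose scale MLE is the
    classical events / total-exposure estimator.
    """
    if dataset.groups is None:
        raise ValueError("fit_group_weibull requires group labels on the dataset")
    fits: dict[str, WeibullArmFit] = {}
    for g in sorted(set(dataset.groups), key=str):
        mask = dataset.groups == g
        if dataset.events[mask].sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 events")
        scale, shape = _fit_weibull_mle(
            dataset.times[mask], dataset.events[mask], fix_shape=fix_shape
        )
        fits[g] = WeibullArmFit(arm=str(g), scale=scale, shape=shape)
    return GroupWeibullPredictor(fits)


def predict_survival_matrix(
    model: SurvivalPredictor, dataset: SurvivalDataset, t_star
) -> np.ndarray:
    """Predicted survival probabilities S(t*|z_i) aligned with record order."""
    return model.predict_survival(dataset, t_star)
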