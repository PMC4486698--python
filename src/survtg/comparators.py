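"""Comparator predictive-ability measures for benchmarking TG_STD(t).

* ``r2_bs`` — the nonparametric Brier-score R-squared at a time point,
  censoring-corrected by inverse-probability-of-censoring weights (IPCW).
* ``r2_pm`` — a function of the variance of the prognostic index.
* ``r2_d`` — Royston-Sauerbrei D-based R-squared from normal rankits.
* ``rho2_w`` — explained randomness from the partial-likelihood gain of the
  full over the null model (Kent-O'Quigley style).

The first is time-dependent like TG_STD(t); the other three summarise the
whole follow-up period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from .data import SurvivalDataset, kaplan_meier
from .predictiveness import MeasureEstimate

__all__ = ["IPCWWeights", "ipcw_weights", "r2_bs", "r2_pm", "r2_d", "rho2_w"]

_KAPPA = np.sqrt(8.0 / np.pi)  # rankit scaling in Royston-Sauerbrei's D
_SIGMA2 = np.pi**2 / 6.0  # variance of a standard Gumbel log-time error


@dataclass(frozen=True)
class IPCWWeights:
    """Per-subject inverse-probability-of-censoring weights at a time t.

    Built from the Kaplan-Meier estimate G of the censoring distribution
    (flipped event indicator).  Subjects with an event by t are weighted by
    1/G(X-), subjects still at risk at t by 1/G(t), and subjects censored
    before t without an event get weight zero.
    """

    t_star: float
    weights: np.ndarray


def _censoring_km_step(dataset: SurvivalDataset):
    """Step-function data (times, values) for the censoring-distribution KM.

    Censorings are the "events" here.  With a death and a censoring tied at
    the same time the death precedes the censoring in the event-time
    estimator, so symmetrically the censoring-KM drop at time x applies only
    strictly after the deaths at x; the left-limit evaluation below handles
    this through strict inequality.
    """
    km = KaplanMeierFitter().fit(dataset.times, 1 - dataset.events)
    sf = km.survival_function_
    return sf.index.to_numpy(float), sf.iloc[:, 0].to_numpy(float)


def _step_eval(times: np.ndarray, values: np.ndarray, at: np.ndarray, left: bool) -> np.ndarray:
    side = "left" if left else "right"
    idx = np.searchsorted(times, at, side=side) - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], 1.0)


def ipcw_weights(dataset: SurvivalDataset, t_star: float) -> IPCWWeights:
    """Graf-style IPCW weights at ``t_star`` from the censoring-distribution KM."""
    times, values = _censoring_km_step(dataset)
    g_at_t = float(_step_eval(times, values, np.array([t_star]), left=False)[0])
    if g_at_t <= 0.0:
        raise ValueError(f"no follow-up information at t={t_star:g}: G(t)=0")
    g_left = _step_eval(times, values, dataset.times, left=True)
    w = np.zeros(dataset.n)
    had_event = (dataset.times <= t_star) & (dataset.events == 1)
    at_risk = dataset.times > t_star
    w[had_event] = 1.0 / g_left[had_event]
    w[at_risk] = 1.0 / g_at_t
    return IPCWWeights(t_star=float(t_star), weights=w)


def r2_bs(dataset: SurvivalDataset, predictions, t_star: float) -> MeasureEstimate:
    """Brier-score R-squared at ``t_star``: 1 - BS_model / BS_null.

    BS(t) is the IPCW-weighted mean squared error between the survival
    status indicator 1{T > t} and the predicted survival probability; the
    null prediction is the pooled Kaplan-Meier estimate.  On uncensored data
    the weights are identically one and BS is the plain mean squared error.
    """
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape[0] != dataset.n:
        raise ValueError("one prediction per subject required")
    w = ipcw_weights(dataset, t_star).weights
    alive = (dataset.times > t_star).astype(float)
    bs_model = float(np.mean(w * (alive - predictions) ** 2))
    null_pred = kaplan_meier(dataset, t_star)
    bs_null = float(np.mean(w * (alive - null_pred) ** 2))
    if bs_null == 0.0:
        raise ValueError("null Brier score is 0: no outcome variability at t")
    return MeasureEstimate(name="R2_BS", value=1.0 - bs_model / bs_null, t_star=float(t_star))


def r2_pm(pi) -> MeasureEstimate:
    """Prognostic-index-variance R-squared: Var(PI) / (Var(PI) + pi^2/6)."""
    pi = np.asarray(pi, dtype=float)
    v = float(np.var(pi, ddof=1))
    if v == 0.0:
        raise ValueError("prognostic index has zero variance")
    return MeasureEstimate(name="R2_PM", value=v / (v + _SIGMA2))


def r2_d(pi, dataset: SurvivalDataset) -> MeasureEstimate:
    """Royston-Sauerbrei D-based R-squared.

    Subjects are ordered by prognostic index; Blom normal rankits scaled by
    1/kappa (kappa = sqrt(8/pi)) form an auxiliary covariate whose Cox
    coefficient is the prognostic-separation statistic D, and
    R2_D = (D^2/kappa^2) / (D^2/kappa^2 + pi^2/6).
    """
    from .models import fit_cox  # deferred to avoid an import cycle

    pi = np.asarray(pi, dtype=float)
    if np.var(pi) == 0.0:
        raise ValueError("prognostic index has zero variance")
    n = pi.size
    ranks = np.empty(n, dtype=float)
    ranks[np.argsort(pi, kind="stable")] = np.arange(1, n + 1)
    rankits = norm.ppf((ranks - 0.375) / (n + 0.25))  # Blom approximation
    aux = SurvivalDataset(
        times=dataset.times,
        events=dataset.events,
        covariates=(rankits / _KAPPA)[:, None],
        covariate_names=["scaled_rankit"],
    )
    d_stat = float(fit_cox(aux).beta[0])
    d2k2 = d_stat**2 / _KAPPA**2
    return MeasureEstimate(name="R2_D", value=d2k2 / (d2k2 + _SIGMA2))


def _null_partial_loglik(dataset: SurvivalDataset) -> float:
    """Cox partial log-likelihood of the covariate-free model (Efron ties).

    With beta = 0 every subject's relative hazard is 1, so each of the d_j
    tied events at an event time contributes -log(n_j - l) for
    l = 0..d_j - 1, n_j being the at-risk count.
    """
    order = np.argsort(dataset.times, kind="stable")
    times = dataset.times[order]
    events = dataset.events[order]
    ll = 0.0
    n = dataset.n
    for t in np.unique(times[events == 1]):
        n_at_risk = n - int(np.searchsorted(times, t, side="left"))
        d = int(((times == t) & (events == 1)).sum())
        ll -= sum(np.log(n_at_risk - l) for l in range(d))
    return ll


def rho2_w(dataset: SurvivalDataset, model=None) -> MeasureEstimate:
    """Entropy-based explained randomness: 1 - exp(-2 * Gamma).

    Gamma is the per-event average gain in Cox partial log-likelihood of the
    full model over the null model.  This is one member of the
    Kent-O'Quigley family; variants normalising per subject instead of per
    event exist, so the measure is validated here only through range and
    monotonicity properties, not against external point values.
    """
    from .models import fit_cox

    if dataset.n_events < 2:
        raise ValueError("rho2_w requires at least 2 events")
    if model is None or "log_likelihood" not in getattr(model, "meta", {}):
        model = fit_cox(dataset)
    ll_full = model.meta["log_likelihood"]
    gamma = (ll_full - _null_partial_loglik(dataset)) / dataset.n_events
    return MeasureEstimate(name="rho2_W", value=1.0 - float(np.exp(-2.0 * gamma)))
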