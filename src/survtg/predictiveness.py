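"""Predictiveness curve and the total gain statistics TG(t) and TG_STD(t).

The predictiveness curve at a time ``t*`` plots the model-predicted survival
probability ``R(v; t*)`` against the proportional rank ``v`` of the
prognostic index.  The total gain

    TG(t*) = integral over v in (0,1] of |R(v; t*) - pi0(t*)|

is the area between the curve and the horizontal marginal-survival anchor
``pi0(t*)`` (the pooled Kaplan-Meier estimate).  Its upper bound
``2 pi0 (1 - pi0)`` standardises it to ``TG_STD in [0, 1]``.

The empirical integral is the equal-weight mean over subjects (rectangle
rule on the v-grid i/n): for a step-shaped curve this is exactly the shaded
area between curve and anchor, and it makes the two-group closed form
``TG = 2 p (1-p) |S1 - S2|`` exact.

The binary-outcome total gain is the same computation with predicted event
probabilities as the curve and prevalence as the anchor; there is no
separate code path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .data import SurvivalDataset, kaplan_meier

logger = logging.getLogger(__name__)

__all__ = [
    "PredictivenessCurve",
    "MeasureEstimate",
    "BinaryRiskSet",
    "build_curve",
    "total_gain",
    "total_gain_std",
    "r2_pepe",
    "schemper_v_binary",
    "bootstrap_ci",
    "write_curve",
    "read_curve",
]


@dataclass(frozen=True)
class MeasureEstimate:
    """A named predictive-ability statistic, optionally with a bootstrap CI."""

    name: str
    value: float
    t_star: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class PredictivenessCurve:
    """Ranked pairs (v_i, R(v_i; t*)) plus the marginal anchor pi0(t*).

    ``upsilon[i] = (i+1)/n`` are the proportional ranks of the prognostic
    index; ``risk[i]`` is the predicted survival probability of the subject
    at sorted PI position i.
    """

    upsilon: np.ndarray
    risk: np.ndarray
    t_star: float
    pi0: float

    def __post_init__(self) -> None:
        if len(self.upsilon) != len(self.risk):
            raise ValueError("upsilon and risk must have equal length")
        if len(self.risk) == 0:
            raise ValueError("empty predictiveness curve")
        if np.any((self.risk < 0) | (self.risk > 1)):
            raise ValueError("risk values must lie in [0, 1]")
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError(f"pi0 must lie in [0, 1], got {self.pi0}")

    @property
    def n(self) -> int:
        return len(self.risk)


def build_curve(predictions, pi, pi0: float, t_star: float) -> PredictivenessCurve:
    """Assemble the predictiveness curve from per-subject quantities.

    Subjects are ordered by prognostic index ascending (stable sort, so PI
    ties keep original record order — TG is unaffected by the tie-break
    since absolute deviations are permutation-invariant); ranks are i/n.
    The curve depends on the PI only through this ordering, hence is
    invariant under strictly monotone PI transformations.
    """
    predictions = np.asarray(predictions, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if predictions.size == 0:
        raise ValueError("no predictions supplied")
    if predictions.shape != pi.shape:
        raise ValueError("predictions and prognostic index must have equal length")
    order = np.argsort(pi, kind="stable")
    n = predictions.size
    return PredictivenessCurve(
        upsilon=np.arange(1, n + 1) / n,
        risk=predictions[order],
        t_star=float(t_star),
        pi0=float(pi0),
    )


def total_gain(curve: PredictivenessCurve) -> MeasureEstimate:
    """TG(t*): empirical integral of |R(v;t*) - pi0(t*)| over the rank grid."""
    value = float(np.mean(np.abs(curve.risk - curve.pi0)))
    return MeasureEstimate(name="TG", value=value, t_star=curve.t_star)


def total_gain_std(curve: PredictivenessCurve) -> MeasureEstimate:
    """TG_STD(t*) = TG(t*) / (2 pi0 (1 - pi0)), the standardised total gain.

    Ranges from 0 (uninformative model) to 1 (perfect step-function curve).
    A value above 1 signals an incompatibility between predictions and the
    marginal anchor (e.g. a badly misspecified model); it is returned
    unmodified with a warning rather than clipped.
    """
    if curve.pi0 in (0.0, 1.0):
        raise ValueError("standardisation undefined: pi0(t*) is 0 or 1")
    bound = 2.0 * curve.pi0 * (1.0 - curve.pi0)
    value = total_gain(curve).value / bound
    if value > 1.0:
        warnings.warn(
            f"TG_STD(t*={curve.t_star:g}) = {value:.4f} exceeds 1: predictions and "
            "marginal anchor look incompatible",
            stacklevel=2,
        )
    return MeasureEstimate(name="TG_STD", value=value, t_star=curve.t_star)


def r2_pepe(curve: PredictivenessCurve) -> MeasureEstimate:
    """Squared-error-loss analogue of TG_STD on the predictiveness curve.

    R2_Pepe(t*) = [pi0 (1-pi0)]^-1 * mean over subjects of (R(v;t*) - pi0)^2.
    """
    if curve.pi0 in (0.0, 1.0):
        raise ValueError("R2_Pepe undefined: pi0(t*) is 0 or 1")
    value = float(np.mean((curve.risk - curve.pi0) ** 2) / (curve.pi0 * (1.0 - curve.pi0)))
    return MeasureEstimate(name="R2_Pepe", value=value, t_star=curve.t_star)


@dataclass(frozen=True)
class BinaryRiskSet:
    """Binary outcomes with model-predicted event probabilities."""

    outcomes: np.ndarray
    predicted: np.ndarray
    prevalence: float

    @classmethod
    def from_data(cls, outcomes, predicted) -> "BinaryRiskSet":
        outcomes = np.asarray(outcomes, dtype=float)
        predicted = np.asarray(predicted, dtype=float)
        return cls(outcomes=outcomes, predicted=predicted, prevalence=float(outcomes.mean()))

    def __post_init__(self) -> None:
        if self.outcomes.shape != self.predicted.shape:
            raise ValueError("outcomes and predictions must have equal length")
        if not np.isin(self.outcomes, (0, 1)).all():
            raise ValueError("outcomes must be 0/1")


def schemper_v_binary(risks: BinaryRiskSet) -> MeasureEstimate:
    """Schemper's V for a binary outcome: relative Brier-score gain.

    V_B = [sum (Y_i - pi0)^2 - sum (Y_i - pi_i)^2] / sum (Y_i - pi0)^2.
    """
    if not 0.0 < risks.prevalence < 1.0:
        raise ValueError("V_B undefined: all outcomes identical")
    null = np.sum((risks.outcomes - risks.prevalence) ** 2)
    model = np.sum((risks.outcomes - risks.predicted) ** 2)
    return MeasureEstimate(name="V_B", value=float((null - model) / null))


# ---------------------------------------------------------------------------
# measure evaluation on a dataset + bootstrap


def evaluate_measure(
    dataset: SurvivalDataset,
    model,
    measure: str,
    t_star: float | None = None,
) -> MeasureEstimate:
    """Compute a named measure for a fitted model on a dataset.

    Curve-based measures (TG, TG_STD, R2_Pepe) and the comparator measures
    (R2_BS, R2_PM, R2_D, rho2_W) share this single entry point so the
    bootstrap and the experiment runners treat them uniformly.
    """
    from . import comparators  # deferred: comparators depends on this module

    if measure in ("TG", "TG_STD", "R2_Pepe"):
        if t_star is None:
            raise ValueError(f"{measure} is time-dependent: t_star is required")
        predictions = model.predict_survival(dataset, t_star)
        pi = model.prognostic_index(dataset)
        pi0 = kaplan_meier(dataset, t_star)
        curve = build_curve(predictions, pi, pi0, t_star)
        return {"TG": total_gain, "TG_STD": total_gain_std, "R2_Pepe": r2_pepe}[measure](curve)
    if measure == "R2_BS":
        if t_star is None:
            raise ValueError("R2_BS is time-dependent: t_star is required")
        predictions = model.predict_survival(dataset, t_star)
        return comparators.r2_bs(dataset, predictions, t_star)
    if measure == "R2_PM":
        return comparators.r2_pm(model.prognostic_index(dataset))
    if measure == "R2_D":
        return comparators.r2_d(model.prognostic_index(dataset), dataset)
    if measure == "rho2_W":
        return comparators.rho2_w(dataset, model)
    raise ValueError(f"unknown measure {measure!r}")


def bootstrap_ci(
    dataset: SurvivalDataset,
    measure: str,
    t_star: float | None,
    fit: Callable[[SurvivalDataset], object],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> MeasureEstimate:
    """Percentile bootstrap confidence interval with full model refitting.

    Subjects are case-resampled with replacement and the model is refit in
    every resample, so the interval reflects fitting variability as well as
    sampling noise.  A resample with no events or a failed fit is redrawn,
    up to ``10 * n_boot`` attempts in total.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    model = fit(dataset)
    point = evaluate_measure(dataset, model, measure, t_star)

    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    done = attempts = 0
    while done < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError(
                f"bootstrap failed: {attempts} resamples attempted, {done} usable"
            )
        attempts += 1
        idx = rng.integers(0, dataset.n, size=dataset.n)
        sample = dataset.subset(idx)
        try:
            values[done] = evaluate_measure(sample, fit(sample), measure, t_star).value
        except (ValueError, RuntimeError) as err:
            logger.debug("bootstrap resample redrawn: %s", err)
            continue
        done += 1

    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return MeasureEstimate(
        name=point.name,
        value=point.value,
        t_star=point.t_star,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# curve I/O (two-column delimited text with header metadata)


def write_curve(curve: PredictivenessCurve, path, delimiter: str = ",") -> None:
    """Export (upsilon, risk) with t_star and pi0 in comment headers."""
    with open(path, "w") as fh:
        fh.write(f"# t_star={curve.t_star!r}\n")
        fh.write(f"# pi0={curve.pi0!r}\n")
        fh.write(f"upsilon{delimiter}risk\n")
        for u, r in zip(curve.upsilon, curve.risk):
            fh.write(f"{float(u)!r}{delimiter}{float(r)!r}\n")


def read_curve(path, delimiter: str = ",") -> PredictivenessCurve:
    """Inverse of :func:`write_curve` (lossless for finite values)."""
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = float(val)
            elif line and not line.startswith("upsilon"):
                u, r = line.split(delimiter)
                rows.append((float(u), float(r)))
    arr = np.asarray(rows)
    return PredictivenessCurve(
        upsilon=arr[:, 0], risk=arr[:, 1], t_star=meta["t_star"], pi0=meta["pi0"]
    )
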