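"""Censoring-aware discrimination and calibration metrics.

Conventions (deliberately fixed and self-consistent):

* calibration-in-the-large intercept
  ``alpha = logit(observed risk at tau) - logit(mean predicted risk at tau)``
  with the observed risk from Kaplan-Meier; positive alpha means the model
  underestimates risk;
* calibration slope = coefficient of the (frozen) linear predictor in a
  proportional-hazards recalibration fit on the validation data, so a
  well-calibrated model has slope 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.utils import concordance_index

__all__ = [
    "PerformanceResult",
    "c_index",
    "km_observed_risk",
    "calibration_in_the_large",
    "calibration_slope",
    "calibration_curve",
    "bootstrap_ci",
    "evaluate",
]


def _logit(p: float) -> float:
    if not 0.0 < p < 1.0:
        raise ValueError(f"proportion {p} outside (0, 1)")
    return float(np.log(p / (1.0 - p)))


def c_index(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Harrell's concordance: among usable pairs, the fraction where the
    higher linear predictor goes with the earlier event; lp ties count 1/2.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(lp) < 2:
        raise ValueError("need at least two subjects")
    if event.sum() == 0:
        raise ValueError("no events: zero usable pairs, c-index undefined")
    # higher lp should mean shorter survival, so flip the sign for lifelines
    return float(concordance_index(time, -lp, event))


def km_observed_risk(time: np.ndarray, event: np.ndarray, tau: float) -> float:
    """Kaplan-Meier cumulative event risk at the horizon."""
    time = np.asarray(time, dtype=float)
    if tau > time.max():
        raise ValueError(
            f"horizon {tau} beyond the last observed time {time.max()}; "
            "observed risk undefined"
        )
    km = KaplanMeierFitter()
    km.fit(time, event_observed=np.asarray(event, dtype=int))
    return float(1.0 - km.predict(tau))


def calibration_in_the_large(
    predicted_risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tau: float,
) -> float:
    """logit(KM observed at tau) - logit(mean predicted risk)."""
    predicted_risk = np.asarray(predicted_risk, dtype=float)
    if np.any((predicted_risk <= 0) | (predicted_risk >= 1)):
        raise ValueError("predicted risks must lie strictly in (0, 1)")
    observed = km_observed_risk(time, event, tau)
    return _logit(observed) - _logit(float(predicted_risk.mean()))


def calibration_slope(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Coefficient of the frozen linear predictor in a PH recalibration fit."""
    lp = np.asarray(lp, dtype=float)
    if np.std(lp) < 1e-12:
        raise ValueError("degenerate linear predictor (zero variance)")
    df = pd.DataFrame({"lp": lp, "time": np.asarray(time, float),
                       "event": np.asarray(event, int)})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return float(cph.params_["lp"])


def calibration_curve(
    predicted_risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tau: float,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Risk-decile calibration points: (mean predicted, KM observed at tau).

    Bins with no events get observed risk 0 and ``sparse=True``.
    """
    predicted_risk = np.asarray(predicted_risk, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(predicted_risk) < n_bins:
        raise ValueError("fewer subjects than bins")
    order = np.argsort(predicted_risk, kind="mergesort")
    bins = np.array_split(order, n_bins)
    rows = []
    for b, idx in enumerate(bins):
        t, e, p = time[idx], event[idx], predicted_risk[idx]
        if e.sum() == 0:
            obs, sparse = 0.0, True
        else:
            km = KaplanMeierFitter()
            km.fit(t, event_observed=e)
            horizon = min(tau, t.max())
            obs, sparse = float(1.0 - km.predict(horizon)), False
        rows.append(
            {"bin": b, "n": len(idx), "mean_predicted": float(p.mean()),
             "observed": obs, "sparse": sparse}
        )
    return pd.DataFrame(rows)


def bootstrap_ci(values: Sequence[float], level: float = 0.95) -> Tuple[float, float]:
    """Percentile interval over a set of repeat-level metric values."""
    values = np.asarray(list(values), dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two values for a percentile interval")
    lo = 100 * (1 - level) / 2
    return (float(np.percentile(values, lo)), float(np.percentile(values, 100 - lo)))


@dataclass
class PerformanceResult:
    c_index: float
    calibration_intercept: float
    calibration_slope: float
    event_proportion: float  # KM-based risk at tau
    n: int
    median_followup_days: float
    curve: pd.DataFrame = field(repr=False)
    c_index_ci: Optional[Tuple[float, float]] = None
    intercept_ci: Optional[Tuple[float, float]] = None
    slope_ci: Optional[Tuple[float, float]] = None


def evaluate(
    lp: np.ndarray,
    predicted_risk: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    tau: float,
) -> PerformanceResult:
    """All validation metrics for one (model, dataset) pair."""
    return PerformanceResult(
        c_index=c_index(lp, time, event),
        calibration_intercept=calibration_in_the_large(predicted_risk, time, event, tau),
        calibration_slope=calibration_slope(lp, time, event),
        event_proportion=km_observed_risk(time, event, tau),
        n=len(np.asarray(time)),
        median_followup_days=float(np.median(np.asarray(time, dtype=float))),
        curve=calibration_curve(predicted_risk, time, event, tau),
    )
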