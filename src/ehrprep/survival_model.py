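"""Five-predictor proportional-hazards risk model with absolute 10-year risk.

The model uses age (per 10 years), sex, mean systolic blood pressure (per
10 mmHg), mean total cholesterol (mmol/l) and smoking. Fitting is delegated
to lifelines (Efron tie handling, Breslow baseline); the fitted object is a
plain dataclass holding coefficients, centering constants and the baseline
cumulative hazard step function, serializable as JSON text.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

__all__ = [
    "PREDICTORS",
    "TEN_YEARS",
    "prepare_predictors",
    "FittedRiskModel",
    "fit_cox",
    "predict_risk",
    "pool_models",
]

PREDICTORS: Tuple[str, ...] = ("age10", "female", "sbp10", "chol", "smoking")
TEN_YEARS: int = 3650


def prepare_predictors(frame: pd.DataFrame) -> pd.DataFrame:
    """Derive the model's predictor columns from a cohort frame (copy)."""
    out = frame.copy()
    out["age10"] = out["age_at_t0"] / 10.0
    out["sbp10"] = out["mean_sbp"] / 10.0
    out["chol"] = out["mean_chol"]
    return out


@dataclass
class FittedRiskModel:
    coefficients: pd.Series  # indexed by predictor name
    centers: pd.Series  # covariate means used for centering
    baseline_times: np.ndarray  # sorted event times (days)
    baseline_cumhaz: np.ndarray  # H0 at those times; H0(0) = 0, for x = centers
    horizon: int = TEN_YEARS

    def __post_init__(self) -> None:
        if np.any(np.diff(self.baseline_cumhaz) < -1e-12):
            raise ValueError("baseline cumulative hazard must be non-decreasing")

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        x = frame[list(self.coefficients.index)].to_numpy(dtype=float)
        centered = x - self.centers[list(self.coefficients.index)].to_numpy(dtype=float)
        return centered @ self.coefficients.to_numpy(dtype=float)

    def cumulative_baseline_at(self, tau: float) -> float:
        if self.baseline_times.size == 0:
            raise ValueError("model has an empty baseline hazard")
        if tau > self.baseline_times[-1]:
            warnings.warn(
                f"horizon {tau} beyond last derivation event time "
                f"{self.baseline_times[-1]}; using the last baseline step"
            )
        idx = np.searchsorted(self.baseline_times, tau, side="right") - 1
        return 0.0 if idx < 0 else float(self.baseline_cumhaz[idx])

    def predict_risk(self, frame: pd.DataFrame, tau: Optional[float] = None) -> np.ndarray:
        tau = self.horizon if tau is None else tau
        h0 = self.cumulative_baseline_at(tau)
        lp = self.linear_predictor(frame)
        return 1.0 - np.exp(-h0 * np.exp(lp))

    # -- plain-text round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "coefficients": self.coefficients.to_dict(),
                "centers": self.centers.to_dict(),
                "baseline_times": self.baseline_times.tolist(),
                "baseline_cumhaz": self.baseline_cumhaz.tolist(),
                "horizon": self.horizon,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "FittedRiskModel":
        d = json.loads(text)
        return cls(
            coefficients=pd.Series(d["coefficients"]),
            centers=pd.Series(d["centers"]),
            baseline_times=np.asarray(d["baseline_times"], dtype=float),
            baseline_cumhaz=np.asarray(d["baseline_cumhaz"], dtype=float),
            horizon=int(d["horizon"]),
        )


def fit_cox(
    frame: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    predictors: Sequence[str] = PREDICTORS,
    horizon: int = TEN_YEARS,
) -> FittedRiskModel:
    """Fit the Cox model (Efron ties, Breslow baseline) on a complete table.

    Raises if any predictor cell is missing (run a missing-data method first)
    or if the table contains no events.
    """
    cols = list(predictors) + [duration_col, event_col]
    data = frame[cols]
    if data[list(predictors)].isna().any().any():
        bad = [c for c in predictors if data[c].isna().any()]
        raise ValueError(f"missing values in predictor columns {bad}; impute first")
    if int(data[event_col].sum()) == 0:
        raise ValueError("no events in the derivation table; cannot fit")

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=duration_col, event_col=event_col)
    except Exception as exc:  # convergence / separation
        raise RuntimeError(f"Cox fit failed: {exc}") from exc

    # lifelines' baseline cumulative hazard is computed at the training means
    base = cph.baseline_cumulative_hazard_
    times = base.index.to_numpy(dtype=float)
    h0 = base.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return FittedRiskModel(
        coefficients=cph.params_[list(predictors)],
        centers=data[list(predictors)].mean(),
        baseline_times=times[keep],
        baseline_cumhaz=h0[keep],
        horizon=horizon,
    )


def predict_risk(
    model: FittedRiskModel, frame: pd.DataFrame, tau: Optional[float] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """(risk, linear predictor) at horizon ``tau`` for each row."""
    lp = model.linear_predictor(frame)
    tau = model.horizon if tau is None else tau
    h0 = model.cumulative_baseline_at(tau)
    return 1.0 - np.exp(-h0 * np.exp(lp)), lp


def pool_models(models: List[FittedRiskModel]) -> FittedRiskModel:
    """Point-estimate pooling across multiply-imputed fits.

    Coefficients and centers are averaged; baseline cumulative hazards are
    averaged on the union time grid.
    """
    if not models:
        raise ValueError("nothing to pool")
    coef = pd.concat([m.coefficients for m in models], axis=1).mean(axis=1)
    centers = pd.concat([m.centers for m in models], axis=1).mean(axis=1)
    grid = np.unique(np.concatenate([m.baseline_times for m in models]))
    h0 = np.mean(
        [
            np.concatenate([[0.0], m.baseline_cumhaz])[
                np.searchsorted(m.baseline_times, grid, side="right")
            ]
            for m in models
        ],
        axis=0,
    )
    return FittedRiskModel(
        coefficients=coef,
        centers=centers,
        baseline_times=grid,
        baseline_cumhaz=h0,
        horizon=models[0].horizon,
    )
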