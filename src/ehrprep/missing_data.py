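"""Missing-value strategies: chained-equation multiple imputation, fixed
population-mean imputation, and complete-case analysis.

Missingness is confined to the two continuous baseline predictors (mean
systolic blood pressure and mean cholesterol); binary registrations follow
the absence-means-absent rule upstream. Derivation and validation tables are
always imputed separately by the caller to avoid cross-contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from lifelines import NelsonAalenFitter

__all__ = [
    "ImputationSpec",
    "IMPUTABLE_COLUMNS",
    "rank_auxiliary_predictors",
    "mice_impute",
    "mean_impute",
    "complete_case",
    "prepare_missing",
]

IMPUTABLE_COLUMNS: Tuple[str, ...] = ("mean_sbp", "mean_chol")

# Fixed external estimates used by the MEAN method (population means with SD,
# mmHg and mmol/l).
POPULATION_MEANS: Dict[str, float] = {"mean_sbp": 130.0, "mean_chol": 5.7}
POPULATION_SDS: Dict[str, float] = {"mean_sbp": 16.0, "mean_chol": 1.1}


@dataclass(frozen=True)
class ImputationSpec:
    method: str = "MICE"  # MICE | MEAN | COMPLETE_CASE
    m: int = 5
    n_iterations: int = 10
    population_means: Optional[Dict[str, float]] = None
    auxiliary_columns: Tuple[str, ...] = ()
    auxiliary_rank_k: int = 0
    engine: str = "bayes"  # bayes | pmm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("MICE", "MEAN", "COMPLETE_CASE"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.auxiliary_rank_k < 0:
            raise ValueError("auxiliary_rank_k must be >= 0")
        if self.engine not in ("bayes", "pmm"):
            raise ValueError(f"unknown engine {self.engine!r}")
        means = self.population_means or POPULATION_MEANS
        if any(v <= 0 for v in means.values()):
            raise ValueError("population means must be positive")


def rank_auxiliary_predictors(
    frame: pd.DataFrame,
    candidates: Sequence[str],
    k: int,
    duration_col: str = "time",
    event_col: str = "event",
) -> List[str]:
    """Rank auxiliary columns for the imputation model.

    An elastic-net penalized Cox model for the event is fit on the
    standardized candidate columns; candidates are ranked by the absolute
    penalized coefficient at the weakest penalty on the path, and the top-k
    (capped at the number of informative candidates) are returned.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis
    from sksurv.util import Surv

    if not candidates:
        raise ValueError("need at least one candidate auxiliary column")
    x = frame[list(candidates)].to_numpy(dtype=float)
    keep = [i for i in range(x.shape[1]) if np.nanstd(x[:, i]) > 0]
    if not keep:
        warnings.warn("all auxiliary candidates are constant; empty ranking")
        return []
    names = [candidates[i] for i in keep]
    xs = x[:, keep]
    xs = (xs - np.nanmean(xs, axis=0)) / np.nanstd(xs, axis=0)
    xs = np.nan_to_num(xs)
    y = Surv.from_arrays(
        event=frame[event_col].to_numpy(dtype=bool),
        time=frame[duration_col].to_numpy(dtype=float),
    )
    net = CoxnetSurvivalAnalysis(l1_ratio=0.5, alpha_min_ratio=0.01, n_alphas=30)
    net.fit(xs, y)
    coefs = np.abs(net.coef_[:, -1])  # weakest penalty on the path
    order = np.argsort(-coefs)
    ranked = [names[i] for i in order if coefs[i] > 0]
    return ranked[: min(k, len(ranked))]


def _default_model_columns(frame: pd.DataFrame) -> List[str]:
    cols = ["age_at_t0", "female", "smoking"]
    return [c for c in cols if c in frame.columns]


def _imputation_design(
    frame: pd.DataFrame,
    target: str,
    other_targets: Sequence[str],
    aux: Sequence[str],
    cumhaz: Optional[np.ndarray],
) -> np.ndarray:
    cols = _default_model_columns(frame) + list(other_targets) + list(aux)
    x = frame[cols].to_numpy(dtype=float)
    parts = [np.ones((len(frame), 1)), x]
    if "event" in frame.columns:
        parts.append(frame[["event"]].to_numpy(dtype=float))
    if cumhaz is not None:
        parts.append(cumhaz[:, None])
    return np.hstack(parts)


def _bayes_draw_impute(
    x_obs: np.ndarray,
    y_obs: np.ndarray,
    x_mis: np.ndarray,
    rng: np.random.Generator,
    engine: str,
) -> np.ndarray:
    """One posterior-predictive draw of a linear imputation model.

    Standard Bayesian linear regression with a vague prior: sigma^2 from a
    scaled inverse chi-square draw, beta from its normal conditional, then
    either noisy predictions (bayes) or predictive-mean matching (pmm).
    """
    n, p = x_obs.shape
    ridge = 1e-6 * np.eye(p)
    xtx = x_obs.T @ x_obs + ridge
    xtx_inv = np.linalg.inv(xtx)
    beta_hat = xtx_inv @ (x_obs.T @ y_obs)
    resid = y_obs - x_obs @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    chol = np.linalg.cholesky((xtx_inv + xtx_inv.T) / 2 * sigma2)
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    pred_mis = x_mis @ beta_star
    if engine == "bayes":
        return pred_mis + rng.normal(0.0, np.sqrt(sigma2), size=len(pred_mis))
    # predictive mean matching: donor pool of the 5 nearest observed rows by
    # predicted value, using beta_hat predictions for the observed side
    pred_obs = x_obs @ beta_hat
    order = np.argsort(pred_obs)
    sorted_pred = pred_obs[order]
    out = np.empty(len(pred_mis))
    for j, pm in enumerate(pred_mis):
        pos = np.searchsorted(sorted_pred, pm)
        lo, hi = max(0, pos - 5), min(n, pos + 5)
        window = order[lo:hi]
        dist = np.abs(pred_obs[window] - pm)
        donors = window[np.argsort(dist)[:5]]
        out[j] = y_obs[donors[rng.integers(len(donors))]]
    return out


def mice_impute(
    frame: pd.DataFrame,
    spec: ImputationSpec,
    columns: Sequence[str] = IMPUTABLE_COLUMNS,
) -> List[pd.DataFrame]:
    """Multivariate imputation by chained equations; returns m completed tables.

    Each incomplete column is regressed on the model covariates, the other
    incomplete column, the event indicator and the Nelson-Aalen cumulative
    hazard at the censored follow-up time (plus any requested auxiliary
    columns), cycling ``n_iterations`` times per imputed dataset. Observed
    cells are never modified; deterministic given ``spec.seed``.
    """
    columns = [c for c in columns if c in frame.columns]
    masks = {c: frame[c].isna().to_numpy() for c in columns}
    for c, mask in masks.items():
        if mask.all():
            raise ValueError(f"column {c!r} is 100% missing; cannot impute")
    incomplete = [c for c in columns if masks[c].any()]
    if not incomplete:
        return [frame.copy() for _ in range(spec.m)]

    cumhaz = None
    if "time" in frame.columns and "event" in frame.columns:
        naf = NelsonAalenFitter()
        naf.fit(frame["time"], event_observed=frame["event"])
        cum = naf.cumulative_hazard_
        cumhaz = np.interp(
            frame["time"].to_numpy(dtype=float),
            cum.index.to_numpy(dtype=float),
            cum.iloc[:, 0].to_numpy(dtype=float),
        )

    rng = np.random.default_rng(spec.seed)
    aux = [c for c in spec.auxiliary_columns if c in frame.columns]
    completed: List[pd.DataFrame] = []
    for _ in range(spec.m):
        work = frame.copy()
        # initialize missing cells with random draws from the observed values
        for c in incomplete:
            obs = work.loc[~masks[c], c].to_numpy(dtype=float)
            work.loc[masks[c], c] = rng.choice(obs, size=int(masks[c].sum()))
        for _ in range(spec.n_iterations):
            for c in incomplete:
                others = [o for o in columns if o != c]
                design = _imputation_design(work, c, others, aux, cumhaz)
                y = work[c].to_numpy(dtype=float)
                obs_mask = ~masks[c]
                work.loc[masks[c], c] = _bayes_draw_impute(
                    design[obs_mask], y[obs_mask], design[masks[c]], rng, spec.engine
                )
        completed.append(work)
    return completed


def mean_impute(
    frame: pd.DataFrame,
    spec: ImputationSpec,
    columns: Sequence[str] = IMPUTABLE_COLUMNS,
) -> pd.DataFrame:
    """Replace every missing cell with the fixed external population mean."""
    means = spec.population_means or POPULATION_MEANS
    out = frame.copy()
    for c in columns:
        if c not in out.columns:
            continue
        if out[c].isna().any():
            if c not in means:
                raise ValueError(f"no population mean provided for column {c!r}")
            out[c] = out[c].fillna(means[c])
    return out


def complete_case(
    frame: pd.DataFrame, columns: Sequence[str] = IMPUTABLE_COLUMNS
) -> pd.DataFrame:
    """Rows with every listed predictor observed."""
    present = [c for c in columns if c in frame.columns]
    out = frame.dropna(subset=present).copy()
    if out.empty:
        raise ValueError(
            "complete-case analysis removed every row; use MICE or MEAN instead"
        )
    return out


def prepare_missing(
    frame: pd.DataFrame, spec: ImputationSpec
) -> List[pd.DataFrame]:
    """Dispatch on ``spec.method``; always returns a list of completed tables."""
    if spec.method == "MICE":
        return mice_impute(frame, spec)
    if spec.method == "MEAN":
        return [mean_impute(frame, spec)]
    return [complete_case(frame)]
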