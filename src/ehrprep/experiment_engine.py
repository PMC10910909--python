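"""Orchestration of the data-preparation experiment.

Nine dataset variants are derived from one population: a reference recipe
(1-year run-in, composite diagnosis-or-medication outcome, chained-equation
multiple imputation), two run-in variations, four outcome-definition
variations and two missing-data variations. For each variant the population
IDs are split 70/30; the derivation rows come from the variant-prepared
table, the validation rows ALWAYS from the reference-prepared table; the Cox
model is fit on derivation and scored on validation. The split/fit/validate
cycle is repeated ``n_repeats`` times and metrics are summarized with
percentile intervals, mirroring the reference/variant comparison design.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort_builder import CohortConfig, CohortRow, build_cohort
from .missing_data import ImputationSpec, prepare_missing
from .outcome_engine import get_definition, attach_outcome
from .performance import (
    PerformanceResult,
    bootstrap_ci,
    c_index,
    calibration_curve,
    calibration_in_the_large,
    calibration_slope,
    km_observed_risk,
)
from .survival_model import (
    TEN_YEARS,
    fit_cox,
    pool_models,
    predict_risk,
    prepare_predictors,
)
from .synthetic_ehr import PatientRecord

logger = logging.getLogger("ehrprep")

__all__ = [
    "VariantSpec",
    "ExperimentResult",
    "DEFAULT_VARIANTS",
    "split_ids",
    "assemble_sets",
    "run_experiment",
    "report",
    "read_report",
]


@dataclass(frozen=True)
class VariantSpec:
    """One derivation-set recipe; validation always uses the reference recipe."""

    label: str
    run_in_years: int = 1
    outcome: str = "REF"
    imputation_method: str = "MICE"


#: The reference plus the eight variations.
DEFAULT_VARIANTS: Tuple[VariantSpec, ...] = (
    VariantSpec("reference"),
    VariantSpec("run-in 2y", run_in_years=2),
    VariantSpec("run-in 3y", run_in_years=3),
    VariantSpec("outcome ATCexclASA_or_ICPC", outcome="ATCexclASA_or_ICPC"),
    VariantSpec("outcome ATC_only", outcome="ATC_only"),
    VariantSpec("outcome ATCexclASA_only", outcome="ATCexclASA_only"),
    VariantSpec("outcome ICPC_only", outcome="ICPC_only"),
    VariantSpec("complete-case", imputation_method="COMPLETE_CASE"),
    VariantSpec("mean-imputation", imputation_method="MEAN"),
)

REFERENCE_VARIANT = DEFAULT_VARIANTS[0]

_METRIC_COLUMNS = ("c_index", "calibration_intercept", "calibration_slope")
_CHARACTERISTIC_COLUMNS = ("n_derivation", "events_pct_derivation", "median_followup_derivation")


@dataclass
class ExperimentResult:
    metrics: pd.DataFrame  # tidy: variant, repeat, metric, value
    summary: pd.DataFrame  # one row per variant, Table-3-like columns
    n_repeats: int
    seed: int
    curves: Optional[pd.DataFrame] = None  # decile calibration points, repeat 0


def split_ids(
    ids: Sequence[int], fraction: float = 0.7, seed: int | np.random.Generator = 0
) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive 70/30 ID partition; |derivation| = round(f*n)."""
    ids = np.asarray(list(ids))
    n = len(ids)
    if n < 10:
        raise ValueError(f"need at least 10 ids to split, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    return ids[perm[:k]], ids[perm[k:]]


def assemble_sets(
    variant_frame: pd.DataFrame,
    reference_frame: pd.DataFrame,
    derivation_ids: np.ndarray,
    validation_ids: np.ndarray,
) -> Tuple[pd.DataFrame, pd.DataFrame, int]:
    """Join split IDs with the variant (derivation) and reference (validation)
    tables. IDs missing from the variant table (stricter eligibility) are
    dropped; the count of dropped IDs is returned.
    """
    deriv = variant_frame[variant_frame["patient_id"].isin(derivation_ids)].copy()
    valid = reference_frame[reference_frame["patient_id"].isin(validation_ids)].copy()
    overlap = set(deriv["patient_id"]) & set(valid["patient_id"])
    if overlap:
        raise AssertionError(f"{len(overlap)} ids in both derivation and validation")
    dropped = len(derivation_ids) - len(deriv)
    return deriv, valid, dropped


def _variant_seed(master: int, label: str, repeat: int, purpose: int) -> list:
    return [master, zlib.crc32(label.encode()), repeat, purpose]


def _prepare_and_fit(
    deriv: pd.DataFrame,
    valid: pd.DataFrame,
    variant: VariantSpec,
    master_seed: int,
    repeat: int,
    tau: float,
    mice_m: int,
):
    """Impute both arms separately, fit per-imputation models on derivation,
    return per-imputation predicted risks / linear predictors on validation.

    Metrics are pooled per imputation pair (derivation model j scored on
    validation imputation j) rather than computed on across-imputation
    averages: averaging the linear predictor first would shrink its variance
    under heavy missingness and bias the recalibration slope upward.
    """
    deriv_spec = ImputationSpec(
        method=variant.imputation_method,
        m=mice_m,
        seed=zlib.crc32(str(_variant_seed(master_seed, variant.label, repeat, 1)).encode()),
    )
    val_spec = ImputationSpec(
        method="MICE",
        m=mice_m,
        seed=zlib.crc32(str(_variant_seed(master_seed, variant.label, repeat, 2)).encode()),
    )
    deriv_tables = prepare_missing(deriv, deriv_spec)
    val_tables = prepare_missing(valid, val_spec)
    models = [fit_cox(prepare_predictors(t)) for t in deriv_tables]
    pooled = pool_models(models)

    risks, lps = [], []
    for vt in val_tables:
        risk_j, lp_j = predict_risk(pooled, prepare_predictors(vt), tau)
        risks.append(risk_j)
        lps.append(lp_j)
    return pooled, deriv_tables[0], risks, lps


def pooled_evaluate(
    lps: Sequence[np.ndarray],
    risks: Sequence[np.ndarray],
    time: np.ndarray,
    event: np.ndarray,
    tau: float,
) -> PerformanceResult:
    """Validation metrics pooled over multiply-imputed prediction sets.

    Discrimination and slope are averaged over per-imputation estimates; the
    calibration intercept and curve use the across-imputation mean predicted
    risk (the mean is unaffected by pooling order).
    """
    mean_risk = np.mean(np.asarray(risks), axis=0)
    return PerformanceResult(
        c_index=float(np.mean([c_index(lp, time, event) for lp in lps])),
        calibration_intercept=calibration_in_the_large(mean_risk, time, event, tau),
        calibration_slope=float(
            np.mean([calibration_slope(lp, time, event) for lp in lps])
        ),
        event_proportion=km_observed_risk(time, event, tau),
        n=len(time),
        median_followup_days=float(np.median(time)),
        curve=calibration_curve(mean_risk, time, event, tau),
    )


def run_experiment(
    records: Sequence[PatientRecord],
    variants: Sequence[VariantSpec] = DEFAULT_VARIANTS,
    n_repeats: int = 50,
    seed: int = 0,
    cohort_config: Optional[CohortConfig] = None,
    tau: float = TEN_YEARS,
    mice_m: int = 5,
    max_failure_fraction: float = 0.1,
) -> ExperimentResult:
    """Run the full variant-vs-reference validation experiment.

    Deterministic given (records, variants, n_repeats, seed): per-repeat seeds
    are derived from the master seed, the variant label and the repeat index.
    """
    if not variants:
        raise ValueError("need at least one variant")
    labels = [v.label for v in variants]
    if len(set(labels)) != len(labels):
        raise ValueError("variant labels must be unique")

    base_config = cohort_config or CohortConfig()
    cohorts: Dict[int, List[CohortRow]] = {}
    for k in sorted({1, *[v.run_in_years for v in variants]}):
        cfg = CohortConfig(
            run_in_years=k,
            age_min=base_config.age_min,
            age_max=base_config.age_max,
            data_window_start=base_config.data_window_start,
            data_window_end=base_config.data_window_end,
            prior_cvd_codes=base_config.prior_cvd_codes,
        )
        cohorts[k] = build_cohort(records, cfg)
        logger.info("cohort run-in %dy: %d eligible", k, len(cohorts[k]))

    reference_frame = attach_outcome(cohorts[1], get_definition("REF"))
    variant_frames = {
        v.label: attach_outcome(cohorts[v.run_in_years], get_definition(v.outcome))
        for v in variants
    }

    tidy_rows = []
    curve_rows = []
    n_failed = 0
    total = len(variants) * n_repeats
    for variant in variants:
        vframe = variant_frames[variant.label]
        for r in range(n_repeats):
            rng = np.random.default_rng(_variant_seed(seed, variant.label, r, 0))
            deriv_ids, valid_ids = split_ids(
                reference_frame["patient_id"].to_numpy(), 0.7, rng
            )
            deriv, valid, dropped = assemble_sets(
                vframe, reference_frame, deriv_ids, valid_ids
            )
            if dropped:
                logger.debug(
                    "%s repeat %d: %d split ids absent from variant cohort",
                    variant.label, r, dropped,
                )
            try:
                _, deriv_table, risks, lps = _prepare_and_fit(
                    deriv, valid, variant, seed, r, tau, mice_m
                )
                perf = pooled_evaluate(
                    lps, risks,
                    valid["time"].to_numpy(), valid["event"].to_numpy(), tau,
                )
                deriv_events_pct = 100.0 * km_observed_risk(
                    deriv_table["time"].to_numpy(), deriv_table["event"].to_numpy(), tau
                )
            except Exception as exc:
                n_failed += 1
                logger.warning("%s repeat %d failed: %s", variant.label, r, exc)
                continue
            if r == 0:
                curve = perf.curve.copy()
                curve.insert(0, "variant", variant.label)
                curve_rows.append(curve)
            tidy_rows.extend(
                {
                    "variant": variant.label, "repeat": r, "metric": m, "value": val,
                }
                for m, val in (
                    ("c_index", perf.c_index),
                    ("calibration_intercept", perf.calibration_intercept),
                    ("calibration_slope", perf.calibration_slope),
                    ("n_derivation", float(len(deriv_table))),
                    ("events_pct_derivation", deriv_events_pct),
                    ("median_followup_derivation",
                     float(np.median(deriv_table["time"]))),
                    ("n_validation", float(perf.n)),
                    ("dropped_ids", float(dropped)),
                )
            )
    if n_failed > max_failure_fraction * total:
        raise RuntimeError(f"{n_failed}/{total} repeats failed; aborting")

    metrics = pd.DataFrame(tidy_rows)
    summary = _summarize(metrics, labels)
    curves = pd.concat(curve_rows, ignore_index=True) if curve_rows else None
    return ExperimentResult(
        metrics=metrics, summary=summary, n_repeats=n_repeats, seed=seed, curves=curves
    )


def _summarize(metrics: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    rows = []
    for label in labels:
        sub = metrics[metrics["variant"] == label]
        row = {"variant": label}
        for m in _CHARACTERISTIC_COLUMNS:
            vals = sub.loc[sub["metric"] == m, "value"]
            row[f"{m}_median"] = vals.median()
            row[f"{m}_min"] = vals.min()
            row[f"{m}_max"] = vals.max()
        for m in _METRIC_COLUMNS:
            vals = sub.loc[sub["metric"] == m, "value"]
            row[f"{m}_median"] = vals.median()
            if len(vals) >= 2:
                lo, hi = bootstrap_ci(vals)
            else:
                lo = hi = vals.median()
            row[f"{m}_lo"] = lo
            row[f"{m}_hi"] = hi
        rows.append(row)
    return pd.DataFrame(rows)


def report(result: ExperimentResult, out_prefix: str) -> pd.DataFrame:
    """Write the tidy metrics, summary table and calibration curve points as
    CSV; return the summary."""
    result.metrics.to_csv(f"{out_prefix}_metrics.csv", index=False)
    result.summary.to_csv(f"{out_prefix}_summary.csv", index=False)
    if result.curves is not None:
        result.curves.to_csv(f"{out_prefix}_curves.csv", index=False)
    return result.summary


def read_report(out_prefix: str) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Round-trip reader for :func:`report` output."""
    metrics = pd.read_csv(f"{out_prefix}_metrics.csv")
    summary = pd.read_csv(f"{out_prefix}_summary.csv")
    return metrics, summary
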