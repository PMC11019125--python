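"""Clock scoring, residual age, and selection-frequency summaries.

Following the clock literature, accuracy is reported two ways: R² (and its
adjusted form) from an OLS regression of predicted on observed age — the
strength of the scatter's linear trend — and RMSE on the raw prediction
errors. "Residual age" (age acceleration) is the signed residual of each dog
from that predicted-versus-observed regression line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .association import ols_fit
from .clock import LoocvClockResult

logger = logging.getLogger(__name__)


@dataclass
class ClockEvaluation:
    r2: float
    r2_adj: float
    rmse: float
    rmse_regression: float   # RMSE of the regression residuals, for reference
    n: int
    stratum: str = "all"
    r2_skill: float = float("nan")      # 1 - SSE/SST on the raw pairs
    r2_skill_adj: float = float("nan")


def evaluate_predictions(predicted, observed, stratum: str = "all") -> ClockEvaluation:
    """Score predictions two ways.

    r2 / r2_adj come from the OLS regression of predicted on observed (the
    convention behind the headline clock numbers); they quantify the linear
    trend of the scatter regardless of calibration — note that squared
    correlation is sign-agnostic, so on skill-free leave-one-out predictions
    (which equal the training mean, an exact *anti*-correlate of the held-out
    age) it reflects that artifact rather than skill. r2_skill / r2_skill_adj
    are the out-of-sample convention, 1 - SSE/SST on the raw pairs, at or
    below zero in expectation for predictions with no skill. RMSE is on the
    raw pairs.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    n = len(predicted)
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if not (np.isfinite(predicted).all() and np.isfinite(observed).all()):
        raise ValueError("non-finite predictions or ages")
    if np.ptp(observed) == 0:
        raise ValueError("observed ages are constant; R^2 undefined")
    X = np.column_stack([np.ones(n), observed])
    fit = ols_fit(predicted, X, ["intercept", "observed"])
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    rmse_reg = float(np.sqrt(np.mean(fit.residuals**2)))
    sst = float(((observed - observed.mean()) ** 2).sum())
    r2_skill = 1.0 - float(((predicted - observed) ** 2).sum()) / sst
    r2_skill_adj = 1.0 - (1.0 - r2_skill) * (n - 1) / (n - 2)
    return ClockEvaluation(
        fit.r2, fit.r2_adj, rmse, rmse_reg, n, stratum, r2_skill, r2_skill_adj
    )


def stratified_evaluation(
    predicted, observed, weight_category, min_n: int = 3
) -> list[ClockEvaluation]:
    """Overall evaluation plus one per breed-size stratum (small/medium/large);
    strata with fewer than `min_n` dogs are skipped with a log entry."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    cats = np.asarray(weight_category)
    out = [evaluate_predictions(predicted, observed, "all")]
    for stratum in pd.unique(cats):
        mask = cats == stratum
        if mask.sum() < min_n:
            logger.info("stratified_evaluation: skipping %r (n=%d < %d)", stratum, int(mask.sum()), min_n)
            continue
        try:
            out.append(evaluate_predictions(predicted[mask], observed[mask], str(stratum)))
        except ValueError as exc:
            logger.info("stratified_evaluation: skipping %r (%s)", stratum, exc)
    return out


def residual_age(predicted, observed) -> np.ndarray:
    """Signed residuals of the OLS regression of predicted on observed age."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(predicted)
    X = np.column_stack([np.ones(n), observed])
    fit = ols_fit(predicted, X, ["intercept", "observed"])
    return fit.residuals


def residual_vs_weight(residuals, breed_weight) -> tuple[float, float, float]:
    """OLS slope of residual age on breed mean weight: (slope, p, r2)."""
    residuals = np.asarray(residuals, dtype=float)
    weight = np.asarray(breed_weight, dtype=float)
    if residuals.shape != weight.shape:
        raise ValueError("residuals and weights must align")
    X = np.column_stack([np.ones(len(weight)), weight])
    fit = ols_fit(residuals, X, ["intercept", "weight"])
    return float(fit.params[1]), float(fit.pvalues[1]), float(fit.r2)


def cross_clock_residual_correlation(residuals_a, residuals_b) -> tuple[float, float]:
    """Pearson correlation between two clocks' residual-age vectors."""
    a = np.asarray(residuals_a, dtype=float)
    b = np.asarray(residuals_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def selection_frequency_report(
    results: dict[str, LoocvClockResult],
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, set[str]]]:
    """Per-feature selection counts per clock.

    Returns (all-feature table, meta-feature table, per-clock sets of
    ever-selected epigenetic features — the input to the nearest-gene
    overlap).
    """
    freq = pd.DataFrame({dt: res.selection_frequency() for dt, res in results.items()})
    freq = freq.fillna(0).astype(int)
    freq.index.name = "feature_id"
    is_meta = freq.index.str.startswith(("cell.", "meta."))
    meta_table = freq.loc[is_meta]
    epigenetic_ever = {
        dt: {f for f in res.ever_selected() if not f.startswith(("cell.", "meta."))}
        for dt, res in results.items()
    }
    return freq, meta_table, epigenetic_ever
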