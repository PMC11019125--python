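"""Per-feature age-association models and the metadata/age screen.

Each epigenetic feature is modelled by ordinary least squares as

    feature ~ age + weight + sex + exercise + cell.CD8 + cell.DN

where weight is the breed mean weight, sex a binary indicator, exercise
dummy-coded, and cell.CD8 / cell.DN the two age-correlated memory T-cell
gate proportions. Only the age term's effect, standard error and p-value are
collected; p-values are adjusted by the Benjamini-Hochberg step-up procedure
(Benjamini-Yekutieli variant available) and significant features are
classified as increasing or decreasing with age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .simulate import CELL_CD8, CELL_DN

import logging

logger = logging.getLogger(__name__)


class RankDeficientDesignError(ValueError):
    """The design matrix is rank deficient; names the collinear columns."""


@dataclass
class OlsResult:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    r2: float
    r2_adj: float
    df_resid: int
    column_names: list[str]


def _dependent_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns beyond the numerical rank via pivoted QR."""
    from scipy.linalg import qr

    _, _, piv = qr(X, mode="economic", pivoting=True)
    rank = np.linalg.matrix_rank(X)
    return [names[j] for j in sorted(piv[rank:])]


def ols_fit(y: np.ndarray, X: np.ndarray, column_names: list[str] | None = None) -> OlsResult:
    """Ordinary least squares with t-based two-sided p-values.

    Requires n > rank(X) and a full-rank design; a rank-deficient design
    raises with the names of the dependent columns.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = column_names or [f"x{j}" for j in range(p)]
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {_dependent_columns(X, names)}"
        )
    if n <= rank:
        raise ValueError(f"need n > rank(X) ({n} <= {rank})")
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    fitted = X @ beta
    resid = y - fitted
    df_resid = n - rank
    rss = float(resid @ resid)
    sigma2 = rss / df_resid
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid
    return OlsResult(beta, se, t, pvals, resid, r2, r2_adj, df_resid, names)


def build_age_design(metadata: pd.DataFrame) -> tuple[np.ndarray, list[str], int]:
    """Design matrix for the per-feature age model.

    Returns (X, column names, index of the age column). Raises before any fit
    if a covariate is missing or the dummy-coded design is rank deficient.
    """
    required = ["age", "breed_weight_kg", "sex", "exercise", CELL_CD8, CELL_DN]
    missing = [c for c in required if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata is missing covariates: {missing}")
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(metadata))}
    cols["age"] = metadata["age"].to_numpy(dtype=float)
    cols["weight"] = metadata["breed_weight_kg"].to_numpy(dtype=float)
    sex_levels = sorted(metadata["sex"].unique())
    if len(sex_levels) > 1:
        cols[f"sex_{sex_levels[1]}"] = (metadata["sex"] == sex_levels[1]).to_numpy(dtype=float)
    ex_levels = sorted(metadata["exercise"].unique())
    for level in ex_levels[1:]:  # drop-first dummy coding
        cols[f"exercise_{level}"] = (metadata["exercise"] == level).to_numpy(dtype=float)
    cols[CELL_CD8] = metadata[CELL_CD8].to_numpy(dtype=float)
    cols[CELL_DN] = metadata[CELL_DN].to_numpy(dtype=float)
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise RankDeficientDesignError(
            f"age-model design is rank deficient; collinear columns: {_dependent_columns(X, names)}"
        )
    return X, names, names.index("age")


def fit_feature_age_models(features: FeatureMatrix, metadata: pd.DataFrame) -> pd.DataFrame:
    """Fit the age model to every feature column; collect the age term.

    One shared design is solved once (pseudoinverse) and applied to all
    features, which is algebraically identical to per-feature OLS.
    Zero-variance features get beta 0 / p 1.
    """
    meta = metadata.set_index("sample_id").loc[features.sample_ids].reset_index()
    X, names, age_ix = build_age_design(meta)
    Y = features.values.to_numpy(dtype=float)
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise ValueError(f"need more samples than design columns ({n} <= {p})")
    xtx_inv = np.linalg.inv(X.T @ X)
    B = xtx_inv @ X.T @ Y                      # p x m coefficients
    resid = Y - X @ B
    rss = (resid ** 2).sum(axis=0)
    sigma2 = rss / df_resid
    se_age = np.sqrt(sigma2 * xtx_inv[age_ix, age_ix])
    beta_age = B[age_ix]
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(se_age > 0, beta_age / np.where(se_age > 0, se_age, 1.0), 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    pvals = np.where(se_age > 0, pvals, 1.0)
    return pd.DataFrame(
        {
            "feature_id": features.feature_ids,
            "beta_age": beta_age,
            "se": se_age,
            "t": t,
            "p": pvals,
        }
    )


def bh_adjust(p: np.ndarray, method: str = "bh") -> np.ndarray:
    """Step-up false-discovery-rate adjustment.

    q_(i) = min_{j >= i} (m/j) p_(j), capped at 1, in input order. The
    Benjamini-Yekutieli variant (method="by") multiplies by sum(1/k).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    factor = np.sum(1.0 / np.arange(1, m + 1)) if method == "by" else 1.0
    if method not in ("bh", "by"):
        raise ValueError(f"unknown method {method!r}")
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m * factor / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_direction(results: pd.DataFrame, q_threshold: float = 0.05) -> pd.Series:
    """'increasing' / 'decreasing' for significant features, else 'ns'."""
    q = results["q"].to_numpy()
    beta = results["beta_age"].to_numpy()
    labels = np.where(
        q < q_threshold, np.where(beta > 0, "increasing", "decreasing"), "ns"
    )
    # a zero effect can never be directional
    labels[(q < q_threshold) & (beta == 0)] = "ns"
    return pd.Series(labels, index=results.index, name="direction")


def associate_features(
    features: FeatureMatrix,
    metadata: pd.DataFrame,
    q_threshold: float = 0.05,
    method: str = "bh",
) -> pd.DataFrame:
    """Age model per feature + FDR adjustment + direction classification."""
    results = fit_feature_age_models(features, metadata)
    results["q"] = bh_adjust(results["p"].to_numpy(), method=method)
    results["direction"] = classify_direction(results, q_threshold)
    n_sig = int((results["q"] < q_threshold).sum())
    logger.info(
        "associate_features[%s]: %d/%d features age-associated at q < %g",
        features.kind, n_sig, len(results), q_threshold,
    )
    return results


def screen_metadata_age(
    metadata: pd.DataFrame,
    categorical: tuple[str, ...] = ("sex", "exercise", "weight_category"),
    method: str = "bh",
) -> pd.DataFrame:
    """Screen every metadata variable for association with age.

    Cell-type proportions: OLS of proportion on age (slope, t-based p).
    Categorical variables: one-way ANOVA F-test of age across levels.
    One BH adjustment spans the whole screen.
    """
    rows = []
    age = metadata["age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(age)), age])
    cell_cols = [c for c in metadata.columns if c.startswith("cell.")]
    for col in cell_cols:
        fit = ols_fit(metadata[col].to_numpy(dtype=float), X, ["intercept", "age"])
        rows.append((col, "numeric", fit.params[1], fit.pvalues[1]))
    for col in categorical:
        groups = [g.to_numpy(dtype=float) for _, g in metadata.groupby(col)["age"] if len(g)]
        if len(groups) < 2:
            logger.info("screen_metadata_age: skipping %r (< 2 levels)", col)
            continue
        f_stat, p = stats.f_oneway(*groups)
        rows.append((col, "categorical", float(f_stat), float(p)))
    out = pd.DataFrame(rows, columns=["variable", "kind", "stat", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy(), method=method)
    return out
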