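"""Elastic-net age clocks under manual leave-one-out cross-validation.

The outer loop leaves out one dog at a time; on the remaining N-1 an inner
K-fold cross-validation picks the penalty lambda (alpha fixed, default 0.5),
a final model is fit at that lambda, and the held-out dog's age is predicted.
The design offers every epigenetic feature plus the "meta features" — all
cell-type proportions and the ordinal breed weight category — to the
selection process on equal footing.

By default features are standardized once on the full cohort before the
loop, replicating the published processing order; `scaling="fold"`
restandardizes inside each training fold (no information from the held-out
dog), the honest-performance variant used for null calibration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import elasticnet as en
from .features import EmptyFeatureSetError, FeatureMatrix, standardize_columns
from .simulate import WEIGHT_CATEGORIES

logger = logging.getLogger(__name__)

_WEIGHT_ORDINAL = {cat: i + 1 for i, cat in enumerate(WEIGHT_CATEGORIES)}
META_WEIGHT_COLUMN = "meta.weight_category"


def meta_feature_block(metadata: pd.DataFrame) -> pd.DataFrame:
    """Cell-type proportion columns plus ordinal-coded (1/2/3) breed weight
    category, indexed by sample."""
    cell_cols = [c for c in metadata.columns if c.startswith("cell.")]
    block = metadata.set_index("sample_id")[cell_cols].astype(float)
    block[META_WEIGHT_COLUMN] = (
        metadata.set_index("sample_id")["weight_category"].map(_WEIGHT_ORDINAL).astype(float)
    )
    if block[META_WEIGHT_COLUMN].isna().any():
        bad = sorted(set(metadata["weight_category"]) - set(_WEIGHT_ORDINAL))
        raise ValueError(f"unknown weight categories {bad}")
    return block


def build_design(
    features: FeatureMatrix | Sequence[FeatureMatrix],
    metadata: pd.DataFrame,
    data_type: str | None = None,
) -> FeatureMatrix:
    """Concatenate epigenetic feature block(s) and standardized meta features.

    For the combined clock pass the ATAC and DNAm matrices together; their
    columns are concatenated before the meta block. All blocks must cover the
    same samples (mismatches are reported by id).
    """
    blocks = [features] if isinstance(features, FeatureMatrix) else list(features)
    if not blocks:
        raise ValueError("no feature blocks given")
    if any(b.values.shape[1] == 0 for b in blocks):
        raise EmptyFeatureSetError("a feature block is empty; refusing to build a clock design")
    sample_ids = blocks[0].sample_ids
    meta_samples = set(metadata["sample_id"])
    for b in blocks:
        if b.sample_ids != sample_ids:
            offenders = sorted(set(b.sample_ids) ^ set(sample_ids))
            raise ValueError(f"feature blocks cover different samples: {offenders[:10]}")
    missing = sorted(set(sample_ids) - meta_samples)
    if missing:
        raise ValueError(f"metadata missing samples: {missing[:10]}")
    meta_block = meta_feature_block(metadata).loc[sample_ids]
    meta_scaled, meta_zero = standardize_columns(meta_block)
    pieces = [b.values for b in blocks] + [meta_scaled]
    values = pd.concat(pieces, axis=1)
    if values.columns.duplicated().any():
        dup = values.columns[values.columns.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate feature ids across blocks: {dup}")
    kind = data_type or ("combined" if len(blocks) > 1 else blocks[0].kind)
    provenance = [f"{b.kind} block: {b.values.shape[1]} features" for b in blocks]
    provenance.append(f"meta block: {meta_scaled.shape[1]} features (standardized)")
    return FeatureMatrix(
        values=values, kind=kind, provenance=provenance,
        zero_variance=sum((b.zero_variance for b in blocks), []) + meta_zero,
    )


@dataclass
class FoldModel:
    """The final elastic-net model of one leave-one-out fold."""

    index: int
    sample_id: str
    lam: float
    alpha: float
    intercept: float
    coef: np.ndarray = field(repr=False)
    predicted_age: float
    feature_ids: list[str] = field(repr=False)

    def nonzero_coefficients(self) -> dict[str, float]:
        return {self.feature_ids[j]: float(self.coef[j]) for j in np.flatnonzero(self.coef)}

    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coef))


@dataclass
class LoocvClockResult:
    """All N leave-one-out folds of one clock."""

    data_type: str
    alpha: float
    sample_ids: list[str]
    ages: np.ndarray
    predictions: np.ndarray
    folds: list[FoldModel]
    feature_ids: list[str]
    scaling: str

    def lambdas(self) -> np.ndarray:
        return np.array([f.lam for f in self.folds])

    def selection_frequency(self) -> pd.Series:
        """Folds in which each feature received a nonzero coefficient (0..N)."""
        counts = np.zeros(len(self.feature_ids), dtype=int)
        for f in self.folds:
            counts += f.coef != 0
        return pd.Series(counts, index=pd.Index(self.feature_ids, name="feature_id"),
                         name=f"{self.data_type}_selection_frequency")

    def ever_selected(self) -> set[str]:
        freq = self.selection_frequency()
        return set(freq.index[freq > 0])

    def predictions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "age": self.ages,
                "predicted_age": self.predictions,
                "lambda": self.lambdas(),
                "n_selected": [f.n_selected() for f in self.folds],
            }
        )


def _fold_standardize(X: np.ndarray, train: np.ndarray):
    """Standardize columns by training-fold statistics only."""
    mu = X[train].mean(axis=0)
    sd = X[train].std(axis=0, ddof=1)
    safe = np.where(sd > 0, sd, 1.0)
    out = (X - mu) / safe
    out[:, sd == 0] = 0.0
    return out


def loocv_clock(
    design: FeatureMatrix,
    ages: np.ndarray | pd.Series,
    alpha: float = 0.5,
    inner_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    scaling: str = "global",
    tol: float = 1e-7,
    cv_tol: float = 1e-4,
) -> LoocvClockResult:
    """Manual leave-one-out elastic-net clock.

    For each sample: inner `inner_folds`-fold CV on the remaining N-1 picks
    lambda (minimum mean CV MSE, ties to the larger lambda), the final model
    is refit tight (KKT-certified) at that lambda by a warm-started path, and
    the held-out sample is predicted. Inner fold assignment derives
    deterministically from `seed` and the fold index.
    """
    if scaling not in ("global", "fold"):
        raise ValueError(f"scaling must be 'global' or 'fold', got {scaling!r}")
    X_all = design.values.to_numpy(dtype=float)
    sample_ids = design.sample_ids
    y = np.asarray(ages, dtype=float)
    n = len(y)
    if X_all.shape[0] != n:
        raise ValueError(f"{X_all.shape[0]} design rows but {n} ages")
    if X_all.shape[1] == 0:
        raise EmptyFeatureSetError("empty design; refusing to fit")
    feature_ids = design.feature_ids
    predictions = np.empty(n)
    folds: list[FoldModel] = []
    for i in range(n):
        try:
            train = np.ones(n, dtype=bool)
            train[i] = False
            X = _fold_standardize(X_all, train) if scaling == "fold" else X_all
            X_tr, y_tr = X[train], y[train]
            path = en.lambda_path(X_tr, y_tr, alpha, n_lambda)
            inner_seed = int(np.random.default_rng([seed, i]).integers(2**31))
            cv = en.cv_select_lambda(
                X_tr, y_tr, alpha, k=inner_folds, path=path, seed=inner_seed, tol=cv_tol
            )
            coefs, intercepts = en.fit_path(
                X_tr, y_tr, path[: cv.best_index + 1], alpha, tol=tol
            )
            fit = en.ElasticNetFit(
                intercept=float(intercepts[-1]),
                coef=coefs[-1],
                lam=cv.lam,
                alpha=alpha,
                n_iter=0,
                objective=en.elastic_net_objective(
                    X_tr, y_tr, float(intercepts[-1]), coefs[-1], cv.lam, alpha
                ),
                feature_ids=feature_ids,
            )
            pred = en.predict(fit, X[i])
        except Exception as exc:
            raise RuntimeError(
                f"LOOCV fold {i} (held-out sample {sample_ids[i]}) failed: {exc}"
            ) from exc
        predictions[i] = pred
        folds.append(
            FoldModel(
                index=i, sample_id=sample_ids[i], lam=cv.lam, alpha=alpha,
                intercept=fit.intercept, coef=fit.coef, predicted_age=float(pred),
                feature_ids=feature_ids,
            )
        )
    logger.info(
        "loocv_clock[%s]: %d folds, median lambda %.4g, median selected %d",
        design.kind, n, float(np.median([f.lam for f in folds])),
        int(np.median([f.n_selected() for f in folds])),
    )
    return LoocvClockResult(
        data_type=design.kind, alpha=alpha, sample_ids=sample_ids, ages=y,
        predictions=predictions, folds=folds, feature_ids=feature_ids, scaling=scaling,
    )
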