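"""The samples x features container shared by both data types."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class EmptyFeatureSetError(ValueError):
    """Every feature was removed by filtering; downstream fitting refuses to run."""


@dataclass
class FeatureMatrix:
    """A fully processed samples x features matrix.

    `values` is indexed by sample_id with one column per feature;
    `kind` is 'atac', 'dnam' or 'meta'; `provenance` is the ordered list of
    transforms applied; `zero_variance` lists columns that were constant
    before scaling (left at all-zeros).
    """

    values: pd.DataFrame
    kind: str
    provenance: list[str] = field(default_factory=list)
    zero_variance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any()].tolist()[:5]
            raise ValueError(f"feature matrix contains missing values (e.g. {bad})")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.index.tolist()


def standardize_columns(
    values: pd.DataFrame, ddof: int = 1
) -> tuple[pd.DataFrame, list[str]]:
    """Center each column to mean 0 and scale to SD 1 (n-ddof denominator).

    Zero-variance columns are left at all-zeros after centering and returned
    in the flag list.
    """
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=ddof) if arr.shape[0] > ddof else np.zeros(arr.shape[1])
    zero_var = sd == 0
    safe_sd = np.where(zero_var, 1.0, sd)
    out = (arr - mean) / safe_sd
    out[:, zero_var] = 0.0
    flagged = [c for c, z in zip(values.columns, zero_var) if z]
    return pd.DataFrame(out, index=values.index, columns=values.columns), flagged
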