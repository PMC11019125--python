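"""Methylation-matrix processing.

Per-CpG methylated fraction (beta value) computation, depth and
intermediate-methylation filtering, contig removal, and standardization.
Unlike the accessibility matrix, fractions are used on their natural scale
with no log transform.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .atac import EXCLUDED_CONTIG_PATTERN, is_excluded_contig
from .features import EmptyFeatureSetError, FeatureMatrix, standardize_columns
from .simulate import MethylationData

logger = logging.getLogger(__name__)


def compute_fractions(meth: MethylationData) -> pd.DataFrame:
    """Sites x samples methylated fraction; depth-0 cells are NaN (missing),
    never 0."""
    m = meth.methylated.to_numpy(dtype=float)
    u = meth.unmethylated.to_numpy(dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("negative methylation counts")
    d = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(d > 0, m / np.where(d > 0, d, 1.0), np.nan)
    return pd.DataFrame(frac, index=meth.methylated.index, columns=meth.methylated.columns)


def _site_chroms(fractions: pd.DataFrame, chroms=None) -> np.ndarray:
    if chroms is not None:
        return np.asarray(chroms)
    # site ids follow the "chrom:pos" convention
    return np.array([str(s).rsplit(":", 1)[0] for s in fractions.index])


def filter_sites(
    fractions: pd.DataFrame,
    depths: pd.DataFrame,
    mean_depth_min: float = 5.0,
    median_low: float = 0.1,
    median_high: float = 0.9,
    chroms=None,
    contig_pattern: str = EXCLUDED_CONTIG_PATTERN,
    impute: bool = True,
) -> pd.DataFrame:
    """Retain sites with across-sample mean depth >= `mean_depth_min`,
    across-sample median fraction within [`median_low`, `median_high`]
    (inclusive — dropping constitutively hyper-/hypo-methylated sites), on
    canonical contigs. Remaining missing cells are imputed with the site's
    across-sample mean fraction so the matrix is complete for model fitting.
    """
    frac = fractions.to_numpy(dtype=float)
    depth = depths.loc[fractions.index, fractions.columns].to_numpy(dtype=float)
    mean_depth = depth.mean(axis=1)
    with np.errstate(all="ignore"):
        med = np.nanmedian(frac, axis=1)
    med_ok = ~np.isnan(med) & (med >= median_low) & (med <= median_high)
    keep = (mean_depth >= mean_depth_min) & med_ok & ~is_excluded_contig(
        _site_chroms(fractions, chroms), contig_pattern
    )
    kept = fractions.loc[keep]
    logger.info(
        "filter_sites: %d -> %d sites (mean depth >= %g, median fraction in [%g, %g], canonical contig)",
        len(fractions), len(kept), mean_depth_min, median_low, median_high,
    )
    if kept.empty:
        raise EmptyFeatureSetError("every CpG site was removed by filtering")
    if impute and kept.isna().any().any():
        arr = kept.to_numpy(dtype=float)
        site_mean = np.nanmean(arr, axis=1)
        rows, cols = np.nonzero(np.isnan(arr))
        arr[rows, cols] = site_mean[rows]
        kept = pd.DataFrame(arr, index=kept.index, columns=kept.columns)
    return kept


def center_scale_meth(fractions: pd.DataFrame) -> FeatureMatrix:
    """Standardize filtered fractions to per-site mean 0 / SD 1.

    Input is sites x samples; output samples x sites. No transform precedes
    scaling: beta values enter the clock on their own scale.
    """
    if fractions.isna().any().any():
        raise ValueError("missing fractions must be imputed before scaling")
    scaled, flagged = standardize_columns(fractions.T)
    if flagged:
        logger.warning("center_scale_meth: %d zero-variance sites left at 0", len(flagged))
    return FeatureMatrix(
        values=scaled,
        kind="dnam",
        provenance=["methylated fraction", "center to mean 0", "scale to sd 1 (n-1)"],
        zero_variance=flagged,
    )


def process_methylation(
    meth: MethylationData,
    mean_depth_min: float = 5.0,
    median_low: float = 0.1,
    median_high: float = 0.9,
    contig_pattern: str = EXCLUDED_CONTIG_PATTERN,
) -> FeatureMatrix:
    """Full methylation pipeline: fractions -> filters -> standardization."""
    fractions = compute_fractions(meth)
    chroms = meth.sites.set_index("site_id").loc[fractions.index, "chrom"].to_numpy()
    kept = filter_sites(
        fractions, meth.depth, mean_depth_min, median_low, median_high,
        chroms=chroms, contig_pattern=contig_pattern,
    )
    fm = center_scale_meth(kept)
    fm.provenance = (
        [
            f"mean depth >= {mean_depth_min}, median fraction in [{median_low}, {median_high}], "
            f"canonical contig ({len(fractions)} -> {len(kept)})",
        ]
        + fm.provenance
    )
    return fm
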