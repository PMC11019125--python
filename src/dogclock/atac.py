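"""Accessibility-matrix processing.

From a consensus peak catalogue and a peak x sample read-count matrix to an
analysis-ready samples x peaks matrix: summit-distance peak merging,
median-coverage and contig filters, RPKM normalization, log2 transform,
centering and scaling.
"""

from __future__ import annotations

import logging
import re

import numpy as np
import pandas as pd

from .features import FeatureMatrix, standardize_columns

logger = logging.getLogger(__name__)

# contigs excluded from analysis: mitochondrial and scaffold/unplaced sequence
EXCLUDED_CONTIG_PATTERN = r"(?i)^(?:chrm|mt|chrmt)$|scaffold|chrun|_random|_alt"


def is_excluded_contig(chroms: pd.Series | np.ndarray, pattern: str = EXCLUDED_CONTIG_PATTERN) -> np.ndarray:
    return pd.Series(chroms).str.contains(pattern, regex=True).to_numpy()


def merge_peaks(
    peaks: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    min_summit_dist: int = 500,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Merge peaks whose summits lie closer than `min_summit_dist` bp.

    Single-linkage chaining per chromosome: consecutive summits strictly
    closer than the threshold join one cluster, so a run of peaks each within
    the threshold of its neighbour collapses to a single feature. The merged
    feature spans min(start)..max(end); its summit is the midpoint of the
    member-summit range, which keeps merged summits at least the threshold
    apart and makes the operation idempotent. Count rows of merged peaks are
    summed. Cross-chromosome pairs never merge.
    """
    if peaks.empty:
        return peaks.copy(), None if counts is None else counts.copy()
    work = peaks.sort_values(["chrom", "summit"], kind="mergesort").reset_index(drop=True)
    same_chrom = work["chrom"].to_numpy()[1:] == work["chrom"].to_numpy()[:-1]
    gap = np.diff(work["summit"].to_numpy())
    new_cluster = np.concatenate([[True], ~(same_chrom & (gap < min_summit_dist))])
    cluster = np.cumsum(new_cluster) - 1

    grouped = work.groupby(cluster, sort=True)
    merged = grouped.agg(
        chrom=("chrom", "first"),
        start=("start", "min"),
        end=("end", "max"),
        name=("name", "first"),
        score=("score", "max"),
        strand=("strand", "first"),
        summit_min=("summit", "min"),
        summit_max=("summit", "max"),
        members=("name", lambda s: ",".join(s)),
        n_members=("name", "size"),
    ).reset_index(drop=True)
    merged["summit"] = (merged["summit_min"] + merged["summit_max"]) // 2
    merged = merged.drop(columns=["summit_min", "summit_max"])
    merged = merged[["chrom", "start", "end", "name", "score", "strand", "summit", "members", "n_members"]]

    merged_counts = None
    if counts is not None:
        mat = counts.loc[work["name"]].to_numpy()
        sums = np.zeros((cluster[-1] + 1, mat.shape[1]), dtype=mat.dtype)
        np.add.at(sums, cluster, mat)
        merged_counts = pd.DataFrame(sums, index=merged["name"].tolist(), columns=counts.columns)
    n_merged = int((merged["n_members"] > 1).sum())
    logger.info("merge_peaks: %d peaks -> %d features (%d merged clusters)", len(peaks), len(merged), n_merged)
    return merged, merged_counts


def filter_peaks(
    peaks: pd.DataFrame,
    counts: pd.DataFrame,
    median_min: float = 20.0,
    contig_pattern: str = EXCLUDED_CONTIG_PATTERN,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep peaks with across-sample median count strictly greater than
    `median_min` on canonical (non-mitochondrial, non-scaffold) contigs.
    Input order is preserved."""
    mat = counts.loc[peaks["name"]].to_numpy()
    medians = np.median(mat, axis=1)
    keep = (medians > median_min) & ~is_excluded_contig(peaks["chrom"], contig_pattern)
    kept = peaks.loc[keep].reset_index(drop=True)
    kept_counts = counts.loc[kept["name"]]
    logger.info(
        "filter_peaks: %d -> %d peaks (median > %g and canonical contig)",
        len(peaks), len(kept), median_min,
    )
    if kept.empty:
        logger.warning("filter_peaks removed every peak; downstream stages will refuse to fit")
    return kept, kept_counts


def rpkm_normalize(
    counts: pd.DataFrame, widths: np.ndarray, lib_sizes: np.ndarray
) -> pd.DataFrame:
    """Reads per kilobase of peak per million library reads:
    count / (width/1e3) / (lib_size/1e6)."""
    widths = np.asarray(widths, dtype=float)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if (widths <= 0).any():
        bad = counts.index[np.flatnonzero(widths <= 0)[0]]
        raise ValueError(f"non-positive peak width for feature {bad!r}")
    if (lib_sizes <= 0).any():
        bad = counts.columns[np.flatnonzero(lib_sizes <= 0)[0]]
        raise ValueError(f"non-positive library size for sample {bad!r}")
    vals = counts.to_numpy(dtype=float) / (widths[:, None] / 1e3) / (lib_sizes[None, :] / 1e6)
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


def log_center_scale(matrix: pd.DataFrame, pseudocount: float = 1.0) -> FeatureMatrix:
    """log2(x + pseudocount), then per-feature centering to mean 0 and scaling
    to sample SD 1. Input is features x samples; output is samples x features."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("log transform requires non-negative values")
    logged = np.log2(matrix.to_numpy(dtype=float) + pseudocount)
    df = pd.DataFrame(logged, index=matrix.index, columns=matrix.columns).T
    scaled, flagged = standardize_columns(df)
    if flagged:
        logger.warning("log_center_scale: %d zero-variance features left at 0", len(flagged))
    return FeatureMatrix(
        values=scaled,
        kind="atac",
        provenance=[f"log2(x + {pseudocount})", "center to mean 0", "scale to sd 1 (n-1)"],
        zero_variance=flagged,
    )


def process_atac(
    peaks: pd.DataFrame,
    counts: pd.DataFrame,
    min_summit_dist: int = 500,
    median_min: float = 20.0,
    pseudocount: float = 1.0,
    contig_pattern: str = EXCLUDED_CONTIG_PATTERN,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Full accessibility pipeline; returns the processed matrix and the
    retained (merged, filtered) peak catalogue.

    Library sizes are the per-sample totals of the input count matrix,
    computed before filtering (merging only reassigns rows, so the totals
    are unaffected by it).
    """
    lib_sizes = counts.sum(axis=0).to_numpy(dtype=float)
    merged, merged_counts = merge_peaks(peaks, counts, min_summit_dist)
    kept, kept_counts = filter_peaks(merged, merged_counts, median_min, contig_pattern)
    widths = (kept["end"] - kept["start"]).to_numpy()
    rpkm = rpkm_normalize(kept_counts, widths, lib_sizes)
    fm = log_center_scale(rpkm, pseudocount)
    fm.provenance = (
        [
            f"merge summits < {min_summit_dist} bp ({len(peaks)} -> {len(merged)})",
            f"median > {median_min} & canonical contig ({len(merged)} -> {len(kept)})",
            "rpkm",
        ]
        + fm.provenance
    )
    return fm, kept
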