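"""Feature annotation and chromatin-state enrichment.

Maps peaks and CpG sites onto a 13-state chromatin segmentation (maximal
base-pair overlap), tests whether states are enriched among age-increasing
versus age-decreasing peaks with a two-sided Fisher exact test, assigns each
feature its nearest gene, and computes the three-clock nearest-gene overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


def _validate_statemap(states: pd.DataFrame) -> None:
    if (states["start"] >= states["end"]).any():
        bad = states[states["start"] >= states["end"]].iloc[0]
        raise ValueError(f"malformed state interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    for chrom, grp in states.groupby("chrom"):
        srt = grp.sort_values("start")
        if (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping state intervals on {chrom}")


def assign_state(
    features: pd.DataFrame, states: pd.DataFrame, mode: str = "max_overlap"
) -> pd.Series:
    """State label per feature, indexed by feature name.

    `features` needs chrom/start/end (half-open) and a name column (or an
    index of names). With mode="max_overlap" a feature spanning several state
    intervals gets the state covering it by the most bases (ties to the
    leftmost interval); mode="midpoint" uses the interval containing the
    feature midpoint. Features overlapping nothing are "unannotated".
    """
    if mode not in ("max_overlap", "midpoint"):
        raise ValueError(f"unknown mode {mode!r}")
    _validate_statemap(states)
    names = features["name"] if "name" in features.columns else features.index.to_series()
    out = pd.Series(UNANNOTATED, index=pd.Index(names, name="feature_id"), dtype=object)
    if features.empty:
        return out
    work = features.copy()
    if mode == "midpoint":
        mid = (work["start"] + work["end"]) // 2
        work = work.assign(start=mid, end=mid + 1)
    by_chrom = {c: g.sort_values("start") for c, g in states.groupby("chrom")}
    labels = np.array(out, dtype=object)
    feat_pos = {n: i for i, n in enumerate(out.index)}
    for chrom, grp in work.groupby("chrom"):
        seg = by_chrom.get(chrom)
        if seg is None:
            continue
        seg_start = seg["start"].to_numpy()
        seg_end = seg["end"].to_numpy()
        seg_state = seg["state"].to_numpy()
        for name, s, e in zip(
            grp["name"] if "name" in grp.columns else grp.index, grp["start"], grp["end"]
        ):
            lo = int(np.searchsorted(seg_end, s, side="right"))
            hi = int(np.searchsorted(seg_start, e, side="left"))
            if hi <= lo:
                continue
            overlaps = np.minimum(seg_end[lo:hi], e) - np.maximum(seg_start[lo:hi], s)
            labels[feat_pos[name]] = seg_state[lo + int(np.argmax(overlaps))]
    return pd.Series(labels, index=out.index, name="state")


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test by hypergeometric-support summation.

    p sums the probabilities of every table with the observed margins whose
    probability does not exceed the observed table's (within relative
    tolerance 1e-7 to guard float ties). The odds ratio is (a d)/(b c), with
    a 0.5 continuity correction applied only when some cell is zero; a zero
    margin gives p = 1 and an undefined (NaN) odds ratio.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        if (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if r1 == 0 or c1 == 0 or r1 == n or c1 == n:
        return float("nan"), 1.0
    if (a == 0) or (b == 0) or (c == 0) or (d == 0):
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    support = np.arange(max(0, r1 + c1 - n), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return float(odds), min(p, 1.0)


@dataclass
class EnrichmentResult:
    state: str
    table: np.ndarray       # [[in-state inc, in-state dec], [other inc, other dec]]
    odds_ratio: float
    p: float
    q: float = np.nan


def state_enrichment(
    directions: pd.Series, states: pd.Series, method: str = "bh"
) -> pd.DataFrame:
    """Per-state 2x2 Fisher test of direction composition.

    Only direction-classified ('increasing'/'decreasing') peaks enter. For
    each state s the table is (state == s vs != s) x (increasing vs
    decreasing); odds ratio > 1 means s is enriched among increasing peaks.
    BH adjustment spans the tested states.
    """
    aligned = pd.DataFrame({"direction": directions, "state": states}).dropna()
    aligned = aligned[aligned["direction"].isin(["increasing", "decreasing"])]
    n_inc = int((aligned["direction"] == "increasing").sum())
    n_dec = int((aligned["direction"] == "decreasing").sum())
    if n_inc < 1 or n_dec < 1:
        raise ValueError(
            f"state enrichment needs at least one peak per direction "
            f"(increasing={n_inc}, decreasing={n_dec})"
        )
    rows = []
    inc = aligned["direction"].to_numpy() == "increasing"
    state_arr = aligned["state"].to_numpy()
    for state in sorted(aligned["state"].unique(), key=str):
        if state == UNANNOTATED:
            logger.info("state_enrichment: skipping unannotated peaks")
            continue
        in_state = state_arr == state
        a = int((in_state & inc).sum())
        b = int((in_state & ~inc).sum())
        c = n_inc - a
        d = n_dec - b
        odds, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append((state, a, b, c, d, odds, p))
    out = pd.DataFrame(rows, columns=["state", "a", "b", "c", "d", "odds_ratio", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy(), method=method)
    return out


def nearest_gene(features: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per feature (strand-agnostic gene-body distance).

    Distance is 0 when the feature overlaps the gene body, otherwise the gap
    between the intervals. Ties break to the gene with the smaller start,
    then the lexicographically smaller name. Features on contigs with no
    genes get gene NA / distance NaN.
    """
    if genes.empty:
        raise ValueError("empty gene set")
    names = features["name"] if "name" in features.columns else features.index.to_series()
    result = pd.DataFrame(
        {"gene": pd.Series(pd.NA, index=names, dtype=object),
         "distance": pd.Series(np.nan, index=names)},
    )
    result.index.name = "feature_id"
    gsorted = genes.sort_values(["start", "name"], kind="mergesort")
    for chrom, grp in features.groupby("chrom"):
        g = gsorted[gsorted["chrom"] == chrom]
        if g.empty:
            logger.info("nearest_gene: no genes on %s", chrom)
            continue
        gs, ge = g["start"].to_numpy(), g["end"].to_numpy()
        gnames = g["name"].to_numpy()
        fs = grp["start"].to_numpy()[:, None]
        fe = grp["end"].to_numpy()[:, None]
        gap = np.maximum(np.maximum(gs[None, :] - fe, fs - ge[None, :]), 0)
        best = np.argmin(gap, axis=1)  # first minimum = smallest start, then name
        fnames = grp["name"] if "name" in grp.columns else grp.index
        result.loc[list(fnames), "gene"] = gnames[best]
        result.loc[list(fnames), "distance"] = gap[np.arange(len(grp)), best].astype(float)
    return result


def clock_gene_overlap(
    selected_features: dict[str, set[str]], gene_map: pd.Series
) -> dict:
    """Three-clock nearest-gene overlap.

    `selected_features` maps each clock label to its ever-selected epigenetic
    feature ids; `gene_map` maps feature id -> nearest gene. Returns the
    unique gene set per clock, all seven Venn-region counts, and the triple
    intersection gene list.
    """
    clocks = list(selected_features)
    gene_sets = {
        clock: {gene_map[f] for f in feats if f in gene_map.index and pd.notna(gene_map[f])}
        for clock, feats in selected_features.items()
    }
    regions: dict[str, int] = {}
    for r in range(1, len(clocks) + 1):
        for combo in combinations(clocks, r):
            inside = set.intersection(*(gene_sets[c] for c in combo)) if combo else set()
            outside = set.union(*(gene_sets[c] for c in clocks if c not in combo), set())
            regions["&".join(combo)] = len(inside - outside)
    intersection = sorted(set.intersection(*gene_sets.values())) if clocks else []
    return {
        "genes_per_clock": {c: sorted(gene_sets[c]) for c in clocks},
        "venn_counts": regions,
        "intersection": intersection,
        "n_intersection": len(intersection),
    }
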