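#!/usr/bin/env python
"""Score the clocks and test residual age.

Reports R2_adj / RMSE overall and by breed-size stratum, computes residual
age (residuals of predicted-versus-observed OLS), regresses it on breed mean
weight, correlates residuals across clocks, and maps each clock's
ever-selected epigenetic features to nearest genes for the three-clock
overlap."""

import argparse
from pathlib import Path

import pandas as pd

from dogclock import io as dio
from dogclock.annotation import clock_gene_overlap, nearest_gene
from dogclock.evaluation import (
    cross_clock_residual_correlation,
    residual_age,
    residual_vs_weight,
    stratified_evaluation,
)

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

meta = dio.read_metadata(args.data / "metadata.tsv").set_index("sample_id")
residuals, rows = {}, []
for dt in ("atac", "dnam", "combined"):
    preds = dio.read_association(args.out / f"clock_{dt}_predictions.tsv")
    cats = meta.loc[preds.sample_id, "weight_category"].to_numpy()
    for ev in stratified_evaluation(preds.predicted_age, preds.age, cats):
        rows.append({"data_type": dt, "stratum": ev.stratum, "n": ev.n,
                     "r2_adj": ev.r2_adj, "rmse": ev.rmse})
    residuals[dt] = residual_age(preds.predicted_age, preds.age)
    weights = meta.loc[preds.sample_id, "breed_weight_kg"].to_numpy()
    slope, p, _ = residual_vs_weight(residuals[dt], weights)
    overall = next(r for r in rows if r["data_type"] == dt and r["stratum"] == "all")
    print(f"{dt}: R2_adj={overall['r2_adj']:.3f} RMSE={overall['rmse']:.2f}; "
          f"residual age vs weight: slope {slope:+.4f}/kg (p={p:.3f})")
evaluation = pd.DataFrame(rows)
dio.write_association(evaluation, args.out / "clock_evaluation.tsv")

for a, b in [("atac", "dnam"), ("atac", "combined"), ("dnam", "combined")]:
    r, p = cross_clock_residual_correlation(residuals[a], residuals[b])
    print(f"residual correlation {a} vs {b}: r={r:.2f} (p={p:.3f})")

genes = dio.read_genes(args.data / "genes.bed")
peaks = dio.read_peaks(args.out / "retained_peaks.bed")
ever = {}
for dt in ("atac", "dnam", "combined"):
    freq = dio.read_association(args.out / f"clock_{dt}_selection.tsv").set_index("feature_id")
    col = freq.columns[0]
    epi = freq[~freq.index.str.startswith(("cell.", "meta."))]
    ever[dt] = set(epi.index[epi[col] > 0])
cpg = sorted(set().union(*ever.values()) - set(peaks["name"]))
cpg_coords = pd.DataFrame({
    "chrom": [s.rsplit(":", 1)[0] for s in cpg],
    "start": [int(s.rsplit(":", 1)[1]) - 1 for s in cpg],
    "end": [int(s.rsplit(":", 1)[1]) for s in cpg],
    "name": cpg,
})
coords = pd.concat([peaks[["chrom", "start", "end", "name"]], cpg_coords], ignore_index=True)
gene_map = nearest_gene(coords, genes)["gene"].dropna()
overlap = clock_gene_overlap(ever, gene_map)
print(f"ever-selected features: " +
      ", ".join(f"{dt}={len(v)}" for dt, v in ever.items()))
print(f"genes shared by all three clocks: {overlap['n_intersection']}")
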