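#!/usr/bin/env python
"""Build the analysis-ready feature matrices.

ATAC: peaks with summits closer than 500 bp merge into single features;
features need an across-sample median of more than 20 reads and a canonical
contig; counts become RPKM, then log2, then per-feature standardization.
Methylation: per-site methylated fractions; sites need mean depth >= 5x, a
median fraction inside [0.1, 0.9] and a canonical contig; fractions are
standardized without a log transform."""

import argparse
from pathlib import Path

from dogclock import io as dio
from dogclock.atac import process_atac
from dogclock.methylation import process_methylation

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

peaks = dio.read_peaks(args.data / "peaks.bed")
counts = dio.read_count_matrix(args.data / "atac_counts.tsv")
atac_fm, retained = process_atac(peaks, counts)
dio.write_matrix(atac_fm.values, args.out / "processed_atac.tsv", atac_fm.provenance)
dio.write_peaks(retained, args.out / "retained_peaks.bed")
print(f"ATAC: {len(peaks)} peaks -> {atac_fm.values.shape[1]} features "
      f"({'; '.join(atac_fm.provenance[:2])})")

meta = dio.read_metadata(args.data / "metadata.tsv")
meth = dio.read_coverage_dir(args.data / "coverage", meta["sample_id"])
dnam_fm = process_methylation(meth)
dio.write_matrix(dnam_fm.values, args.out / "processed_dnam.tsv", dnam_fm.provenance)
print(f"DNAm: {len(meth.sites)} sites -> {dnam_fm.values.shape[1]} features")
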