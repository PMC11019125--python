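#!/usr/bin/env python
"""Generate the synthetic study cohort.

Emulates the post-quantification inputs of the dog aging study: 71 dogs aged
1-16 with owner-reported metadata and 31 flow-cytometry cell-type
proportions (two of which truly increase with age), per-CpG methylation
counts, an ATAC consensus-peak count matrix, a 13-state chromatin
segmentation and a gene annotation, plus the ground-truth manifest of the 5%
of features that carry a real age effect. Outputs land in
results/analysis/data/."""

import argparse
from pathlib import Path

from dogclock.config import SimulationConfig
from dogclock.simulate import simulate_dataset, write_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results/analysis/data"))
args = parser.parse_args()

config = SimulationConfig(seed=args.seed)
dataset = simulate_dataset(config)
paths = write_dataset(dataset, args.out)

meta = dataset.metadata
print(f"cohort: {len(meta)} dogs, ages {meta.age.min()}-{meta.age.max()}, "
      f"{(meta.sex == 'F').sum()} F / {(meta.sex == 'M').sum()} M")
print(f"peaks: {len(dataset.atac.peaks)} (incl. {config.n_decoy_features} decoys), "
      f"CpG sites: {len(dataset.methylation.sites)}")
print(f"truly age-associated: {len(dataset.truth.age_assoc_atac_ids)} peaks, "
      f"{len(dataset.truth.age_assoc_meth_ids)} CpGs")
print(f"written to {args.out}")
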