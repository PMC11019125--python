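#!/usr/bin/env python
"""Fit the three elastic-net age clocks (ATAC, DNAm, combined).

For each data type, a leave-one-out loop fits 71 models: on each fold the
inner 10-fold CV picks lambda (alpha fixed at 0.5), a final KKT-certified
model is fit, and the held-out dog's age is predicted. The design offers
the epigenetic features plus the meta features (all cell-type proportions
and ordinal breed weight category) for selection."""

import argparse
from pathlib import Path

import numpy as np

from dogclock import io as dio
from dogclock.clock import build_design, loocv_clock
from dogclock.features import FeatureMatrix

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

meta = dio.read_metadata(args.data / "metadata.tsv")
blocks = {}
for kind in ("atac", "dnam"):
    values, prov = dio.read_matrix(args.out / f"processed_{kind}.tsv")
    blocks[kind] = FeatureMatrix(values=values, kind=kind, provenance=prov)

designs = {
    "atac": build_design(blocks["atac"], meta, "atac"),
    "dnam": build_design(blocks["dnam"], meta, "dnam"),
    "combined": build_design([blocks["atac"], blocks["dnam"]], meta, "combined"),
}
for dt, design in designs.items():
    ages = meta.set_index("sample_id").loc[design.sample_ids, "age"]
    res = loocv_clock(design, ages, seed=args.seed)
    dio.write_association(res.predictions_frame(), args.out / f"clock_{dt}_predictions.tsv")
    dio.write_association(res.selection_frequency().reset_index(),
                          args.out / f"clock_{dt}_selection.tsv")
    dio.write_model_archive(res, args.out / f"clock_{dt}_models.jsonl")
    lam = res.lambdas()
    nsel = [f.n_selected() for f in res.folds]
    print(f"{dt}: {len(res.folds)} folds, median lambda {np.median(lam):.3g}, "
          f"median features/model {int(np.median(nsel))}")
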