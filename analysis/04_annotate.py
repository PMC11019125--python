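#!/usr/bin/env python
"""Chromatin-state annotation and direction enrichment.

Every retained peak gets the chromatin state (1-13) covering it by the most
bases; for each state a 2x2 Fisher exact test asks whether age-increasing
versus age-decreasing peaks fall in it disproportionately (odds ratio > 1:
enriched among increasing peaks)."""

import argparse
from pathlib import Path

from dogclock import io as dio
from dogclock.annotation import assign_state, state_enrichment

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

peaks = dio.read_peaks(args.out / "retained_peaks.bed")
states = dio.read_states(args.data / "states.bed")
assigned = assign_state(peaks, states)
assigned.rename("state").reset_index().to_csv(
    args.out / "peak_states.tsv", sep="\t", index=False
)
print(f"assigned states to {len(assigned)} peaks "
      f"({(assigned == 'unannotated').sum()} unannotated)")

table = dio.read_association(args.out / "association_atac.tsv")
directions = table.set_index("feature_id")["direction"]
try:
    enr = state_enrichment(directions, assigned)
    dio.write_association(enr, args.out / "state_enrichment.tsv")
    hits = enr[enr.q < 0.05]
    print(f"state enrichment: {len(hits)} of {len(enr)} states at q<0.05")
    for _, row in hits.iterrows():
        side = "increasing" if row.odds_ratio > 1 else "decreasing"
        print(f"  state {row.state}: OR={row.odds_ratio:.2f} (enriched among {side}), q={row.q:.3g}")
except ValueError as exc:
    print(f"state enrichment skipped: {exc}")
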