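#!/usr/bin/env python
"""Per-feature age models and the metadata/age screen.

Each feature is regressed on age with breed weight, sex, exercise and the
two age-correlated memory T-cell proportions as covariates; age-term
p-values get Benjamini-Hochberg adjustment and significant features are
labelled increasing/decreasing. The screen regresses each cell-type
proportion on age and ANOVAs age across the levels of each categorical
variable."""

import argparse
from pathlib import Path

from dogclock import io as dio
from dogclock.association import associate_features, screen_metadata_age
from dogclock.features import FeatureMatrix

parser = argparse.ArgumentParser()
parser.add_argument("--data", type=Path, default=Path("results/analysis/data"))
parser.add_argument("--out", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

meta = dio.read_metadata(args.data / "metadata.tsv")
for kind in ("atac", "dnam"):
    values, prov = dio.read_matrix(args.out / f"processed_{kind}.tsv")
    fm = FeatureMatrix(values=values, kind=kind, provenance=prov)
    table = associate_features(fm, meta)
    dio.write_association(table, args.out / f"association_{kind}.tsv")
    sig = table[table.q < 0.05]
    print(f"{kind}: {len(sig)}/{len(table)} age-associated at q<0.05 "
          f"({(sig.direction == 'decreasing').sum()} decreasing, "
          f"{(sig.direction == 'increasing').sum()} increasing)")

screen = screen_metadata_age(meta)
dio.write_association(screen, args.out / "metadata_screen.tsv")
flagged = screen[screen.q < 0.05]["variable"].tolist()
print(f"metadata screen: {flagged} significantly associated with age")
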