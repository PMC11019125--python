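import numpy as np
import pandas as pd
import pytest

from dogclock.config import SimulationConfig
from dogclock.simulate import MethylationData, simulate_dataset


@pytest.fixture(scope="session")
def dataset():
    """A small signal-bearing synthetic cohort shared across tests."""
    return simulate_dataset(
        SimulationConfig(
            n_samples=40, n_cpg_sites=300, n_atac_peaks=300, n_decoy_features=10, seed=7
        )
    )


@pytest.fixture(scope="session")
def toy_peaks():
    """10 peaks with engineered failures: 3 fail the median>20 filter (one at
    the exact boundary), 1 sits on a scaffold; 6 survive."""
    samples = [f"s{i}" for i in range(11)]  # odd count -> median is an entry
    rows, counts = [], {}

    def add(name, chrom, start, median):
        rows.append((chrom, start, start + 200, name, 0, ".", start + 100))
        vals = np.full(11, median, dtype=int)
        vals[:3] = median - 2 if median >= 2 else 0   # some spread, same median
        vals[-3:] = median + 2
        counts[name] = vals

    add("p01", "chr1", 1_000, 5)        # fails median
    add("p02", "chr1", 3_000, 0)        # fails median
    add("p03", "chr1", 5_000, 20)       # exact boundary: 20 is NOT > 20
    add("p04", "chr1", 7_000, 21)       # just above: retained
    add("p05", "chr1", 9_000, 50)
    add("p06", "chr1", 11_000, 100)
    add("p07", "chr2", 1_000, 30)
    add("p08", "chr2", 3_000, 45)
    add("p09", "chr2", 5_000, 80)
    add("p10", "scaffold_1", 1_000, 100)  # high coverage but excluded contig

    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand", "summit"]
    )
    count_df = pd.DataFrame(counts, index=samples).T
    manifest = {"retained": ["p04", "p05", "p06", "p07", "p08", "p09"], "n_retained": 6}
    return peaks, count_df, manifest


@pytest.fixture(scope="session")
def toy_methylation():
    """20 CpG sites with 6 engineered failures: 2 below mean depth 5, 2
    constitutively hyper- (median 0.95), 1 hypo-methylated (median 0.05),
    1 on chrM; 14 survive."""
    samples = [f"s{i}" for i in range(8)]
    sites, meth_rows, unmeth_rows = [], [], []

    def add(chrom, pos, depth, frac):
        depth = np.asarray(depth, dtype=int)
        m = np.rint(depth * frac).astype(int)
        sites.append((chrom, pos, f"{chrom}:{pos}"))
        meth_rows.append(m)
        unmeth_rows.append(depth - m)

    add("chr1", 101, [4] * 8, 0.5)                    # mean depth 4 -> fail
    add("chr1", 201, [5] * 7 + [4], 0.5)              # mean 4.875 -> fail
    add("chr1", 301, [20] * 8, 0.95)                  # hyper -> fail
    add("chr1", 401, [20] * 8, 0.95)                  # hyper -> fail
    add("chr1", 501, [20] * 8, 0.05)                  # hypo -> fail
    add("chrM", 601, [30] * 8, 0.5)                   # decoy contig -> fail
    add("chr1", 701, [5] * 8, 0.5)                    # exact depth boundary -> keep
    add("chr1", 801, [20] * 8, 0.9)                   # exact median boundary -> keep
    add("chr1", 901, [20] * 8, 0.1)                   # exact median boundary -> keep
    for i in range(11):                               # 11 ordinary keepers
        add("chr2", 101 + 100 * i, [10 + i] * 8, 0.3 + 0.04 * i)

    site_df = pd.DataFrame(sites, columns=["chrom", "pos", "site_id"])
    ids = site_df["site_id"].tolist()
    meth = pd.DataFrame(np.array(meth_rows), index=ids, columns=samples)
    unmeth = pd.DataFrame(np.array(unmeth_rows), index=ids, columns=samples)
    manifest = {"n_retained": 14, "removed": ids[:6]}
    return MethylationData(sites=site_df, methylated=meth, unmethylated=unmeth), manifest
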