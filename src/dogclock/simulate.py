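"""Synthetic dog-cohort generator.

Emulates the post-quantification inputs of a companion-dog aging study:
owner-reported metadata with flow-cytometry cell-type proportions, RRBS-style
per-CpG methylated/unmethylated counts, an ATAC-style consensus peak set with
a peak x sample read-count matrix, a 13-state chromatin segmentation of a toy
genome, and a gene annotation — together with a ground-truth manifest of which
features truly change with age, so every downstream stage can be tested for
recovery without any external download.

Ages are drawn as whole years, uniform over the configured range; cell-type
proportions are "percent of parent gate" values, unconstrained across types.
Methylated counts are Binomial over a negative-binomial read depth with
logit(p) linear in age; accessibility counts are negative binomial with
log-mean linear in age plus a per-sample library-size offset. Decoy features
on chrM and scaffold contigs, constitutively hyper/hypo-methylated sites, and
low-coverage peaks are planted deliberately so the quality-control filters
have something to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

CELL_CD8 = "cell.CD8"   # CD62L+/CD44+/CD8+ memory-like T-cell gate
CELL_DN = "cell.DN"     # CD62L+/CD44+/CD4-CD8- (double-negative) gate
EXERCISE_LEVELS = ("light", "moderate", "vigorous")
WEIGHT_CATEGORIES = ("small", "medium", "large")

# RNG substream tags so each stage is independently reproducible
_STREAM_COHORT, _STREAM_METH, _STREAM_ATAC, _STREAM_ANNOT = 1, 2, 3, 4


@dataclass
class GroundTruth:
    """Which simulated features truly carry an age effect, and how strongly."""

    age_assoc_meth_ids: set[str] = field(default_factory=set)
    age_assoc_atac_ids: set[str] = field(default_factory=set)
    true_slopes: dict[str, float] = field(default_factory=dict)
    true_cell_slopes: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            age_assoc_meth_ids=self.age_assoc_meth_ids | other.age_assoc_meth_ids,
            age_assoc_atac_ids=self.age_assoc_atac_ids | other.age_assoc_atac_ids,
            true_slopes={**self.true_slopes, **other.true_slopes},
            true_cell_slopes={**self.true_cell_slopes, **other.true_cell_slopes},
        )


@dataclass
class MethylationData:
    """Per-site counts across the cohort: sites x samples matrices."""

    sites: pd.DataFrame          # columns: chrom, pos (1-based), site_id
    methylated: pd.DataFrame     # sites x samples
    unmethylated: pd.DataFrame   # sites x samples

    @property
    def depth(self) -> pd.DataFrame:
        return self.methylated + self.unmethylated


@dataclass
class AtacData:
    peaks: pd.DataFrame   # chrom, start, end, name, score, strand, summit (absolute bp)
    counts: pd.DataFrame  # peaks x samples


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    metadata: pd.DataFrame
    methylation: MethylationData
    atac: AtacData
    states: pd.DataFrame  # chrom, start, end, state
    genes: pd.DataFrame   # chrom, start, end, name, score, strand
    truth: GroundTruth


def cell_type_names(config: SimulationConfig) -> list[str]:
    names = [CELL_CD8, CELL_DN]
    names += [f"cell.T{i:02d}" for i in range(3, config.n_cell_types + 1)]
    return names[: config.n_cell_types]


def chromosome_lengths(config: SimulationConfig) -> dict[str, int]:
    """Deterministic toy-genome geometry, sized to hold the peak catalogue."""
    per_chrom = -(-config.n_atac_peaks // config.n_chromosomes)  # ceil
    length = per_chrom * 4000 + 20_000
    return {f"chr{i + 1}": length for i in range(config.n_chromosomes)}


def _weight_category(weights: np.ndarray, thresholds: tuple[float, float]) -> np.ndarray:
    lo, hi = thresholds
    cats = np.where(weights < lo, "small", np.where(weights < hi, "medium", "large"))
    return cats


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate the sample-metadata table.

    Designated cell types increase linearly with age in expectation; exercise
    shifts stochastically toward less vigorous levels in older dogs; every
    other variable is age-independent.
    """
    rng = np.random.default_rng([config.seed, _STREAM_COHORT])
    n = config.n_samples
    lo, hi = config.age_range
    ages = rng.integers(lo, hi + 1, size=n)
    sexes = rng.choice(["F", "M"], size=n)

    n_breeds = 30
    breed_names = [f"Breed{i:02d}" for i in range(1, n_breeds + 1)]
    breed_weights = np.exp(rng.uniform(np.log(4.0), np.log(60.0), size=n_breeds))
    breed_idx = rng.integers(0, n_breeds, size=n)
    weights = breed_weights[breed_idx]

    # exercise vigor declines with age (softmax over age-linear scores)
    scores = np.stack(
        [
            -0.8 + 0.12 * ages,   # light
            np.zeros(n),          # moderate
            0.8 - 0.12 * ages,    # vigorous
        ],
        axis=1,
    )
    probs = np.exp(scores)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.uniform(size=n)
    exercise = np.array(EXERCISE_LEVELS)[(u[:, None] > cum).sum(axis=1)]

    cells = cell_type_names(config)
    baselines = rng.uniform(10.0, 60.0, size=len(cells))
    true_cell_slopes: dict[str, float] = {}
    data = {}
    for t, cell in enumerate(cells):
        slope = config.celltype_age_slope if t < config.n_age_assoc_cell_types else 0.0
        vals = baselines[t] + slope * ages + rng.normal(0.0, config.celltype_noise_sd, size=n)
        data[cell] = np.clip(vals, 0.0, 100.0)
        if slope != 0.0:
            true_cell_slopes[cell] = slope

    meta = pd.DataFrame(
        {
            "sample_id": [f"dog_{i + 1:03d}" for i in range(n)],
            "age": ages,
            "sex": sexes,
            "breed": [breed_names[i] for i in breed_idx],
            "breed_weight_kg": np.round(weights, 2),
            "weight_category": _weight_category(weights, config.weight_thresholds),
            "exercise": exercise,
            **data,
        }
    )
    return meta, GroundTruth(true_cell_slopes=true_cell_slopes)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_param: np.ndarray) -> np.ndarray:
    """Negative binomial via gamma-Poisson mixture; `size_param` broadcast over rows."""
    lam = rng.gamma(shape=size_param, scale=mean / size_param)
    return rng.poisson(lam)


def simulate_methylation(
    metadata: pd.DataFrame, config: SimulationConfig
) -> tuple[MethylationData, GroundTruth]:
    """Per-CpG methylated/unmethylated counts for every sample.

    logit(p_ij) = baseline_i + slope_i * age_j; read depth is negative
    binomial with the configured mean. Exactly
    round(frac_age_assoc_meth * n_cpg_sites) canonical sites carry nonzero
    slopes; a configured minority of sites is constitutively extreme; decoy
    sites sit on chrM and scaffold contigs.
    """
    rng = np.random.default_rng([config.seed, _STREAM_METH])
    n_sites, n_decoy = config.n_cpg_sites, config.n_decoy_features
    ages = metadata["age"].to_numpy(dtype=float)
    samples = metadata["sample_id"].tolist()

    lengths = chromosome_lengths(config)
    chrom_names = list(lengths)
    chroms = np.array(chrom_names)[rng.integers(0, len(chrom_names), size=n_sites)]
    positions = np.array([rng.integers(1, lengths[c]) for c in chroms])
    # decoys: half chrM, half scaffold
    d_chroms = np.array(["chrM"] * (n_decoy // 2) + [f"scaffold_{i + 1}" for i in range(n_decoy - n_decoy // 2)])
    d_pos = rng.integers(1, 16_000, size=n_decoy)
    all_chroms = np.concatenate([chroms, d_chroms]) if n_decoy else chroms
    all_pos = np.concatenate([positions, d_pos]) if n_decoy else positions
    # site ids must be unique; resolve position collisions deterministically
    seen: set[tuple[str, int]] = set()
    for i in range(len(all_pos)):
        while (all_chroms[i], int(all_pos[i])) in seen:
            all_pos[i] = int(all_pos[i]) + 1
        seen.add((all_chroms[i], int(all_pos[i])))
    site_ids = [f"{c}:{p}" for c, p in zip(all_chroms, all_pos)]

    total = n_sites + n_decoy
    baseline = rng.normal(0.0, 1.2, size=total)
    n_extreme = int(round(config.frac_extreme_meth * n_sites))
    extreme_idx = rng.choice(n_sites, size=n_extreme, replace=False)
    baseline[extreme_idx] = rng.choice([-4.0, 4.0], size=n_extreme)

    slopes = np.zeros(total)
    n_assoc = int(round(config.frac_age_assoc_meth * n_sites))
    candidates = np.setdiff1d(np.arange(n_sites), extreme_idx)
    assoc_idx = rng.choice(candidates, size=n_assoc, replace=False)
    slopes[assoc_idx] = rng.normal(0.0, config.meth_age_slope_sd, size=n_assoc)
    # guard against a drawn slope of exactly zero
    slopes[assoc_idx[slopes[assoc_idx] == 0.0]] = config.meth_age_slope_sd

    size_param = np.exp(
        rng.normal(config.nb_dispersion_meanlog, config.nb_dispersion_sdlog, size=total)
    )
    mean_depth = np.full((total, len(samples)), config.mean_depth_meth)
    depth = _nb_counts(rng, mean_depth, size_param[:, None])
    logit_p = baseline[:, None] + slopes[:, None] * ages[None, :]
    p = 1.0 / (1.0 + np.exp(-logit_p))
    meth = rng.binomial(depth, p)

    sites = pd.DataFrame({"chrom": all_chroms, "pos": all_pos.astype(int), "site_id": site_ids})
    meth_df = pd.DataFrame(meth, index=site_ids, columns=samples)
    unmeth_df = pd.DataFrame(depth - meth, index=site_ids, columns=samples)
    truth = GroundTruth(
        age_assoc_meth_ids={site_ids[i] for i in assoc_idx},
        true_slopes={site_ids[i]: float(slopes[i]) for i in assoc_idx},
    )
    return MethylationData(sites=sites, methylated=meth_df, unmethylated=unmeth_df), truth


def simulate_atac(
    metadata: pd.DataFrame, config: SimulationConfig
) -> tuple[AtacData, GroundTruth]:
    """Consensus-peak catalogue plus peak x sample counts.

    log E[count_ij] = baseline_i + slope_i * age_j + u_j where the library
    offsets u_j are rescaled to span exactly [-log 1.5, log 1.5] so library
    sizes always vary >= 2-fold. Peak 1 and 2 on chr1 are planted with summits
    400 bp apart to exercise summit merging; a configured fraction of peaks is
    low coverage and decoys sit on chrM / scaffold contigs.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ATAC])
    n_peaks, n_decoy = config.n_atac_peaks, config.n_decoy_features
    ages = metadata["age"].to_numpy(dtype=float)
    samples = metadata["sample_id"].tolist()
    n_samples = len(samples)

    lengths = chromosome_lengths(config)
    chrom_names = list(lengths)
    per_chrom = -(-n_peaks // len(chrom_names))

    rows = []
    k = 0
    for chrom in chrom_names:
        pos = 10_000
        for _ in range(min(per_chrom, n_peaks - k)):
            width = int(rng.integers(200, 801))
            gap = int(rng.integers(1200, 3001))
            start = pos + gap
            end = start + width
            summit = start + int(rng.integers(width // 4, 3 * width // 4 + 1))
            rows.append((chrom, start, end, f"peak_{k + 1:06d}", 0, ".", summit))
            pos = end
            k += 1
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand", "summit"])

    if len(peaks) >= 2:
        # plant a close summit pair: move peak 2 right next to peak 1 on chr1
        s0 = int(peaks.loc[0, "summit"])
        w1 = int(peaks.loc[1, "end"] - peaks.loc[1, "start"])
        new_summit = s0 + 400
        new_start = max(new_summit - w1 // 2, int(peaks.loc[0, "start"]) + 1)
        peaks.loc[1, ["chrom", "start", "end", "summit"]] = (
            peaks.loc[0, "chrom"], new_start, new_start + w1, new_summit,
        )

    if n_decoy:
        d_rows = []
        for i in range(n_decoy):
            chrom = "chrM" if i < n_decoy // 2 else f"scaffold_{i - n_decoy // 2 + 1}"
            start = 100 + 1500 * i
            width = int(rng.integers(200, 801))
            d_rows.append((chrom, start, start + width, f"decoy_{i + 1:04d}", 0, ".", start + width // 2))
        peaks = pd.concat(
            [peaks, pd.DataFrame(d_rows, columns=peaks.columns)], ignore_index=True
        )

    total = len(peaks)
    baseline = rng.normal(np.log(config.mean_depth_atac), 0.8, size=total)
    n_low = int(round(config.frac_low_coverage_atac * n_peaks))
    low_idx = rng.choice(n_peaks, size=n_low, replace=False)
    baseline[low_idx] = np.log(5.0)

    slopes = np.zeros(total)
    n_assoc = int(round(config.frac_age_assoc_atac * n_peaks))
    candidates = np.setdiff1d(np.arange(n_peaks), low_idx)
    assoc_idx = rng.choice(candidates, size=n_assoc, replace=False)
    slopes[assoc_idx] = rng.normal(0.0, config.atac_age_slope_sd, size=n_assoc)
    slopes[assoc_idx[slopes[assoc_idx] == 0.0]] = config.atac_age_slope_sd

    u = rng.uniform(-1.0, 1.0, size=n_samples)
    if n_samples > 1:  # rescale to span exactly [-log 1.5, log 1.5]
        u = (u - u.min()) / (u.max() - u.min()) * (2 * np.log(1.5)) - np.log(1.5)
    size_param = np.exp(
        rng.normal(config.nb_dispersion_meanlog, config.nb_dispersion_sdlog, size=total)
    )
    log_mean = baseline[:, None] + slopes[:, None] * ages[None, :] + u[None, :]
    counts = _nb_counts(rng, np.exp(log_mean), size_param[:, None])

    counts_df = pd.DataFrame(counts, index=peaks["name"].tolist(), columns=samples)
    names = peaks["name"].tolist()
    truth = GroundTruth(
        age_assoc_atac_ids={names[i] for i in assoc_idx},
        true_slopes={names[i]: float(slopes[i]) for i in assoc_idx},
    )
    return AtacData(peaks=peaks, counts=counts_df), truth


def simulate_annotation(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromatin-state segmentation and gene set for the toy genome.

    Each canonical chromosome is tiled end-to-end by non-overlapping state
    intervals labelled "1".."13" (all 13 labels guaranteed to appear); genes
    get unique names, a strand, and widths of 1-10 kb.
    """
    rng = np.random.default_rng([config.seed, _STREAM_ANNOT])
    lengths = chromosome_lengths(config)

    state_rows = []
    for chrom, length in lengths.items():
        pos = 0
        while pos < length:
            width = int(rng.integers(500, 5001))
            end = min(pos + width, length)
            state_rows.append((chrom, pos, end, 0))
            pos = end
    states = pd.DataFrame(state_rows, columns=["chrom", "start", "end", "state"])
    labels = rng.integers(1, 14, size=len(states))
    labels[:13] = rng.permutation(np.arange(1, 14))
    states["state"] = labels.astype(str)

    n_genes = max(20, config.n_atac_peaks // 10)
    gene_rows = []
    chrom_names = list(lengths)
    for g in range(n_genes):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        width = int(rng.integers(1000, 10_001))
        start = int(rng.integers(0, max(lengths[chrom] - width, 1)))
        strand = "+" if rng.uniform() < 0.5 else "-"
        gene_rows.append((chrom, start, start + width, f"gene_{g + 1:04d}", 0, strand))
    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    genes = genes.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    return states, genes


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all generators and bundle the complete synthetic study."""
    metadata, truth_c = simulate_cohort(config)
    meth, truth_m = simulate_methylation(metadata, config)
    atac, truth_a = simulate_atac(metadata, config)
    states, genes = simulate_annotation(config)
    truth = truth_c.merge(truth_m).merge(truth_a)
    return SimulatedDataset(
        config=config, metadata=metadata, methylation=meth, atac=atac,
        states=states, genes=genes, truth=truth,
    )


def simulate_direction_state_labels(
    n_peaks: int,
    biased_state: str = "1",
    enrichment: float = 5.0,
    p_decreasing: float = 0.5,
    n_states: int = 13,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series]:
    """Direction + chromatin-state labels with one state enriched among
    decreasing peaks by the given factor — a controlled input for testing
    state-enrichment recovery."""
    rng = np.random.default_rng(seed)
    names = [f"peak_{i:05d}" for i in range(n_peaks)]
    directions = np.where(rng.uniform(size=n_peaks) < p_decreasing, "decreasing", "increasing")
    all_states = [str(s) for s in range(1, n_states + 1)]
    base = np.ones(n_states)
    biased = base.copy()
    biased[all_states.index(biased_state)] = enrichment
    p_inc = base / base.sum()
    p_dec = biased / biased.sum()
    states = np.empty(n_peaks, dtype=object)
    for i, d in enumerate(directions):
        p = p_dec if d == "decreasing" else p_inc
        states[i] = all_states[int(rng.choice(n_states, p=p))]
    idx = pd.Index(names, name="feature_id")
    return pd.Series(directions, index=idx, name="direction"), pd.Series(states, index=idx, name="state")


def write_dataset(dataset: SimulatedDataset, directory: str | Path) -> dict[str, Path]:
    """Write every synthetic output in its on-disk format plus the truth manifest.

    Round-trips losslessly through the readers in :mod:`dogclock.io`.
    """
    from . import io as dio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["metadata"] = dio.write_metadata(dataset.metadata, directory / "metadata.tsv")
    cov_dir = directory / "coverage"
    paths["coverage_dir"] = dio.write_coverage_files(dataset.methylation, cov_dir)
    paths["peaks"] = dio.write_peaks(dataset.atac.peaks, directory / "peaks.bed")
    paths["atac_counts"] = dio.write_count_matrix(dataset.atac.counts, directory / "atac_counts.tsv")
    paths["states"] = dio.write_states(dataset.states, directory / "states.bed")
    paths["genes"] = dio.write_genes(dataset.genes, directory / "genes.bed")
    paths["truth"] = dio.write_truth(dataset.truth, directory / "truth.json")
    paths["config"] = dio.write_simulation_config(dataset.config, directory / "simulation_config.json")
    return paths
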