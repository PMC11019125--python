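"""Readers and writers for every on-disk format the pipeline touches.

Conventions: BED-like files are 0-based half-open; bismark-style coverage
files are 1-based with start == end at the CpG; all coordinates are
normalized to the BED convention in memory at read time. Matrix files are
TSV with optional ``#``-prefixed provenance header lines. Strand is carried
but never interpreted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .simulate import AtacData, GroundTruth, MethylationData


class FileFormatError(ValueError):
    """A malformed input line, reported with file, line number and content."""

    def __init__(self, path, line_no: int, content: str, reason: str):
        super().__init__(f"{path}:{line_no}: {reason} (offending content: {content!r})")
        self.path, self.line_no, self.content = str(path), line_no, content


def _check(df: pd.DataFrame, mask: pd.Series, path, header_lines: int, reason: str) -> None:
    """Raise on the first row where `mask` is True."""
    if mask.any():
        i = int(np.flatnonzero(mask.to_numpy())[0])
        line_no = i + 1 + header_lines
        content = "\t".join(str(v) for v in df.iloc[i].tolist())
        raise FileFormatError(path, line_no, content, reason)


# ---------------------------------------------------------------- metadata

def write_metadata(metadata: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    metadata.to_csv(path, sep="\t", index=False)
    return path


def read_metadata(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    meta = pd.read_csv(path, sep="\t")
    required = {"sample_id", "age", "sex", "breed", "breed_weight_kg", "weight_category", "exercise"}
    missing = required - set(meta.columns)
    if missing:
        raise FileFormatError(path, 1, ",".join(meta.columns), f"missing metadata columns {sorted(missing)}")
    _check(meta, meta["sample_id"].duplicated(), path, 1, "duplicate sample_id")
    return meta


# ---------------------------------------------------------------- coverage

_COV_COLUMNS = ["chrom", "start", "end", "methylation_percent", "count_methylated", "count_unmethylated"]


def write_coverage_files(meth: MethylationData, directory: str | Path) -> Path:
    """One bismark-dialect .cov file per sample (1-based positions)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    depth = meth.depth
    for sample in meth.methylated.columns:
        m = meth.methylated[sample].to_numpy()
        d = depth[sample].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(d > 0, 100.0 * m / np.maximum(d, 1), 0.0)
        df = pd.DataFrame(
            {
                "chrom": meth.sites["chrom"].to_numpy(),
                "start": meth.sites["pos"].to_numpy(),
                "end": meth.sites["pos"].to_numpy(),
                "methylation_percent": np.round(pct, 6),
                "count_methylated": m,
                "count_unmethylated": meth.unmethylated[sample].to_numpy(),
            }
        )
        df.to_csv(directory / f"{sample}.cov", sep="\t", index=False, header=False)
    return directory


def read_coverage_file(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=_COV_COLUMNS,
                         dtype={"chrom": str})
    except ValueError as exc:
        raise FileFormatError(path, 0, "", f"unparseable coverage file: {exc}") from exc
    if df.empty:
        return df
    for col in ("start", "end", "count_methylated", "count_unmethylated"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _check(df, vals.isna(), path, 0, f"non-numeric {col}")
        df[col] = vals.astype(int)
    _check(df, df["start"] < 1, path, 0, "coverage position must be 1-based (>= 1)")
    _check(df, (df["count_methylated"] < 0) | (df["count_unmethylated"] < 0), path, 0, "negative count")
    return df


def read_coverage_dir(directory: str | Path, samples: Iterable[str] | None = None) -> MethylationData:
    """Assemble sites x samples count matrices from per-sample .cov files.

    Sites absent from a sample's file get depth 0 (flagged missing downstream).
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.cov"))
    if samples is not None:
        wanted = list(samples)
        files = [directory / f"{s}.cov" for s in wanted]
    per_sample = {f.stem: read_coverage_file(f) for f in files}
    keys: dict[tuple[str, int], int] = {}
    for df in per_sample.values():
        for c, p in zip(df["chrom"], df["start"]):
            keys.setdefault((c, int(p)), len(keys))
    site_list = sorted(keys, key=keys.get)
    site_ids = [f"{c}:{p}" for c, p in site_list]
    index = {key: i for i, key in enumerate(site_list)}
    n_sites, n_samp = len(site_list), len(per_sample)
    meth = np.zeros((n_sites, n_samp), dtype=int)
    unmeth = np.zeros((n_sites, n_samp), dtype=int)
    for j, (sample, df) in enumerate(per_sample.items()):
        rows = [index[(c, int(p))] for c, p in zip(df["chrom"], df["start"])]
        meth[rows, j] = df["count_methylated"].to_numpy()
        unmeth[rows, j] = df["count_unmethylated"].to_numpy()
    sites = pd.DataFrame(
        {"chrom": [c for c, _ in site_list], "pos": [p for _, p in site_list], "site_id": site_ids}
    )
    cols = list(per_sample)
    return MethylationData(
        sites=sites,
        methylated=pd.DataFrame(meth, index=site_ids, columns=cols),
        unmethylated=pd.DataFrame(unmeth, index=site_ids, columns=cols),
    )


# ---------------------------------------------------------------- peaks (BED6+1)

def write_peaks(peaks: pd.DataFrame, path: str | Path) -> Path:
    """BED6+1: chrom, start, end, name, score, strand, summit offset from start."""
    path = Path(path)
    out = peaks[["chrom", "start", "end", "name", "score", "strand"]].copy()
    out["summit_offset"] = peaks["summit"] - peaks["start"]
    out.to_csv(path, sep="\t", index=False, header=False)
    return path


def read_peaks(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    names = ["chrom", "start", "end", "name", "score", "strand", "summit_offset"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str, "name": str})
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand", "summit"])
    for col in ("start", "end", "summit_offset"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _check(df, vals.isna(), path, 0, f"non-numeric {col}")
        df[col] = vals.astype(int)
    _check(df, df["start"] >= df["end"], path, 0, "BED interval must satisfy start < end")
    _check(df, df["start"] < 0, path, 0, "negative start coordinate")
    bad_summit = (df["summit_offset"] < 0) | (df["summit_offset"] >= df["end"] - df["start"])
    _check(df, bad_summit, path, 0, "summit offset outside [0, width)")
    _check(df, df["name"].duplicated(), path, 0, "duplicate peak name")
    df["summit"] = df["start"] + df["summit_offset"]
    return df.drop(columns=["summit_offset"])


# ---------------------------------------------------------------- BED intervals

def write_states(states: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    states[["chrom", "start", "end", "state"]].to_csv(path, sep="\t", index=False, header=False)
    return path


def read_states(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "state"],
                     dtype={"chrom": str, "state": str})
    if df.empty:
        return df
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _check(df, vals.isna(), path, 0, f"non-numeric {col}")
        df[col] = vals.astype(int)
    _check(df, df["start"] >= df["end"], path, 0, "BED interval must satisfy start < end")
    return df


def write_genes(genes: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    genes[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )
    return path


def read_genes(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, names=names, dtype={"chrom": str, "name": str})
    if df.empty:
        return df
    for col in ("start", "end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        _check(df, vals.isna(), path, 0, f"non-numeric {col}")
        df[col] = vals.astype(int)
    _check(df, df["start"] >= df["end"], path, 0, "BED interval must satisfy start < end")
    _check(df, df["name"].duplicated(), path, 0, "duplicate gene name")
    return df


# ---------------------------------------------------------------- matrices

def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="feature_id")
    return path


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    if df.empty:
        return df
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        raise FileFormatError(path, 1, ",".join(non_numeric), "non-numeric count columns")
    return df


def write_matrix(values: pd.DataFrame, path: str | Path, provenance: Iterable[str] = ()) -> Path:
    """Processed-matrix TSV with '#'-prefixed provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        values.to_csv(fh, sep="\t", index_label="feature_id")
    return path


def read_matrix(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    path = Path(path)
    provenance: list[str] = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            provenance.append(line[1:].strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = None
    return df, provenance


# ---------------------------------------------------------------- truth / config

def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "age_assoc_meth_ids": sorted(truth.age_assoc_meth_ids),
        "age_assoc_atac_ids": sorted(truth.age_assoc_atac_ids),
        "true_slopes": {k: truth.true_slopes[k] for k in sorted(truth.true_slopes)},
        "true_cell_slopes": {k: truth.true_cell_slopes[k] for k in sorted(truth.true_cell_slopes)},
    }
    path.write_text(json.dumps(payload, indent=1) + "\n")
    return path


def read_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        age_assoc_meth_ids=set(payload["age_assoc_meth_ids"]),
        age_assoc_atac_ids=set(payload["age_assoc_atac_ids"]),
        true_slopes=dict(payload["true_slopes"]),
        true_cell_slopes=dict(payload["true_cell_slopes"]),
    )


def write_simulation_config(config: SimulationConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(config.to_dict(), indent=1, sort_keys=True) + "\n")
    return path


def read_simulation_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------- results

def write_association(results: pd.DataFrame, path: str | Path, provenance: Iterable[str] = ()) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for line in provenance:
            fh.write(f"# {line}\n")
        results.to_csv(fh, sep="\t", index=False)
    return path


def read_association(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    return pd.read_csv(path, sep="\t", comment="#")


def write_model_archive(result, path: str | Path) -> Path:
    """Serialize the per-fold LOOCV models: one JSON object per line.

    Coefficients are stored sparsely (selected features only), so the archive
    stays small and text-only while allowing an exact recount of selection
    frequencies.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for fold in result.folds:
            payload = {
                "fold": fold.index,
                "held_out_sample": fold.sample_id,
                "lambda": fold.lam,
                "alpha": fold.alpha,
                "intercept": fold.intercept,
                "coefficients": {k: v for k, v in fold.nonzero_coefficients().items()},
                "predicted_age": fold.predicted_age,
            }
            fh.write(json.dumps(payload) + "\n")
    return path


def read_model_archive(path: str | Path) -> list[dict]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
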