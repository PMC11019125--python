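"""Configuration objects for the synthetic cohort and pipeline runs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic dog cohort.

    Defaults describe the study conditions emulated throughout: 71 companion
    dogs aged 1-16 years, 31 flow-cytometry cell-type proportions of which two
    (a CD8 memory-like and a double-negative memory-like population) increase
    with age, RRBS-style CpG counts and ATAC-style peak counts in which a
    small fraction of features carries a true per-year age effect.
    """

    n_samples: int = 71
    age_range: tuple[int, int] = (1, 16)
    n_cpg_sites: int = 2000
    n_atac_peaks: int = 2000
    frac_age_assoc_meth: float = 0.05
    frac_age_assoc_atac: float = 0.05
    meth_age_slope_sd: float = 0.15   # per-year effect on the logit of the methylated fraction
    atac_age_slope_sd: float = 0.05   # per-year effect on log expected read count
    mean_depth_meth: float = 30.0
    mean_depth_atac: float = 80.0
    n_decoy_features: int = 20        # chrM / scaffold features per data type
    frac_low_coverage_atac: float = 0.05
    frac_extreme_meth: float = 0.08   # constitutively hyper/hypo-methylated sites
    n_cell_types: int = 31
    n_age_assoc_cell_types: int = 2
    celltype_age_slope: float = 1.0   # percent of parent gate per year of age
    celltype_noise_sd: float = 5.0
    nb_dispersion_meanlog: float = 1.5  # log of the NB size parameter
    nb_dispersion_sdlog: float = 0.5
    weight_thresholds: tuple[float, float] = (10.0, 25.0)  # small < 10 <= medium < 25 <= large
    n_chromosomes: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_cpg_sites": self.n_cpg_sites,
            "n_atac_peaks": self.n_atac_peaks,
            "n_cell_types": self.n_cell_types,
            "n_chromosomes": self.n_chromosomes,
        }
        for name, value in counts.items():
            if not isinstance(value, (int,)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if self.n_decoy_features < 0:
            raise ConfigError(f"n_decoy_features must be >= 0, got {self.n_decoy_features!r}")
        for name in (
            "frac_age_assoc_meth",
            "frac_age_assoc_atac",
            "frac_low_coverage_atac",
            "frac_extreme_meth",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {value!r}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigError(f"age_range min must be < max, got {self.age_range!r}")
        if self.n_age_assoc_cell_types > self.n_cell_types:
            raise ConfigError(
                "n_age_assoc_cell_types cannot exceed n_cell_types "
                f"({self.n_age_assoc_cell_types} > {self.n_cell_types})"
            )
        for name in ("mean_depth_meth", "mean_depth_atac"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        t_lo, t_hi = self.weight_thresholds
        if not 0 < t_lo < t_hi:
            raise ConfigError(f"weight_thresholds must be increasing and positive, got {self.weight_thresholds!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_range"] = list(self.age_range)
        d["weight_thresholds"] = list(self.weight_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "weight_thresholds" in d:
            d["weight_thresholds"] = tuple(d["weight_thresholds"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown SimulationConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """Fully resolved parameters of one pipeline run.

    Every stage default named elsewhere in the package appears here so that a
    run directory carries a complete record of what produced it.
    """

    out_dir: str = "results/run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    # atac processing
    min_summit_dist: int = 500
    atac_median_min: float = 20.0
    log_pseudocount: float = 1.0
    # methylation processing
    meth_mean_depth_min: float = 5.0
    meth_median_low: float = 0.1
    meth_median_high: float = 0.9
    # association
    q_threshold: float = 0.05
    fdr_method: str = "bh"            # "bh" or "by"
    # clock
    alpha: float = 0.5
    inner_folds: int = 10
    n_lambda: int = 100
    scaling: str = "global"           # "global" (matches the published order) or "fold"
    data_types: tuple[str, ...] = ("atac", "dnam", "combined")

    def __post_init__(self) -> None:
        if self.scaling not in ("global", "fold"):
            raise ConfigError(f"scaling must be 'global' or 'fold', got {self.scaling!r}")
        if self.fdr_method not in ("bh", "by"):
            raise ConfigError(f"fdr_method must be 'bh' or 'by', got {self.fdr_method!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha must lie in [0, 1], got {self.alpha!r}")
        bad = [t for t in self.data_types if t not in ("atac", "dnam", "combined")]
        if bad:
            raise ConfigError(f"unknown data_types: {bad}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["data_types"] = list(self.data_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        if "data_types" in d:
            d["data_types"] = tuple(d["data_types"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration; where the outputs
        land does not change what they are."""
        d = self.to_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
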