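"""End-to-end pipeline: simulate -> process -> associate -> annotate ->
clock x3 -> evaluate, with every stage's outputs written under one run
directory.

Each output file starts with '#' header lines naming the package version and
the hash of the fully resolved run configuration, which is itself written
next to the outputs; QC logging records feature counts before and after
every filter. A run is fully determined by its RunConfig (one seed governs
simulation, inner CV folds, everything)."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as dio
from .annotation import clock_gene_overlap, nearest_gene, state_enrichment, assign_state
from .association import associate_features, screen_metadata_age
from .atac import process_atac
from .clock import LoocvClockResult, build_design, loocv_clock
from .config import RunConfig
from .evaluation import (
    cross_clock_residual_correlation,
    residual_age,
    residual_vs_weight,
    selection_frequency_report,
    stratified_evaluation,
)
from .features import FeatureMatrix
from .methylation import process_methylation
from .simulate import SimulatedDataset, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: RunConfig
    out_dir: Path
    dataset: SimulatedDataset
    atac_features: FeatureMatrix
    dnam_features: FeatureMatrix
    retained_peaks: pd.DataFrame
    associations: dict[str, pd.DataFrame]
    metadata_screen: pd.DataFrame
    enrichment: pd.DataFrame | None
    clocks: dict[str, LoocvClockResult]
    evaluations: dict[str, list]
    residuals: dict[str, np.ndarray]
    gene_overlap: dict | None
    selection_frequencies: pd.DataFrame = field(default=None)


def _headers(config: RunConfig) -> list[str]:
    return [f"dogclock {__version__}", f"config_hash={config.config_hash()}"]


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.time()


def _done(name: str, t0: float):
    logger.info("stage %s: done in %.1fs", name, time.time() - t0)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis into ``config.out_dir``.

    The run seed overrides the simulation seed so one integer reproduces the
    whole run. Any stage failure aborts with the stage name; outputs written
    so far are left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    headers = _headers(config)
    (out / "run_config.yaml").write_text(
        "\n".join(f"# {h}" for h in headers) + "\n" + yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    sim_config = dataclasses.replace(config.simulation, seed=config.seed)

    stage = "simulate"
    try:
        t0 = _stage(stage)
        dataset = simulate_dataset(sim_config)
        dio.write_metadata(dataset.metadata, out / "metadata.tsv")
        dio.write_truth(dataset.truth, out / "truth.json")
        _done(stage, t0)

        stage = "process-atac"
        t0 = _stage(stage)
        atac_fm, retained_peaks = process_atac(
            dataset.atac.peaks, dataset.atac.counts,
            min_summit_dist=config.min_summit_dist,
            median_min=config.atac_median_min,
            pseudocount=config.log_pseudocount,
        )
        dio.write_matrix(atac_fm.values, out / "processed_atac.tsv", headers + atac_fm.provenance)
        dio.write_peaks(retained_peaks, out / "retained_peaks.bed")
        _done(stage, t0)

        stage = "process-meth"
        t0 = _stage(stage)
        dnam_fm = process_methylation(
            dataset.methylation,
            mean_depth_min=config.meth_mean_depth_min,
            median_low=config.meth_median_low,
            median_high=config.meth_median_high,
        )
        dio.write_matrix(dnam_fm.values, out / "processed_dnam.tsv", headers + dnam_fm.provenance)
        _done(stage, t0)

        stage = "associate"
        t0 = _stage(stage)
        associations = {
            "atac": associate_features(atac_fm, dataset.metadata, config.q_threshold, config.fdr_method),
            "dnam": associate_features(dnam_fm, dataset.metadata, config.q_threshold, config.fdr_method),
        }
        for dt, table in associations.items():
            dio.write_association(table, out / f"association_{dt}.tsv", headers)
        screen = screen_metadata_age(dataset.metadata, method=config.fdr_method)
        dio.write_association(screen, out / "metadata_screen.tsv", headers)
        _done(stage, t0)

        stage = "annotate"
        t0 = _stage(stage)
        peak_states = assign_state(retained_peaks, dataset.states)
        directions = associations["atac"].set_index("feature_id")["direction"]
        enrichment = None
        try:
            enrichment = state_enrichment(directions, peak_states, method=config.fdr_method)
            dio.write_association(enrichment, out / "state_enrichment.tsv", headers)
        except ValueError as exc:
            logger.warning("state enrichment skipped: %s", exc)
        _done(stage, t0)

        stage = "clock"
        t0 = _stage(stage)
        ages = dataset.metadata.set_index("sample_id").loc[atac_fm.sample_ids, "age"]
        designs = {}
        if "atac" in config.data_types:
            designs["atac"] = build_design(atac_fm, dataset.metadata, "atac")
        if "dnam" in config.data_types:
            designs["dnam"] = build_design(dnam_fm, dataset.metadata, "dnam")
        if "combined" in config.data_types:
            designs["combined"] = build_design([atac_fm, dnam_fm], dataset.metadata, "combined")
        clocks: dict[str, LoocvClockResult] = {}
        for dt, design in designs.items():
            clocks[dt] = loocv_clock(
                design, ages, alpha=config.alpha, inner_folds=config.inner_folds,
                n_lambda=config.n_lambda, seed=config.seed, scaling=config.scaling,
            )
            preds = clocks[dt].predictions_frame()
            dio.write_association(preds, out / f"clock_{dt}_predictions.tsv", headers)
            dio.write_model_archive(clocks[dt], out / f"clock_{dt}_models.jsonl")
        _done(stage, t0)

        stage = "evaluate"
        t0 = _stage(stage)
        meta_indexed = dataset.metadata.set_index("sample_id")
        evaluations, residuals = {}, {}
        for dt, res in clocks.items():
            cats = meta_indexed.loc[res.sample_ids, "weight_category"].to_numpy()
            evaluations[dt] = stratified_evaluation(res.predictions, res.ages, cats)
            residuals[dt] = residual_age(res.predictions, res.ages)
        eval_rows = [
            {"data_type": dt, "stratum": ev.stratum, "n": ev.n, "r2": ev.r2,
             "r2_adj": ev.r2_adj, "rmse": ev.rmse, "rmse_regression": ev.rmse_regression,
             "r2_skill": ev.r2_skill, "r2_skill_adj": ev.r2_skill_adj}
            for dt, evs in evaluations.items() for ev in evs
        ]
        dio.write_association(pd.DataFrame(eval_rows), out / "clock_evaluation.tsv", headers)

        resid_rows = []
        for dt, res in clocks.items():
            weights = meta_indexed.loc[res.sample_ids, "breed_weight_kg"].to_numpy()
            slope, p, r2 = residual_vs_weight(residuals[dt], weights)
            resid_rows.append({"data_type": dt, "slope_per_kg": slope, "p": p, "r2": r2})
        dio.write_association(pd.DataFrame(resid_rows), out / "residual_vs_weight.tsv", headers)
        resid_table = pd.DataFrame({"sample_id": next(iter(clocks.values())).sample_ids})
        for dt in clocks:
            resid_table[f"residual_{dt}"] = residuals[dt]
        dio.write_association(resid_table, out / "residual_age.tsv", headers)

        cross_rows = []
        types = list(clocks)
        for i in range(len(types)):
            for j in range(i + 1, len(types)):
                r, p = cross_clock_residual_correlation(residuals[types[i]], residuals[types[j]])
                cross_rows.append({"clock_a": types[i], "clock_b": types[j], "r": r, "p": p})
        if cross_rows:
            dio.write_association(pd.DataFrame(cross_rows), out / "residual_correlations.tsv", headers)

        freq, meta_freq, ever_selected = selection_frequency_report(clocks)
        dio.write_association(freq.reset_index(), out / "selection_frequency.tsv", headers)
        dio.write_association(meta_freq.reset_index(), out / "meta_selection_frequency.tsv", headers)

        gene_overlap = None
        if len(clocks) >= 2:
            coords = retained_peaks[["chrom", "start", "end", "name"]].copy()
            cpg = dnam_fm.feature_ids
            cpg_coords = pd.DataFrame(
                {
                    "chrom": [s.rsplit(":", 1)[0] for s in cpg],
                    "start": [int(s.rsplit(":", 1)[1]) - 1 for s in cpg],
                    "end": [int(s.rsplit(":", 1)[1]) for s in cpg],
                    "name": cpg,
                }
            )
            all_coords = pd.concat([coords, cpg_coords], ignore_index=True)
            gene_map = nearest_gene(all_coords, dataset.genes)["gene"].dropna()
            gene_overlap = clock_gene_overlap(ever_selected, gene_map)
            overlap_lines = [f"# {h}" for h in headers]
            overlap_lines.append(f"triple intersection ({gene_overlap['n_intersection']} genes): "
                                 + ",".join(gene_overlap["intersection"]))
            for region, count in gene_overlap["venn_counts"].items():
                overlap_lines.append(f"{region}\t{count}")
            (out / "gene_overlap.txt").write_text("\n".join(overlap_lines) + "\n")
        _done(stage, t0)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _run_report(config, dataset, atac_fm, dnam_fm, associations, clocks, evaluations)
    (out / "run_report.txt").write_text(report)
    return PipelineResult(
        config=config, out_dir=out, dataset=dataset, atac_features=atac_fm,
        dnam_features=dnam_fm, retained_peaks=retained_peaks, associations=associations,
        metadata_screen=screen, enrichment=enrichment, clocks=clocks,
        evaluations=evaluations, residuals=residuals, gene_overlap=gene_overlap,
        selection_frequencies=freq,
    )


def _run_report(config, dataset, atac_fm, dnam_fm, associations, clocks, evaluations) -> str:
    lines = [
        f"# dogclock {__version__}",
        f"# config_hash={config.config_hash()}",
        f"seed: {config.seed}",
        f"samples: {len(dataset.metadata)}",
        f"atac peaks simulated: {len(dataset.atac.peaks)}  retained: {atac_fm.values.shape[1]}",
        f"cpg sites simulated: {len(dataset.methylation.sites)}  retained: {dnam_fm.values.shape[1]}",
    ]
    for dt, table in associations.items():
        n_sig = int((table["q"] < config.q_threshold).sum())
        n_dec = int((table["direction"] == "decreasing").sum())
        lines.append(f"age-associated {dt}: {n_sig} (decreasing {n_dec}, increasing {n_sig - n_dec})")
    for dt, evs in evaluations.items():
        ev = evs[0]
        lines.append(
            f"clock {dt}: r2_adj={ev.r2_adj:.3f} rmse={ev.rmse:.2f} "
            f"median lambda={float(np.median(clocks[dt].lambdas())):.4g}"
        )
    return "\n".join(lines) + "\n"
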