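"""End-to-end orchestration of the EV peptide longevity analysis.

One :func:`run` call takes a cohort (synthetic by default, or files on
disk), normalizes quantities to the volumetric basis, stratifies peptides
by missingness, runs the dual-track differential analysis with per-track
BH control, fits the requested prediction encodings on a stratified
discovery split, maps differential peptides onto protein regions, computes
marker statistics, and writes every stage's table plus a machine-readable
report. All randomness flows from one root seed; two runs with the same
configuration and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, io, markers as markers_mod, pepmap, predict, quantify
from .stats_core import t_test_summary
from .synthetic_data import CohortBundle, SyntheticConfig, generate_cohort, write_fixtures

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run-wide thresholds, modes and seeding."""

    q_level: float = 0.01
    marker_alpha: float = 0.05
    encoding_modes: tuple[str, ...] = predict.ENCODING_MODES
    cv_folds: int = 5
    cv_repeats: int = 10
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    input_dir: str | None = None

    def __post_init__(self) -> None:
        for name, level in (("q_level", self.q_level), ("marker_alpha", self.marker_alpha)):
            if not 0.0 < level < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        unknown = set(self.encoding_modes) - set(predict.ENCODING_MODES)
        if unknown:
            raise ValueError(f"unknown encoding modes: {sorted(unknown)}")


def baseline_table(summaries: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Group-comparison table from per-row clinical summary statistics.

    ``summaries`` needs columns mean_long, sd_long, n_long, mean_short,
    sd_short, n_short (row index = variable name). A pooled two-sample
    t-test is applied per row; inputs are usually rounded published
    summaries, so p-values inherit that rounding.
    """
    required = {"mean_long", "sd_long", "n_long", "mean_short", "sd_short", "n_short"}
    missing = required - set(summaries.columns)
    if missing:
        raise ValueError(f"baseline summaries lack columns: {sorted(missing)}")
    rows = []
    for name, row in summaries.iterrows():
        res = t_test_summary(
            row["mean_long"], row["sd_long"], int(row["n_long"]),
            row["mean_short"], row["sd_short"], int(row["n_short"]),
        )
        rows.append({"variable": name, "t": res.statistic, "p": res.p_value,
                     "significant": res.p_value < alpha})
    return pd.DataFrame(rows).set_index("variable")


def _load_bundle(config: PipelineConfig) -> CohortBundle:
    if config.input_dir is not None:
        d = Path(config.input_dir)
        table = io.read_peptide_table(d / "peptides.tsv")
        annotation = io.read_sample_annotation(d / "samples.tsv")
        markers = io.read_marker_table(d / "markers.tsv")
        truth = io.read_truth(d / "truth.json") if (d / "truth.json").exists() else None
        proteins = io.read_proteins_fasta(d / "proteins.fasta")
        regions = json.loads((d / "regions.json").read_text())["proteins"]
        pep_seqs, pep_prot = io.read_peptide_sequences(d / "peptide_sequences.tsv")
        return CohortBundle(
            table=table, annotation=annotation, markers=markers, truth=truth,
            proteins=proteins, regions=regions, peptide_sequences=pep_seqs,
            peptide_to_protein=pep_prot, config=config.synthetic,
        )
    syn = config.synthetic or SyntheticConfig(seed=config.seed)
    return generate_cohort(syn)


def run(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; write tables and report.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = _load_bundle(config)
    log.info("cohort: %d samples x %d peptides", *bundle.table.quantities.shape)

    volumetric = quantify.normalize_volumetric(bundle.table, bundle.annotation)
    io.write_peptide_table(volumetric, out / "volumetric.tsv")

    profile = quantify.missingness_profile(volumetric, bundle.annotation)
    complete_ids, incomplete_ids = quantify.stratify(profile)
    log.info("stratify: %d complete, %d incomplete", len(complete_ids), len(incomplete_ids))

    quant = differential.quant_track(volumetric, bundle.annotation, complete_ids, config.q_level)
    miss = differential.missing_track(
        volumetric, bundle.annotation, incomplete_ids, config.q_level, profile=profile
    )
    diff_results = pd.concat([quant, miss], ignore_index=True)
    diff_results.insert(1, "protein", diff_results["peptide_id"].map(bundle.peptide_to_protein))
    diff_results.to_csv(out / "differential.tsv", sep="\t", index=False)
    counts = differential.rollup(diff_results, bundle.peptide_to_protein)
    counts.table.to_csv(out / "rollup.tsv", sep="\t")

    models = predict.run_prediction(
        volumetric, bundle.annotation, modes=config.encoding_modes,
        split_seed=config.seed,
        cv_config=predict.CVConfig(config.cv_folds, config.cv_repeats, config.seed),
    )
    for mode, model in models.items():
        (out / f"model_{mode}.json").write_text(json.dumps(
            {
                "mode": mode,
                "cv_config": {"folds": model.cv_config.folds,
                              "repeats": model.cv_config.repeats,
                              "seed": model.cv_config.seed},
                "selected_peptides": model.selected_peptides,
                "weights": model.weights,
                "cv_auc": model.cv_auc,
                "holdout_auc": model.holdout_auc,
                "holdout_scores": (
                    {k: float(v) for k, v in model.holdout_scores.items()}
                    if model.holdout_scores is not None else {}
                ),
            },
            indent=1,
        ))

    rejected = diff_results[diff_results["reject"]]
    directions = dict(zip(rejected["peptide_id"], rejected["direction"]))
    region_set = pepmap.RegionAnnotationSet.from_records(bundle.regions)
    hit_seqs = {pid: bundle.peptide_sequences[pid] for pid in directions
                if pid in bundle.peptide_sequences}
    locations = pepmap.map_peptides(hit_seqs, bundle.proteins, region_set)
    region_summary = pepmap.summarize_regions(locations, directions)
    region_summary.to_csv(out / "region_summary.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"peptide_id": loc.peptide_id, "protein": loc.protein,
          "start": loc.intervals[0][0], "end": loc.intervals[0][1],
          "n_sites": len(loc.intervals)}
         for loc in locations if loc.intervals]
    ).to_csv(out / "pepmap.tsv", sep="\t", index=False)

    marker_tests = markers_mod.compare_markers(
        bundle.markers, bundle.annotation, alpha=config.marker_alpha
    )
    marker_tests.to_csv(out / "marker_tests.tsv", sep="\t", index=False)
    corr, corr_counts = markers_mod.correlate_markers_peptides(
        bundle.markers, volumetric, list(directions), alpha=config.marker_alpha
    )
    corr.to_csv(out / "marker_peptide_correlations.tsv", sep="\t", index=False)
    corr_counts.to_csv(out / "marker_correlation_counts.tsv", sep="\t", index=False)

    # clinical baseline comparison from the cohort's covariates
    baseline = None
    if "age" in bundle.annotation.table.columns:
        rows = {}
        for var in ("age",):
            g = bundle.annotation.table.groupby("group")[var]
            stats = g.agg(["mean", "std", "count"])
            rows[var] = {
                "mean_long": stats.loc[quantify.LONG, "mean"],
                "sd_long": stats.loc[quantify.LONG, "std"],
                "n_long": stats.loc[quantify.LONG, "count"],
                "mean_short": stats.loc[quantify.SHORT, "mean"],
                "sd_short": stats.loc[quantify.SHORT, "std"],
                "n_short": stats.loc[quantify.SHORT, "count"],
            }
        baseline = baseline_table(pd.DataFrame(rows).T)
        baseline.to_csv(out / "baseline.tsv", sep="\t")

    report = {
        "seed": config.seed,
        "n_samples": len(bundle.table.sample_ids),
        "n_peptides": len(bundle.table.peptide_ids),
        "n_proteins": len(set(bundle.peptide_to_protein.values())),
        "n_complete": len(complete_ids),
        "n_incomplete": len(incomplete_ids),
        "rollup": {
            f"{track}:{direction}": {
                "n_peptides": int(row["n_peptides"]),
                "n_proteins": int(row["n_proteins"]),
            }
            for (track, direction), row in counts.table.iterrows()
        },
        "models": {
            mode: {"cv_auc": m.cv_auc, "holdout_auc": m.holdout_auc,
                   "n_selected": len(m.selected_peptides)}
            for mode, m in models.items()
        },
        "n_marker_tests": int(len(marker_tests)),
        "n_significant_markers": int(marker_tests["significant"].sum()) if len(marker_tests) else 0,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
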