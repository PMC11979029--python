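"""Operating-characteristic benchmarks of the pipeline on synthetic cohorts.

Each function replays the full analysis path (generate -> stratify ->
dual-track differential, or generate -> encode -> fit -> holdout) over many
independently seeded cohorts and summarizes error rates or AUCs against the
generator's ground truth. They are used both by the test suite and by the
reproduction script.

Default cohort scale for these sweeps: 24 samples per group and ~1080
peptides in 120 proteins — large enough for stable FDR/sensitivity
estimates, small enough to run hundreds of replicates on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .differential import missing_track, quant_track
from .predict import CVConfig, run_prediction
from .quantify import missingness_profile, stratify
from .synthetic_data import SyntheticConfig, generate_cohort

#: sweep-scale cohort: ~1080 peptides nested in 120 proteins
SWEEP_SCALE = dict(n_proteins=120, peptides_per_protein_mean=9)


def _differential_run(config: SyntheticConfig, q_level: float):
    bundle = generate_cohort(config)
    profile = missingness_profile(bundle.table, bundle.annotation)
    complete, incomplete = stratify(profile)
    quant = quant_track(bundle.table, bundle.annotation, complete, q_level=q_level)
    miss = missing_track(
        bundle.table, bundle.annotation, incomplete, q_level=q_level, profile=profile
    )
    return bundle, complete, quant, miss


def null_fdp(n_cohorts: int = 200, base_seed: int = 0, q_level: float = 0.01) -> dict:
    """Mean realized false-discovery proportion per track on effect-free
    cohorts (every rejection is false; FDP is 1 when any rejection occurs)."""
    fdp = {"quantitative": [], "missingness": []}
    for i in range(n_cohorts):
        config = SyntheticConfig(
            seed=base_seed + i, frac_differential=0.0, effect_size=0.0,
            frac_informative_missing=0.0, n_markers=0, **SWEEP_SCALE,
        )
        _, _, quant, miss = _differential_run(config, q_level)
        for track, res in (("quantitative", quant), ("missingness", miss)):
            rejected = int(res["reject"].sum())
            fdp[track].append(1.0 if rejected else 0.0)
    return {
        "mean_fdp_quant": float(np.mean(fdp["quantitative"])),
        "mean_fdp_missing": float(np.mean(fdp["missingness"])),
        "n_cohorts": n_cohorts,
    }


def recovery(
    n_seeds: int = 100,
    base_seed: int = 0,
    q_level: float = 0.01,
    frac_differential: float = 0.05,
    effect_size: float = 1.5,
) -> dict:
    """Recovery of planted differential peptides by the dual-track analysis.

    Pooled sensitivity counts a planted peptide as recovered when either
    track rejects it with the planted direction; quantitative-track
    sensitivity restricts both numerator and denominator to planted
    peptides that are complete (the track where an abundance shift is
    tested directly). Realized FDR is the mean per-cohort false-discovery
    proportion over the pooled rejections.
    """
    pooled_sens, quant_sens, fdp = [], [], []
    for i in range(n_seeds):
        config = SyntheticConfig(
            seed=base_seed + i, frac_differential=frac_differential,
            effect_size=effect_size, frac_informative_missing=0.0,
            n_markers=0, **SWEEP_SCALE,
        )
        bundle, complete, quant, miss = _differential_run(config, q_level)
        truth = bundle.truth.differential_directions
        results = pd.concat([quant, miss], ignore_index=True)
        rejected = results[results["reject"]]
        correct = {
            pid for pid, d in zip(rejected["peptide_id"], rejected["direction"])
            if truth.get(pid) == d
        }
        pooled_sens.append(len(correct) / len(truth))
        planted_complete = set(truth) & set(complete)
        if planted_complete:
            quant_hits = correct & planted_complete
            quant_sens.append(len(quant_hits) / len(planted_complete))
        n_false = int((~rejected["peptide_id"].isin(truth)).sum())
        fdp.append(n_false / max(len(rejected), 1))
    return {
        "sensitivity_pooled": float(np.mean(pooled_sens)),
        "sensitivity_quant_track": float(np.mean(quant_sens)),
        "realized_fdr": float(np.mean(fdp)),
        "n_seeds": n_seeds,
    }


#: model-sweep cohorts are smaller (~360 peptides) so that dozens of
#: penalized fits stay cheap
MODEL_SCALE = dict(n_proteins=60, peptides_per_protein_mean=6)


def missingness_signal_auc(n_seeds: int = 10, base_seed: int = 0,
                           cv_repeats: int = 3) -> dict:
    """Holdout AUC of the missing-binary model on cohorts whose only group
    signal is differential detection (no abundance shifts at all)."""
    aucs = []
    for i in range(n_seeds):
        config = SyntheticConfig(
            seed=base_seed + i, frac_differential=0.0, effect_size=0.0,
            frac_informative_missing=0.02, n_markers=0, **MODEL_SCALE,
        )
        bundle = generate_cohort(config)
        models = run_prediction(
            bundle.table, bundle.annotation, modes=("missing_binary",),
            split_seed=config.seed, cv_config=CVConfig(5, cv_repeats, config.seed),
        )
        aucs.append(models["missing_binary"].holdout_auc)
    return {"mean_holdout_auc": float(np.mean(aucs)),
            "min_holdout_auc": float(np.min(aucs)), "n_seeds": n_seeds}


def null_holdout_auc(n_seeds: int = 50, base_seed: int = 0,
                     cv_repeats: int = 2) -> dict:
    """Across-seed mean holdout AUC on cohorts with zero planted signal."""
    aucs = []
    for i in range(n_seeds):
        config = SyntheticConfig(
            seed=base_seed + i, frac_differential=0.0, effect_size=0.0,
            frac_informative_missing=0.0, n_markers=0, **MODEL_SCALE,
        )
        bundle = generate_cohort(config)
        models = run_prediction(
            bundle.table, bundle.annotation, modes=("missing_binary",),
            split_seed=config.seed, cv_config=CVConfig(5, cv_repeats, config.seed),
        )
        aucs.append(models["missing_binary"].holdout_auc)
    return {"mean_holdout_auc": float(np.mean(aucs)), "n_seeds": n_seeds}
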