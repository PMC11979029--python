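# evlong

Missingness-aware differential analysis and longevity prediction for
plasma extracellular-vesicle (EV) peptide panels.

## The problem

Plasma EVs carry peptide cargo from their parent cells, and label-free
quantification (LFQ) proteomics of EV preparations yields a
samples × peptides quantity matrix with a distinctive pathology: peptides
below the instrument's detection limit are *missing, not at random* (MNAR)
— the probability that a value is absent depends on the unobserved
abundance itself. In a cohort of older adults split into long-lived and
short-lived groups, this turns missingness from a nuisance into a signal:
a peptide that is detected more often in one group is more abundant there.

`evlong` implements the complete analysis for such a cohort:

- **Volumetric normalization** — per-µg LFQ values are converted to a
  per-µl plasma basis: `value / volume_for_20ug × 2`, where
  `volume_for_20ug` is each sample's plasma-equivalent volume that yielded
  20 µg of EV protein and the factor 2 undoes the lysis-buffer dilution.
- **Dual-track differential analysis** — peptides with a missing rate of
  exactly 0 % in both groups are compared with the two-sided Wilcoxon
  rank-sum test on their quantitative values; all other peptides are
  compared through their per-group missing rates with a Pearson χ² test on
  the 2×2 missing/observed × group table. Each track is its own
  Benjamini–Hochberg family with FDR controlled at q = 0.01. Direction
  semantics: lower missing rate in the long-lived group ⇒ higher
  abundance in the long-lived group.
- **Three-encoding longevity prediction** — features are (1) complete
  peptides as continuous values, (2) incomplete peptides as binary
  detection indicators (1 = observed, 0 = missing), or (3) all peptides
  with missing values imputed as zero. The cohort is split, stratified by
  group, into discovery (2/3) and holdout (1/3) sets; an L1-penalized
  logistic regression is tuned by repeated stratified 5-fold CV on
  discovery only, and performance is the rank AUC
  (P(score⁺ > score⁻) + ½·P(tie)) on the untouched holdout set.
- **Peptide-to-region mapping** — peptide ids follow the
  `SYMBOL__N[ox]` convention; sequences are located by exact substring
  match in protein sequences (1-based inclusive coordinates) and
  annotated against named regions (chains, fragments, anaphylatoxins such
  as C3a/C5a), with residue-overlap fractions and per-direction counts.
- **Surface-marker statistics** — Mann–Whitney group comparisons per
  (marker, EV size class) at raw p < 0.05, and Spearman screening of
  marker percentages against longevity-associated peptide abundances.

Because the matching clinical dataset is not bundled, the package ships a
first-class synthetic cohort generator (`evlong.synthetic_data`) that
reproduces the *structure* of such a study — 24 + 24 samples, thousands of
log-normal peptides nested in hundreds of proteins, a logistic detection
curve producing MNAR missingness, planted group effects and
detection-shift peptides with ground truth — so every stage is exercised
and its operating characteristics (FDR control, sensitivity, holdout AUC)
are measurable.

## Worked example

```python
from evlong.pipeline import PipelineConfig, run
from evlong.synthetic_data import SyntheticConfig

report = run(PipelineConfig(seed=3, synthetic=SyntheticConfig(seed=3)), "out/")
print(report["n_peptides"], report["n_complete"])
print(report["rollup"]["quantitative:higher_in_long"])
print(report["models"]["missing_binary"])
```

prints (abridged):

```
2074 1091
{'n_peptides': 15, 'n_proteins': 15}
{'cv_auc': 0.9966666666666667, 'holdout_auc': 1.0, 'n_selected': 18}
```

Of 2074 simulated peptides, 1091 were detected in every sample and enter
the quantitative track; 15 peptides (from 15 distinct proteins) come out
significantly more abundant in the long-lived group at q = 0.01. The
binary missingness encoding alone — no quantitative values at all —
cross-validates at AUC 0.997 on the 32-sample discovery set and scores a
perfect 1.0 on the 16-sample holdout, because the generator plants
group-differential detection for a small peptide subset. `out/` also
receives per-stage tables (`differential.tsv`, `model_*.json`,
`region_summary.tsv`, `marker_tests.tsv`, ...).

The same pipeline is scriptable from the shell:

```sh
evlong simulate --out cohort/ --seed 3
evlong run --seed 3 --out out/
```

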