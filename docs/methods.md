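# Methods

This note documents the statistical model behind `evlong`, the synthetic
cohort generator that stands in for real data, the numerical choices made
where the design was open, and what the package's tests do and do not
demonstrate about real EV proteomics data.

## Statistical kernel

All tests are two-sided.

**Wilcoxon rank-sum.** Exact enumeration of the permutation null when the
combined sample size is ≤ 14 and there are no ties
(`stats_core.EXACT_RANKSUM_LIMIT`); otherwise the normal approximation
with average-rank tie correction and continuity correction. The 24 + 24
study design always falls in the approximate regime, so p-values are
bit-reproducible given that rule. A fully tied comparison (all values
equal) returns p = 1.

**Pearson χ² on 2×2 tables.** No Yates continuity correction — plain
Pearson with 1 df is the default reading of "chi-squared test" and keeps
the statistic equal to the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)).
Tables with a zero row or column margin are *excluded and logged*, never
patched with pseudo-counts: within the incomplete stratum this means
peptides missing in every sample of the cohort.

**Benjamini–Hochberg.** Standard step-up; the adjusted q-values are
monotone-enforced and a peptide is rejected iff q ≤ 0.01. The two
differential tracks are **separate BH families** — the quantitative and
missingness analyses each control their own FDR, mirroring the two
separate FDR statements of the study design. Adding peptides to one track
therefore never moves the other track's q-values (tested).

**Summary-statistic t-test.** Pooled-variance two-sample t
(df = n₁+n₂−2) from group means/SDs/sizes, Welch behind a flag. Published
summary rows are rounded, so recomputed p-values inherit that rounding;
for a row whose SDs are small relative to rounding granularity (the age
row: SD 0.91 against a 0.38 mean difference) the recomputed p can differ
from the printed one by ~0.01 no matter the variance assumption.

**Rank AUC.** (concordant + ½·tied) / (all positive–negative pairs),
computed from average ranks; equals the Mann–Whitney U normalization.

## Quantification and stratification

Quantities are non-negative with NaN marking *not detected*; an observed
zero is distinct from missing. The gravimetric→volumetric conversion
(value / volume_for_20ug × 2) is per-sample — each sample carries its own
`volume_for_20ug` in the annotation, with a constant default — and is
guarded by a basis flag so it cannot be applied twice. No log transform
is applied before the rank tests (ranks are invariant to monotone
transforms); the prediction stage standardizes continuous features
instead.

A peptide is **complete** only if its missing rate is exactly 0 in both
groups; one missing cell anywhere makes it incomplete. The two sets
partition the panel.

## Dual-track differential analysis

Direction for the quantitative track is the sign of
(long-lived median − short-lived median), consistent with the rank test;
for the missingness track, a significantly *lower* missing rate in the
long-lived group is reported as higher-in-long (less missing = more
abundant). Rejected peptides with exactly tied evidence get direction
`none`. Rollups count peptides and *distinct* proteins per
(track, direction) category; a protein contributing to two categories is
counted once in each.

## Prediction

The published analysis defers its classifier and selection algorithm to
an unavailable supplement; `evlong` therefore makes **no claim of
algorithmic fidelity** and uses a transparent stand-in with the same
contract: L1-penalized logistic regression (liblinear), penalty weight
chosen by grid search (C ∈ {0.01 … 10}) under repeated stratified 5-fold
CV (default 10 repeats) *on the discovery samples only*, final refit on
all discovery samples, selected peptides = nonzero-weight features.
Continuous features are z-scored inside each fold; all-binary matrices
stay on the 0/1 scale. The discovery/holdout split is stratified 2/3 vs
1/3 (16+16 / 8+8 for the 24+24 design) and re-drawable by seed; holdout
samples never touch fitting or selection, enforced by id bookkeeping that
raises on overlap. Constant features are dropped up front; a cohort with
nothing to learn from scores constant and reports AUC 0.5 by convention.

Binary-encoding feature eligibility ("has ≥ 1 missing value") is defined
on the full table before splitting, matching the study's fixed peptide
panels; labels of holdout samples are never used, which is the leakage
property the tests verify.

## Synthetic cohorts

The generator defines the conditions under which every operating
characteristic is measured. Latent ln-abundance for sample i, peptide j
of protein p:

    x_ij = b_j + δ_j·1[i long-lived]·effect_size + a_ip + e_ij

- peptide baseline b_j ~ N(µ_p, 2.0²) around a protein level
  µ_p ~ N(0, 1.5²): total baseline SD 2.5 ln-units, i.e. a ~4-decade
  dynamic range, typical of LFQ panels;
- protein–sample effect a_ip ~ N(0, 0.5²) shared by all peptides of a
  protein (within-protein correlation 0.25 — this is what makes
  peptide-level and protein-level rollup counts differ);
- residual scaled so the within-group latent SD is exactly 1, making
  `effect_size` a standardized mean shift;
- detection: a cell is observed with probability
  expit((x − midpoint)·slope), observed cells carry exp(x). Slope 2.5 per
  ln-unit makes detection rise 5 %→95 % over about one decade of
  abundance; midpoint −3.0 puts roughly half of all peptides at 100 %
  detection across 48 samples, mirroring the 1834/1861
  complete/incomplete split of the motivating study.

Planted structure, all recorded as ground truth: a `frac_differential`
subset (default 5 %) with ± effect_size shifts (default 1.5 SD); a
disjoint `frac_informative_missing` subset (default 2 %) whose detection
midpoint — not abundance — shifts by 2 latent units in one group, drawn
from peptides whose baseline detection probability lies in (0.5, 0.995)
because a detection shift is only expressible near the detection limit;
and marker-linked peptide sets. Each linked surface marker mirrors the
standardized mean latent signal of one protein's high-abundance peptides
(mixed with noise at `marker_link_strength`, default 0.8, then mapped
through a logistic into a 0–100 % scale). Same-protein sets are used
because their members co-vary, giving each individual peptide a marker
correlation of ≈ 0.57 at link strength 0.8 — strong enough that the
p < 0.05 Spearman screen recovers ≈ all set members, which is the
calibration the marker module's invariant demands; it is also the more
realistic reading (a marker tags a parent-cell population whose cargo
co-varies). All draws descend from one root seed through named
`SeedSequence` spawns; identical configurations are bit-identical.

**What the generator does not emulate:** real peptide quantity
distributions (no public description exists; log-normal is a stand-in),
shared-peptide ambiguity between homologous proteins, batch effects,
interference/ratio-compression, covariate structure beyond age/sex
labels, and any biological pathway structure. Passing tests demonstrate
the pipeline's statistical behavior under the stated model, not
performance on real cohorts.

## Measured operating characteristics

The benchmark sweeps (`evlong.benchmarks`) run at 24 + 24 samples with
~1080 peptides in 120 proteins for differential sweeps, and ~360 peptides
in 60 proteins for model sweeps — sizes chosen so hundreds of replicates
run in tens of seconds on one CPU while estimates stay stable. At these
conditions:

- **Null FDR:** on effect-free cohorts both tracks' mean realized
  false-discovery proportion at q = 0.01 stays ≤ 0.02 (BH is in fact
  conservative here; measured ≈ 0).
- **Recovery:** with 5 % planted 1.5-SD shifts, sensitivity restricted to
  the quantitative track is ≈ 0.85 with realized FDR ≈ 0.005. Pooled over
  both tracks sensitivity is ≈ 0.42: about half of planted peptides fall
  below full detection and are testable only through their missing rates,
  where the χ² test at 24/group under BH 0.01 has little power against
  the moderate rate gaps a 1.5-SD shift induces. That asymmetry is a
  property of the dual-track method itself — the motivating study's own
  discovery counts show the same imbalance (792 quantitative vs 94
  missingness rejections) — and is reported rather than hidden.
- **Missingness as signal:** on cohorts whose *only* group signal is
  differential detection, the binary-encoding model reaches mean holdout
  AUC ≈ 0.95; with zero planted signal the across-seed mean holdout AUC
  sits at ≈ 0.5, as it must.

## Degenerate inputs and tie-breaks

Empty samples, single-class labels, constant vectors for Spearman,
non-positive volumes/SDs/slopes, zero 2×2 margins and malformed peptide
ids all raise typed errors rather than returning silently wrong numbers.
Multi-site peptide matches are all reported; region summaries use the
first match. Peptide ordinals in `SYMBOL__N` are opaque identifiers, not
residue positions — mapping is by sequence only — and symbol comparison
is case-insensitive (`C4A__136` ≡ `C4a__136`).

## Known limitations

- The prediction stand-in will not reproduce any particular published
  peptide selection; only the interface contract and the qualitative
  claim (few-peptide sparse models, missingness alone predictive) are
  reproducible.
- Exact rank-sum enumeration is limited to tie-free inputs ≤ 14
  observations; real LFQ values rarely tie, but heavily rounded inputs
  would silently use the approximation.
- The χ² missingness track is underpowered at n = 24/group for modest
  rate differences; results there should be read as high-confidence
  discoveries, not an exhaustive catalogue.
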