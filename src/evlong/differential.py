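"""Dual-track differential peptide analysis.

Complete peptides (no missing value in either group) are compared between
long- and short-lived groups with the Wilcoxon rank-sum test on their
quantitative values; incomplete peptides are compared through their missing
rates with a Pearson chi-squared test on the 2x2 missing/observed x group
table. Each track is its own Benjamini-Hochberg family, controlled at
q = 0.01 by default. Direction semantics: a rejected quantitative peptide
is higher_in_long when its long-lived median exceeds the short-lived
median; a rejected missingness peptide is higher_in_long when its missing
rate is *lower* in the long-lived group (less missing = more abundant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import LONG, SHORT, MissingnessProfile, PeptideQuantTable, SampleAnnotation, missingness_profile
from .stats_core import EXACT_RANKSUM_LIMIT, bh_adjust, rank_sum_test

log = logging.getLogger(__name__)

HIGHER = "higher_in_long"
LOWER = "lower_in_long"
NONE = "none"

RESULT_COLUMNS = [
    "peptide_id", "track", "statistic", "p", "q", "reject", "direction",
    "median_long", "median_short", "missing_rate_long", "missing_rate_short",
]


@dataclass
class RollupCounts:
    """Fig.-2-style category counts: peptides and distinct proteins per
    direction within each track."""

    table: pd.DataFrame  # index (track, direction); columns n_peptides, n_proteins


def _empty_results(track: str) -> pd.DataFrame:
    df = pd.DataFrame(columns=RESULT_COLUMNS)
    df["track"] = df["track"].astype(str)
    return df


def quant_track(
    table: PeptideQuantTable,
    annotation: SampleAnnotation,
    complete_ids,
    q_level: float = 0.01,
) -> pd.DataFrame:
    """Rank-sum test per complete peptide, BH within this family only."""
    complete_ids = list(complete_ids)
    if not complete_ids:
        return _empty_results("quantitative")
    sub = table.quantities[complete_ids]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"peptides with missing values passed to quant_track: {bad[:5]}")
    long_ids = annotation.group_samples(LONG)
    short_ids = annotation.group_samples(SHORT)
    x = sub.loc[long_ids].to_numpy(float)
    y = sub.loc[short_ids].to_numpy(float)
    n_total = len(long_ids) + len(short_ids)
    if n_total <= EXACT_RANKSUM_LIMIT:
        # small cohorts: per-peptide exact/approximate switch
        results = [rank_sum_test(x[:, j], y[:, j]) for j in range(x.shape[1])]
        stat = np.array([r.statistic for r in results])
        p = np.array([r.p_value for r in results])
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=0,
        )
        stat = np.asarray(res.statistic, dtype=float)
        p = np.asarray(res.pvalue, dtype=float)
        # fully tied columns yield nan under the approximation; no evidence
        p = np.where(np.isnan(p), 1.0, p)
    q_values, reject = bh_adjust(p, q=q_level)
    med_long = np.median(x, axis=0)
    med_short = np.median(y, axis=0)
    direction = np.where(
        ~reject, NONE, np.where(med_long > med_short, HIGHER, LOWER)
    )
    # a rejected peptide with identical medians has no defensible direction
    direction = np.where(reject & (med_long == med_short), NONE, direction)
    return pd.DataFrame(
        {
            "peptide_id": complete_ids,
            "track": "quantitative",
            "statistic": stat,
            "p": p,
            "q": q_values,
            "reject": reject,
            "direction": direction,
            "median_long": med_long,
            "median_short": med_short,
            "missing_rate_long": 0.0,
            "missing_rate_short": 0.0,
        }
    )


def missing_track(
    table: PeptideQuantTable,
    annotation: SampleAnnotation,
    incomplete_ids,
    q_level: float = 0.01,
    profile: MissingnessProfile | None = None,
) -> pd.DataFrame:
    """Chi-squared test on missing/observed x group per incomplete peptide.

    Peptides whose 2x2 table has a zero row margin within this cohort
    (e.g. missing in every sample) are excluded and logged, not patched.
    A peptide observed everywhere does not belong to this track.
    """
    incomplete_ids = list(incomplete_ids)
    if not incomplete_ids:
        return _empty_results("missingness")
    if profile is None:
        profile = missingness_profile(table.subset(incomplete_ids), annotation)
    prof = profile.table.loc[incomplete_ids]
    if (prof["n_missing_long"] + prof["n_missing_short"] == 0).any():
        fully_observed = prof.index[prof["n_missing_long"] + prof["n_missing_short"] == 0]
        raise ValueError(
            f"fully observed peptides passed to missing_track: {list(fully_observed)[:5]}"
        )
    a = prof["n_missing_long"].to_numpy(float)
    b = prof["n_observed_long"].to_numpy(float)
    c = prof["n_missing_short"].to_numpy(float)
    d = prof["n_observed_short"].to_numpy(float)
    # row margins: missing (a+c) is >=1 by contract; observed (b+d) may be 0
    degenerate = (b + d) == 0
    if degenerate.any():
        excluded = prof.index[degenerate].tolist()
        log.info("missing_track: excluding %d degenerate peptides (all missing): %s",
                 len(excluded), excluded[:5])
    keep = ~degenerate
    ids = prof.index[keep]
    a, b, c, d = a[keep], b[keep], c[keep], d[keep]
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    stat = num / den
    p = stats.chi2.sf(stat, df=1)
    q_values, reject = bh_adjust(p, q=q_level)
    rate_long = a / (a + b)
    rate_short = c / (c + d)
    direction = np.where(
        ~reject, NONE, np.where(rate_long < rate_short, HIGHER, LOWER)
    )
    direction = np.where(reject & (rate_long == rate_short), NONE, direction)
    return pd.DataFrame(
        {
            "peptide_id": ids,
            "track": "missingness",
            "statistic": stat,
            "p": p,
            "q": q_values,
            "reject": reject,
            "direction": direction,
            "median_long": np.nan,
            "median_short": np.nan,
            "missing_rate_long": rate_long,
            "missing_rate_short": rate_short,
        }
    ).reset_index(drop=True)


def run_differential(
    table: PeptideQuantTable,
    annotation: SampleAnnotation,
    q_level: float = 0.01,
) -> pd.DataFrame:
    """Stratify and run both tracks; concatenated per-peptide results."""
    profile = missingness_profile(table, annotation)
    from .quantify import stratify

    complete_ids, incomplete_ids = stratify(profile)
    quant = quant_track(table, annotation, complete_ids, q_level=q_level)
    miss = missing_track(table, annotation, incomplete_ids, q_level=q_level, profile=profile)
    return pd.concat([quant, miss], ignore_index=True)


def rollup(results: pd.DataFrame, peptide_to_protein: dict) -> RollupCounts:
    """Count rejected peptides and distinct proteins per (track, direction).

    Every rejected peptide must map to a protein; a protein contributing to
    several categories is counted once within each.
    """
    rejected = results[results["reject"] & (results["direction"] != NONE)]
    unmapped = set(rejected["peptide_id"]) - set(peptide_to_protein)
    if unmapped:
        raise ValueError(f"rejected peptides without protein mapping: {sorted(unmapped)[:5]}")
    rows = []
    for track in ("quantitative", "missingness"):
        for direction in (HIGHER, LOWER):
            sel = rejected[(rejected["track"] == track) & (rejected["direction"] == direction)]
            proteins = {peptide_to_protein[p] for p in sel["peptide_id"]}
            rows.append(
                {"track": track, "direction": direction,
                 "n_peptides": len(sel), "n_proteins": len(proteins)}
            )
    table = pd.DataFrame(rows).set_index(["track", "direction"])
    return RollupCounts(table)


def annotation_percentage(n_subset: int, n_total: int) -> float:
    """Share of an annotated peptide subset among all peptides, in percent
    rounded to one decimal (the convention used for proteome summaries)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_subset <= n_total:
        raise ValueError("n_subset must lie in [0, n_total]")
    return round(100.0 * n_subset / n_total, 1)
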