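"""EV surface-marker statistics.

Consumes a long-format table of flow-cytometry percentages — per sample,
per marker, per EV size class (LEV ~1000-5000 nm, MEV ~100-1000 nm,
SEV <~100 nm) — and provides (a) Mann-Whitney group comparisons per
(marker, size class) at raw p < 0.05 (no multiplicity adjustment here,
unlike the FDR-controlled proteomic tracks; BH available behind a flag)
and (b) Spearman screening of marker percentages against the quantitative
values of longevity-associated peptides, counting significant positive
correlations per marker subset.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .quantify import LONG, SHORT, PeptideQuantTable, SampleAnnotation
from .stats_core import bh_adjust, rank_sum_test, spearman_corr

log = logging.getLogger(__name__)

MARKER_COLUMNS = ("sample_id", "marker", "size_class", "percentage")


def validate_marker_table(markers: pd.DataFrame) -> pd.DataFrame:
    missing = set(MARKER_COLUMNS) - set(markers.columns)
    if missing:
        raise ValueError(f"marker table lacks columns: {sorted(missing)}")
    pct = markers["percentage"].dropna()
    if ((pct < 0) | (pct > 100)).any():
        raise ValueError("marker percentages must lie in [0, 100]")
    return markers


def compare_markers(
    markers: pd.DataFrame,
    annotation: SampleAnnotation,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Rank-sum test per (marker, size_class); one output row each.

    Significance is raw p < alpha by default; ``adjust=True`` applies BH
    across the marker grid instead. Direction comes from group medians.
    """
    validate_marker_table(markers)
    groups = annotation.groups
    rows = []
    for (marker, size_class), sub in markers.groupby(["marker", "size_class"], sort=True):
        sub = sub.dropna(subset=["percentage"])
        x = sub.loc[[groups.get(s) == LONG for s in sub["sample_id"]], "percentage"]
        y = sub.loc[[groups.get(s) == SHORT for s in sub["sample_id"]], "percentage"]
        if x.empty or y.empty:
            log.info("compare_markers: skipping %s/%s (a group has no values)", marker, size_class)
            continue
        res = rank_sum_test(x.to_numpy(), y.to_numpy())
        med_long, med_short = float(x.median()), float(y.median())
        rows.append(
            {
                "marker": marker,
                "size_class": size_class,
                "statistic": res.statistic,
                "p": res.p_value,
                "median_long": med_long,
                "median_short": med_short,
                "direction": "higher_in_long" if med_long > med_short
                else ("lower_in_long" if med_long < med_short else "none"),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["significant"] = pd.Series(dtype=bool)
        return out
    if adjust:
        q, reject = bh_adjust(out["p"].to_numpy(), q=alpha)
        out["q"] = q
        out["significant"] = reject
    else:
        out["significant"] = out["p"] < alpha
    return out


def correlate_markers_peptides(
    markers: pd.DataFrame,
    table: PeptideQuantTable,
    peptide_ids,
    alpha: float = 0.05,
    min_pairs: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation of each (marker, size_class) percentage against
    each longevity-associated peptide's quantitative values.

    Pairs use pairwise-complete samples (cells where the peptide was
    observed and the marker measured); pairs with fewer than ``min_pairs``
    observations, or a constant vector, are skipped and logged. Returns the
    per-pair results and per-(marker, size_class) counts of significant
    positive correlations (p < alpha and rho > 0, the screening convention).
    """
    validate_marker_table(markers)
    peptide_ids = [p for p in peptide_ids if p in table.quantities.columns]
    wide = markers.pivot_table(
        index="sample_id", columns=["marker", "size_class"], values="percentage"
    )
    rows = []
    for (marker, size_class) in wide.columns:
        mvals = wide[(marker, size_class)]
        for pid in peptide_ids:
            pvals = table.quantities[pid]
            paired = pd.concat([mvals, pvals], axis=1, join="inner").dropna()
            if len(paired) < min_pairs:
                log.info("correlate: skipping %s/%s x %s (<%d pairs)",
                         marker, size_class, pid, min_pairs)
                continue
            try:
                rho, p = spearman_corr(paired.iloc[:, 0].to_numpy(), paired.iloc[:, 1].to_numpy())
            except ValueError:
                log.info("correlate: skipping %s/%s x %s (constant input)",
                         marker, size_class, pid)
                continue
            rows.append(
                {
                    "marker": marker,
                    "size_class": size_class,
                    "peptide_id": pid,
                    "rho": rho,
                    "p": p,
                    "n": len(paired),
                    "significant_positive": bool(p < alpha and rho > 0),
                }
            )
    results = pd.DataFrame(
        rows,
        columns=["marker", "size_class", "peptide_id", "rho", "p", "n", "significant_positive"],
    )
    if results.empty:
        counts = pd.DataFrame(columns=["marker", "size_class", "n_significant_positive"])
    else:
        counts = (
            results.groupby(["marker", "size_class"], sort=True)["significant_positive"]
            .sum()
            .astype(int)
            .reset_index(name="n_significant_positive")
        )
    return results, counts
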