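"""Peptide quantity containers, volumetric normalization and missingness
stratification.

The central object is :class:`PeptideQuantTable`, a samples x peptides
matrix of non-negative label-free quantities in which NaN marks a peptide
not detected in a sample (missing), distinct from an observed zero.
Quantities arrive on a gravimetric (per-ug protein) basis and are converted
to a volumetric (per-ul plasma) basis by dividing each sample's values by
the plasma-equivalent volume that yielded 20 ug of EV protein and
multiplying by 2 (the urea-lysis dilution factor).

Peptides are then stratified by missingness: a peptide with missing rate
exactly 0 in both groups is *complete* and analysed quantitatively; any
peptide missing in at least one sample of either group is *incomplete* and
analysed through its missing rates instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LONG = "long_lived"
SHORT = "short_lived"
GROUPS = (LONG, SHORT)


@dataclass
class PeptideQuantTable:
    """Samples x peptides quantity matrix with an explicit missing mask.

    ``quantities`` is indexed by sample id with one column per peptide id;
    NaN encodes missing. ``basis`` records whether values are per-ug
    (gravimetric) or per-ul (volumetric).
    """

    quantities: pd.DataFrame
    basis: str = "gravimetric"

    def __post_init__(self) -> None:
        if self.basis not in ("gravimetric", "volumetric"):
            raise ValueError(f"unknown basis {self.basis!r}")
        observed = self.quantities.to_numpy(dtype=float)
        if np.nanmin(observed, initial=0.0) < 0:
            raise ValueError("observed quantities must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.quantities.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.quantities.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the peptide was not detected."""
        return self.quantities.isna()

    def subset(self, peptide_ids) -> "PeptideQuantTable":
        return PeptideQuantTable(self.quantities[list(peptide_ids)], basis=self.basis)


@dataclass
class SampleAnnotation:
    """Per-sample group label, dilution bookkeeping and covariates.

    ``table`` is indexed by sample id with a ``group`` column taking values
    ``long_lived``/``short_lived``, a positive ``volume_for_20ug`` column
    (ul of plasma-equivalent that yielded 20 ug EV protein) and optional
    covariate columns (age, sex, race, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise ValueError("annotation requires a 'group' column")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in GROUPS:
            if not (self.table["group"] == g).any():
                raise ValueError(f"group {g!r} is empty")
        if "volume_for_20ug" in self.table.columns:
            if (self.table["volume_for_20ug"] <= 0).any():
                raise ValueError("volume_for_20ug must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_samples(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


@dataclass
class MissingnessProfile:
    """Per-peptide, per-group missingness counts and rates."""

    table: pd.DataFrame  # index peptide_id; columns n_missing_*, n_observed_*, missing_rate_*
    group_sizes: dict = field(default_factory=dict)


def to_volumetric(value: float, volume_for_20ug: float) -> float:
    """Convert one per-ug quantity to a per-ul quantity.

    value / volume_for_20ug * 2; the factor 2 undoes the twofold dilution of
    the EV pellet in urea buffer.
    """
    if volume_for_20ug <= 0:
        raise ValueError("volume_for_20ug must be positive")
    if value < 0:
        raise ValueError("quantity must be non-negative")
    return value / volume_for_20ug * 2.0


def normalize_volumetric(table: PeptideQuantTable, annotation: SampleAnnotation) -> PeptideQuantTable:
    """Apply :func:`to_volumetric` row-wise with each sample's own volume.

    Missing entries stay missing. Converting an already-volumetric table is
    an error (the basis flag guards against double conversion).
    """
    if table.basis == "volumetric":
        raise ValueError("table is already on a volumetric basis")
    if "volume_for_20ug" not in annotation.table.columns:
        raise ValueError("annotation lacks volume_for_20ug")
    volumes = annotation.table.loc[table.sample_ids, "volume_for_20ug"]
    if volumes.isna().any() or (volumes <= 0).any():
        raise ValueError("volume_for_20ug must be positive for every sample")
    converted = table.quantities.div(volumes, axis=0) * 2.0
    return PeptideQuantTable(converted, basis="volumetric")


def missingness_profile(table: PeptideQuantTable, annotation: SampleAnnotation) -> MissingnessProfile:
    """Count missing/observed cells per peptide within each group."""
    unannotated = set(table.sample_ids) - set(annotation.sample_ids)
    if unannotated:
        raise ValueError(f"samples without annotation: {sorted(unannotated)[:5]}")
    mask = table.missing_mask
    rows = {}
    sizes = {}
    for group, key in ((LONG, "long"), (SHORT, "short")):
        members = [s for s in table.sample_ids if annotation.groups.loc[s] == group]
        sizes[key] = len(members)
        sub = mask.loc[members]
        rows[f"n_missing_{key}"] = sub.sum(axis=0).astype(int)
        rows[f"n_observed_{key}"] = (len(members) - sub.sum(axis=0)).astype(int)
        rows[f"missing_rate_{key}"] = sub.mean(axis=0)
    profile = pd.DataFrame(rows)
    profile.index.name = "peptide_id"
    return MissingnessProfile(profile, group_sizes=sizes)


def stratify(profile: MissingnessProfile) -> tuple[list[str], list[str]]:
    """Partition peptides into (complete_ids, incomplete_ids).

    Complete means missing rate exactly 0 in *both* groups; a single missing
    cell anywhere makes a peptide incomplete.
    """
    t = profile.table
    complete = t.index[(t["missing_rate_long"] == 0) & (t["missing_rate_short"] == 0)]
    incomplete = t.index.difference(complete, sort=False)
    return list(complete), list(incomplete)
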