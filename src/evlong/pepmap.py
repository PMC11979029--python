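"""Mapping peptides onto protein sequences and region annotations.

Peptide ids follow the ``SYMBOL__N[ox]`` convention (e.g. ``C3__95``,
``APOB__264ox``): a protein symbol, a double underscore, an opaque ordinal,
and an optional ``ox`` suffix marking the oxidized variant. The ordinal is
NOT a residue position; localization is by exact amino-acid substring match
against the protein sequence. All coordinates are 1-based inclusive, the
protein sequence-feature convention (deliberately not BED half-open).

Regions (chains, fragments, anaphylatoxins — e.g. the C3a/C5a spans nested
inside complement alpha chains) may nest; a peptide overlapping several
regions is reported under each with its residue-overlap fraction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

_ID_RE = re.compile(r"^(?P<symbol>.+?)__(?P<ordinal>\d+)(?P<ox>ox)?$")


class PeptideIdError(ValueError):
    """Malformed peptide identifier."""


@dataclass(frozen=True)
class PeptideId:
    raw: str
    protein_symbol: str
    ordinal: int
    modified: bool

    def same_symbol(self, other: "str | PeptideId") -> bool:
        sym = other.protein_symbol if isinstance(other, PeptideId) else other
        return self.protein_symbol.casefold() == sym.casefold()


@dataclass(frozen=True)
class Region:
    name: str
    kind: str  # chain | fragment | anaphylatoxin
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"bad region bounds {self.start}..{self.end}")


@dataclass
class RegionAnnotationSet:
    """Named intervals per protein, 1-based inclusive, with lengths."""

    regions: dict[str, list[Region]] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def add(self, protein: str, region: Region, length: int | None = None) -> None:
        if length is not None:
            self.lengths[protein] = length
        known = self.lengths.get(protein)
        if known is not None and region.end > known:
            raise ValueError(f"region {region.name} exceeds {protein} length {known}")
        self.regions.setdefault(protein, []).append(region)

    @classmethod
    def from_records(cls, records: list[dict]) -> "RegionAnnotationSet":
        out = cls()
        for rec in records:
            protein = rec["protein"]
            out.lengths[protein] = int(rec["length"])
            for r in rec["regions"]:
                out.add(protein, Region(r["name"], r["kind"], int(r["start"]), int(r["end"])))
        return out


@dataclass
class PeptideLocation:
    peptide_id: str
    protein: str
    intervals: list[tuple[int, int]]  # 1-based inclusive
    region_labels: list[dict] = field(default_factory=list)


def parse_id(raw: str) -> PeptideId:
    """Parse ``SYMBOL__N[ox]``; symbol comparison is case-insensitive."""
    if not raw:
        raise PeptideIdError("empty peptide id")
    match = _ID_RE.match(raw)
    if match is None:
        raise PeptideIdError(f"malformed peptide id: {raw!r}")
    return PeptideId(
        raw=raw,
        protein_symbol=match["symbol"],
        ordinal=int(match["ordinal"]),
        modified=match["ox"] is not None,
    )


def locate_peptide(peptide_seq: str, protein_seq: str) -> list[tuple[int, int]]:
    """All exact-match positions of the peptide, as 1-based inclusive
    intervals; empty list when absent. Overlapping occurrences included."""
    for label, seq in (("peptide", peptide_seq), ("protein", protein_seq)):
        bad = set(seq) - VALID_AA
        if bad or not seq:
            raise ValueError(f"invalid {label} sequence characters: {sorted(bad)}")
    if len(peptide_seq) > len(protein_seq):
        raise ValueError("peptide longer than protein")
    hits = []
    start = protein_seq.find(peptide_seq)
    while start != -1:
        hits.append((start + 1, start + len(peptide_seq)))
        start = protein_seq.find(peptide_seq, start + 1)
    return hits


def annotate_region(location: PeptideLocation, regions: RegionAnnotationSet) -> PeptideLocation:
    """Attach every region overlapping the peptide's first interval, with
    residue-overlap fractions (overlap residues / peptide length). Nested
    regions are all reported; full containment is flagged."""
    if location.protein not in regions.regions:
        raise KeyError(f"no region annotation for protein {location.protein!r}")
    if not location.intervals:
        return location
    start, end = location.intervals[0]
    length = end - start + 1
    labels = []
    for region in regions.regions[location.protein]:
        lo, hi = max(start, region.start), min(end, region.end)
        if lo > hi:
            continue
        labels.append(
            {
                "region": region.name,
                "kind": region.kind,
                "overlap_fraction": (hi - lo + 1) / length,
                "contained": start >= region.start and end <= region.end,
            }
        )
    location.region_labels = labels
    return location


def map_peptides(
    peptide_sequences: dict[str, str],
    proteins: dict[str, str],
    regions: RegionAnnotationSet | None = None,
) -> list[PeptideLocation]:
    """Locate (and optionally region-annotate) a batch of peptides, keyed
    by ``SYMBOL__N[ox]`` ids against their own protein's sequence."""
    out = []
    for pid, pep_seq in peptide_sequences.items():
        symbol = parse_id(pid).protein_symbol
        match = next((p for p in proteins if p.casefold() == symbol.casefold()), None)
        if match is None:
            raise KeyError(f"no protein sequence for {symbol!r}")
        loc = PeptideLocation(pid, match, locate_peptide(pep_seq, proteins[match]))
        if regions is not None and loc.intervals:
            annotate_region(loc, regions)
        out.append(loc)
    return out


def summarize_regions(locations: list[PeptideLocation], directions: dict[str, str]) -> pd.DataFrame:
    """Per-(protein, region, direction) peptide counts.

    ``directions`` maps peptide_id -> higher_in_long / lower_in_long; every
    located peptide must have one. A peptide overlapping k regions
    contributes one count to each; localization uses the first match.
    """
    rows = []
    for loc in locations:
        if not loc.intervals:
            continue
        if loc.peptide_id not in directions:
            raise KeyError(f"no differential direction for {loc.peptide_id!r}")
        for label in loc.region_labels:
            rows.append(
                {
                    "protein": loc.protein,
                    "region": label["region"],
                    "kind": label["kind"],
                    "direction": directions[loc.peptide_id],
                }
            )
    if not rows:
        return pd.DataFrame(columns=["protein", "region", "kind", "direction", "n_peptides"])
    df = pd.DataFrame(rows)
    return (
        df.groupby(["protein", "region", "kind", "direction"], sort=True)
        .size()
        .reset_index(name="n_peptides")
    )
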