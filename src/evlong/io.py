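"""Readers and writers for the on-disk interchange formats.

All formats are plain text: wide TSV for peptide quantities (first column
sample id, empty cell = missing), TSV for sample annotations and marker
percentages, standard FASTA for protein sequences (Biopython), JSON for
region annotations (declared 1-based inclusive) and ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .pepmap import RegionAnnotationSet
from .quantify import PeptideQuantTable, SampleAnnotation
from .synthetic_data import GroundTruth


def read_peptide_table(path, basis: str = "gravimetric") -> PeptideQuantTable:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return PeptideQuantTable(df.astype(float), basis=basis)


def write_peptide_table(table: PeptideQuantTable, path) -> None:
    out = table.quantities.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_sample_annotation(path) -> SampleAnnotation:
    return SampleAnnotation(pd.read_csv(path, sep="\t", index_col=0))


def read_marker_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def read_proteins_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_regions(path) -> RegionAnnotationSet:
    payload = json.loads(Path(path).read_text())
    return RegionAnnotationSet.from_records(payload["proteins"])


def read_peptide_sequences(path) -> tuple[dict[str, str], dict[str, str]]:
    """Returns (peptide_id -> sequence, peptide_id -> protein)."""
    df = pd.read_csv(path, sep="\t")
    return (
        dict(zip(df["peptide_id"], df["sequence"])),
        dict(zip(df["peptide_id"], df["protein"])),
    )


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        differential_directions=payload["differential_directions"],
        informative_missing_directions=payload["informative_missing_directions"],
        marker_linked_peptide_ids=payload["marker_linked_peptide_ids"],
    )
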