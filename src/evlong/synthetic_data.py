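"""Synthetic plasma-EV peptide cohorts with ground truth.

Emulates the statistical structure of a 24+24 long-/short-lived cohort
profiled by label-free quantification: thousands of peptides nested in
hundreds of proteins, log-normal abundances with within-protein
correlation, group effects on abundance for a planted differential subset,
an abundance-dependent logistic detection mechanism (missing-not-at-random:
low-abundance cells fall below the detection limit), a planted
informative-missingness subset whose *detection* differs by group while
abundance does not, and flow-cytometry-style marker percentages correlated
with designated peptide sets.

Latent model, per sample i and peptide j of protein p (natural-log scale):

    x_ij = b_j + delta_j * 1[i in long] * effect_size + a_ip + e_ij

with peptide baseline b_j ~ N(mu_p, sigma_pep^2) around a protein level
mu_p ~ N(0, protein_baseline_sd^2), protein-sample effect
a_ip ~ N(0, protein_effect_sd^2) shared by the protein's peptides (this is
what makes peptide-level and protein-level rollups differ), and residual
e_ij scaled so the within-group latent SD is exactly 1 — effect_size is
therefore a standardized mean shift. A cell is observed with probability
expit((x_ij - midpoint) * slope); observed cells carry exp(x_ij) as their
positive quantity. All draws derive from one root seed through named
SeedSequence spawns, so a cohort is bit-reproducible.

The generator's distributions are stand-ins: no public description of the
real cohort's peptide quantity distribution exists, so defaults were chosen
to reproduce its *structure* (sample sizes, roughly half of peptides fully
observed, ~1-decade detection transition over a ~4-decade dynamic range),
not its values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .quantify import GROUPS, LONG, SHORT, PeptideQuantTable, SampleAnnotation

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

SIZE_CLASSES = ("LEV", "MEV", "SEV")


class ConfigurationError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator knobs; defaults are the emulated study conditions.

    effect_size and informative_missing_shift are in units of the
    within-group latent SD (= 1 by construction). detection_midpoint is on
    the latent ln-abundance scale; detection_slope is per ln-unit.
    """

    n_per_group: int = 24
    n_proteins: int = 200
    peptides_per_protein_mean: float = 10.0
    frac_differential: float = 0.05
    effect_size: float = 1.5
    detection_midpoint: float = -3.0
    detection_slope: float = 2.5
    frac_informative_missing: float = 0.02
    informative_missing_shift: float = 2.0
    n_markers: int = 8
    marker_link_strength: float = 0.8
    marker_link_size: int = 3
    baseline_sd: float = 2.5
    protein_baseline_sd: float = 1.5
    protein_effect_sd: float = 0.5
    volume_for_20ug: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        fractions = {
            "frac_differential": self.frac_differential,
            "frac_informative_missing": self.frac_informative_missing,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")
        counts = {
            "n_per_group": self.n_per_group,
            "n_proteins": self.n_proteins,
            "marker_link_size": self.marker_link_size,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.n_markers < 0:
            raise ConfigurationError("n_markers must be >= 0")
        if self.detection_slope <= 0:
            raise ConfigurationError("detection_slope must be positive")
        if not 0.0 <= self.marker_link_strength < 1.0:
            raise ConfigurationError("marker_link_strength must lie in [0, 1)")
        if self.peptides_per_protein_mean < 1:
            raise ConfigurationError("peptides_per_protein_mean must be >= 1")
        if not 0 < self.protein_effect_sd < 1:
            raise ConfigurationError("protein_effect_sd must lie in (0, 1)")
        if self.volume_for_20ug <= 0:
            raise ConfigurationError("volume_for_20ug must be positive")


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for recovery tests."""

    differential_directions: dict[str, str] = field(default_factory=dict)
    informative_missing_directions: dict[str, str] = field(default_factory=dict)
    marker_linked_peptide_ids: dict[str, list[str]] = field(default_factory=dict)

    @property
    def differential_peptide_ids(self) -> set[str]:
        return set(self.differential_directions)

    @property
    def informative_missing_ids(self) -> set[str]:
        return set(self.informative_missing_directions)


@dataclass
class CohortBundle:
    """Everything one synthetic cohort produces."""

    table: PeptideQuantTable
    annotation: SampleAnnotation
    markers: pd.DataFrame  # long format: sample_id, marker, size_class, percentage
    truth: GroundTruth
    proteins: dict[str, str]  # symbol -> amino-acid sequence
    regions: list[dict]  # per-protein region annotations, 1-based inclusive
    peptide_sequences: dict[str, str]
    peptide_to_protein: dict[str, str]
    config: SyntheticConfig


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def apply_detection(latent, midpoint, slope: float, seed: int):
    """MNAR observation of latent ln-abundances.

    Each cell is observed with probability expit((latent - midpoint) * slope)
    and, when observed, carries exp(latent) (the positive quantity scale).
    Returns (quantities with NaN where missing, missing_mask). ``midpoint``
    may be a scalar or an array broadcastable against ``latent``.
    """
    if slope <= 0:
        raise ValueError("detection slope must be positive")
    latent = np.asarray(latent, dtype=float)
    prob = expit((latent - np.asarray(midpoint, dtype=float)) * slope)
    rng = np.random.default_rng(seed)
    observed = rng.random(latent.shape) < prob
    quantities = np.where(observed, np.exp(latent), np.nan)
    return quantities, ~observed


def generate_cohort(config: SyntheticConfig) -> CohortBundle:
    """Draw one cohort; bit-identical for identical (config, seed)."""
    rng_struct, rng_latent, rng_detect_seed, rng_marker, rng_seq = _spawn(config.seed, 5)

    n = 2 * config.n_per_group
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = np.array([LONG] * config.n_per_group + [SHORT] * config.n_per_group)
    is_long = groups == LONG

    # peptide bookkeeping
    proteins = [f"PROT{k + 1:04d}" for k in range(config.n_proteins)]
    mean_extra = max(config.peptides_per_protein_mean - 1.0, 0.0)
    n_pep_per_prot = 1 + rng_struct.poisson(mean_extra, size=config.n_proteins)
    peptide_ids, pep_protein_idx = [], []
    for k, (prot, npep) in enumerate(zip(proteins, n_pep_per_prot)):
        for j in range(npep):
            peptide_ids.append(f"{prot}__{j + 1}")
            pep_protein_idx.append(k)
    pep_protein_idx = np.array(pep_protein_idx)
    m = len(peptide_ids)
    peptide_to_protein = {pid: proteins[k] for pid, k in zip(peptide_ids, pep_protein_idx)}

    # planted sets (deterministic counts from the realized peptide number)
    n_diff = int(round(config.frac_differential * m))
    order = rng_struct.permutation(m)
    diff_idx = np.sort(order[:n_diff])
    delta = np.zeros(m)
    signs = rng_struct.choice([1.0, -1.0], size=n_diff)
    delta[diff_idx] = signs * config.effect_size

    # baselines
    sigma_pep = float(np.sqrt(max(config.baseline_sd**2 - config.protein_baseline_sd**2, 1e-12)))
    mu_prot = rng_latent.normal(0.0, config.protein_baseline_sd, size=config.n_proteins)
    baseline = mu_prot[pep_protein_idx] + rng_latent.normal(0.0, sigma_pep, size=m)

    # informative missingness: only peptides near the detection limit can
    # carry a detection-shift signal; eligibility is a baseline detection
    # probability in (0.5, 0.995), i.e. mostly-observed but not saturated
    p_base = expit((baseline - config.detection_midpoint) * config.detection_slope)
    eligible = np.flatnonzero((p_base > 0.5) & (p_base < 0.995) & (delta == 0))
    n_inf = min(int(round(config.frac_informative_missing * m)), eligible.size)
    inf_idx = np.sort(rng_struct.permutation(eligible)[:n_inf])
    inf_sign = rng_struct.choice([1.0, -1.0], size=n_inf)  # +1: long detected more

    # latent matrix
    resid_sd = float(np.sqrt(1.0 - config.protein_effect_sd**2))
    prot_effect = rng_latent.normal(0.0, config.protein_effect_sd, size=(n, config.n_proteins))
    latent = (
        baseline[None, :]
        + prot_effect[:, pep_protein_idx]
        + rng_latent.normal(0.0, resid_sd, size=(n, m))
    )
    latent += np.outer(is_long.astype(float), delta)

    # per-cell detection midpoint: informative peptides have a group-shifted
    # midpoint (detection changes, abundance does not)
    midpoint = np.full((n, m), config.detection_midpoint)
    if n_inf:
        shift = config.informative_missing_shift
        for idx, sign in zip(inf_idx, inf_sign):
            if sign > 0:  # harder to detect in the short-lived group
                midpoint[~is_long, idx] += shift
            else:
                midpoint[is_long, idx] += shift
    detect_seed = int(rng_detect_seed.integers(0, 2**31 - 1))
    quantities, _ = apply_detection(latent, midpoint, config.detection_slope, detect_seed)

    table = PeptideQuantTable(
        pd.DataFrame(
            quantities, index=pd.Index(sample_ids, name="sample_id"), columns=peptide_ids
        ),
        basis="gravimetric",
    )
    ages = np.round(rng_struct.normal(77.0, 1.5, size=n), 1)
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "group": groups,
                "volume_for_20ug": config.volume_for_20ug,
                "age": ages,
                "sex": np.tile(["F", "M"], n // 2)[:n],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )

    # markers: linked markers mirror the standardized mean latent signal of
    # their peptide set (drawn from high-abundance, hence complete, peptides)
    truth = GroundTruth(
        differential_directions={
            peptide_ids[i]: ("higher_in_long" if delta[i] > 0 else "lower_in_long")
            for i in diff_idx
        },
        informative_missing_directions={
            peptide_ids[i]: ("higher_in_long" if s > 0 else "lower_in_long")
            for i, s in zip(inf_idx, inf_sign)
        },
    )
    marker_rows = []
    if config.n_markers:
        # a linked marker mirrors one protein's high-abundance peptides:
        # same-protein peptides co-vary (shared protein-sample effect), so
        # the marker correlates strongly with each member individually
        inf_set = set(inf_idx)
        linkable_by_protein: dict[int, list[int]] = {}
        for i in np.argsort(baseline)[::-1]:
            if delta[i] == 0 and i not in inf_set and baseline[i] > np.median(baseline):
                linkable_by_protein.setdefault(int(pep_protein_idx[i]), []).append(int(i))
        donor_proteins = sorted(
            (p for p, peps in linkable_by_protein.items()
             if len(peps) >= config.marker_link_size),
            key=lambda p: -len(linkable_by_protein[p]),
        )
        n_linked = config.n_markers // 2  # half the markers carry a peptide link
        z = (latent - latent.mean(axis=0)) / latent.std(axis=0, ddof=0)
        rho = config.marker_link_strength
        for k in range(config.n_markers):
            name = f"MK{k + 1:02d}"
            if k < n_linked and k < len(donor_proteins):
                members = linkable_by_protein[donor_proteins[k]][: config.marker_link_size]
                combined = z[:, members].mean(axis=1)
                combined = combined / combined.std(ddof=0)
                truth.marker_linked_peptide_ids[name] = [peptide_ids[i] for i in members]
            else:
                combined = None
            for size_class in SIZE_CLASSES:
                noise = rng_marker.normal(0.0, 1.0, size=n)
                if combined is None:
                    signal = noise
                else:
                    signal = rho * combined + np.sqrt(1 - rho**2) * noise
                pct = 100.0 * expit(signal)
                for sid, value in zip(sample_ids, pct):
                    marker_rows.append(
                        {"sample_id": sid, "marker": name,
                         "size_class": size_class, "percentage": value}
                    )
    markers = pd.DataFrame(
        marker_rows, columns=["sample_id", "marker", "size_class", "percentage"]
    )

    # protein sequences containing each peptide as an exact substring, plus
    # a simple chain/anaphylatoxin region annotation per protein
    protein_seqs: dict[str, str] = {}
    peptide_seqs: dict[str, str] = {}
    regions: list[dict] = []
    for k, prot in enumerate(proteins):
        npep = int(n_pep_per_prot[k])
        length = max(90, 24 * npep)
        seq = rng_seq.choice(AMINO_ACIDS, size=length)
        pep_lengths = rng_seq.integers(8, 16, size=npep)
        for j in range(npep):
            plen = int(pep_lengths[j])
            start = int(rng_seq.integers(0, length - plen + 1))
            peptide_seqs[f"{prot}__{j + 1}"] = "".join(seq[start: start + plen])
        protein_seqs[prot] = "".join(seq)
        third = length // 3
        regions.append(
            {
                "protein": prot,
                "length": length,
                "regions": [
                    {"name": "beta chain", "kind": "chain", "start": 1, "end": third},
                    {"name": "alpha chain", "kind": "chain", "start": third + 1, "end": 2 * third},
                    {"name": "gamma chain", "kind": "chain", "start": 2 * third + 1, "end": length},
                    {"name": f"{prot}a anaphylatoxin", "kind": "anaphylatoxin",
                     "start": third + 1, "end": third + 20},
                ],
            }
        )

    return CohortBundle(
        table=table,
        annotation=annotation,
        markers=markers,
        truth=truth,
        proteins=protein_seqs,
        regions=regions,
        peptide_sequences=peptide_seqs,
        peptide_to_protein=peptide_to_protein,
        config=config,
    )


# ---------------------------------------------------------------------------
# fixture files


def write_fixtures(bundle: CohortBundle, directory) -> dict[str, Path]:
    """Write the bundle to the on-disk interchange formats.

    peptides.tsv is wide (row = sample, empty cell = missing); samples.tsv,
    markers.tsv and peptide_sequences.tsv are plain TSV; proteins.fasta is
    standard FASTA with the protein symbol as header; regions.json declares
    1-based inclusive coordinates; truth.json serializes the ground truth.
    Round-trips losslessly through :mod:`evlong.io` readers.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    peptides = directory / "peptides.tsv"
    out = bundle.table.quantities.copy()
    out.index.name = "sample_id"
    out.to_csv(peptides, sep="\t", na_rep="", float_format="%.17g")
    paths["peptides"] = peptides

    samples = directory / "samples.tsv"
    bundle.annotation.table.to_csv(samples, sep="\t")
    paths["samples"] = samples

    markers = directory / "markers.tsv"
    bundle.markers.to_csv(markers, sep="\t", index=False, float_format="%.17g")
    paths["markers"] = markers

    truth = directory / "truth.json"
    truth.write_text(
        json.dumps(
            {
                "differential_directions": bundle.truth.differential_directions,
                "informative_missing_directions": bundle.truth.informative_missing_directions,
                "marker_linked_peptide_ids": bundle.truth.marker_linked_peptide_ids,
            },
            indent=1,
        )
    )
    paths["truth"] = truth

    fasta = directory / "proteins.fasta"
    with fasta.open("w") as fh:
        for symbol, seq in bundle.proteins.items():
            fh.write(f">{symbol}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")
    paths["proteins"] = fasta

    regions = directory / "regions.json"
    regions.write_text(json.dumps({"coordinates": "1-based inclusive", "proteins": bundle.regions}, indent=1))
    paths["regions"] = regions

    pepseq = directory / "peptide_sequences.tsv"
    pd.DataFrame(
        {
            "peptide_id": list(bundle.peptide_sequences),
            "protein": [bundle.peptide_to_protein[p] for p in bundle.peptide_sequences],
            "sequence": list(bundle.peptide_sequences.values()),
        }
    ).to_csv(pepseq, sep="\t", index=False)
    paths["peptide_sequences"] = pepseq
    return paths
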