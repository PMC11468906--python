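"""Seeded synthetic cohorts: transcripts, somatic variants, expression, HLA.

The generator stands in for tumor/normal exome plus tumor RNA sequencing of a
cell line: random complete CDSs, somatic SNVs and anchor-base indels with
tumor/normal/RNA allele frequencies, a long-tailed TPM distribution, and a
fixed small MHC allele panel.  Identical seed and parameters give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import (
    STOP_CODONS_DNA,
    TranscriptRecord,
    VariantRecord,
)

_SENSE_CODONS = sorted(
    c1 + c2 + c3
    for c1 in "ACGT"
    for c2 in "ACGT"
    for c3 in "ACGT"
    if c1 + c2 + c3 not in STOP_CODONS_DNA and c1 + c2 + c3 != "ATG"
)

DEFAULT_HLA_PANEL = ("H-2-Kb", "H-2-Db")


@dataclass(frozen=True)
class CohortParams:
    """Knobs of the synthetic cohort; defaults emulate a murine tumor line.

    VAF distributions: somatic variants draw tumor-DNA VAF from
    Beta(2, 4) truncated to [0.05, 1] (subclonal-to-clonal mix), RNA VAF
    from the DNA VAF perturbed by measurement noise, and normal-DNA VAF 0;
    germline contaminants sit near 0.5 in both tumor and normal.
    """

    cds_len_codons: tuple[int, int] = (60, 200)  # range incl. start, excl. stop
    tpm_log_mean: float = 2.0       # ln-scale; exp(2) ~ 7 TPM median
    tpm_log_sd: float = 1.5
    synonymous_fraction: float = 0.2
    indel_fraction: float = 0.1
    germline_fraction: float = 0.0  # contaminant rows with vaf_normal ~ 0.5
    rna_vaf_noise_sd: float = 0.05
    hla_alleles: tuple[str, ...] = DEFAULT_HLA_PANEL


@dataclass(frozen=True)
class Cohort:
    transcripts: list[TranscriptRecord]
    variants: list[VariantRecord]
    expression: pd.DataFrame
    hla_alleles: list[str]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A complete CDS: ATG, n_codons random sense codons, one stop."""
    body = "".join(rng.choice(_SENSE_CODONS, size=n_codons))
    stop = rng.choice(sorted(STOP_CODONS_DNA))
    return "ATG" + body + stop


def _is_synonymous(cds: str, pos: int, ref: str, alt: str) -> bool:
    edited = cds[: pos - 1] + alt + cds[pos - 1 + len(ref) :]
    p_old = str(Seq(cds).translate(to_stop=True))
    p_new = str(Seq(edited).translate(to_stop=True))
    return p_old == p_new


def _draw_snv(
    rng: np.random.Generator, cds: str, want_synonymous: bool, max_tries: int = 200
) -> tuple[int, str, str] | None:
    """An SNV in the coding body (never start or stop codon) with the requested
    synonymy, or None if not found within the try budget."""
    n = len(cds)
    for _ in range(max_tries):
        pos = int(rng.integers(4, n - 3 + 1))  # 1-based; skips ATG and stop
        ref = cds[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        if _is_synonymous(cds, pos, ref, alt) == want_synonymous:
            return pos, ref, alt
    return None


def _draw_indel(rng: np.random.Generator, cds: str) -> tuple[int, str, str]:
    """A VCF-style anchored indel of 1-3 nt strictly inside the coding body."""
    n = len(cds)
    size = int(rng.integers(1, 4))
    if rng.random() < 0.5:  # insertion
        pos = int(rng.integers(4, n - 3 + 1))
        ref = cds[pos - 1]
        ins = "".join(rng.choice(list("ACGT"), size=size))
        return pos, ref, ref + ins
    # deletion: anchor + size deleted bases must stay clear of the stop codon
    pos = int(rng.integers(4, max(5, n - 3 - size + 1)))
    ref = cds[pos - 1 : pos + size]
    return pos, ref, ref[0]


def generate_cohort(
    seed: int,
    n_transcripts: int,
    n_variants: int,
    params: CohortParams | None = None,
) -> Cohort:
    """Generate a seeded synthetic cohort.

    Somatic variants have vaf_normal_dna = 0 and a ref allele guaranteed to
    match the CDS.  ``params.synonymous_fraction`` of SNVs are silent; with
    fraction 0 every variant changes the protein.  Raises ``ValueError`` when
    more variants are requested than coding positions exist.
    """
    params = params or CohortParams()
    rng = np.random.default_rng(seed)

    transcripts: list[TranscriptRecord] = []
    lo, hi = params.cds_len_codons
    for i in range(n_transcripts):
        n_codons = int(rng.integers(lo, hi + 1))
        tpm = float(np.round(np.exp(rng.normal(params.tpm_log_mean, params.tpm_log_sd)), 3))
        transcripts.append(
            TranscriptRecord(
                transcript_id=f"T{i + 1:04d}",
                cds=_random_cds(rng, n_codons),
                gene_id=f"G{i + 1:04d}",
                tpm=tpm,
            )
        )

    total_positions = sum(max(0, len(t.cds) - 6) for t in transcripts)
    if n_variants > total_positions:
        raise ValueError(
            f"requested {n_variants} variants but cohort has only "
            f"{total_positions} mutable coding positions"
        )

    variants: list[VariantRecord] = []
    seen: set[tuple[str, int]] = set()
    attempts = 0
    while len(variants) < n_variants and attempts < 50 * max(1, n_variants):
        attempts += 1
        t = transcripts[int(rng.integers(0, n_transcripts))]
        germline = rng.random() < params.germline_fraction
        if rng.random() < params.indel_fraction:
            pos, ref, alt = _draw_indel(rng, t.cds)
        else:
            want_syn = rng.random() < params.synonymous_fraction
            drawn = _draw_snv(rng, t.cds, want_synonymous=want_syn)
            if drawn is None:
                continue
            pos, ref, alt = drawn
        if (t.transcript_id, pos) in seen:
            continue
        seen.add((t.transcript_id, pos))
        if germline:
            vaf_dna = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
            vaf_norm = float(np.clip(rng.normal(0.5, 0.05), 0.3, 0.7))
        else:
            vaf_dna = float(np.clip(0.05 + rng.beta(2, 4) * 0.95, 0.05, 1.0))
            vaf_norm = 0.0
        vaf_rna = float(np.clip(vaf_dna + rng.normal(0.0, params.rna_vaf_noise_sd), 0.0, 1.0))
        variants.append(
            VariantRecord(
                transcript_id=t.transcript_id,
                cds_pos=pos,
                ref=ref,
                alt=alt,
                vaf_tumor_dna=round(vaf_dna, 4),
                vaf_normal_dna=round(vaf_norm, 4),
                vaf_tumor_rna=round(vaf_rna, 4),
            )
        )
    if len(variants) < n_variants:
        raise ValueError(
            f"could not place {n_variants} variants after {attempts} attempts"
        )
    variants.sort(key=lambda v: (v.transcript_id, v.cds_pos))

    expression = pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "gene_id": [t.gene_id for t in transcripts],
            "tpm": [t.tpm for t in transcripts],
        }
    )
    return Cohort(
        transcripts=transcripts,
        variants=variants,
        expression=expression,
        hla_alleles=list(params.hla_alleles),
    )


# ---------------------------------------------------------------------------
# feature-level cohorts with planted immunogenic candidates

@dataclass(frozen=True)
class PlantedEffects:
    """Effect sizes separating planted true-immunogenic candidates from
    background: roughly an order of magnitude on affinity and expression and
    a doubling of clonality, the regime the ranker is meant to resolve."""

    background_affinity_nM: tuple[float, float] = (30.0, 5000.0)   # log-uniform
    planted_affinity_nM: tuple[float, float] = (2.0, 50.0)
    background_tpm: tuple[float, float] = (1.0, 50.0)              # log-uniform
    planted_tpm: tuple[float, float] = (30.0, 300.0)
    background_vaf: tuple[float, float] = (0.05, 0.25)
    planted_vaf: tuple[float, float] = (0.30, 0.60)
    background_agretopicity: tuple[float, float] = (0.3, 2.0)
    planted_agretopicity: tuple[float, float] = (2.0, 15.0)


def generate_feature_cohort(
    seed: int,
    n_background: int = 40,
    n_planted: int = 10,
    effects: PlantedEffects | None = None,
):
    """Candidate feature vectors with known planted positives.

    Returns ``(candidates, planted_ids)`` where each candidate is a
    :class:`neovax.ranking.RankInput`.  Used to measure whether default
    weights recover the planted true-immunogenic set in the top ranks.
    """
    from .peptides import PeptidePair
    from .ranking import FeatureVector, RankInput

    eff = effects or PlantedEffects()
    rng = np.random.default_rng(seed)

    def log_u(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def make(i: int, planted: bool) -> RankInput:
        aff = log_u(eff.planted_affinity_nM if planted else eff.background_affinity_nM)
        agre = log_u(eff.planted_agretopicity if planted else eff.background_agretopicity)
        vaf = rng.uniform(*(eff.planted_vaf if planted else eff.background_vaf))
        tpm = log_u(eff.planted_tpm if planted else eff.background_tpm)
        tag = "P" if planted else "B"
        pep = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=27))
        pair = PeptidePair(
            mut_peptide=pep,
            wt_peptide=pep[:13] + ("A" if pep[13] != "A" else "G") + pep[14:],
            window_start=1,
            mutant_offset=14,
        )
        fv = FeatureVector(
            vaf_tumor_dna=round(vaf, 4),
            vaf_normal_dna=0.0,
            vaf_tumor_rna=round(float(np.clip(vaf + rng.normal(0, 0.05), 0, 1)), 4),
            expr_tpm=round(tpm, 3),
            best_mut_affinity_nM=round(aff, 3),
            best_wt_affinity_nM=round(aff * agre, 3),
        )
        return RankInput(candidate_id=f"{tag}{i:03d}", pair=pair, features=fv)

    candidates = [make(i, False) for i in range(n_background)]
    candidates += [make(i, True) for i in range(n_planted)]
    planted_ids = [c.candidate_id for c in candidates if c.candidate_id.startswith("P")]
    return candidates, planted_ids
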