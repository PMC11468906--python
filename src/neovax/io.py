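"""Readers, writers and validated record types for the pipeline's external tables.

All tabular formats are TSV with a header row; sequences travel as FASTA.
Variants are expressed in transcript CDS coordinates (1-based, inclusive),
with indels encoded VCF-style: a shared anchor base, so ref ``G`` / alt
``GAT`` is a 2-nt insertion after the anchor and ref ``GAT`` / alt ``G`` a
2-nt deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGT")
STOP_CODONS_DNA = {"TAA", "TAG", "TGA"}


class ValidationError(ValueError):
    """An input record violates a documented invariant."""


class ParseError(ValueError):
    """A file could not be parsed in its declared format."""


@dataclass(frozen=True)
class TranscriptRecord:
    """A coding sequence with identifier and expression annotation.

    The CDS must be a complete reading frame: starts with ATG, length
    divisible by 3, and exactly one in-frame stop codon, at its end.
    """

    transcript_id: str
    cds: str
    gene_id: str = ""
    tpm: float = 0.0

    def __post_init__(self) -> None:
        validate_cds(self.cds, self.transcript_id)
        if self.tpm < 0:
            raise ValidationError(
                f"{self.transcript_id}: tpm must be non-negative, got {self.tpm}"
            )

    @property
    def protein(self) -> str:
        """Translation of the CDS without the terminal stop."""
        return str(Seq(self.cds).translate())[:-1]


def validate_cds(cds: str, name: str = "<cds>") -> None:
    if set(cds) - DNA_ALPHABET:
        bad = sorted(set(cds) - DNA_ALPHABET)
        raise ValidationError(f"{name}: CDS contains non-ACGT characters {bad}")
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"{name}: CDS length {len(cds)} is not divisible by 3"
        )
    if not cds.startswith("ATG"):
        raise ValidationError(f"{name}: CDS does not begin with ATG")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS_DNA]
    if stops != [len(codons) - 1]:
        raise ValidationError(
            f"{name}: CDS must contain exactly one in-frame stop, at its end "
            f"(stop codon indices: {stops}, n_codons={len(codons)})"
        )


@dataclass(frozen=True)
class VariantRecord:
    """A somatic (or germline-contaminant) variant in transcript CDS coordinates.

    ``cds_pos`` is the 1-based position of the first ``ref`` base.  VAFs are
    variant allele frequencies at the tumor DNA, matched normal DNA, and
    tumor RNA level respectively.
    """

    transcript_id: str
    cds_pos: int
    ref: str
    alt: str
    vaf_tumor_dna: float
    vaf_normal_dna: float
    vaf_tumor_rna: float

    def __post_init__(self) -> None:
        if self.cds_pos < 1:
            raise ValidationError(
                f"{self.transcript_id}: cds_pos must be >= 1, got {self.cds_pos}"
            )
        if self.ref == self.alt:
            raise ValidationError(
                f"{self.transcript_id}:{self.cds_pos}: ref equals alt ({self.ref})"
            )
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or set(allele) - DNA_ALPHABET:
                raise ValidationError(
                    f"{self.transcript_id}:{self.cds_pos}: {label} allele "
                    f"{allele!r} is not a non-empty ACGT string"
                )
        for vaf, label in (
            (self.vaf_tumor_dna, "vaf_tumor_dna"),
            (self.vaf_normal_dna, "vaf_normal_dna"),
            (self.vaf_tumor_rna, "vaf_tumor_rna"),
        ):
            if not 0.0 <= vaf <= 1.0:
                raise ValidationError(
                    f"{self.transcript_id}:{self.cds_pos}: {label}={vaf} "
                    "outside [0,1]"
                )

    @property
    def variant_id(self) -> str:
        return f"{self.transcript_id}:{self.cds_pos}:{self.ref}>{self.alt}"

    def check_against(self, cds: str) -> None:
        """Verify that ``ref`` matches the CDS at ``cds_pos``."""
        end = self.cds_pos - 1 + len(self.ref)
        observed = cds[self.cds_pos - 1 : end]
        if observed != self.ref:
            raise ValidationError(
                f"{self.transcript_id}:{self.cds_pos}: ref {self.ref!r} does not "
                f"match CDS ({observed!r} at that position)"
            )


# ---------------------------------------------------------------------------
# codon usage

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class CodonUsageTable:
    """Per-codon usage fractions and relative adaptiveness w.

    Codons are stored as RNA (AUGC).  ``fraction`` is the within-amino-acid
    synonymous usage fraction (normalized to sum to 1 per amino acid);
    ``w`` is fraction / max synonymous fraction, so each amino acid's most
    frequent codon has w = 1.
    """

    fraction: dict[str, float]
    amino_acid: dict[str, str]
    w: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.fraction) != 61:
            raise ValidationError(
                f"codon usage table must list 61 sense codons, got {len(self.fraction)}"
            )
        by_aa: dict[str, list[str]] = {}
        for codon, aa in self.amino_acid.items():
            by_aa.setdefault(aa, []).append(codon)
        if set(by_aa) != set(AA_ALPHABET):
            raise ValidationError(
                f"codon usage table must cover the 20 canonical amino acids, "
                f"got {sorted(by_aa)}"
            )
        # normalize per amino acid, then derive w
        for aa, codons in by_aa.items():
            total = sum(self.fraction[c] for c in codons)
            if total <= 0:
                raise ValidationError(f"usage fractions for {aa} sum to {total}")
            for c in codons:
                self.fraction[c] /= total
        self.w = {}
        for aa, codons in by_aa.items():
            m = max(self.fraction[c] for c in codons)
            for c in codons:
                self.w[c] = self.fraction[c] / m
        self._codons_by_aa = {aa: sorted(cs) for aa, cs in by_aa.items()}

    def codons_for(self, aa: str) -> list[str]:
        try:
            return self._codons_by_aa[aa]
        except KeyError:
            raise ValidationError(f"no codons for amino acid {aa!r}") from None

    def best_codon(self, aa: str) -> str:
        """The most used codon for ``aa`` (w = 1); ties broken lexicographically."""
        return max(self.codons_for(aa), key=lambda c: (self.fraction[c], [-ord(x) for x in c]))


def _to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")


def read_codon_usage(path: str | Path) -> CodonUsageTable:
    """Read a Kazusa-style TSV (codon, amino_acid, fraction); T or U accepted."""
    df = pd.read_csv(path, sep="\t")
    required = {"codon", "amino_acid", "fraction"}
    if not required <= set(df.columns):
        raise ParseError(
            f"{path}: codon usage TSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    fraction = {_to_rna(r.codon): float(r.fraction) for r in df.itertuples()}
    amino = {_to_rna(r.codon): str(r.amino_acid) for r in df.itertuples()}
    return CodonUsageTable(fraction=fraction, amino_acid=amino)


def builtin_codon_usage() -> CodonUsageTable:
    """The bundled human codon usage table."""
    with resources.as_file(
        resources.files("neovax.data") / "codon_usage_human.tsv"
    ) as p:
        return read_codon_usage(p)


# ---------------------------------------------------------------------------
# ELISpot

@dataclass(frozen=True)
class ElispotRow:
    group: str
    peptide_id: str
    replicate: int
    spot_count: int
    cells_per_well: int = 250_000
    is_negative_control: bool = False
    is_positive_control: bool = False

    def __post_init__(self) -> None:
        if self.spot_count < 0:
            raise ValidationError(
                f"{self.group}/{self.peptide_id}: spot_count must be >= 0"
            )


ELISPOT_COLUMNS = [
    "group",
    "peptide_id",
    "replicate",
    "spot_count",
    "cells_per_well",
    "is_negative_control",
    "is_positive_control",
]


def read_elispot(path: str | Path) -> list[ElispotRow]:
    df = pd.read_csv(path, sep="\t")
    missing = set(ELISPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: ELISpot TSV missing columns {sorted(missing)}")
    rows = [
        ElispotRow(
            group=str(r.group),
            peptide_id=str(r.peptide_id),
            replicate=int(r.replicate),
            spot_count=int(r.spot_count),
            cells_per_well=int(r.cells_per_well),
            is_negative_control=bool(r.is_negative_control),
            is_positive_control=bool(r.is_positive_control),
        )
        for r in df.itertuples()
    ]
    groups = {r.group for r in rows}
    for g in sorted(groups):
        if not any(r.is_negative_control for r in rows if r.group == g):
            raise ValidationError(f"group {g!r} has no negative-control row")
    return rows


def write_elispot(rows: Iterable[ElispotRow], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) for r in rows], columns=ELISPOT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA / TSV round-trip I/O

def read_cds_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read CDS FASTA; header token 1 is the transcript id, then optional
    ``gene_id=...`` and ``tpm=...`` key=value fields."""
    records: list[TranscriptRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - Biopython raises rarely here
        raise ParseError(f"{path}: {exc}") from exc
    if not parsed and Path(path).stat().st_size > 0:
        raise ParseError(f"{path}: not a FASTA file (no '>' records found)")
    for rec in parsed:
        fields = rec.description.split()
        kv = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        records.append(
            TranscriptRecord(
                transcript_id=rec.id,
                cds=str(rec.seq).upper(),
                gene_id=kv.get("gene_id", ""),
                tpm=float(kv.get("tpm", 0.0)),
            )
        )
    return records


def write_cds_fasta(transcripts: Iterable[TranscriptRecord], path: str | Path) -> None:
    recs = [
        SeqRecord(
            Seq(t.cds),
            id=t.transcript_id,
            description=f"gene_id={t.gene_id} tpm={t.tpm:g}",
        )
        for t in transcripts
    ]
    SeqIO.write(recs, str(path), "fasta")


VARIANT_COLUMNS = [
    "transcript_id",
    "cds_pos",
    "ref",
    "alt",
    "vaf_tumor_dna",
    "vaf_normal_dna",
    "vaf_tumor_rna",
]


def read_variant_table(
    path: str | Path,
    transcripts: Sequence[TranscriptRecord] | None = None,
) -> list[VariantRecord]:
    """Read a variant TSV; when ``transcripts`` is given, cross-check each
    ref allele against the CDS."""
    df = pd.read_csv(path, sep="\t", dtype={"ref": str, "alt": str})
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: variant TSV missing columns {sorted(missing)}")
    variants = [
        VariantRecord(
            transcript_id=str(r.transcript_id),
            cds_pos=int(r.cds_pos),
            ref=str(r.ref),
            alt=str(r.alt),
            vaf_tumor_dna=float(r.vaf_tumor_dna),
            vaf_normal_dna=float(r.vaf_normal_dna),
            vaf_tumor_rna=float(r.vaf_tumor_rna),
        )
        for r in df.itertuples()
    ]
    if transcripts is not None:
        by_id = {t.transcript_id: t for t in transcripts}
        for v in variants:
            if v.transcript_id not in by_id:
                raise ValidationError(f"{v.variant_id}: unknown transcript")
            v.check_against(by_id[v.transcript_id].cds)
    return variants


def write_variant_table(variants: Iterable[VariantRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(v) for v in variants], columns=VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_expression_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "gene_id", "tpm"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: expression TSV missing columns {sorted(missing)}")
    if (df["tpm"] < 0).any():
        raise ValidationError(f"{path}: negative TPM values")
    return df


def write_expression_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_hla_alleles(path: str | Path) -> list[str]:
    """One allele label per line (e.g. H-2-Kb, HLA-A*02:01); '#' comments allowed."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_hla_alleles(alleles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(a + "\n" for a in alleles))
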