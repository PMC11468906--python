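"""Tandem-minigene mRNA construct assembly.

The vaccine mRNA is 5'UTR - ORF - stop - 3'UTR - polyA, where the ORF is
SP - linker - neoantigen1 - linker - ... - neoantigenK - end-linker - MITD:
a secretion signal peptide routes the polyprotein into the ER, flexible
GS linkers separate the 27-mer neoantigen segments, and the MHC class I
trafficking domain (MITD) at the C terminus enhances routing of processed
epitopes onto MHC.  The 5'UTR starts with AG (required for co-transcriptional
capping) and ends in the Kozak hexamer GCCACC immediately before the AUG.
Constructs are synthesized with N1-methylpseudouridine in place of uridine;
that substitution is chemistry metadata and the sequence stays in AUGC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .io import AA_ALPHABET, CodonUsageTable, ValidationError

STOP_CODONS_RNA = {"UAA", "UAG", "UGA"}


@dataclass(frozen=True)
class ConstructSpec:
    """Construct sequence constants; defaults are the published vaccine design."""

    sp_aa: str = "MRVTAPRTLILLLSGALALTETWAGS"
    start_linker: str = "GGSGGGGSGG"
    middle_linker: str = "GGSGGGGSGG"
    end_linker: str = "GGSLGGGGSG"
    mitd_aa: str = "VGIVAGLAVLAVVVIGAVVATVMCRRKSSGGKGGSYSQAASSDSAQGSDVSLTA"
    utr5_rna: str = (
        "AGGAAAUUCCAUUUGGCUGCAGCUUCUGGAGGGAGCCGACAGGAGACGUGGGGAGACGGCCACC"
    )
    utr3_rna: str = (
        "GCUGCCUUCUGCGGGGCUUGCCUUCUGGCCAUGCCCUUCUUCUCUCCCUUGCACCUGUACCUCUUGG"
        "UCUUUGAAUAAAGCCUGAGUAGGAAGU"
    )
    polyA_len: int = 75
    stop_codon: str = "UAA"  # paper silent on the stop; UAA has lowest read-through
    nucleoside: str = "N1-methylpseudouridine"  # chemistry note, not sequence

    def __post_init__(self) -> None:
        if not self.utr5_rna.endswith("GCCACC"):
            raise ValidationError("5'UTR must end with the Kozak hexamer GCCACC")
        if not self.utr5_rna.startswith("AG"):
            raise ValidationError("5'UTR must begin with AG (capping requirement)")
        if self.polyA_len <= 0:
            raise ValidationError("polyA_len must be positive")
        if self.stop_codon not in STOP_CODONS_RNA:
            raise ValidationError(f"{self.stop_codon!r} is not a stop codon")


@dataclass(frozen=True)
class Region:
    name: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class AssembledConstruct:
    rna_sequence: str
    regions: tuple[Region, ...]
    peptide_manifest: tuple[str, ...]
    notes: dict[str, str] = field(default_factory=dict)

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def region_seq(self, name: str) -> str:
        r = self.region(name)
        return self.rna_sequence[r.start - 1 : r.end]

    @property
    def orf_rna(self) -> str:
        start = self.region("SP").start
        end = self.region("MITD").end
        return self.rna_sequence[start - 1 : end]


def assemble_orf(
    peptides: Sequence[str],
    spec: ConstructSpec | None = None,
    peptide_ids: Sequence[str] | None = None,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Concatenate SP | start-linker | p1 | linker | ... | pK | end-linker | MITD.

    Returns the amino-acid string and a segment map of (name, start, end) in
    1-based inclusive residue coordinates.
    """
    spec = spec or ConstructSpec()
    if not peptides:
        raise ValidationError("at least one neoantigen peptide is required")
    ids = list(peptide_ids) if peptide_ids is not None else [
        f"neo_{i + 1}" for i in range(len(peptides))
    ]
    if len(ids) != len(peptides):
        raise ValidationError("peptide_ids length mismatch")
    for pid, p in zip(ids, peptides):
        bad = sorted(set(p) - set(AA_ALPHABET))
        if not p or bad:
            raise ValidationError(
                f"peptide {pid}: non-canonical residues {bad}" if bad
                else f"peptide {pid} is empty"
            )
    segments: list[tuple[str, str]] = [("SP", spec.sp_aa), ("start_linker", spec.start_linker)]
    for i, (pid, p) in enumerate(zip(ids, peptides)):
        if i > 0:
            segments.append((f"middle_linker_{i}", spec.middle_linker))
        segments.append((f"neo|{pid}", p))
    segments.append(("end_linker", spec.end_linker))
    segments.append(("MITD", spec.mitd_aa))

    seq_parts: list[str] = []
    seg_map: list[tuple[str, int, int]] = []
    pos = 1
    for name, s in segments:
        seq_parts.append(s)
        seg_map.append((name, pos, pos + len(s) - 1))
        pos += len(s)
    return "".join(seq_parts), seg_map


def naive_codon_source(usage: CodonUsageTable) -> Callable[[str], str]:
    """Reverse-translate with each amino acid's most used codon."""

    def encode(aa_seq: str) -> str:
        return "".join(usage.best_codon(aa) for aa in aa_seq)

    return encode


def build_mrna(
    orf_aa: str,
    spec: ConstructSpec | None = None,
    codon_source: Callable[[str], str] | None = None,
    usage: CodonUsageTable | None = None,
    seg_map: Sequence[tuple[str, int, int]] | None = None,
    peptide_manifest: Sequence[str] | None = None,
    extra_notes: dict[str, str] | None = None,
) -> AssembledConstruct:
    """Build the complete mRNA: 5'UTR | codons(ORF) | stop | 3'UTR | polyA.

    ``codon_source`` maps an amino-acid string to RNA codons (the optimizer
    or the naive most-frequent-codon source); the default is naive encoding
    with ``usage``.  The region map covers the whole molecule with 1-based
    inclusive, gap-free coordinates.
    """
    spec = spec or ConstructSpec()
    if codon_source is None:
        if usage is None:
            raise ValidationError("either codon_source or usage must be given")
        codon_source = naive_codon_source(usage)
    orf_rna = codon_source(orf_aa).upper().replace("T", "U")
    if len(orf_rna) != 3 * len(orf_aa):
        raise ValidationError(
            f"codon source returned {len(orf_rna)} nt for {len(orf_aa)} residues"
        )
    codons = [orf_rna[i : i + 3] for i in range(0, len(orf_rna), 3)]
    stops = [i for i, c in enumerate(codons) if c in STOP_CODONS_RNA]
    if stops:
        raise ValidationError(f"codon source emitted stop codon at codon {stops[0] + 1}")
    if str(Seq(orf_rna).translate()) != orf_aa:
        raise ValidationError("codon source does not encode the requested protein")

    if seg_map is None:
        seg_map = [("ORF", 1, len(orf_aa))]

    pieces = [
        ("5UTR", spec.utr5_rna),
        ("__ORF__", orf_rna),
        ("stop", spec.stop_codon),
        ("3UTR", spec.utr3_rna),
        ("polyA", "A" * spec.polyA_len),
    ]
    regions: list[Region] = []
    seq_parts: list[str] = []
    pos = 1
    for name, s in pieces:
        if name == "__ORF__":
            # expand the amino-acid segment map to nucleotide coordinates
            for seg_name, aa_start, aa_end in seg_map:
                nt_start = pos + 3 * (aa_start - 1)
                nt_end = pos + 3 * aa_end - 1
                regions.append(Region(seg_name, nt_start, nt_end))
        else:
            regions.append(Region(name, pos, pos + len(s) - 1))
        seq_parts.append(s)
        pos += len(s)
    rna = "".join(seq_parts)

    notes = {
        "nucleoside_modification": f"{spec.nucleoside} substituted for U (metadata only)",
        "stop_codon": f"{spec.stop_codon} appended after MITD (declared convention)",
        "coordinates": "1-based inclusive",
    }
    if extra_notes:
        notes.update(extra_notes)
    return AssembledConstruct(
        rna_sequence=rna,
        regions=tuple(regions),
        peptide_manifest=tuple(peptide_manifest or ()),
        notes=notes,
    )


def assemble_construct(
    peptides: Sequence[str],
    peptide_ids: Sequence[str] | None = None,
    spec: ConstructSpec | None = None,
    codon_source: Callable[[str], str] | None = None,
    usage: CodonUsageTable | None = None,
    extra_notes: dict[str, str] | None = None,
) -> AssembledConstruct:
    """One-call assembly from ranked peptides to the full mRNA."""
    spec = spec or ConstructSpec()
    orf_aa, seg_map = assemble_orf(peptides, spec, peptide_ids)
    return build_mrna(
        orf_aa,
        spec,
        codon_source=codon_source,
        usage=usage,
        seg_map=seg_map,
        peptide_manifest=peptide_ids or [f"neo_{i+1}" for i in range(len(peptides))],
        extra_notes=extra_notes,
    )


# ---------------------------------------------------------------------------
# export / import

EXPORT_FORMATS = ("fasta", "genbank", "tsv")


def export(construct: AssembledConstruct, path: str | Path, fmt: str) -> None:
    """Write the construct as RNA FASTA, a GenBank-style flat file with one
    feature per region, or a region TSV.  All are round-trip safe."""
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; available: {EXPORT_FORMATS}")
    if fmt == "fasta":
        rec = SeqRecord(
            Seq(construct.rna_sequence),
            id="mrna_construct",
            description="coordinates=1-based-inclusive",
        )
        SeqIO.write([rec], str(path), "fasta")
    elif fmt == "genbank":
        rec = SeqRecord(
            Seq(construct.rna_sequence.replace("U", "T")),
            id="mrnaconstr",
            name="mrnaconstr",
            description="tandem minigene mRNA construct (U stored as T)",
            annotations={"molecule_type": "mRNA"},
        )
        for r in construct.regions:
            rec.features.append(
                SeqFeature(
                    SimpleLocation(r.start - 1, r.end, strand=1),
                    type="misc_feature",
                    qualifiers={"label": [r.name]},
                )
            )
        SeqIO.write([rec], str(path), "genbank")
    else:
        df = pd.DataFrame(
            [
                {
                    "name": r.name,
                    "start": r.start,
                    "end": r.end,
                    "sequence": construct.region_seq(r.name),
                }
                for r in construct.regions
            ]
        )
        df.to_csv(path, sep="\t", index=False)


def import_construct(path: str | Path, fmt: str) -> AssembledConstruct:
    """Re-import an exported construct (sequence + regions where the format
    carries them)."""
    path = Path(path)
    if fmt not in EXPORT_FORMATS:
        raise ValidationError(f"unknown format {fmt!r}; available: {EXPORT_FORMATS}")
    if fmt == "fasta":
        rec = SeqIO.read(str(path), "fasta")
        return AssembledConstruct(str(rec.seq).upper(), (), ())
    if fmt == "genbank":
        rec = SeqIO.read(str(path), "genbank")
        regions = tuple(
            Region(
                f.qualifiers["label"][0],
                int(f.location.start) + 1,
                int(f.location.end),
            )
            for f in rec.features
            if f.type == "misc_feature"
        )
        return AssembledConstruct(
            str(rec.seq).upper().replace("T", "U"), regions, ()
        )
    df = pd.read_csv(path, sep="\t")
    regions = tuple(Region(r["name"], int(r["start"]), int(r["end"])) for _, r in df.iterrows())
    seq = "".join(df["sequence"])
    return AssembledConstruct(seq, regions, ())


def translate_orf(construct: AssembledConstruct) -> str:
    """Translate the ORF region (SP through MITD) back to amino acids."""
    return str(Seq(construct.orf_rna).translate())
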