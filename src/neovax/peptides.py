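"""Variant application, translation, and 27-mer peptide window extraction.

A candidate neoantigen peptide is the 27-residue window around the mutated
position: 13 wild-type flanking residues on each side of a missense residue
(truncated, never padded, at protein termini), or the 13 residues upstream of
the first frame-shifted residue plus the novel downstream sequence capped at
27.  The window carries every mutation-spanning MHC-I 8-11-mer and MHC-II
15-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .io import TranscriptRecord, VariantRecord, ValidationError

DEFAULT_WINDOW = 27
FLANK = 13  # residues each side of the mutation in a full window


class VariantClass(str, Enum):
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    STOP_GAIN = "stop_gain"
    START_LOSS = "start_loss"  # excluded downstream, like stop_gain
    STOP_LOSS = "stop_loss"    # read-through; excluded downstream

#: classes that yield a vaccine candidate peptide
CODING_CLASSES = {
    VariantClass.MISSENSE,
    VariantClass.INFRAME_INDEL,
    VariantClass.FRAMESHIFT,
}


@dataclass(frozen=True)
class MutantProtein:
    transcript_id: str
    variant_id: str
    wt_protein: str
    mut_protein: str
    first_changed_residue: int | None  # 1-based; None for synonymous
    variant_class: VariantClass


@dataclass(frozen=True)
class PeptidePair:
    """Mutant 27-mer (or shorter, near termini) and its aligned WT window.

    ``window_start`` is the 1-based residue index of the window in the mutant
    protein; ``mutant_offset`` the 1-based index of the first altered residue
    within the peptide.  Frameshift peptides have no aligned WT window.
    """

    mut_peptide: str
    wt_peptide: str | None
    window_start: int
    mutant_offset: int
    frameshift: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.mutant_offset <= len(self.mut_peptide):
            raise ValidationError(
                f"mutant_offset {self.mutant_offset} outside peptide of length "
                f"{len(self.mut_peptide)}"
            )
        if self.wt_peptide is not None and self.wt_peptide == self.mut_peptide:
            raise ValidationError("mutant and WT peptides are identical")


def _translate_to_stop(cds: str) -> str:
    trimmed = cds[: len(cds) - len(cds) % 3]  # frameshifts may leave a partial codon
    return str(Seq(trimmed).translate(to_stop=True))


def apply_variant(transcript: TranscriptRecord, variant: VariantRecord) -> MutantProtein:
    """Apply one variant to the CDS and classify its protein consequence.

    Classes: frameshift when |ref|-|alt| is not a multiple of 3; inframe_indel
    for in-frame length changes; substitutions are synonymous / missense /
    stop_gain by protein comparison.  Edits destroying the start codon are
    flagged start_loss, edits removing the stop without a replacement
    stop_loss; both are excluded from candidates downstream.
    """
    cds = transcript.cds
    if variant.cds_pos - 1 + len(variant.ref) > len(cds):
        raise ValidationError(
            f"{variant.variant_id}: variant extends past CDS end ({len(cds)} nt)"
        )
    variant.check_against(cds)

    edited = (
        cds[: variant.cds_pos - 1]
        + variant.alt
        + cds[variant.cds_pos - 1 + len(variant.ref) :]
    )
    wt_protein = _translate_to_stop(cds)
    if not edited.startswith("ATG"):
        return MutantProtein(
            transcript.transcript_id,
            variant.variant_id,
            wt_protein,
            "",
            None,
            VariantClass.START_LOSS,
        )
    mut_protein = _translate_to_stop(edited)

    frame = (len(variant.ref) - len(variant.alt)) % 3
    first_diff = _first_difference(wt_protein, mut_protein)

    if frame != 0:
        cls = VariantClass.FRAMESHIFT
    elif len(variant.ref) != len(variant.alt):
        cls = VariantClass.INFRAME_INDEL
    elif mut_protein == wt_protein:
        cls = VariantClass.SYNONYMOUS
    elif len(mut_protein) < len(wt_protein) and wt_protein.startswith(mut_protein):
        cls = VariantClass.STOP_GAIN
    elif len(mut_protein) > len(wt_protein) and mut_protein.startswith(wt_protein):
        cls = VariantClass.STOP_LOSS
    else:
        cls = VariantClass.MISSENSE

    if cls is VariantClass.SYNONYMOUS:
        first_diff = None
    elif first_diff is None:
        # truncation/extension with identical shared prefix: first change is
        # the residue after the shared prefix
        first_diff = min(len(wt_protein), len(mut_protein)) + 1
    return MutantProtein(
        transcript.transcript_id,
        variant.variant_id,
        wt_protein,
        mut_protein,
        first_diff,
        cls,
    )


def _first_difference(a: str, b: str) -> int | None:
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return i + 1
    return None


def extract_peptide_pair(mp: MutantProtein, window: int = DEFAULT_WINDOW) -> PeptidePair:
    """Extract the candidate window around the first changed residue.

    Missense / in-frame indel: the window is centered on the (first) mutant
    residue, 13 residues of flank on each side when the protein permits and
    truncated at the termini otherwise; the WT peptide is the same coordinate
    window on the WT protein.  Frameshift: the window starts 13 residues
    upstream of the first changed residue and runs toward the stop, capped at
    ``window``; there is no aligned WT peptide.
    """
    if mp.variant_class not in CODING_CLASSES:
        raise ValidationError(
            f"{mp.variant_id}: no neoantigen for class {mp.variant_class.value}"
        )
    assert mp.first_changed_residue is not None
    flank = (window - 1) // 2
    r = mp.first_changed_residue
    n = len(mp.mut_protein)
    if r > n:
        raise ValidationError(
            f"{mp.variant_id}: first changed residue {r} beyond mutant protein"
        )
    start = max(1, r - flank)
    if mp.variant_class is VariantClass.FRAMESHIFT:
        end = min(n, start + window - 1)
        return PeptidePair(
            mut_peptide=mp.mut_protein[start - 1 : end],
            wt_peptide=None,
            window_start=start,
            mutant_offset=r - start + 1,
            frameshift=True,
        )
    end = min(n, r + flank)
    wt = mp.wt_protein[start - 1 : end] or None
    if wt == mp.mut_protein[start - 1 : end]:
        # degenerate in-frame indel inside a repeat: window looks wild-type
        wt = None
    return PeptidePair(
        mut_peptide=mp.mut_protein[start - 1 : end],
        wt_peptide=wt,
        window_start=start,
        mutant_offset=r - start + 1,
    )


# ---------------------------------------------------------------------------
# cohort-level convenience + export

@dataclass(frozen=True)
class CandidateWindow:
    """A peptide pair joined back to its source variant."""

    variant: VariantRecord
    protein: MutantProtein
    pair: PeptidePair

    @property
    def candidate_id(self) -> str:
        return self.variant.variant_id


def extract_candidates(
    transcripts: Iterable[TranscriptRecord],
    variants: Iterable[VariantRecord],
    window: int = DEFAULT_WINDOW,
) -> tuple[list[CandidateWindow], list[tuple[str, str]]]:
    """Apply every variant and window the coding consequences.

    Returns ``(candidates, skipped)`` where ``skipped`` holds
    ``(variant_id, reason)`` for synonymous/start-loss/stop-gain/stop-loss
    variants that yield no vaccine candidate.
    """
    by_id = {t.transcript_id: t for t in transcripts}
    out: list[CandidateWindow] = []
    skipped: list[tuple[str, str]] = []
    for v in variants:
        t = by_id.get(v.transcript_id)
        if t is None:
            raise ValidationError(f"{v.variant_id}: unknown transcript")
        mp = apply_variant(t, v)
        if mp.variant_class not in CODING_CLASSES:
            skipped.append((v.variant_id, f"variant class {mp.variant_class.value}"))
            continue
        if mp.first_changed_residue is None or mp.first_changed_residue > len(
            mp.mut_protein
        ):
            # e.g. a frameshift whose novel frame stops immediately
            skipped.append((v.variant_id, "no altered residue within mutant protein"))
            continue
        out.append(CandidateWindow(v, mp, extract_peptide_pair(mp, window)))
    return out, skipped


def write_peptide_fastas(
    candidates: Iterable[CandidateWindow],
    mut_path: str | Path,
    wt_path: str | Path,
) -> None:
    """Mutant and WT peptide FASTAs, IDs keyed transcript:pos:ref>alt."""
    muts, wts = [], []
    for c in candidates:
        muts.append(SeqRecord(Seq(c.pair.mut_peptide), id=c.candidate_id, description=""))
        if c.pair.wt_peptide is not None:
            wts.append(SeqRecord(Seq(c.pair.wt_peptide), id=c.candidate_id, description=""))
    SeqIO.write(muts, str(mut_path), "fasta")
    SeqIO.write(wts, str(wt_path), "fasta")


def peptide_table(candidates: Iterable[CandidateWindow]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        rows.append(
            {
                "candidate_id": c.candidate_id,
                "transcript_id": c.variant.transcript_id,
                "variant_class": c.protein.variant_class.value,
                "mut_peptide": c.pair.mut_peptide,
                "wt_peptide": c.pair.wt_peptide or "",
                "window_start": c.pair.window_start,
                "mutant_offset": c.pair.mutant_offset,
                "frameshift_window_rule": c.pair.frameshift,  # declared convention
                "vaf_tumor_dna": c.variant.vaf_tumor_dna,
                "vaf_normal_dna": c.variant.vaf_normal_dna,
                "vaf_tumor_rna": c.variant.vaf_tumor_rna,
            }
        )
    return pd.DataFrame(rows)
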