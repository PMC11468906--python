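"""Variant application, classification, and 27-mer window extraction."""

import pytest
from hypothesis import given, settings, strategies as st

from neovax.io import TranscriptRecord, ValidationError, VariantRecord
from neovax.peptides import (
    VariantClass,
    apply_variant,
    extract_candidates,
    extract_peptide_pair,
)
from neovax.simulate import generate_cohort, CohortParams

from conftest import make_protein_transcript

# independent codon table for the translation cross-check (DNA codons)
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "AGT": "S", "AGC": "S", "CCT": "P", "CCC": "P",
    "CCA": "P", "CCG": "P", "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGA": "R", "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G", "TAA": "*", "TAG": "*", "TGA": "*",
}


def reference_translate(cds: str) -> str:
    """Codon-by-codon translation with a hand-rolled table, up to first stop."""
    out = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def _variant(transcript_id, pos, ref, alt):
    return VariantRecord(transcript_id, pos, ref, alt, 0.3, 0.0, 0.25)


class TestApplyVariant:
    def test_missense_toy_cds(self, toy_transcript):
        mp = apply_variant(toy_transcript, _variant("T1", 4, "G", "A"))
        assert mp.wt_protein == "MAD" and mp.mut_protein == "MTD"
        assert mp.variant_class is VariantClass.MISSENSE
        assert mp.first_changed_residue == 2

    def test_synonymous_gct_to_gca(self, toy_transcript):
        mp = apply_variant(toy_transcript, _variant("T1", 6, "T", "A"))
        assert mp.variant_class is VariantClass.SYNONYMOUS
        assert mp.first_changed_residue is None
        assert mp.mut_protein == mp.wt_protein

    def test_frameshift_insertion(self, toy_transcript):
        # ref G -> alt GA at pos 4: ATG AGC TGA ... diverges from residue 2
        mp = apply_variant(toy_transcript, _variant("T1", 4, "G", "GA"))
        assert mp.variant_class is VariantClass.FRAMESHIFT
        assert mp.first_changed_residue == 2
        assert mp.mut_protein != mp.wt_protein

    def test_inframe_insertion(self, toy_transcript):
        mp = apply_variant(toy_transcript, _variant("T1", 4, "G", "GGCT"))
        assert mp.variant_class is VariantClass.INFRAME_INDEL
        assert len(mp.mut_protein) == len(mp.wt_protein) + 1

    def test_stop_gain(self, usage):
        t = make_protein_transcript("MKLV", usage)
        # K codon AAG at 4-6 -> TAG stop
        mp = apply_variant(t, _variant("TP", 4, "A", "T"))
        assert mp.variant_class is VariantClass.STOP_GAIN
        assert mp.mut_protein == "M"

    def test_start_loss_flagged(self, toy_transcript):
        mp = apply_variant(toy_transcript, _variant("T1", 1, "A", "C"))
        assert mp.variant_class is VariantClass.START_LOSS

    def test_variant_past_end_raises(self, toy_transcript):
        with pytest.raises(ValidationError, match="past CDS end"):
            apply_variant(toy_transcript, _variant("T1", 12, "AAA", "A"))

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_translation_matches_independent_table(self, seed):
        """Edited-CDS translation agrees with a hand-rolled codon table."""
        cohort = generate_cohort(seed=seed, n_transcripts=3, n_variants=5)
        by_id = {t.transcript_id: t for t in cohort.transcripts}
        for v in cohort.variants:
            t = by_id[v.transcript_id]
            mp = apply_variant(t, v)
            edited = t.cds[: v.cds_pos - 1] + v.alt + t.cds[v.cds_pos - 1 + len(v.ref):]
            assert mp.wt_protein == reference_translate(t.cds)
            if mp.variant_class is not VariantClass.START_LOSS:
                assert mp.mut_protein == reference_translate(edited)


class TestExtractPeptidePair:
    def test_interior_missense_full_window(self, usage):
        protein = "M" + "A" * 299
        t = make_protein_transcript(protein, usage)
        pos = 3 * 99 + 1  # first base of codon 100
        ref = t.cds[pos - 1]
        alt = "G" if ref != "G" else "C"
        mp = apply_variant(t, _variant("TP", pos, ref, alt))
        assert mp.variant_class is VariantClass.MISSENSE
        assert mp.first_changed_residue == 100
        pair = extract_peptide_pair(mp)
        assert pair.window_start == 87
        assert len(pair.mut_peptide) == 27
        assert pair.mutant_offset == 14
        assert pair.mut_peptide == mp.mut_protein[86:113]
        assert pair.wt_peptide == mp.wt_protein[86:113]

    def test_n_terminal_truncation(self, usage):
        protein = "M" + "A" * 99
        t = make_protein_transcript(protein, usage)
        pos = 3 * 4 + 1  # codon 5
        ref = t.cds[pos - 1]
        mp = apply_variant(t, _variant("TP", pos, ref, "G" if ref != "G" else "C"))
        pair = extract_peptide_pair(mp)
        assert pair.window_start == 1
        assert len(pair.mut_peptide) == 18  # residues 1-18
        assert pair.mutant_offset == 5

    def test_frameshift_window_rule(self, usage):
        """First change at residue 50, novel frame stops after residue 60:
        window covers 37-60 (24 aa), no WT peptide."""
        protein = "M" + "A" * 58  # 59 residues; will extend via frameshift
        t = make_protein_transcript(protein, usage)
        pos = 3 * 49 + 1  # start of codon 50
        ref = t.cds[pos - 1]
        mp_candidates = []
        # build an explicit frameshifted transcript: insert one base so that
        # residues 50.. change and a stop appears at residue 61
        from neovax.io import VariantRecord
        v = VariantRecord("TP", pos, ref, ref + "G", 0.3, 0.0, 0.25)
        mp = apply_variant(t, v)
        assert mp.variant_class is VariantClass.FRAMESHIFT
        pair = extract_peptide_pair(mp)
        assert pair.wt_peptide is None
        assert pair.window_start == mp.first_changed_residue - 13
        assert len(pair.mut_peptide) <= 27
        assert pair.mut_peptide == mp.mut_protein[
            pair.window_start - 1 : pair.window_start - 1 + len(pair.mut_peptide)
        ]

    def test_synonymous_rejected(self, toy_transcript):
        mp = apply_variant(toy_transcript, _variant("T1", 6, "T", "A"))
        with pytest.raises(ValidationError, match="no neoantigen"):
            extract_peptide_pair(mp)


class TestWindowProperties:
    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_interior_missense_windows_are_centered_27mers(self, seed):
        params = CohortParams(synonymous_fraction=0.0, indel_fraction=0.0,
                              cds_len_codons=(80, 150))
        cohort = generate_cohort(seed=seed, n_transcripts=4, n_variants=6,
                                 params=params)
        candidates, _ = extract_candidates(cohort.transcripts, cohort.variants)
        for c in candidates:
            r = c.protein.first_changed_residue
            n = len(c.protein.mut_protein)
            if c.protein.variant_class is VariantClass.MISSENSE and 13 < r <= n - 13:
                assert len(c.pair.mut_peptide) == 27
                assert c.pair.mutant_offset == 14
            # peptide is a substring of the mutant protein at its coordinates
            s = c.pair.window_start
            assert c.pair.mut_peptide == c.protein.mut_protein[
                s - 1 : s - 1 + len(c.pair.mut_peptide)
            ]

    def test_synonymous_variants_never_yield_pairs(self):
        params = CohortParams(synonymous_fraction=1.0, indel_fraction=0.0)
        cohort = generate_cohort(seed=5, n_transcripts=5, n_variants=8, params=params)
        candidates, skipped = extract_candidates(cohort.transcripts, cohort.variants)
        assert candidates == []
        assert len(skipped) == 8
        assert all("synonymous" in reason for _, reason in skipped)
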