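import pytest

from neovax.io import CodonUsageTable, TranscriptRecord, builtin_codon_usage


@pytest.fixture(scope="session")
def usage() -> CodonUsageTable:
    return builtin_codon_usage()


@pytest.fixture()
def toy_transcript() -> TranscriptRecord:
    # ATG GCT GAT TAA -> protein MAD
    return TranscriptRecord("T1", "ATGGCTGATTAA", gene_id="G1", tpm=10.0)


def make_protein_transcript(protein: str, usage: CodonUsageTable) -> TranscriptRecord:
    """A transcript whose CDS encodes ``protein`` via most-used codons."""
    cds = "".join(usage.best_codon(aa).replace("U", "T") for aa in protein) + "TAA"
    return TranscriptRecord("TP", cds, gene_id="GP", tpm=5.0)
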