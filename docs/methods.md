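# Methods

This note documents the models, conventions, and numerical choices behind
`neovax`, in the spirit of the model documentation shipped by simulation and
statistics packages. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Variant model and peptide windows

Variants live in transcript CDS coordinates (1-based, inclusive), with
indels in the anchored VCF dialect (ref `G`, alt `GAT` is a 2-nt insertion).
Genomic-coordinate VCF ingestion is out of scope: it would add a commodity
annotation step without touching any of the bespoke computation.

Consequence classes are derived by editing the CDS and comparing
translations: frame offset `(|ref| − |alt|) mod 3 ≠ 0` ⇒ frameshift;
in-frame length change ⇒ in-frame indel; substitutions are synonymous,
missense, or stop-gain by protein comparison. Two additional classes —
start-loss (the edit destroys the initiator AUG) and stop-loss (read-through)
— are flagged and excluded from vaccine candidates, as is stop-gain: a
truncating variant leaves no mutant residue to present. Multiple variants on
one transcript are applied independently (one peptide per variant); phasing
is not modeled.

The candidate peptide is a 27-mer centered on the mutant residue
(13 + 1 + 13), the standard tandem-minigene convention: it maximizes
simultaneous coverage of mutation-spanning MHC-I 8–11-mers and MHC-II
15-mers. Windows are truncated, never padded, at protein termini. For
frameshifts — where no centering target exists because every residue from
the first changed one onward is novel — the window starts 13 residues
upstream of the first changed residue and runs toward the stop, capped at
27, with no aligned wild-type window. This frameshift rule is a declared
convention (flagged in output metadata), not an attested procedure.

## Scoring and ranking

Binding prediction is an interface. The built-in model is a deterministic
position-weight matrix per (allele, length) whose normalized log-score
s ∈ [0, 1] maps to affinity 50000^(1−s) nM (floored at 1 nM), so the full
scan/aggregate/rank machinery is testable without external neural
predictors; it has no biological calibration. External predictor output in
the common (peptide, allele, affinity, %rank) tabular dialect can be
ingested instead.

Normalized features: affinities use the fixed 1 − log(aff)/log(50000)
transform (clipped to [0, 1]); VAFs and TPM are min-max normalized within
the filtered candidate pool (a degenerate pool maps to 0.5 — the feature
then carries no information and must not perturb the ordering); germline
VAF enters as 1 − normalized value; agretopicity as min(1, log₂(A+1)/4),
which saturates at A = 15 — also the value assigned to frameshift peptides,
which have no wild-type counterpart. Stability and immunogenicity default to
a neutral 0.5 when no predictor supplies them, keeping the total order
well-defined.

The composite is linear with weights (affinity 0.30, agretopicity 0.15,
expression 0.15, RNA VAF 0.15, DNA VAF 0.10, stability 0.05, immunogenicity
0.05, germline-absence 0.05), normalized to sum to 1. These are this
package's own documented defaults: the originating composite's coefficients
are not public, and whether it is even linear is unknown — linearity is our
declared choice, made for transparency and testability (monotonicity and
scale-invariance properties are exact for a linear composite). Hard filters
(tumor-DNA VAF ≥ 0.05, germline VAF ≤ 0.02, TPM ≥ 1, mutant affinity
≤ 500 nM) are standard field conventions, configurable, and every exclusion
is reported with the specific threshold violated. Ties break by higher
tumor-DNA VAF, then lower mutant affinity, then lexicographic peptide, so
ranking is a deterministic total order.

## Construct

ORF pattern: SP ∥ start-linker ∥ neo₁ ∥ middle-linker ∥ … ∥ neo_k ∥
end-linker ∥ MITD, with the published signal-peptide, linker, and MITD
amino-acid sequences as defaults and the published 5′UTR (beginning AG, as
required for capping; ending in the GCCACC Kozak hexamer), α-globin-derived
3′UTR, and 75-nt polyA. The start and middle linkers are identical
(GGSGGGGSGG); the distinct end linker (GGSLGGGGSG) precedes MITD — the only
reading consistent with the stated SP-Linker-…-linker-MITD pattern. A stop
codon is nowhere specified in the source design; we append a single UAA
(lowest read-through of the three stops) after MITD, configurable and echoed
in output metadata. Sequences are RNA (AUGC); the N1-methylpseudouridine
substitution used in synthesis is recorded as metadata only. Coordinates are
1-based inclusive everywhere, and the region map tiles the molecule exactly
(a property test checks gap/overlap freedom over random peptide sets).

## Codon design

Objective: `MFE(s) − λ · Σ log w(cᵢ)`, minimized exactly over all synonymous
codon sequences by a lattice dynamic program — a Nussinov recursion whose
interval endpoints carry the codon choice at their position, with per-codon
CAI costs charged once (at each codon's first consumed position) and
boundary states keeping choices consistent across subproblem splits.
Values are (objective, Σ −log w) tuples compared lexicographically, so exact
objective ties resolve toward higher CAI; traceback prefers
lexicographically smaller codons among optimal options.

The energy model is an additive base-pair score over nested structures
(GC/CG −2, AU/UA −1, GU/UG −0.5; minimum hairpin 3 unpaired bases) rather
than nearest-neighbor thermodynamics. This is a deliberate trade: with an
additive pair model both the folding DP and the joint design DP admit
exhaustive oracles (all nested structures for sequences ≤ 12 nt; the full
codon product for peptides ≤ 4 aa), making the optimizer's exactness a
tested fact rather than a claim. The `EnergyModel` is pluggable for
re-scoring designed sequences with richer thermodynamics; the DP itself
requires additivity. λ defaults to 1.0; the trade-off it controls is
Pareto-consistent (CAI non-decreasing, folding score non-improving in λ),
which the suite verifies on exact-mode designs.

Cost: the lattice DP is O(n³ · c²) in pure Python (c = codon choices per
position). Exact mode is used for coding sequences up to 81 nt — one 27-mer
neoantigen — and longer ORFs are designed in overlapping 13-codon windows
advancing 9 codons, stitched at codon boundaries and re-scored globally.
Windowed results are approximate and say so in their metadata (`mode:
"windowed"`); exact mode at any length remains available. Whether the UTRs
participate in the folding objective is unstated in the source design; we
fold the ORF only.

## Formulation and assay arithmetic

Phosphate moles = mRNA mass / mean per-nucleotide molar mass (default
330 g/mol); ionizable lipid moles = N:P × phosphate moles / amines per
lipid (defaults 4.8 and 1); the other lipids follow from the mole fractions
40 : 15 : 43.5 : 1.5 relative to the ionizable's 40%; masses are moles × MW.
Volumes follow mRNA:protamine 5:1 (v/v) and aqueous:ethanol 3:1. The
ionizable lipid is proprietary and unnamed, so its molar mass is a required
config field; `example_formulation_config()` supplies a synthetic fixture
value (710 g/mol, a typical magnitude for this lipid class). The defining
round-trip invariants — N:P and mole fractions recomputed from emitted
masses equal the configured inputs to 1e-9 relative — are independent of
every molar mass, which is why the acceptance computation is meaningful
without the real lipid identity.

ELISpot responder rule: responder iff mean spots ≥ 2× the group's
negative-control mean AND background-subtracted spots ≥ 10 per well. The
source study does not state its responder definition; this is a standard
ELISpot convention, fully configurable and echoed in each call record.
Responder rates carry exact Clopper–Pearson 95% CIs. Tumor volume is
½·L·W² (dimensions swapped with a warning if given reversed); TGI is
100·(1 − T/C) on group means of user-supplied measurements — figure-derived
volumes are not reproduced here.

## Synthetic data

`generate_cohort` emulates matched tumor/normal exome plus tumor RNA
sequencing of a cell line at the level the pipeline consumes: random
complete CDSs of 60–200 codons; SNVs (a configurable fraction synonymous)
and anchored 1–3-nt indels placed strictly inside the coding body; somatic
tumor-DNA VAFs drawn from a subclonal-to-clonal mix (0.05 + 0.95·Beta(2,4)),
RNA VAFs from the DNA VAF plus N(0, 0.05) measurement noise, germline
contaminants (optional) near VAF 0.5; log-normal TPM (ln-scale mean 2.0,
sd 1.5, median ≈ 7 TPM); and a fixed two-allele murine MHC panel. Identical
seed and parameters give byte-identical cohorts.

What it does not emulate: linkage between variants, mutational signatures,
realistic codon/GC composition, allele-specific expression, HLA LOH, or any
correlation between peptide sequence and true immunogenicity. Passing tests
therefore demonstrate the pipeline's correctness and its ability to recover
candidates that are separated in feature space — not predictive performance
on real tumors.

For ranking-recovery experiments, `generate_feature_cohort` plants "true
immunogenic" candidates directly at the feature level (affinity 2–50 nM vs
a 30–5000 nM background, TPM 30–300 vs 1–50, tumor VAF 0.30–0.60 vs
0.05–0.25, agretopicity 2–15 vs 0.3–2 — order-of-magnitude boosts on
log-uniform draws). Feature-level planting is used because the toy PWM gives
random peptides essentially random affinities, so sequence-level planting
cannot encode "high affinity" without inverting the PWM.

## Problem sizes

The shipped tests and acceptance checks run at desk scale by design: design
oracles use 200 random peptides of ≤ 4 residues against the full codon
product and folding oracles enumerate all nested structures for sequences of
≤ 12 nt; ranking properties run over 100 seeded cohorts of ~23 candidates;
recovery uses 30 cohorts of 50; end-to-end runs use 15–40 transcripts.
These sizes exercise every code path (including windowed design) while
keeping the whole suite fast enough to run habitually.

## Known limitations

- The binding model is a toy; all affinity-dependent numbers are
  placeholders until an external predictor's output is supplied.
- The folding model ignores stacking, loop penalties, and pseudoknots;
  designed "MFE" values are pair-score sums, not kcal/mol.
- Windowed codon design is greedy across windows and carries no optimality
  bound.
- The composite weights are not the originating algorithm's; rank orders
  should be read as reproducible, not canonical.
- No proteasomal-cleavage, TAP-transport, or TCR-recognition modeling.
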