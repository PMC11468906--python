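"""Multi-feature neoantigen scoring, ranking, and top-N selection.

Each candidate 27-mer is scanned for its best (lowest-affinity)
mutation-spanning MHC-I 8-11-mer and MHC-II 15-mer across the allele panel;
together with allele frequencies, expression, agretopicity (WT/mutant
affinity ratio), and optional stability/immunogenicity predictions this
forms the feature vector.  Features are normalized to [0,1] and combined as
a weighted linear composite; candidates failing hard filters are excluded
with machine-readable reasons, survivors ranked and the top N selected.

The default weights are this package's own documented re-parameterization
of a composite whose original coefficients are not public; they carry no
claim of equivalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import pandas as pd

from .binding import (
    BindingPrediction,
    CLASS_I_LENGTHS,
    CLASS_II_LENGTHS,
    MAX_AFFINITY_NM,
)
from .io import ValidationError
from .peptides import PeptidePair

DEFAULT_TOP_N = 20
DEFAULT_AGRETOPICITY_CAP = 15.0

Predictor = Callable[[str, str], BindingPrediction]


@dataclass(frozen=True)
class BindingSummary:
    """Best (minimum) affinities over mutation-spanning sub-peptides x alleles."""

    best_mut_affinity_nM: float
    best_wt_affinity_nM: float | None
    per_class: dict[str, tuple[float, float | None]]
    n_windows: int


def _windows(length: int, offset: int, sub_lengths: Sequence[int]):
    """Start positions (1-based) of sub-windows containing ``offset``."""
    for L in sub_lengths:
        lo = max(1, offset - L + 1)
        hi = min(offset, length - L + 1)
        for s in range(lo, hi + 1):
            yield s, L


def scan_subpeptides(
    pair: PeptidePair,
    alleles: Sequence[str],
    predictor: Predictor,
    class_i_lengths: Sequence[int] = CLASS_I_LENGTHS,
    class_ii_lengths: Sequence[int] = CLASS_II_LENGTHS,
) -> BindingSummary:
    """Enumerate all mutation-overlapping 8-11-mers (class I) and 15-mers
    (class II) of the window and take the best affinity over sub-peptides and
    alleles; the WT best is computed over the aligned WT coordinates."""
    if not alleles:
        raise ValidationError("no alleles supplied")
    per_class: dict[str, tuple[float, float | None]] = {}
    n_windows = 0
    for cls, lengths in (("I", class_i_lengths), ("II", class_ii_lengths)):
        best_mut = math.inf
        best_wt = math.inf
        any_wt = False
        for s, L in _windows(len(pair.mut_peptide), pair.mutant_offset, lengths):
            n_windows += 1
            sub = pair.mut_peptide[s - 1 : s - 1 + L]
            for allele in alleles:
                best_mut = min(best_mut, predictor(sub, allele).affinity_nM)
            if pair.wt_peptide is not None and s - 1 + L <= len(pair.wt_peptide):
                wt_sub = pair.wt_peptide[s - 1 : s - 1 + L]
                any_wt = True
                for allele in alleles:
                    best_wt = min(best_wt, predictor(wt_sub, allele).affinity_nM)
        per_class[cls] = (
            best_mut if best_mut < math.inf else MAX_AFFINITY_NM,
            best_wt if any_wt else None,
        )
    best_mut_all = min(v[0] for v in per_class.values())
    wt_values = [v[1] for v in per_class.values() if v[1] is not None]
    return BindingSummary(
        best_mut_affinity_nM=best_mut_all,
        best_wt_affinity_nM=min(wt_values) if wt_values else None,
        per_class=per_class,
        n_windows=n_windows,
    )


# ---------------------------------------------------------------------------
# features and scoring

@dataclass(frozen=True)
class FeatureVector:
    vaf_tumor_dna: float
    vaf_normal_dna: float
    vaf_tumor_rna: float
    expr_tpm: float
    best_mut_affinity_nM: float
    best_wt_affinity_nM: float | None = None
    stability_halflife_h: float | None = None
    immunogenicity_score: float = 0.5  # neutral default without a predictor
    agretopicity_cap: float = DEFAULT_AGRETOPICITY_CAP

    def __post_init__(self) -> None:
        for name in (
            "vaf_tumor_dna",
            "vaf_normal_dna",
            "vaf_tumor_rna",
            "expr_tpm",
            "best_mut_affinity_nM",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not 0 <= self.immunogenicity_score <= 1:
            raise ValidationError("immunogenicity_score outside [0,1]")

    @property
    def agretopicity(self) -> float:
        """WT/mutant affinity ratio; the configured cap when no WT exists
        (frameshift) — a frameshift peptide has no germline counterpart."""
        if self.best_wt_affinity_nM is None:
            return self.agretopicity_cap
        return self.best_wt_affinity_nM / self.best_mut_affinity_nM


@dataclass(frozen=True)
class ScoreWeights:
    """Linear composite weights (normalized to sum 1) and hard filters.

    Defaults are documented, non-canonical choices: affinity dominates,
    clonality/expression/agretopicity follow, stability and immunogenicity
    contribute only when predictors supply them.
    """

    affinity: float = 0.30
    agretopicity: float = 0.15
    expression: float = 0.15
    rna_vaf: float = 0.15
    dna_vaf: float = 0.10
    stability: float = 0.05
    immunogenicity: float = 0.05
    germline_absence: float = 0.05
    # hard filters
    min_vaf_tumor_dna: float = 0.05
    max_vaf_normal_dna: float = 0.02
    min_expr_tpm: float = 1.0
    max_mut_affinity_nM: float = 500.0

    _FEATURES = (
        "affinity",
        "agretopicity",
        "expression",
        "rna_vaf",
        "dna_vaf",
        "stability",
        "immunogenicity",
        "germline_absence",
    )

    def normalized(self) -> dict[str, float]:
        raw = {f: getattr(self, f) for f in self._FEATURES}
        if any(v < 0 for v in raw.values()):
            raise ValidationError("weights must be non-negative")
        total = sum(raw.values())
        if total <= 0:
            raise ValidationError("at least one weight must be positive")
        return {k: v / total for k, v in raw.items()}


@dataclass
class PoolContext:
    """Per-feature min/max over the candidate pool, for min-max features."""

    ranges: dict[str, tuple[float, float]]

    @classmethod
    def from_features(cls, fvs: Sequence[FeatureVector]) -> "PoolContext":
        ranges = {}
        for name in ("vaf_tumor_dna", "vaf_normal_dna", "vaf_tumor_rna", "expr_tpm"):
            vals = [getattr(fv, name) for fv in fvs]
            ranges[name] = (min(vals), max(vals)) if vals else (0.0, 0.0)
        stab = [fv.stability_halflife_h for fv in fvs if fv.stability_halflife_h is not None]
        ranges["stability_halflife_h"] = (min(stab), max(stab)) if stab else (0.0, 0.0)
        return cls(ranges)

    def minmax(self, name: str, value: float) -> float:
        lo, hi = self.ranges[name]
        if hi <= lo:
            return 0.5  # degenerate pool: feature carries no information
        return (value - lo) / (hi - lo)


def _affinity_transform(affinity_nM: float) -> float:
    """1 - log-50k transform: 1 at <=1 nM, 0 at >=50,000 nM."""
    return min(1.0, max(0.0, 1.0 - math.log(affinity_nM) / math.log(MAX_AFFINITY_NM)))


def normalized_features(fv: FeatureVector, pool: PoolContext) -> dict[str, float]:
    stab = (
        0.5
        if fv.stability_halflife_h is None
        else pool.minmax("stability_halflife_h", fv.stability_halflife_h)
    )
    return {
        "affinity": _affinity_transform(fv.best_mut_affinity_nM),
        "agretopicity": min(1.0, math.log2(fv.agretopicity + 1.0) / 4.0),
        "expression": pool.minmax("expr_tpm", fv.expr_tpm),
        "rna_vaf": pool.minmax("vaf_tumor_rna", fv.vaf_tumor_rna),
        "dna_vaf": pool.minmax("vaf_tumor_dna", fv.vaf_tumor_dna),
        "stability": stab,
        "immunogenicity": fv.immunogenicity_score,
        "germline_absence": 1.0 - pool.minmax("vaf_normal_dna", fv.vaf_normal_dna),
    }


def composite_score(fv: FeatureVector, weights: ScoreWeights, pool: PoolContext) -> float:
    """Weighted sum of normalized features; in [0,1] by construction."""
    w = weights.normalized()
    f = normalized_features(fv, pool)
    return sum(w[k] * f[k] for k in w)


# ---------------------------------------------------------------------------
# ranking

@dataclass(frozen=True)
class RankInput:
    candidate_id: str
    pair: PeptidePair
    features: FeatureVector


@dataclass(frozen=True)
class CandidateNeoantigen:
    candidate_id: str
    pair: PeptidePair
    features: FeatureVector
    composite_score: float
    rank: int


@dataclass(frozen=True)
class FilterReport:
    candidate_id: str
    reasons: tuple[str, ...]


def hard_filter_reasons(fv: FeatureVector, w: ScoreWeights) -> tuple[str, ...]:
    reasons = []
    if fv.vaf_tumor_dna < w.min_vaf_tumor_dna:
        reasons.append(f"vaf_tumor_dna {fv.vaf_tumor_dna} < min {w.min_vaf_tumor_dna}")
    if fv.vaf_normal_dna > w.max_vaf_normal_dna:
        reasons.append(
            f"vaf_normal_dna {fv.vaf_normal_dna} > max {w.max_vaf_normal_dna}"
        )
    if fv.expr_tpm < w.min_expr_tpm:
        reasons.append(f"expr_tpm {fv.expr_tpm} < min {w.min_expr_tpm}")
    if fv.best_mut_affinity_nM > w.max_mut_affinity_nM:
        reasons.append(
            f"best_mut_affinity_nM {fv.best_mut_affinity_nM} > max "
            f"{w.max_mut_affinity_nM}"
        )
    return tuple(reasons)


def rank_and_select(
    candidates: Sequence[RankInput],
    weights: ScoreWeights | None = None,
    top_n: int = DEFAULT_TOP_N,
) -> tuple[list[CandidateNeoantigen], list[FilterReport]]:
    """Filter, score, rank, and keep the top ``top_n`` candidates.

    Ties are broken by higher tumor-DNA VAF, then lower mutant affinity,
    then lexicographic mutant peptide.  Zero survivors is not an error: the
    result is an empty list plus the filter-attrition report.
    """
    weights = weights or ScoreWeights()
    attrition: list[FilterReport] = []
    survivors: list[RankInput] = []
    for c in candidates:
        reasons = hard_filter_reasons(c.features, weights)
        if reasons:
            attrition.append(FilterReport(c.candidate_id, reasons))
        else:
            survivors.append(c)
    if not survivors:
        return [], attrition
    pool = PoolContext.from_features([c.features for c in survivors])
    scored = [
        (composite_score(c.features, weights, pool), c) for c in survivors
    ]
    scored.sort(
        key=lambda sc: (
            -sc[0],
            -sc[1].features.vaf_tumor_dna,
            sc[1].features.best_mut_affinity_nM,
            sc[1].pair.mut_peptide,
        )
    )
    selected = [
        CandidateNeoantigen(
            candidate_id=c.candidate_id,
            pair=c.pair,
            features=c.features,
            composite_score=score,
            rank=i + 1,
        )
        for i, (score, c) in enumerate(scored[:top_n])
    ]
    return selected, attrition


def ranked_table(
    selected: Sequence[CandidateNeoantigen], attrition: Sequence[FilterReport] = ()
) -> pd.DataFrame:
    rows = []
    for c in selected:
        fv = c.features
        rows.append(
            {
                "rank": c.rank,
                "candidate_id": c.candidate_id,
                "mut_peptide": c.pair.mut_peptide,
                "wt_peptide": c.pair.wt_peptide or "",
                "composite_score": c.composite_score,
                "best_mut_affinity_nM": fv.best_mut_affinity_nM,
                "best_wt_affinity_nM": (
                    fv.best_wt_affinity_nM if fv.best_wt_affinity_nM is not None else ""
                ),
                "agretopicity": fv.agretopicity,
                "vaf_tumor_dna": fv.vaf_tumor_dna,
                "vaf_normal_dna": fv.vaf_normal_dna,
                "vaf_tumor_rna": fv.vaf_tumor_rna,
                "expr_tpm": fv.expr_tpm,
                "status": "selected",
            }
        )
    for rep in attrition:
        rows.append(
            {
                "rank": "",
                "candidate_id": rep.candidate_id,
                "status": "filtered: " + "; ".join(rep.reasons),
            }
        )
    return pd.DataFrame(rows)
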