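"""Peptide-MHC binding prediction interface.

The pipeline treats binding prediction as pluggable: any callable
``predictor(peptide, allele) -> BindingPrediction`` works.  Two
implementations ship here:

* :class:`ToyPWMPredictor` — a deterministic position-weight-matrix model
  whose normalized log-score s maps to affinity 50000^(1-s) nM.  It exists so
  the scoring and ranking machinery is fully testable without external
  neural predictors; it makes no claim of biological accuracy.
* :func:`read_binding_tsv` — ingest for external predictor output in the
  common (peptide, allele, affinity nM, %rank) tabular dialect.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AA_ALPHABET, ParseError, ValidationError

MAX_AFFINITY_NM = 50_000.0
CLASS_I_LENGTHS = (8, 9, 10, 11)
CLASS_II_LENGTHS = (15,)


@dataclass(frozen=True)
class BindingPrediction:
    peptide: str
    allele: str
    affinity_nM: float
    percentile_rank: float | None = None
    stability_halflife_h: float | None = None

    def __post_init__(self) -> None:
        if self.affinity_nM <= 0:
            raise ValidationError(f"affinity must be positive, got {self.affinity_nM}")
        if self.percentile_rank is not None and not 0 <= self.percentile_rank <= 100:
            raise ValidationError(
                f"percentile_rank {self.percentile_rank} outside [0,100]"
            )


class ToyPWMPredictor:
    """Deterministic PWM scorer: affinity = 50000^(1 - s), s in [0, 1].

    One PWM per (allele, length); matrices are derived reproducibly from the
    allele label and a seed, so two predictors built with the same arguments
    agree everywhere.  s is the PWM log-score min-max normalized by the
    matrix's own best/worst attainable sums.
    """

    def __init__(
        self,
        alleles: Sequence[str],
        lengths: Sequence[int] = CLASS_I_LENGTHS + CLASS_II_LENGTHS,
        seed: int = 0,
    ) -> None:
        self.lengths = tuple(lengths)
        self.pwms: dict[tuple[str, int], np.ndarray] = {}
        for allele in alleles:
            for L in self.lengths:
                rng = np.random.default_rng(
                    [seed, zlib.crc32(allele.encode()), L]
                )
                self.pwms[(allele, L)] = rng.normal(0.0, 1.0, size=(L, 20))

    @property
    def alleles(self) -> list[str]:
        return sorted({a for a, _ in self.pwms})

    def __call__(self, peptide: str, allele: str) -> BindingPrediction:
        key = (allele, len(peptide))
        if key not in self.pwms:
            if allele not in self.alleles:
                raise ValidationError(
                    f"no PWM for allele {allele!r}; available: {self.alleles}"
                )
            raise ValidationError(
                f"no PWM of length {len(peptide)} for {allele!r}; "
                f"lengths: {sorted(self.lengths)}"
            )
        pwm = self.pwms[key]
        try:
            idx = [AA_ALPHABET.index(aa) for aa in peptide]
        except ValueError:
            bad = sorted(set(peptide) - set(AA_ALPHABET))
            raise ValidationError(f"non-canonical residues {bad} in {peptide!r}")
        score = float(pwm[np.arange(len(peptide)), idx].sum())
        lo = float(pwm.min(axis=1).sum())
        hi = float(pwm.max(axis=1).sum())
        s = (score - lo) / (hi - lo)
        affinity = max(1.0, MAX_AFFINITY_NM ** (1.0 - s))
        return BindingPrediction(peptide=peptide, allele=allele, affinity_nM=affinity)


class TablePredictor:
    """Look up (peptide, allele) affinities from external predictor output."""

    def __init__(self, predictions: Iterable[BindingPrediction]) -> None:
        self.table: dict[tuple[str, str], BindingPrediction] = {
            (p.peptide, p.allele): p for p in predictions
        }

    def __call__(self, peptide: str, allele: str) -> BindingPrediction:
        try:
            return self.table[(peptide, allele)]
        except KeyError:
            raise ValidationError(
                f"no external prediction for ({peptide!r}, {allele!r})"
            ) from None


#: column aliases accepted in external predictor TSVs
_TSV_ALIASES: Mapping[str, tuple[str, ...]] = {
    "peptide": ("peptide", "Peptide"),
    "allele": ("allele", "MHC", "HLA"),
    "affinity_nM": ("affinity_nM", "affinity", "Aff(nM)", "ic50"),
    "percentile_rank": ("percentile_rank", "%Rank", "rank", "%Rank_EL"),
}


def read_binding_tsv(path: str | Path) -> list[BindingPrediction]:
    """Parse external binding-predictor output: columns peptide, allele,
    affinity (nM) and optionally a percentile rank; extra columns ignored."""
    df = pd.read_csv(path, sep="\t")
    cols: dict[str, str] = {}
    for canon, aliases in _TSV_ALIASES.items():
        for a in aliases:
            if a in df.columns:
                cols[canon] = a
                break
    missing = {"peptide", "allele", "affinity_nM"} - set(cols)
    if missing:
        raise ParseError(
            f"{path}: binding TSV missing columns for {sorted(missing)}; "
            f"got {list(df.columns)}"
        )
    out = []
    for _, row in df.iterrows():
        rank = (
            float(row[cols["percentile_rank"]]) if "percentile_rank" in cols else None
        )
        out.append(
            BindingPrediction(
                peptide=str(row[cols["peptide"]]),
                allele=str(row[cols["allele"]]),
                affinity_nM=float(row[cols["affinity_nM"]]),
                percentile_rank=rank,
            )
        )
    return out
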