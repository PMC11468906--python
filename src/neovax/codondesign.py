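"""Joint folding-energy / codon-adaptation codon design.

Given a protein, choose among its synonymous codon sequences the RNA that
minimizes

    objective(s) = MFE(s) - lambda * sum_i log w(codon_i)

where MFE is the minimum folding score of a Nussinov base-pair model
(nested structures, per-pair scores, a minimum hairpin loop) and w is the
per-codon relative adaptiveness of a codon usage table, so the second term
is -lambda * n * log CAI.  The optimizer is an exact dynamic program on the
codon lattice: a Nussinov recursion in which each nucleotide position
carries the set of admissible codon choices and interval endpoints track the
codon chosen at their position, keeping choices consistent across the
recursion.  Structures are scored by an additive pair-score model rather
than nearest-neighbor thermodynamics; that keeps an exhaustive
codon-combination oracle feasible, and the model is pluggable for
re-scoring.  For long ORFs a windowed mode designs overlapping codon
windows, stitches them at codon boundaries, and re-scores the result
globally; it is flagged approximate in its metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from Bio.Seq import Seq

from .io import CodonUsageTable, ValidationError

NEG_INF = float("-inf")
INF = float("inf")

DEFAULT_PAIR_SCORES = {
    "GC": -2.0, "CG": -2.0,
    "AU": -1.0, "UA": -1.0,
    "GU": -0.5, "UG": -0.5,
}

#: exact-design size cap (nt); one 27-mer neoantigen window designs exactly
DEFAULT_EXACT_LIMIT_NT = 81
DEFAULT_WINDOW_CODONS = 13
DEFAULT_WINDOW_STRIDE = 9


@dataclass(frozen=True)
class EnergyModel:
    """Additive base-pair scores over nested structures.

    ``min_hairpin`` is the minimum number of unpaired bases enclosed by any
    pair (>= 3, the steric minimum for a hairpin loop).
    """

    pair_scores: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PAIR_SCORES)
    )
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if any(v >= 0 for v in self.pair_scores.values()):
            raise ValidationError("pair scores must be negative")
        if self.min_hairpin < 3:
            raise ValidationError("min_hairpin must be >= 3")

    def pair(self, a: str, b: str) -> float | None:
        return self.pair_scores.get(a + b)


@dataclass(frozen=True)
class DesignResult:
    rna_codons: str
    mfe_proxy: float
    cai: float
    lam: float
    objective: float
    structure: str
    mode: str  # "exact" | "windowed"


# ---------------------------------------------------------------------------
# CAI

def cai(rna_codons: str, usage: CodonUsageTable) -> float:
    """Geometric mean of relative adaptiveness w over codons; in (0, 1]."""
    seq = rna_codons.upper().replace("T", "U")
    if len(seq) % 3 != 0:
        raise ValidationError(f"length {len(seq)} not divisible by 3")
    if not seq:
        raise ValidationError("empty sequence")
    log_sum = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon not in usage.w:
            raise ValidationError(f"codon {codon!r} absent from usage table")
        log_sum += math.log(usage.w[codon])
    return math.exp(log_sum / (len(seq) // 3))


# ---------------------------------------------------------------------------
# Nussinov folding

def fold_mfe(rna: str, model: EnergyModel | None = None) -> tuple[float, str]:
    """Minimum additive pair score over nested structures, with one optimal
    structure in dot-bracket notation.  O(n^3); empty input scores 0."""
    model = model or EnergyModel()
    seq = rna.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        return 0.0, ""
    mh = model.min_hairpin
    E = [[0.0] * n for _ in range(n)]
    for span in range(mh + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i + 1][j]  # i unpaired
            for k in range(i + mh + 1, j + 1):
                ps = model.pair(seq[i], seq[k])
                if ps is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                outer = E[k + 1][j] if k + 1 <= j else 0.0
                cand = ps + inner + outer
                if cand < best:
                    best = cand
            E[i][j] = best
    structure = ["."] * n

    def traceback(i: int, j: int) -> None:
        while i < j:
            if E[i][j] == E[i + 1][j]:
                i += 1
                continue
            for k in range(i + mh + 1, j + 1):
                ps = model.pair(seq[i], seq[k])
                if ps is None:
                    continue
                inner = E[i + 1][k - 1] if k - 1 >= i + 1 else 0.0
                outer = E[k + 1][j] if k + 1 <= j else 0.0
                if abs(E[i][j] - (ps + inner + outer)) < 1e-9:
                    structure[i], structure[k] = "(", ")"
                    traceback(i + 1, k - 1)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")

    traceback(0, n - 1)
    return E[0][n - 1], "".join(structure)


# ---------------------------------------------------------------------------
# lattice DP: joint MFE + CAI over codon choices

class _LatticeDP:
    """Exact minimization of pair-score + lambda * codon cost over the codon
    lattice.  Values are (objective, q) tuples with q = sum of -log w,
    compared lexicographically so exact objective ties resolve toward higher
    CAI."""

    def __init__(
        self,
        peptide: str,
        usage: CodonUsageTable,
        model: EnergyModel,
        lam: float,
    ) -> None:
        self.model = model
        self.lam = lam
        self.choices: list[list[str]] = []
        self.costs: list[list[float]] = []  # -log w per codon choice
        for aa in peptide:
            codons = usage.codons_for(aa)
            self.choices.append(codons)
            self.costs.append([-math.log(usage.w[c]) for c in codons])
        self.n = 3 * len(peptide)
        self.memo: dict[tuple[int, int, int, int], tuple[float, float]] = {}

    # position helpers ------------------------------------------------------
    def nt(self, p: int, t: int) -> str:
        return self.choices[p // 3][t][p % 3]

    def ccost(self, p: int, t: int) -> tuple[float, float]:
        """Codon cost attributed at the codon's first position."""
        if p % 3 != 0:
            return (0.0, 0.0)
        q = self.costs[p // 3][t]
        return (self.lam * q, q)

    def nch(self, p: int) -> int:
        return len(self.choices[p // 3])

    # DP --------------------------------------------------------------------
    def emin(
        self, i: int, j: int, ci: int | None, cj: int | None
    ) -> tuple[float, float]:
        """Min over free endpoint codon states; empty interval is 0."""
        if i > j:
            return (0.0, 0.0)
        if i // 3 == j // 3:
            if ci is not None and cj is not None and ci != cj:
                return (INF, INF)
            c = ci if ci is not None else cj
            if c is not None:
                return self.E(i, j, c, c)
            return min(self.E(i, j, t, t) for t in range(self.nch(i)))
        a_opts = [ci] if ci is not None else range(self.nch(i))
        b_opts = [cj] if cj is not None else range(self.nch(j))
        return min(self.E(i, j, a, b) for a in a_opts for b in b_opts)

    def E(self, i: int, j: int, a: int, b: int) -> tuple[float, float]:
        key = (i, j, a, b)
        hit = self.memo.get(key)
        if hit is not None:
            return hit
        cod = lambda p: p // 3
        if i == j:
            val = self.ccost(i, a)
            self.memo[key] = val
            return val
        mh = self.model.min_hairpin
        base = self.ccost(i, a)
        # option 1: i unpaired
        ci1 = a if cod(i + 1) == cod(i) else None
        sub = self.emin(i + 1, j, ci1, b)
        best = (base[0] + sub[0], base[1] + sub[1])
        # option 2: i pairs k
        for k in range(i + mh + 1, j + 1):
            if cod(k) == cod(j):
                k_opts: Sequence[int] = (b,)
            elif cod(k) == cod(i):  # unreachable for mh >= 3, kept for safety
                k_opts = (a,)
            else:
                k_opts = range(self.nch(k))
            nt_i = self.nt(i, a)
            for ck in k_opts:
                ps = self.model.pair(nt_i, self.nt(k, ck))
                if ps is None:
                    continue
                kc = self.ccost(k, ck)
                # inner interval [i+1, k-1]
                if i + 1 <= k - 1:
                    in_ci = (
                        a if cod(i + 1) == cod(i)
                        else ck if cod(i + 1) == cod(k)
                        else None
                    )
                    in_cj = (
                        ck if cod(k - 1) == cod(k)
                        else a if cod(k - 1) == cod(i)
                        else None
                    )
                    inner = self.emin(i + 1, k - 1, in_ci, in_cj)
                else:
                    inner = (0.0, 0.0)
                # outer interval [k+1, j]
                if k + 1 <= j:
                    out_ci = ck if cod(k + 1) == cod(k) else None
                    outer = self.emin(k + 1, j, out_ci, b)
                else:
                    outer = (0.0, 0.0)
                cand = (
                    base[0] + ps + kc[0] + inner[0] + outer[0],
                    base[1] + kc[1] + inner[1] + outer[1],
                )
                if cand < best:
                    best = cand
        self.memo[key] = best
        return best

    # traceback -------------------------------------------------------------
    def solve(self) -> tuple[tuple[float, float], list[int]]:
        n = self.n
        assign: list[int | None] = [None] * (n // 3)

        best = self.emin(0, n - 1, None, None)

        def pick_states(i, j, ci, cj) -> tuple[int, int]:
            """Endpoint states achieving emin(i,j,ci,cj), preferring
            lexicographically smaller codons."""
            target = self.emin(i, j, ci, cj)
            if i // 3 == j // 3:
                opts = [ci if ci is not None else cj]
                if opts[0] is None:
                    opts = sorted(
                        range(self.nch(i)), key=lambda t: self.choices[i // 3][t]
                    )
                for t in opts:
                    if self.E(i, j, t, t) == target:
                        return t, t
                raise AssertionError("state reconstruction failed")
            a_opts = [ci] if ci is not None else sorted(
                range(self.nch(i)), key=lambda t: self.choices[i // 3][t]
            )
            b_opts = [cj] if cj is not None else sorted(
                range(self.nch(j)), key=lambda t: self.choices[j // 3][t]
            )
            for a in a_opts:
                for b in b_opts:
                    if self.E(i, j, a, b) == target:
                        return a, b
            raise AssertionError("state reconstruction failed")

        def trace(i: int, j: int, a: int, b: int) -> None:
            cod = lambda p: p // 3
            assign[cod(i)] = a
            assign[cod(j)] = b
            if i == j:
                return
            target = self.E(i, j, a, b)
            mh = self.model.min_hairpin
            base = self.ccost(i, a)
            ci1 = a if cod(i + 1) == cod(i) else None
            sub = self.emin(i + 1, j, ci1, b)
            if (base[0] + sub[0], base[1] + sub[1]) == target:
                a2, b2 = pick_states(i + 1, j, ci1, b)
                trace(i + 1, j, a2, b2)
                return
            nt_i = self.nt(i, a)
            for k in range(i + mh + 1, j + 1):
                if cod(k) == cod(j):
                    k_opts: Sequence[int] = (b,)
                elif cod(k) == cod(i):
                    k_opts = (a,)
                else:
                    k_opts = sorted(
                        range(self.nch(k)), key=lambda t: self.choices[k // 3][t]
                    )
                for ck in k_opts:
                    ps = self.model.pair(nt_i, self.nt(k, ck))
                    if ps is None:
                        continue
                    kc = self.ccost(k, ck)
                    if i + 1 <= k - 1:
                        in_ci = (
                            a if cod(i + 1) == cod(i)
                            else ck if cod(i + 1) == cod(k)
                            else None
                        )
                        in_cj = (
                            ck if cod(k - 1) == cod(k)
                            else a if cod(k - 1) == cod(i)
                            else None
                        )
                        inner = self.emin(i + 1, k - 1, in_ci, in_cj)
                    else:
                        in_ci = in_cj = None
                        inner = (0.0, 0.0)
                    if k + 1 <= j:
                        out_ci = ck if cod(k + 1) == cod(k) else None
                        outer = self.emin(k + 1, j, out_ci, b)
                    else:
                        out_ci = None
                        outer = (0.0, 0.0)
                    cand = (
                        base[0] + ps + kc[0] + inner[0] + outer[0],
                        base[1] + kc[1] + inner[1] + outer[1],
                    )
                    if cand == target:
                        assign[cod(k)] = ck
                        if i + 1 <= k - 1:
                            ia, ib = pick_states(i + 1, k - 1, in_ci, in_cj)
                            trace(i + 1, k - 1, ia, ib)
                        if k + 1 <= j:
                            oa, ob = pick_states(k + 1, j, out_ci, b)
                            trace(k + 1, j, oa, ob)
                        return
            raise AssertionError("traceback failed")  # pragma: no cover

        a0, b0 = pick_states(0, n - 1, None, None)
        trace(0, n - 1, a0, b0)
        # codons untouched by any decision cannot occur (every first position
        # is consumed), but fill deterministically just in case
        full = [
            t if t is not None else 0 for t in assign
        ]
        return best, full


def design(
    peptide: str,
    usage: CodonUsageTable,
    model: EnergyModel | None = None,
    lam: float = 1.0,
    exact_limit_nt: int = DEFAULT_EXACT_LIMIT_NT,
    window_codons: int = DEFAULT_WINDOW_CODONS,
    window_stride: int = DEFAULT_WINDOW_STRIDE,
) -> DesignResult:
    """Design codons for ``peptide`` minimizing MFE - lambda*sum(log w).

    Exact (lattice DP) when the coding sequence is at most
    ``exact_limit_nt`` nt; otherwise overlapping windows of
    ``window_codons`` codons advancing by ``window_stride`` are designed
    exactly, stitched at codon boundaries, and the stitched sequence is
    re-scored globally (mode "windowed", approximate).
    """
    model = model or EnergyModel()
    if not peptide:
        raise ValidationError("peptide must be non-empty")
    if lam < 0:
        raise ValidationError("lambda must be non-negative")
    for aa in peptide:
        usage.codons_for(aa)  # raises for unknown residues

    if 3 * len(peptide) <= exact_limit_nt:
        dp = _LatticeDP(peptide, usage, model, lam)
        (_, _), assign = dp.solve()
        seq = "".join(dp.choices[c][t] for c, t in enumerate(assign))
        mode = "exact"
    else:
        if window_stride < 1 or window_codons < window_stride:
            raise ValidationError("need window_codons >= window_stride >= 1")
        parts: list[str] = []
        start = 0
        while start < len(peptide):
            sub = peptide[start : start + window_codons]
            dp = _LatticeDP(sub, usage, model, lam)
            _, assign = dp.solve()
            codons = [dp.choices[c][t] for c, t in enumerate(assign)]
            keep = len(sub) if start + window_codons >= len(peptide) else window_stride
            parts.extend(codons[:keep])
            start += keep
        seq = "".join(parts)
        mode = "windowed"

    mfe, structure = fold_mfe(seq, model)
    seq_cai = cai(seq, usage)
    q = -len(peptide) * math.log(seq_cai)
    result = DesignResult(
        rna_codons=seq,
        mfe_proxy=mfe,
        cai=seq_cai,
        lam=lam,
        objective=mfe + lam * q,
        structure=structure,
        mode=mode,
    )
    if str(Seq(seq).translate()) != peptide:  # pragma: no cover - defensive
        raise AssertionError("designed sequence does not encode the peptide")
    return result
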