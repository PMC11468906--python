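"""Binding toy model, sub-peptide scanning, composite scoring, and ranking."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neovax.binding import (
    MAX_AFFINITY_NM,
    BindingPrediction,
    TablePredictor,
    ToyPWMPredictor,
    read_binding_tsv,
)
from neovax.io import ValidationError
from neovax.peptides import PeptidePair
from neovax.ranking import (
    FeatureVector,
    PoolContext,
    RankInput,
    ScoreWeights,
    composite_score,
    hard_filter_reasons,
    normalized_features,
    rank_and_select,
    scan_subpeptides,
)
from neovax.simulate import generate_feature_cohort


def _pair(mut="ACDEFGHIKLMNPQRSTVWYACDEFGH", offset=14, wt=None):
    if wt is None:
        wt = mut[: offset - 1] + ("A" if mut[offset - 1] != "A" else "G") + mut[offset:]
    return PeptidePair(mut_peptide=mut, wt_peptide=wt, window_start=1,
                       mutant_offset=offset)


class TestToyPredictor:
    def test_affinity_from_pwm_matches_hand_computation(self):
        pred = ToyPWMPredictor(["H-2-Kb"], seed=1)
        pep = "SIINFEKL"
        pwm = pred.pwms[("H-2-Kb", 8)]
        # explicit per-position arithmetic, independent of the class internals
        score = sum(
            pwm[i, "ACDEFGHIKLMNPQRSTVWY".index(aa)] for i, aa in enumerate(pep)
        )
        lo = sum(min(pwm[i]) for i in range(8))
        hi = sum(max(pwm[i]) for i in range(8))
        s = (score - lo) / (hi - lo)
        expected = max(1.0, 50000 ** (1 - s))
        assert math.isclose(pred(pep, "H-2-Kb").affinity_nM, expected, rel_tol=1e-12)

    def test_extremes_of_the_mapping(self):
        pred = ToyPWMPredictor(["X"], seed=0)
        pwm = pred.pwms[("X", 8)]
        aas = "ACDEFGHIKLMNPQRSTVWY"
        best = "".join(aas[int(np.argmax(pwm[i]))] for i in range(8))
        worst = "".join(aas[int(np.argmin(pwm[i]))] for i in range(8))
        assert pred(best, "X").affinity_nM == pytest.approx(1.0)     # s = 1
        assert pred(worst, "X").affinity_nM == pytest.approx(50000)  # s = 0

    def test_unknown_allele_lists_available(self):
        pred = ToyPWMPredictor(["A", "B"], seed=0)
        with pytest.raises(ValidationError, match="available.*'A', 'B'"):
            pred("SIINFEKL", "C")

    def test_determinism_across_instances(self):
        a = ToyPWMPredictor(["H-2-Kb", "H-2-Db"], seed=3)
        b = ToyPWMPredictor(["H-2-Db", "H-2-Kb"], seed=3)  # order must not matter
        assert a("SIINFEKL", "H-2-Db").affinity_nM == b("SIINFEKL", "H-2-Db").affinity_nM

    def test_invalid_predictions_rejected(self):
        with pytest.raises(ValidationError):
            BindingPrediction("SIINFEKL", "X", affinity_nM=0.0)
        with pytest.raises(ValidationError):
            BindingPrediction("SIINFEKL", "X", affinity_nM=5.0, percentile_rank=120)


class TestScanSubpeptides:
    def test_mutation_spanning_class_i_window_count_is_38(self):
        """27-mer, mutant residue at 14: the number of mutation-spanning
        sub-windows over L in 8..11 is 38, by exhaustive enumeration."""
        pair = _pair()
        seen: list[str] = []

        def predictor(pep, allele):
            seen.append(pep)
            return BindingPrediction(pep, allele, affinity_nM=100.0)

        summary = scan_subpeptides(pair, ["X"], predictor, class_ii_lengths=())
        enumerated = [
            pair.mut_peptide[s : s + L]
            for L in (8, 9, 10, 11)
            for s in range(0, 28 - L)
            if s + 1 <= 14 <= s + L
        ]
        assert len(enumerated) == 38
        assert summary.n_windows == 38
        # every enumerated mutant window was actually scored
        assert set(enumerated) <= set(seen)

    def test_length_8_peptide_single_window(self):
        pair = _pair(mut="ACDEFGHI", offset=4, wt="ACDQFGHI")
        calls = []
        def predictor(pep, allele):
            calls.append((pep, allele))
            return BindingPrediction(pep, allele, affinity_nM=50.0)
        summary = scan_subpeptides(pair, ["X"], predictor, class_ii_lengths=())
        mut_calls = [c for c in calls if c[0] == "ACDEFGHI"]
        assert len(mut_calls) == 1
        assert summary.n_windows == 1

    def test_duplicate_alleles_do_not_change_best(self):
        pred1 = ToyPWMPredictor(["X"], seed=0)
        pwms = dict(pred1.pwms)
        pred2 = ToyPWMPredictor(["X", "Y"], seed=0)
        pred2.pwms.update({("Y", L): pwms[("X", L)] for L in pred1.lengths})
        pair = _pair()
        one = scan_subpeptides(pair, ["X"], pred1)
        two = scan_subpeptides(pair, ["X", "Y"], pred2)
        assert one.best_mut_affinity_nM == two.best_mut_affinity_nM

    def test_brute_force_minimum_oracle(self):
        """DP-free oracle: best affinity equals the explicit minimum over all
        enumerated windows x alleles, for windows of several lengths."""
        rng = np.random.default_rng(42)
        aas = "ACDEFGHIKLMNPQRSTVWY"
        pred = ToyPWMPredictor(["X", "Y"], seed=9)
        for n in (8, 12, 18, 27):
            pep = "".join(rng.choice(list(aas), size=n))
            offset = int(rng.integers(1, n + 1))
            wt = pep[: offset - 1] + ("A" if pep[offset - 1] != "A" else "C") + pep[offset:]
            pair = PeptidePair(pep, wt, 1, offset)
            summary = scan_subpeptides(pair, ["X", "Y"], pred)
            best = math.inf
            for L in (8, 9, 10, 11, 15):
                for s in range(1, n - L + 2):
                    if not s <= offset <= s + L - 1:
                        continue
                    sub = pep[s - 1 : s - 1 + L]
                    for al in ("X", "Y"):
                        best = min(best, pred(sub, al).affinity_nM)
            if best < math.inf:
                assert summary.best_mut_affinity_nM == pytest.approx(best)

    def test_frameshift_pair_has_capped_agretopicity(self):
        fv = FeatureVector(0.3, 0.0, 0.2, 10.0, best_mut_affinity_nM=50.0,
                           best_wt_affinity_nM=None)
        assert fv.agretopicity == fv.agretopicity_cap


class TestCompositeScore:
    WEIGHTS = ScoreWeights()

    def _fvs(self):
        return [
            FeatureVector(0.4, 0.0, 0.35, 50.0, 20.0, 400.0),
            FeatureVector(0.2, 0.01, 0.15, 10.0, 100.0, 150.0),
            FeatureVector(0.1, 0.02, 0.05, 2.0, 450.0, 300.0),
        ]

    def test_three_candidate_hand_table(self):
        """Frozen spreadsheet-style arithmetic for three candidates under
        default weights."""
        fvs = self._fvs()
        pool = PoolContext.from_features(fvs)
        expected = [0.8669373291723436, 0.4052180799490573, 0.20824509781454212]
        for fv, exp in zip(fvs, expected):
            assert composite_score(fv, self.WEIGHTS, pool) == pytest.approx(
                exp, abs=1e-12
            )

    def test_all_normalized_features_one_gives_score_one(self):
        fv = FeatureVector(0.5, 0.0, 0.5, 100.0, 1.0, None,
                           stability_halflife_h=None, immunogenicity_score=1.0)
        other = FeatureVector(0.1, 0.3, 0.1, 1.0, 50000.0, 1.0)
        pool = PoolContext.from_features([fv, other])
        f = normalized_features(fv, pool)
        # every feature hits 1 except stability, which stays neutral (0.5)
        assert all(v == 1.0 for k, v in f.items() if k != "stability")
        assert f["stability"] == 0.5
        w = self.WEIGHTS.normalized()
        assert composite_score(fv, self.WEIGHTS, pool) == pytest.approx(
            1.0 - 0.5 * w["stability"]
        )

    def test_one_hot_expression_weight_reduces_to_tpm_order(self):
        w = ScoreWeights(affinity=0, agretopicity=0, expression=1.0, rna_vaf=0,
                         dna_vaf=0, stability=0, immunogenicity=0,
                         germline_absence=0, min_expr_tpm=0.0,
                         max_mut_affinity_nM=1e9, min_vaf_tumor_dna=0.0)
        fvs = self._fvs()
        inputs = [
            RankInput(f"c{i}", _pair(), fv) for i, fv in enumerate(fvs)
        ]
        selected, _ = rank_and_select(inputs, w, top_n=10)
        tpms = [c.features.expr_tpm for c in selected]
        assert tpms == sorted(tpms, reverse=True)

    def test_degenerate_pool_feature_is_half(self):
        fvs = [FeatureVector(0.3, 0.0, 0.2, 10.0, 50.0, 100.0)] * 3
        pool = PoolContext.from_features(fvs)
        f = normalized_features(fvs[0], pool)
        assert f["expression"] == 0.5 and f["dna_vaf"] == 0.5


class TestRankAndSelect:
    def _inputs(self, n, seed=0):
        cands, _ = generate_feature_cohort(seed, n_background=n, n_planted=0)
        return cands

    def test_thirty_candidates_default_selects_twenty(self):
        inputs = self._inputs(30, seed=2)
        # lift everything over the hard filters
        inputs = [
            RankInput(c.candidate_id, c.pair, dataclasses.replace(
                c.features, expr_tpm=max(c.features.expr_tpm, 2.0),
                best_mut_affinity_nM=min(c.features.best_mut_affinity_nM, 400.0)))
            for c in inputs
        ]
        selected, attrition = rank_and_select(inputs)
        assert len(selected) == 20
        assert [c.rank for c in selected] == list(range(1, 21))
        scores = [c.composite_score for c in selected]
        assert scores == sorted(scores, reverse=True)

    def test_fewer_than_top_n_returns_all(self):
        inputs = self._inputs(5, seed=3)
        selected, attrition = rank_and_select(inputs, top_n=20)
        assert len(selected) + len(attrition) == 5

    def test_tie_break_order(self):
        fv_hi_vaf = FeatureVector(0.40, 0.0, 0.2, 10.0, 100.0, 100.0)
        fv_lo_vaf = FeatureVector(0.30, 0.0, 0.2, 10.0, 100.0, 100.0)
        w = ScoreWeights(affinity=1, agretopicity=0, expression=0, rna_vaf=0,
                         dna_vaf=0, stability=0, immunogenicity=0,
                         germline_absence=0)
        a = RankInput("a", _pair(mut="B" * 13 + "Y" + "A" * 13), fv_lo_vaf)
        b = RankInput("b", _pair(mut="A" * 13 + "Y" + "A" * 13), fv_hi_vaf)
        # identical affinity-only scores; higher tumor-DNA VAF must win
        selected, _ = rank_and_select([a, b], w, top_n=2)
        assert [c.candidate_id for c in selected] == ["b", "a"]
        # equal VAF too: lexicographic mutant peptide decides
        c1 = RankInput("c", _pair(mut="B" * 13 + "Y" + "A" * 13), fv_hi_vaf)
        selected, _ = rank_and_select([c1, b], w, top_n=2)
        assert [c.candidate_id for c in selected] == ["b", "c"]

    def test_zero_survivors_reports_attrition(self):
        fv = FeatureVector(0.01, 0.5, 0.0, 0.1, 40000.0, 100.0)
        selected, attrition = rank_and_select([RankInput("x", _pair(), fv)])
        assert selected == []
        (rep,) = attrition
        assert len(rep.reasons) == 4  # violates every default filter

    def test_filter_soundness_exhaustive(self):
        """Every exclusion cites a violated threshold; every survivor
        violates none."""
        w = ScoreWeights()
        cands, _ = generate_feature_cohort(17, n_background=60, n_planted=5)
        selected, attrition = rank_and_select(cands, w, top_n=1000)
        excluded = {r.candidate_id: r for r in attrition}
        for c in cands:
            reasons = hard_filter_reasons(c.features, w)
            if c.candidate_id in excluded:
                assert reasons and excluded[c.candidate_id].reasons == reasons
            else:
                assert reasons == ()

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(min_value=0, max_value=2**31 - 1),
           boost=st.floats(min_value=0.01, max_value=0.5))
    def test_monotonicity_in_dna_vaf(self, seed, boost):
        """Raising a positively weighted feature of one candidate never
        lowers its rank."""
        cands, _ = generate_feature_cohort(seed, n_background=15, n_planted=0)
        selected, _ = rank_and_select(cands, top_n=100)
        if not selected:
            return
        target = selected[-1]
        improved = dataclasses.replace(
            target.features,
            vaf_tumor_dna=min(1.0, target.features.vaf_tumor_dna + boost),
        )
        new_inputs = [
            RankInput(c.candidate_id, c.pair,
                      improved if c.candidate_id == target.candidate_id else c.features)
            for c in cands
        ]
        new_selected, _ = rank_and_select(new_inputs, top_n=100)
        new_rank = {c.candidate_id: c.rank for c in new_selected}
        assert new_rank[target.candidate_id] <= target.rank

    def test_tpm_affine_rescaling_leaves_ranks_unchanged(self):
        cands, _ = generate_feature_cohort(23, n_background=25, n_planted=5)
        selected, _ = rank_and_select(cands, top_n=100)
        rescaled = [
            RankInput(c.candidate_id, c.pair,
                      dataclasses.replace(c.features, expr_tpm=3.0 * c.features.expr_tpm + 7.0))
            for c in cands
        ]
        # keep the expression hard filter from re-admitting candidates
        w = ScoreWeights(min_expr_tpm=3.0 * ScoreWeights().min_expr_tpm + 7.0)
        base_w = ScoreWeights()
        base = rank_and_select(cands, base_w, top_n=100)[0]
        new = rank_and_select(rescaled, w, top_n=100)[0]
        assert [c.candidate_id for c in base] == [c.candidate_id for c in new]
        for a, b in zip(base, new):
            assert a.composite_score == pytest.approx(b.composite_score, abs=1e-12)


class TestExternalBindingTsv:
    def test_netmhcpan_style_ingest(self, tmp_path):
        p = tmp_path / "b.tsv"
        p.write_text(
            "Peptide\tMHC\taffinity\t%Rank\textra\n"
            "SIINFEKL\tH-2-Kb\t12.5\t0.3\tfoo\n"
            "SIINFEKV\tH-2-Kb\t250.0\t2.1\tbar\n"
        )
        preds = read_binding_tsv(p)
        assert len(preds) == 2
        assert preds[0].affinity_nM == 12.5 and preds[0].percentile_rank == 0.3
        table = TablePredictor(preds)
        assert table("SIINFEKV", "H-2-Kb").affinity_nM == 250.0
        with pytest.raises(ValidationError, match="no external prediction"):
            table("AAAAAAAA", "H-2-Kb")
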