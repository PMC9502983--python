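from fractions import Fraction
from math import comb

import numpy as np
import pytest

from ecdyn.motifs import (
    PWM,
    enrich_by_category,
    hypergeom_upper_tail,
    match_ecre_consensus,
    scan_pwm,
)

COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(COMP)[::-1]


def pwm_for(word, motif_id="m", pseudocount=0.0):
    mat = np.zeros((len(word), 4))
    for i, b in enumerate(word):
        mat[i, "ACGT".index(b)] = 1.0
    return PWM(motif_id, mat, pseudocount=pseudocount)


class TestScanPwm:
    def test_perfect_match_score_is_two_bits_per_position(self):
        pwm = pwm_for("ACGT")
        hits = scan_pwm("ACGT", pwm, score_min=7.9)
        fwd = [h for h in hits if h.strand == "+"]
        assert fwd[0].score == pytest.approx(8.0)  # 4 * log2(4)

    def test_mismatch_with_zero_pseudocount_scores_minus_infinity(self):
        pwm = pwm_for("AAAA")
        hits = scan_pwm("AAAT", pwm, score_min=-1e9)
        fwd = [h for h in hits if h.strand == "+" and h.offset == 0]
        assert fwd == []  # -inf never reaches any threshold

    def test_n_bases_contribute_zero_bits(self):
        pwm = pwm_for("ACGT")
        (hit,) = [h for h in scan_pwm("ANGT", pwm, score_min=5.9)
                  if h.strand == "+"]
        assert hit.score == pytest.approx(6.0)

    def test_reverse_strand_hit_reported_in_forward_coordinates(self):
        pwm = pwm_for("ACCGT")
        seq = "TTTT" + revcomp("ACCGT") + "GG"
        hits = [h for h in scan_pwm(seq, pwm) if h.strand == "-"]
        assert [h.offset for h in hits] == [4]

    def test_matches_exhaustive_scoring_oracle(self, rng):
        for _ in range(5):
            L = int(rng.integers(4, 8))
            mat = rng.dirichlet(np.ones(4), size=L)
            pwm = PWM("r", mat, pseudocount=0.01)
            seq = "".join(rng.choice(list("ACGT"), size=60))
            threshold = 0.5 * pwm.max_score
            lo = pwm.log_odds

            def score_word(word):
                total = 0.0
                for l, b in enumerate(word):
                    total += lo[l, "ACGTN".index(b)]
                return total

            expected = set()
            for off in range(60 - L + 1):
                word = seq[off:off + L]
                if score_word(word) >= threshold:
                    expected.add((off, "+"))
                if score_word(revcomp(word)) >= threshold:
                    expected.add((off, "-"))
            got = {(h.offset, h.strand) for h in scan_pwm(seq, pwm, threshold)}
            assert got == expected

    def test_reverse_complement_mirror_symmetry(self, rng):
        mat = rng.dirichlet(np.ones(4), size=6)
        pwm = PWM("r", mat, pseudocount=0.01)
        seq = "".join(rng.choice(list("ACGT"), size=80))
        threshold = 0.3 * pwm.max_score
        fwd_hits = scan_pwm(seq, pwm, threshold)
        rc_hits = scan_pwm(revcomp(seq), pwm, threshold)
        flip = {"+": "-", "-": "+"}
        mirrored = {
            (len(seq) - len(pwm) - h.offset, flip[h.strand], round(h.score, 9))
            for h in rc_hits
        }
        assert {(h.offset, h.strand, round(h.score, 9)) for h in fwd_hits} == mirrored

    def test_unreachable_threshold_gives_empty_list(self):
        pwm = pwm_for("ACGT")
        assert scan_pwm("ACGTACGT", pwm, score_min=100.0) == []


class TestConsensusMatch:
    def test_degenerate_code_matches(self):
        hits = match_ecre_consensus("TTAGGTCATT", "RGGTCA")
        assert [(h.offset, h.strand) for h in hits if h.strand == "+"] == [(2, "+")]

    def test_exceeding_mismatch_budget_gives_no_hit(self):
        assert all(
            h.strand == "-" or h.offset != 0
            for h in match_ecre_consensus("TGGTCA", "RGGTCA", max_mismatch=0)
        ) and not [h for h in match_ecre_consensus("TGGTCA", "RGGTCA") if h.strand == "+"]

    def test_palindrome_has_strand_symmetric_hit_counts(self, rng):
        consensus = "GGTACC"  # its own reverse complement
        seq = "".join(rng.choice(list("ACGT"), size=300))
        hits = match_ecre_consensus(seq, consensus, max_mismatch=1)
        assert len([h for h in hits if h.strand == "+"]) == len(
            [h for h in hits if h.strand == "-"]
        )

    def test_invalid_iupac_code_raises(self):
        with pytest.raises(ValueError):
            match_ecre_consensus("ACGT", "AXGT")


def exact_upper_tail(k, N, K, n):
    num = sum(comb(K, i) * comb(N - K, n - i)
              for i in range(k, min(n, K) + 1))
    return Fraction(num, comb(N, n))


class TestHypergeometric:
    def test_worked_example(self):
        # sum_{i=6..8} C(8,i) C(12,10-i) / C(20,10) = 15686/184756
        assert hypergeom_upper_tail(6, 20, 8, 10) == pytest.approx(
            15686 / 184756, rel=1e-12
        )

    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(0, 20, 8, 10) == 1.0

    def test_matches_exact_enumeration_small_sweep(self):
        for N in range(1, 16):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        exact = float(exact_upper_tail(k, N, K, n))
                        assert hypergeom_upper_tail(k, N, K, n) == pytest.approx(
                            exact, rel=1e-10, abs=1e-14
                        )


class TestEnrichment:
    def _population(self, rng, n_fg=30, n_bg=70, fg_rate=0.8, bg_rate=0.1):
        word = "ACGTACGTAC"
        seqs, cats = {}, {}
        for i in range(n_fg + n_bg):
            sid = f"s{i}"
            seq = "".join(rng.choice(list("ACGT"), size=60))
            is_fg = i < n_fg
            rate = fg_rate if is_fg else bg_rate
            if rng.random() < rate:
                seq = seq[:20] + word + seq[30:]
            seqs[sid] = seq
            cats[sid] = "increasing" if is_fg else "unclassified"
        return seqs, cats, pwm_for(word, "planted", pseudocount=0.01)

    def test_planted_motif_ranks_first(self, rng):
        seqs, cats, planted = self._population(rng)
        fillers = [pwm_for("GGGGCCCCAA", "filler1", 0.01),
                   pwm_for("TTTTAAACCG", "filler2", 0.01)]
        results = enrich_by_category(seqs, cats, [planted] + fillers, "increasing")
        assert results[0].motif_id == "planted"
        assert results[0].p < 1e-6

    def test_counts_and_fold_consistency(self, rng):
        seqs, cats, planted = self._population(rng)
        (res,) = enrich_by_category(seqs, cats, [planted], "increasing")
        assert 0 <= res.k <= min(res.n, res.K)
        assert res.fold == pytest.approx((res.k / res.n) / (res.K / res.N))

    def test_bh_adjustment_preserves_p_order(self, rng):
        seqs, cats, planted = self._population(rng)
        motifs = [planted, pwm_for("GGGGCCCCAA", "f1", 0.01),
                  pwm_for("TTTTAAACCG", "f2", 0.01),
                  pwm_for("CACACACACA", "f3", 0.01)]
        results = enrich_by_category(seqs, cats, motifs, "increasing")
        ps = [r.p for r in results]
        qs = [r.q for r in results]
        assert ps == sorted(ps)
        assert qs == sorted(qs)
        assert all(q >= p for p, q in zip(ps, qs))

    def test_empty_motif_list_raises(self):
        with pytest.raises(ValueError):
            enrich_by_category({"a": "ACGT" * 10}, {"a": "increasing"}, [],
                               "increasing")
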