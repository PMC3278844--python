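"""The four base distances, checked against independent oracles.

Alignment scores are compared with exhaustive recursion, edit distance with
a naive recursive definition, and DNFP with the direct Pearson formula.
"""

import math
from functools import lru_cache
from itertools import product

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ptigsid import (
    GLOBAL_DEFAULTS,
    LOCAL_DEFAULTS,
    PairwiseAlignment,
    dnfp_distance,
    edit_distance,
    global_align,
    k2p_distance,
    kmer_profile,
    local_align,
    p_distance,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=8)


# ---------------------------------------------------------------- oracles
@lru_cache(maxsize=None)
def naive_edit(a: str, b: str) -> int:
    if not a:
        return len(b)
    if not b:
        return len(a)
    return min(
        naive_edit(a[1:], b[1:]) + (a[0] != b[0]),
        1 + naive_edit(a[1:], b),
        1 + naive_edit(a, b[1:]),
    )


def brute_global(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = -math.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


def brute_local_affine(a: str, b: str, match=1, mismatch=-3, open_=-5, ext=-2):
    """Best local score: max over substring pairs of an exhaustive
    affine-gap global recursion (0 when nothing scores positive)."""

    def sub_score(x: str, y: str) -> float:
        @lru_cache(maxsize=None)
        def rec(i, j, prev):
            if i == len(x) and j == len(y):
                return 0
            best = -math.inf
            if i < len(x) and j < len(y):
                s = match if x[i] == y[j] else mismatch
                best = max(best, s + rec(i + 1, j + 1, "M"))
            if i < len(x):
                g = ext if prev == "A" else open_
                best = max(best, g + rec(i + 1, j, "A"))
            if j < len(y):
                g = ext if prev == "B" else open_
                best = max(best, g + rec(i, j + 1, "B"))
            return best

        return rec(0, 0, "M")

    best = 0.0
    for i1 in range(len(a)):
        for i2 in range(i1 + 1, len(a) + 1):
            for j1 in range(len(b)):
                for j2 in range(j1 + 1, len(b) + 1):
                    best = max(best, sub_score(a[i1:i2], b[j1:j2]))
    return best


def _aln(a: str, b: str) -> PairwiseAlignment:
    return PairwiseAlignment(aligned_a=a, aligned_b=b, score=0.0)


# ----------------------------------------------------------- k-mer / DNFP
class TestKmerProfile:
    def test_direct_enumeration(self):
        p = kmer_profile("ACGT", 2)
        freqs = {k: f for k, f in zip(_kmers(2), p.frequencies) if f > 0}
        assert p.total_windows == 3
        assert freqs == {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}

    def test_homopolymer(self):
        p = kmer_profile("AAAA", 2)
        assert p.counts[0] == 3 and p.total_windows == 3
        assert p.frequencies[0] == 1.0

    def test_ambiguous_windows_skipped(self):
        p = kmer_profile("ACGTN", 2)
        assert p.total_windows == 3  # AC, CG, GT counted; TN skipped

    def test_ambiguity_mid_sequence_skips_overlapping_windows(self):
        p = kmer_profile("ACNGT", 2)  # AC and GT count; CN, NG skipped
        assert p.total_windows == 2

    def test_window_count_invariant(self):
        for seq in ("ACGTACGT", "AANNTT", "ACGT"):
            for k in (1, 2, 3):
                p = kmer_profile(seq, k)
                assert p.counts.sum() == p.total_windows <= len(seq) - k + 1

    def test_k_validation(self):
        with pytest.raises(ValueError, match="shorter"):
            kmer_profile("AC", 3)
        with pytest.raises(ValueError, match="refused|large"):
            kmer_profile("A" * 20, 9)


class TestDnfp:
    def test_identical_sequences_distance_zero(self):
        p = kmer_profile("ACGTTGCA", 2)
        assert dnfp_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_direct_pearson_value(self):
        d = dnfp_distance(kmer_profile("AAAA", 2), kmer_profile("CCCC", 2))
        assert d == pytest.approx(16 / 15, abs=1e-12)

    def test_scaling_invariance(self):
        pa = kmer_profile("ACGTACGTTT", 2)
        pb = kmer_profile("ACGGTACGTA", 2)
        scaled = type(pa)(k=2, counts=pa.counts * 7, total_windows=pa.total_windows * 7)
        assert dnfp_distance(pa, pb) == pytest.approx(dnfp_distance(scaled, pb), abs=1e-12)

    @given(dna, dna)
    def test_symmetry(self, a, b):
        if len(a) < 2 or len(b) < 2:
            return
        pa, pb = kmer_profile(a, 2), kmer_profile(b, 2)
        assert dnfp_distance(pa, pb) == pytest.approx(dnfp_distance(pb, pa), abs=1e-12)

    def test_mismatched_k_rejected(self):
        with pytest.raises(ValueError, match="mismatched k"):
            dnfp_distance(kmer_profile("ACGT", 2), kmer_profile("ACGT", 3))

    def test_zero_variance_profile_defined_as_one(self):
        flat = kmer_profile("ACGT", 1)  # every base once: zero variance
        with pytest.warns(UserWarning, match="zero-variance"):
            assert dnfp_distance(flat, kmer_profile("AACGT", 1)) == 1.0


# ------------------------------------------------------------- alignments
class TestGlobalAlign:
    def test_identity(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4 and aln.aligned_a == aln.aligned_b == "ACGT"

    def test_single_gap_forced_by_scoring(self):
        aln = global_align("ACGT", "AGT")
        assert aln.score == 1
        assert aln.aligned_a == "ACGT" and aln.aligned_b in ("A-GT", "AG-T")

    def test_recovers_inputs_and_no_gap_gap_columns(self):
        aln = global_align("ACGGTT", "AGT")
        assert aln.aligned_a.replace("-", "") == "ACGGTT"
        assert aln.aligned_b.replace("-", "") == "AGT"
        assert all(c != ("-", "-") for c in aln.columns())

    @given(dna, dna)
    def test_score_matches_exhaustive_enumeration(self, a, b):
        assert global_align(a, b).score == brute_global(a, b)


class TestLocalAlign:
    def test_self_hit_full_identity_and_spans(self):
        s = "ACGTT" * 12 + "A"  # 61 nt
        hit = local_align(s, s)
        assert hit.identity_pct == 100.00
        assert (hit.query_start, hit.query_end) == (1, 61)
        assert (hit.target_start, hit.target_end) == (1, 61)

    def test_no_positive_region_is_no_hit(self):
        assert local_align("AAAA", "CCCC") is None

    @given(st.text(alphabet="ACGT", min_size=1, max_size=7),
           st.text(alphabet="ACGT", min_size=1, max_size=7))
    def test_score_matches_brute_force(self, a, b):
        oracle = brute_local_affine(a, b)
        hit = local_align(a, b)
        assert (0.0 if hit is None else hit.score) == oracle


# ---------------------------------------------------------------- P / K2P
class TestPDistance:
    def test_identical(self):
        assert p_distance(_aln("ACGT", "ACGT")) == 0.0

    def test_one_difference_in_four(self):
        assert p_distance(_aln("AAAA", "AAAT")) == 0.25

    def test_gap_columns_excluded(self):
        assert p_distance(_aln("AC-GT", "ACCGT")) == 0.0

    def test_ambiguity_columns_excluded(self):
        assert p_distance(_aln("ACNT", "ACGT")) == 0.0

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(ValueError, match="comparable"):
            p_distance(_aln("A-", "-A"))


class TestK2P:
    def test_self_comparison_zero(self):
        seq = "ACGTTGCAACGT"
        assert k2p_distance(global_align(seq, seq)) == pytest.approx(0.0, abs=1e-9)

    def test_one_transition_in_hundred(self):
        a = "A" * 100
        b = "G" + "A" * 99  # A->G is a transition
        expected = -0.5 * math.log(1 - 2 * 0.01)  # independent formula
        assert k2p_distance(_aln(a, b)) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.010101, abs=1e-6)

    def test_saturation_returns_inf_with_warning(self):
        with pytest.warns(UserWarning, match="saturation"):
            assert k2p_distance(_aln("AAAA", "GGGG")) == math.inf

    @given(st.integers(1, 3), st.integers(0, 2))
    def test_k2p_at_least_p(self, ts, tv):
        n = 200
        a = "A" * n
        b = "G" * ts + "C" * tv + "A" * (n - ts - tv)
        aln = _aln(a, b)
        assert k2p_distance(aln) >= p_distance(aln)

    def test_k2p_approaches_p_at_low_divergence(self):
        a = "A" * 300
        b = "G" + "C" + "A" * 298  # P+Q < 0.02
        aln = _aln(a, b)
        assert k2p_distance(aln) == pytest.approx(p_distance(aln), rel=0.05)


# ----------------------------------------------------------- edit distance
class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("ACGT", "ACGT", 0), ("ACGT", "AGT", 1), ("", "ACG", 3), ("", "", 0)],
    )
    def test_forced_minimal_edits(self, a, b, expected):
        assert edit_distance(a, b) == expected

    def test_matches_naive_recursion_exhaustively(self):
        strings = [
            "".join(p) for n in range(7) for p in product("AC", repeat=n)
        ]
        for a in strings:
            for b in strings:
                assert edit_distance(a, b) == naive_edit(a, b)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            a, b, c = (
                "".join(rng.choice(list("ACGT"), size=rng.integers(0, 15)))
                for _ in range(3)
            )
            dab, dba = edit_distance(a, b), edit_distance(b, a)
            assert dab == dba
            assert edit_distance(a, a) == 0
            assert edit_distance(a, c) <= dab + edit_distance(b, c)
            assert abs(len(a) - len(b)) <= dab <= max(len(a), len(b), 0)


def _kmers(k):
    return ["".join(p) for p in product("ACGT", repeat=k)]
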