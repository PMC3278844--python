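"""The four base sequence distances for indel-rich spacer barcodes.

* ``D`` — DNFP: alignment-free k-mer frequency-profile distance, 1 minus the
  Pearson correlation of the two k-mer frequency vectors (default k=2,
  di-nucleotide frequency profile).
* ``E`` — unit-cost edit (Levenshtein) distance; uses every nucleotide of
  both sequences, indels included.
* ``P`` — proportion of differing sites among comparable (non-gap,
  unambiguous) columns of a global alignment, or its Kimura two-parameter
  correction (K2P, the default metric for method P).
* ``B`` — local-alignment similarity search; the distance is the negated
  Smith-Waterman raw score, so the nearest neighbor is the best local hit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import product

import edlib
import numpy as np

from .align import (
    GLOBAL_DEFAULTS,
    LOCAL_DEFAULTS,
    LocalHit,
    PairwiseAlignment,
    ScoringParams,
    global_align,
    local_align,
)

MAX_K = 8

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


class Method(str, Enum):
    """Base distance methods; the building blocks of cascade chains."""

    B = "B"  # local alignment (BLAST-style)
    P = "P"  # P / K2P distance on a global alignment
    E = "E"  # edit distance
    D = "D"  # k-mer frequency profile (DNFP at k=2)


@dataclass
class KmerProfile:
    """k-mer count vector of a sequence over {A,C,G,T}^k (lexicographic)."""

    k: int
    counts: np.ndarray
    total_windows: int

    @property
    def frequencies(self) -> np.ndarray:
        if self.total_windows == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total_windows


@dataclass
class DistanceParams:
    """Tunable knobs shared by the distance methods and cascades."""

    k: int = 2
    p_metric: str = "k2p"  # metric reported by method P: "p" or "k2p"
    global_scoring: ScoringParams = field(default_factory=lambda: GLOBAL_DEFAULTS)
    local_scoring: ScoringParams = field(default_factory=lambda: LOCAL_DEFAULTS)
    tie_eps: float = 1e-9


@dataclass
class DistanceResult:
    """A query-target distance under one method (smaller = more similar)."""

    query_id: str
    target_id: str
    method: Method
    distance: float
    aux: LocalHit | None = None


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_profile(seq: str, k: int) -> KmerProfile:
    """Count sliding k-mer windows; windows containing any non-ACGT
    character are skipped (not counted in ``total_windows``)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > MAX_K:
        raise ValueError(f"k={k} refused: profile size 4^k grows too large (max {MAX_K})")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} shorter than k={k}")
    size = 4**k
    counts = np.zeros(size, dtype=np.int64)
    # rolling window index; reset on ambiguous characters so any window
    # containing one is skipped
    idx = 0
    valid = 0
    for ch in seq:
        b = _BASE_INDEX.get(ch)
        if b is None:
            valid = 0
            idx = 0
            continue
        idx = (idx * 4 + b) % size
        valid += 1
        if valid >= k:
            counts[idx] += 1
    total = int(counts.sum())
    return KmerProfile(k=k, counts=counts, total_windows=total)


def dnfp_distance(pa: KmerProfile, pb: KmerProfile) -> float:
    """1 minus the Pearson correlation of the two frequency vectors.

    0 for proportional profiles, up to 2 for perfectly anti-correlated ones.
    A zero-variance profile (all 4^k frequencies equal) has undefined
    correlation; it is defined here as r=0 (distance 1) with a warning.
    """
    if pa.k != pb.k:
        raise ValueError(f"mismatched k: {pa.k} != {pb.k}")
    if pa.total_windows == 0 or pb.total_windows == 0:
        raise ValueError("profile with no counted windows")
    fa, fb = pa.frequencies, pb.frequencies
    sa, sb = fa.std(), fb.std()
    if sa == 0 or sb == 0:
        warnings.warn("zero-variance k-mer profile; distance defined as 1.0")
        return 1.0
    r = float(np.dot(fa - fa.mean(), fb - fb.mean()) / (len(fa) * sa * sb))
    return 1.0 - r


def _comparable_columns(aln: PairwiseAlignment):
    for x, y in aln.columns():
        if x in _BASE_INDEX and y in _BASE_INDEX:
            yield x, y


def p_distance(aln: PairwiseAlignment) -> float:
    """Proportion of differing sites among comparable aligned columns.

    Columns containing a gap or an ambiguity code in either sequence are
    excluded from both numerator and denominator.
    """
    n = diff = 0
    for x, y in _comparable_columns(aln):
        n += 1
        diff += x != y
    if n == 0:
        raise ValueError("no comparable sites")
    return diff / n


def k2p_distance(aln: PairwiseAlignment) -> float:
    """Kimura two-parameter distance over the comparable aligned columns.

    With transition proportion P and transversion proportion Q:
    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).  Saturated alignments
    (either log argument non-positive) return +inf with a warning.
    """
    n = ts = tv = 0
    for x, y in _comparable_columns(aln):
        n += 1
        if x != y:
            if (x, y) in _TRANSITIONS:
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    a1, a2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        warnings.warn("K2P saturation: distance undefined, returning +inf")
        return math.inf
    return max(0.0, -0.5 * math.log(a1) - 0.25 * math.log(a2))


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (substitutions, insertions, deletions)."""
    if not a or not b:
        return max(len(a), len(b))
    return int(edlib.align(a, b, task="distance")["editDistance"])


def pairwise_distance(
    query_seq: str,
    target_seq: str,
    method: Method,
    params: DistanceParams | None = None,
    *,
    query_id: str = "query",
    target_id: str = "target",
    query_profile: KmerProfile | None = None,
    target_profile: KmerProfile | None = None,
) -> DistanceResult | None:
    """Distance between two sequences under one base method.

    Returns ``None`` for method B when no local region scores above zero
    (no hit).  Precomputed k-mer profiles may be passed for method D.
    """
    params = params or DistanceParams()
    if method is Method.D:
        pa = query_profile or kmer_profile(query_seq, params.k)
        pb = target_profile or kmer_profile(target_seq, params.k)
        d = dnfp_distance(pa, pb)
        return DistanceResult(query_id, target_id, method, d)
    if method is Method.E:
        return DistanceResult(
            query_id, target_id, method, float(edit_distance(query_seq, target_seq))
        )
    if method is Method.P:
        aln = global_align(query_seq, target_seq, params.global_scoring)
        d = k2p_distance(aln) if params.p_metric == "k2p" else p_distance(aln)
        return DistanceResult(query_id, target_id, method, d)
    if method is Method.B:
        hit = local_align(query_seq, target_seq, params.local_scoring)
        if hit is None:
            return None
        return DistanceResult(query_id, target_id, method, -hit.score, aux=hit)
    raise ValueError(f"unknown method {method!r}")


def all_kmers(k: int) -> list[str]:
    """Lexicographic k-mers over {A,C,G,T}, the coordinate order of profiles."""
    return ["".join(p) for p in product("ACGT", repeat=k)]
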