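"""Pairwise global and local alignment.

Thin, deterministic wrappers around :class:`Bio.Align.PairwiseAligner`.
Global alignment uses simple barcoding defaults (match +1, mismatch -1,
gap -2, linear); local alignment uses blastn-like scoring (match +1,
mismatch -3, gap open -5, gap extend -2).  Among co-optimal alignments the
aligner's first-listed traceback is taken, so outputs are bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align


@dataclass(frozen=True)
class ScoringParams:
    """Alignment scoring. ``gap_open``/``gap_extend`` are per-gap-opening and
    per-extension costs (negative); with ``gap_open == gap_extend`` the gap
    penalty is linear."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -2.0


GLOBAL_DEFAULTS = ScoringParams(match=1, mismatch=-1, gap_open=-2, gap_extend=-2)
LOCAL_DEFAULTS = ScoringParams(match=1, mismatch=-3, gap_open=-5, gap_extend=-2)


@dataclass
class PairwiseAlignment:
    """A pairwise alignment as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float
    id_a: str = "a"
    id_b: str = "b"

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


@dataclass
class LocalHit:
    """Best local alignment of a query against a target.

    Coordinates are 1-based inclusive (``query_start``..``query_end``), the
    convention of tabular BLAST-style reports; ``identity_pct`` is percent
    identity over the aligned columns, to 2 decimals.
    """

    score: float
    identity_pct: float
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    aligned_query: str = ""
    aligned_target: str = ""


def _aligner(params: ScoringParams, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = params.gap_open
    al.extend_gap_score = params.gap_extend
    return al


def global_align(
    a: str, b: str, params: ScoringParams = GLOBAL_DEFAULTS,
    id_a: str = "a", id_b: str = "b",
) -> PairwiseAlignment:
    """Optimal Needleman-Wunsch global alignment of two sequences."""
    if not a or not b:
        raise ValueError("global_align requires two non-empty sequences")
    aln = _aligner(params, "global").align(a, b)[0]
    return PairwiseAlignment(
        aligned_a=str(aln[0]), aligned_b=str(aln[1]),
        score=float(aln.score), id_a=id_a, id_b=id_b,
    )


def local_align(
    query: str, target: str, params: ScoringParams = LOCAL_DEFAULTS
) -> LocalHit | None:
    """Optimal Smith-Waterman local alignment; ``None`` when no region scores
    above zero (no hit)."""
    if not query or not target:
        raise ValueError("local_align requires two non-empty sequences")
    aligner = _aligner(params, "local")
    if aligner.score(query, target) <= 0:
        return None
    aln = aligner.align(query, target)[0]
    qa, ta = str(aln[0]), str(aln[1])
    ncols = len(qa)
    ident = sum(1 for x, y in zip(qa, ta) if x == y and x != "-")
    qblocks, tblocks = aln.aligned
    return LocalHit(
        score=float(aln.score),
        identity_pct=round(100.0 * ident / ncols, 2),
        query_start=int(qblocks[0][0]) + 1,
        query_end=int(qblocks[-1][1]),
        target_start=int(tblocks[0][0]) + 1,
        target_end=int(tblocks[-1][1]),
        aligned_query=qa,
        aligned_target=ta,
    )
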