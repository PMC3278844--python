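"""Profile-HMM locus annotation.

A small position-specific profile model (match / insert / delete states,
Laplace pseudocounts, local-mode Viterbi scanning in log-odds bits against
a uniform background) is built from ungapped-or-gapped alignments of the
conserved 5' psbA and 3' trnH flank fragments.  Scanning an unannotated
locus sequence with both models delimits the indel-rich core spacer
between the two flank matches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .records import SequenceRecord, reverse_complement

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3}
_LOG2_BG = -2.0  # log2(0.25), uniform background


@dataclass
class ProfileHMM:
    """Position-specific profile with M match states.

    ``match_emissions``: (M, 4) probabilities over A,C,G,T per match state.
    ``transitions``: dict of per-position probability arrays; source states
    are match (mm/mi/md), insert (im/ii) and delete (dm/dd); index k is the
    source position with k=0 the begin state.
    """

    length: int
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: dict[str, np.ndarray]
    null_model: np.ndarray

    def __post_init__(self) -> None:
        assert self.match_emissions.shape == (self.length, 4)


@dataclass
class ScanHit:
    start: int  # 0-based half-open span of the match in the scanned sequence
    end: int
    score: float  # log-odds, bits


class AnnotationStatus(str, Enum):
    FULL = "full"
    PARTIAL = "partial"
    NONE = "none"


class Strand(str, Enum):
    FORWARD = "forward"
    REVERSE = "reverse"


@dataclass
class LocusAnnotation:
    """5'/core/3' segmentation of one locus sequence.

    Intervals are 0-based half-open on the input's forward strand; for
    reverse-strand annotations the reading-strand order of the segments is
    therefore reversed along the forward coordinates.
    """

    sequence_id: str
    strand: Strand
    status: AnnotationStatus
    five_prime: tuple[int, int] | None = None
    core: tuple[int, int] | None = None
    three_prime: tuple[int, int] | None = None
    scores: dict[str, float] = field(default_factory=dict)

    def core_sequence(self, seq: str) -> str | None:
        """The core spacer in reading-strand orientation."""
        if self.core is None:
            return None
        s, e = self.core
        frag = seq[s:e]
        return frag if self.strand is Strand.FORWARD else reverse_complement(frag)


def build_profile_hmm(aligned_fragments: list[str]) -> ProfileHMM:
    """Estimate a profile from equal-length aligned flank fragments.

    Columns with more than 50% gaps become insert columns, the rest match
    columns; emissions are column base frequencies with +1 Laplace
    pseudocounts; transitions are estimated from the gap structure, also
    with +1 pseudocounts.
    """
    seqs = [s.upper().replace("U", "T") for s in aligned_fragments]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned fragments")
    if len(seqs) < 10:
        warnings.warn(
            f"only {len(seqs)} fragments; >10 are recommended for a stable model"
        )
    width = len(seqs[0])
    if any(len(s) != width for s in seqs):
        raise ValueError("ragged alignment: fragments differ in aligned length")
    nseq = len(seqs)
    gap_counts = [sum(s[j] == "-" for s in seqs) for j in range(width)]
    is_match = [2 * g <= nseq for g in gap_counts]
    M = sum(is_match)
    if M == 0:
        raise ValueError("alignment has zero match columns")

    em = np.ones((M, 4))  # +1 Laplace pseudocount
    match_cols = [j for j in range(width) if is_match[j]]
    for m, j in enumerate(match_cols):
        for s in seqs:
            b = _BASE.get(s[j])
            if b is not None:
                em[m, b] += 1
    em /= em.sum(axis=1, keepdims=True)

    # transition counts from each sequence's implied state path
    cnt = {key: np.ones(M + 1) for key in ("mm", "mi", "md", "im", "ii", "dm", "dd")}
    for s in seqs:
        path: list[tuple[str, int]] = [("M", 0)]  # begin treated as match 0
        k = 0
        for j in range(width):
            if is_match[j]:
                k += 1
                path.append(("M" if s[j] != "-" else "D", k))
            elif s[j] != "-":
                path.append(("I", k))
        for (a, ka), (b, _) in zip(path, path[1:]):
            cnt[a.lower() + b.lower()][ka] += 1

    trans = {}
    m_tot = cnt["mm"] + cnt["mi"] + cnt["md"]
    i_tot = cnt["im"] + cnt["ii"]
    d_tot = cnt["dm"] + cnt["dd"]
    for key in ("mm", "mi", "md"):
        trans[key] = cnt[key] / m_tot
    for key in ("im", "ii"):
        trans[key] = cnt[key] / i_tot
    for key in ("dm", "dd"):
        trans[key] = cnt[key] / d_tot
    bg = np.full(4, 0.25)
    return ProfileHMM(
        length=M,
        match_emissions=em,
        insert_emissions=bg.copy(),
        transitions=trans,
        null_model=bg,
    )


def scan_profile(
    hmm: ProfileHMM, seq: str, threshold: float = 0.0
) -> ScanHit | None:
    """Best-scoring local match of the profile within ``seq`` by Viterbi.

    The profile may be entered at any match state and left from any match
    state; unmodelled flanking sequence is free (scored as background).
    Returns ``None`` when the best log-odds score is below ``threshold``
    bits.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper().replace("U", "T")
    M = hmm.length
    L = len(s)
    e = np.log2(hmm.match_emissions) - _LOG2_BG  # (M,4) match log-odds
    t = {k: np.log2(v) for k, v in hmm.transitions.items()}
    NEG = -1e30

    vm = np.full(M + 1, NEG)
    vi = np.full(M + 1, NEG)
    vd = np.full(M + 1, NEG)
    sm = np.zeros(M + 1, dtype=np.int64)
    si = np.zeros(M + 1, dtype=np.int64)
    sd = np.zeros(M + 1, dtype=np.int64)
    best_score, best_end, best_start = -math.inf, 0, 0

    for i in range(1, L + 1):
        b = _BASE.get(s[i - 1])
        emis = e[:, b] if b is not None else np.zeros(M)
        nvm = np.full(M + 1, NEG)
        nvi = np.full(M + 1, NEG)
        nvd = np.full(M + 1, NEG)
        nsm = np.zeros(M + 1, dtype=np.int64)
        nsi = np.zeros(M + 1, dtype=np.int64)
        nsd = np.zeros(M + 1, dtype=np.int64)
        for k in range(1, M + 1):
            # match state k emits residue i
            cand = (
                (0.0, i - 1),  # local entry
                (vm[k - 1] + t["mm"][k - 1], sm[k - 1]),
                (vi[k - 1] + t["im"][k - 1], si[k - 1]),
                (vd[k - 1] + t["dm"][k - 1], sd[k - 1]),
            )
            val, org = max(cand, key=lambda c: c[0])
            nvm[k] = val + emis[k - 1]
            nsm[k] = org
            # insert state k emits residue i (background log-odds 0)
            cand_i = (
                (vm[k] + t["mi"][k], sm[k]),
                (vi[k] + t["ii"][k], si[k]),
            )
            val, org = max(cand_i, key=lambda c: c[0])
            nvi[k] = val
            nsi[k] = org
        # delete states consume no residue: resolve left-to-right at time i
        for k in range(1, M + 1):
            cand_d = (
                (nvm[k - 1] + t["md"][k - 1], nsm[k - 1]),
                (nvd[k - 1] + t["dd"][k - 1], nsd[k - 1]),
            )
            val, org = max(cand_d, key=lambda c: c[0])
            nvd[k] = val
            nsd[k] = org
        vm, vi, vd = nvm, nvi, nvd
        sm, si, sd = nsm, nsi, nsd
        k_best = int(np.argmax(vm[1:])) + 1
        if vm[k_best] > best_score:
            best_score = float(vm[k_best])
            best_end = i
            best_start = int(sm[k_best])
    if best_score < threshold:
        return None
    return ScanHit(start=best_start, end=best_end, score=best_score)


def annotate_locus(
    seq: SequenceRecord | str,
    hmm5: ProfileHMM,
    hmm3: ProfileHMM,
    min_score: float = 0.0,
) -> LocusAnnotation:
    """Segment a locus sequence into 5' flank / core / 3' flank.

    Both strands are scanned; the strand with the higher combined flank
    score is reported, with all coordinates on the input's forward strand.
    When only one flank scores above ``min_score`` an open-ended core is
    reported with status ``partial``; when neither does, status ``none``.
    A 3' flank match preceding the 5' match is an error.
    """
    if isinstance(seq, SequenceRecord):
        sid, s = seq.accession, seq.sequence
    else:
        sid, s = "query", seq.upper().replace("U", "T")
    L = len(s)

    def scan_strand(text: str):
        h5 = scan_profile(hmm5, text, threshold=min_score)
        h3 = scan_profile(hmm3, text, threshold=min_score)
        combined = (h5.score if h5 else 0.0) + (h3.score if h3 else 0.0)
        return h5, h3, combined

    fwd = scan_strand(s)
    rev = scan_strand(reverse_complement(s))
    strand, (h5, h3, _) = (
        (Strand.FORWARD, fwd) if fwd[2] >= rev[2] else (Strand.REVERSE, rev)
    )

    def to_forward(iv: tuple[int, int]) -> tuple[int, int]:
        return iv if strand is Strand.FORWARD else (L - iv[1], L - iv[0])

    scores = {}
    if h5:
        scores["five_prime"] = h5.score
    if h3:
        scores["three_prime"] = h3.score
    if h5 is None and h3 is None:
        return LocusAnnotation(sid, strand, AnnotationStatus.NONE)
    if h5 and h3:
        if h3.start < h5.end:
            raise ValueError(
                f"inconsistent flank order in {sid}: 3' match at "
                f"{h3.start}-{h3.end} precedes 5' match at {h5.start}-{h5.end}"
            )
        return LocusAnnotation(
            sid,
            strand,
            AnnotationStatus.FULL,
            five_prime=to_forward((h5.start, h5.end)),
            core=to_forward((h5.end, h3.start)),
            three_prime=to_forward((h3.start, h3.end)),
            scores=scores,
        )
    if h5:
        return LocusAnnotation(
            sid,
            strand,
            AnnotationStatus.PARTIAL,
            five_prime=to_forward((h5.start, h5.end)),
            core=to_forward((h5.end, L)),
            scores=scores,
        )
    return LocusAnnotation(
        sid,
        strand,
        AnnotationStatus.PARTIAL,
        core=to_forward((0, h3.start)),
        three_prime=to_forward((h3.start, h3.end)),
        scores=scores,
    )
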