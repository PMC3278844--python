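"""Nearest-neighbor species inference and cascade method chains.

The species call for a query is the species of its nearest neighbor(s) in
the reference database under a chosen distance.  A cascade chain such as
``B+P`` first ranks the whole database with the fast method; only when the
tied nearest neighbors span more than one species is the next, more
sensitive method applied — and only to those tied candidates — until a
single species remains or the chain is exhausted.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from enum import Enum

from .distances import (
    DistanceParams,
    DistanceResult,
    KmerProfile,
    Method,
    kmer_profile,
    pairwise_distance,
)
from .records import SequenceRecord
from .refdb import ReferenceDB

#: The eight cascade methods: four base methods and their refinements.
NAMED_CHAINS = ("B", "B+P", "B+E", "D", "D+P", "D+E", "B+P+E", "D+P+E")


class Status(str, Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    NO_HIT = "no_hit"


@dataclass(frozen=True)
class MethodChain:
    """An ordered cascade of base methods, e.g. D+P+E."""

    stages: tuple[Method, ...]

    def __post_init__(self) -> None:
        if not self.stages:
            raise ValueError("empty method chain")
        if len(set(self.stages)) != len(self.stages):
            raise ValueError("repeated stage in method chain")
        if self.stages[0] not in (Method.B, Method.D):
            raise ValueError("a chain must start with a fast method (B or D)")

    @classmethod
    def parse(cls, text: str) -> "MethodChain":
        return cls(tuple(Method(tok.strip()) for tok in text.split("+")))

    def __str__(self) -> str:
        return "+".join(m.value for m in self.stages)


@dataclass
class IdentificationResult:
    """Per-stage candidate sets and the final species call of a cascade."""

    query_id: str
    per_stage: list[tuple[Method, list[DistanceResult]]]
    final_taxids: set[int]
    status: Status
    elapsed: float = 0.0

    @property
    def final_candidates(self) -> list[DistanceResult]:
        """Tied candidates of the last stage that produced any hit."""
        for _, tied in reversed(self.per_stage):
            if tied:
                return tied
        return []


class ProfileCache:
    """Memo of k-mer profiles keyed by (accession, k) for repeated scans."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, int], KmerProfile] = {}

    def get(self, rec: SequenceRecord, k: int) -> KmerProfile:
        key = (rec.accession, k)
        prof = self._store.get(key)
        if prof is None:
            prof = kmer_profile(rec.sequence, k)
            self._store[key] = prof
        return prof


def nearest_neighbors(
    query: SequenceRecord,
    targets: list[SequenceRecord],
    method: Method,
    params: DistanceParams | None = None,
    cache: ProfileCache | None = None,
) -> list[DistanceResult]:
    """All targets tied (within tolerance) for the smallest distance.

    Results are sorted by (distance, target accession) for determinism.
    The tie tolerance is ``params.tie_eps`` for real-valued distances and
    exact for the integer edit distance.  Method B returns an empty list
    (no hit) when no target has a positive-scoring local alignment.
    """
    if not targets:
        raise ValueError("no target sequences")
    params = params or DistanceParams()
    qprof = None
    if method is Method.D:
        cache = cache or ProfileCache()
        qprof = cache.get(query, params.k)
    results: list[DistanceResult] = []
    for t in targets:
        res = pairwise_distance(
            query.sequence,
            t.sequence,
            method,
            params,
            query_id=query.accession,
            target_id=t.accession,
            query_profile=qprof,
            target_profile=cache.get(t, params.k) if method is Method.D else None,
        )
        if res is not None:
            results.append(res)
    if not results:
        return []
    best = min(r.distance for r in results)
    eps = 0.0 if method is Method.E else params.tie_eps
    tied = [r for r in results if r.distance <= best + eps]
    tied.sort(key=lambda r: (r.distance, r.target_id))
    return tied


def identify(
    query: SequenceRecord,
    db: ReferenceDB | list[SequenceRecord],
    chain: MethodChain | str,
    params: DistanceParams | None = None,
    cache: ProfileCache | None = None,
) -> IdentificationResult:
    """Run a cascade chain: stage 1 scans the whole database; later stages
    re-rank only the previous stage's tied candidates.  Stops at the first
    stage whose tied set maps to a single species."""
    if isinstance(chain, str):
        chain = MethodChain.parse(chain)
    params = params or DistanceParams()
    t0 = time.perf_counter()
    if isinstance(db, ReferenceDB):
        targets = db.core_records()
        taxid_of = {r.accession: db.taxonomy.resolve(r) for r in targets}
    else:
        targets = list(db)
        taxid_of = {r.accession: r.taxid for r in targets}
    if not targets:
        raise ValueError("empty reference database")

    by_accession = {r.accession: r for r in targets}
    per_stage: list[tuple[Method, list[DistanceResult]]] = []
    candidates = targets
    final_taxids: set[int] = set()
    status = Status.NO_HIT
    for method in chain.stages:
        tied = nearest_neighbors(query, candidates, method, params, cache)
        per_stage.append((method, tied))
        if not tied:
            # no positive-scoring hit at this stage: fall through to the
            # next method over the same candidate set
            continue
        final_taxids = {taxid_of[r.target_id] for r in tied}
        if len(final_taxids) == 1:
            status = Status.RESOLVED
            break
        status = Status.AMBIGUOUS
        candidates = [by_accession[r.target_id] for r in tied]
    return IdentificationResult(
        query_id=query.accession,
        per_stage=per_stage,
        final_taxids=final_taxids,
        status=status,
        elapsed=time.perf_counter() - t0,
    )
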