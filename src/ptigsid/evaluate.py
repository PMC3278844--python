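"""Leave-one-out evaluation of the identification methods.

Every core sequence in the database is used once as a query, searched
against the database either with itself retained ("include self") or
removed ("exclude self"); the success ratio correct/(correct+wrong) is the
discrimination success rate of a method on the dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import pandas as pd

from .distances import DistanceParams, Method
from .identify import MethodChain, ProfileCache, Status, identify
from .records import SequenceRecord
from .refdb import ReferenceDB


class Mode(str, Enum):
    INCLUDE_SELF = "include_self"
    EXCLUDE_SELF = "exclude_self"


class Criterion(str, Enum):
    """What counts as a successful include-self identification.

    ``SPECIES``: every tied nearest neighbor (besides the query itself)
    belongs to the query's species.  ``STRICT_SEQUENCE``: the tied set is
    exactly the query sequence alone (the literal self-only reading;
    include-self mode only).
    """

    SPECIES = "species"
    STRICT_SEQUENCE = "strict_sequence"


@dataclass
class QueryOutcome:
    query_id: str
    correct: bool
    status: Status
    final_taxids: set[int]


@dataclass
class EvaluationReport:
    """Success counts for one chain/mode, mirroring a Correct/Wrong/Ratio/
    Time results row."""

    chain: MethodChain
    mode: Mode
    criterion: Criterion
    correct: int
    wrong: int
    mean_time: float
    per_query: list[QueryOutcome] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.correct + self.wrong

    @property
    def ratio(self) -> float:
        return self.correct / self.n if self.n else float("nan")


def _check_min_two(db: ReferenceDB) -> None:
    singletons = [t for t in db.species() if len(db.core_records_of(t)) < 2]
    if singletons:
        raise ValueError(
            "database contains species with a single core sequence "
            f"(e.g. taxid {singletons[0]}); rebuild with min_seqs_per_species=2"
        )


def _judge(
    result, query: SequenceRecord, query_taxid: int, mode: Mode, criterion: Criterion
) -> bool:
    if result.status is Status.NO_HIT:
        return False
    if criterion is Criterion.STRICT_SEQUENCE:
        if mode is not Mode.INCLUDE_SELF:
            raise ValueError("strict_sequence criterion applies to include_self only")
        ids = {r.target_id for r in result.final_candidates}
        return ids == {query.accession}
    # species criterion: all finally tied species equal the query's species
    return result.final_taxids == {query_taxid}


def evaluate_loo(
    db: ReferenceDB,
    chain: MethodChain | str,
    mode: Mode | str = Mode.INCLUDE_SELF,
    criterion: Criterion | str = Criterion.SPECIES,
    params: DistanceParams | None = None,
    queries: list[SequenceRecord] | None = None,
    cache: ProfileCache | None = None,
    keep_per_query: bool = True,
) -> EvaluationReport:
    """Leave-one-out evaluation of one cascade chain.

    The database must have been built with ``min_seqs_per_species=2`` so
    that exclude-self searches still contain conspecifics.  ``queries``
    restricts evaluation to a subset (used for per-taxon reports); targets
    are always the full database.
    """
    chain = MethodChain.parse(chain) if isinstance(chain, str) else chain
    mode, criterion = Mode(mode), Criterion(criterion)
    params = params or DistanceParams()
    _check_min_two(db)
    all_targets = db.core_records()
    taxid_of = {r.accession: db.taxonomy.resolve(r) for r in all_targets}
    cache = cache or ProfileCache()
    if queries is None:
        queries = all_targets
    correct = wrong = 0
    total_time = 0.0
    outcomes: list[QueryOutcome] = []
    for q in queries:
        targets = (
            all_targets
            if mode is Mode.INCLUDE_SELF
            else [t for t in all_targets if t.accession != q.accession]
        )
        # pass bare record lists so exclude-self needs no database rebuild
        result = identify(q, targets, chain, params, cache)
        # record-list identify trusts header taxids; patch with resolved ones
        if result.final_candidates:
            result.final_taxids = {
                taxid_of[r.target_id] for r in result.final_candidates
            }
            result.status = (
                Status.RESOLVED if len(result.final_taxids) == 1 else Status.AMBIGUOUS
            )
        ok = _judge(result, q, taxid_of[q.accession], mode, criterion)
        correct += ok
        wrong += not ok
        total_time += result.elapsed
        if keep_per_query:
            outcomes.append(
                QueryOutcome(q.accession, ok, result.status, result.final_taxids)
            )
    return EvaluationReport(
        chain=chain,
        mode=mode,
        criterion=criterion,
        correct=correct,
        wrong=wrong,
        mean_time=total_time / len(queries) if queries else 0.0,
        per_query=outcomes,
    )


def evaluate_chains(
    db: ReferenceDB,
    chains: list[str] | None = None,
    mode: Mode | str = Mode.INCLUDE_SELF,
    criterion: Criterion | str = Criterion.SPECIES,
    params: DistanceParams | None = None,
) -> pd.DataFrame:
    """Evaluate several chains; one Correct/Wrong/Ratio/Time row per chain."""
    from .identify import NAMED_CHAINS

    cache = ProfileCache()
    rows = []
    for name in chains or list(NAMED_CHAINS):
        rep = evaluate_loo(
            db, name, mode, criterion, params, cache=cache, keep_per_query=False
        )
        rows.append(
            {
                "method": name,
                "correct": rep.correct,
                "wrong": rep.wrong,
                "ratio": round(rep.ratio, 4),
                "mean_time": rep.mean_time,
            }
        )
    return pd.DataFrame(rows)


def kmer_size_scan(
    db: ReferenceDB,
    ks: list[int],
    mode: Mode | str = Mode.INCLUDE_SELF,
    criterion: Criterion | str = Criterion.SPECIES,
    params: DistanceParams | None = None,
) -> pd.DataFrame:
    """Success rate of the single-stage k-mer profile method at each k."""
    params = params or DistanceParams()
    rows = []
    for k in ks:
        rep = evaluate_loo(
            db,
            MethodChain((Method.D,)),
            mode,
            criterion,
            replace(params, k=k),
            keep_per_query=False,
        )
        rows.append({"k": k, "ratio": rep.ratio, "mean_time": rep.mean_time})
    return pd.DataFrame(rows)


def evaluate_by_taxon(
    db: ReferenceDB,
    chain: MethodChain | str,
    mode: Mode | str = Mode.INCLUDE_SELF,
    level: str = "family",
    criterion: Criterion | str = Criterion.SPECIES,
    params: DistanceParams | None = None,
) -> dict[int, EvaluationReport]:
    """Per-taxon success reports: queries are partitioned by their lineage
    at ``level`` but each group is still searched against the full
    database, matching a per-group report of a global search."""
    groups: dict[int, list[SequenceRecord]] = {}
    for rec in db.core_records():
        taxid = db.taxonomy.resolve(rec)
        group = db.taxonomy.group_at(taxid, level)
        if group is None:
            warnings.warn(
                f"record {rec.accession}: no {level}-level group; omitted"
            )
            continue
        groups.setdefault(group, []).append(rec)
    cache = ProfileCache()
    return {
        g: evaluate_loo(db, chain, mode, criterion, params, queries=recs, cache=cache)
        for g, recs in sorted(groups.items())
    }
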