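"""Two-dimensional reference database and per-species consensus sequences.

Barcode references are organised along two dimensions: the locus region
(5' psbA / core / 3' trnH / full locus) and the taxonomy level (species,
genus, family, order, class).  For each species a consensus of its core
sequences serves as the species reference sequence.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import GLOBAL_DEFAULTS, ScoringParams, global_align
from .records import (
    LEVELS,
    Region,
    SequenceRecord,
    TaxonomyMap,
    iupac_code_for,
)


class EmptyDatabaseError(ValueError):
    """No records survive database construction (e.g. after the
    at-least-two-sequences-per-species filter)."""


def _is_core_like(rec: SequenceRecord) -> bool:
    # bare spacer submissions carry no region tag; treat them as core
    return rec.region in (Region.CORE, Region.UNKNOWN)


@dataclass
class ReferenceDB:
    """Reference records indexed by (region, taxonomy level, group taxid)."""

    records: list[SequenceRecord]
    taxonomy: TaxonomyMap
    consensus: dict[int, SequenceRecord] = field(default_factory=dict)
    _core_by_species: dict[int, list[SequenceRecord]] = field(
        default_factory=dict, repr=False
    )

    def core_records(self) -> list[SequenceRecord]:
        return [r for r in self.records if _is_core_like(r)]

    def species(self) -> list[int]:
        return sorted(self._core_by_species)

    def core_records_of(self, taxid: int) -> list[SequenceRecord]:
        return list(self._core_by_species.get(taxid, []))


def build_reference_db(
    records: list[SequenceRecord],
    taxonomy: TaxonomyMap,
    min_seqs_per_species: int = 1,
    *,
    build_consensus_refs: bool = True,
) -> ReferenceDB:
    """Assemble a reference database.

    Species with fewer than ``min_seqs_per_species`` core-region records are
    excluded entirely (min=2 is the leave-one-out evaluation filter; min=1
    keeps everything for identification use).  A consensus reference is
    built for every retained species.
    """
    if not records:
        raise ValueError("no input records")
    by_species: dict[int, list[SequenceRecord]] = defaultdict(list)
    for rec in records:
        taxid = taxonomy.resolve(rec)
        if _is_core_like(rec):
            by_species[taxid].append(rec)
    kept_species = {
        t for t, recs in by_species.items() if len(recs) >= min_seqs_per_species
    }
    if not kept_species:
        raise EmptyDatabaseError(
            f"no species has >= {min_seqs_per_species} core sequences"
        )
    kept_records = [
        r for r in records if taxonomy.resolve(r) in kept_species
    ]
    db = ReferenceDB(
        records=kept_records,
        taxonomy=taxonomy,
        _core_by_species={t: by_species[t] for t in sorted(kept_species)},
    )
    if build_consensus_refs:
        for taxid in sorted(kept_species):
            db.consensus[taxid] = build_consensus(by_species[taxid], taxid=taxid)
    return db


def retrieve(
    db: ReferenceDB, group_taxid: int, region: Region, level: str = "species"
) -> list[SequenceRecord]:
    """All records whose lineage at ``level`` equals ``group_taxid`` and
    whose region matches.  An unknown taxid yields an empty result with a
    warning rather than an error."""
    if level not in ("species", "genus", "family", "order", "class"):
        raise ValueError(f"unsupported retrieval level {level!r}")
    hits = []
    for rec in db.records:
        taxid = db.taxonomy.resolve(rec)
        if db.taxonomy.group_at(taxid, level) != group_taxid:
            continue
        if region is Region.CORE and _is_core_like(rec):
            hits.append(rec)
        elif rec.region is region:
            hits.append(rec)
    if not hits:
        warnings.warn(
            f"no sequences available for taxid {group_taxid} "
            f"(region={region.value}, level={level})"
        )
    return hits


def build_consensus(
    records: list[SequenceRecord],
    taxid: int | None = None,
    scoring: ScoringParams = GLOBAL_DEFAULTS,
) -> SequenceRecord:
    """Species consensus by star alignment and per-column majority vote.

    All members are globally aligned to the longest member (the star
    center); columns whose majority character is a gap are dropped; among
    the remaining characters the majority base wins and ties are broken by
    the IUPAC ambiguity code covering the tied bases.
    """
    if not records:
        raise ValueError("consensus of zero records")
    taxids = {r.taxid for r in records}
    if taxid is None:
        if len(taxids) > 1:
            raise ValueError(f"mixed species taxids in consensus input: {taxids}")
        taxid = next(iter(taxids))
    elif taxids - {taxid, 0}:
        raise ValueError(f"records with taxids {taxids} do not all match {taxid}")

    center = max(records, key=lambda r: (len(r.sequence), r.accession))
    others = [r for r in records if r is not center]
    msa = _star_msa(center.sequence, [r.sequence for r in others])
    consensus = _column_vote(msa)
    return SequenceRecord(
        accession=f"CONSENSUS_{taxid}",
        taxid=taxid,
        sequence=consensus,
        region=Region.CORE,
    )


def _star_msa(center: str, others: list[str]) -> list[str]:
    """Merge pairwise alignments to the center into one gapped matrix."""
    n = len(center)
    # per sequence: chars at each center column, insertions keyed by the
    # center position they precede (0..n)
    aligned_cols: list[list[str]] = []
    aligned_ins: list[dict[int, str]] = []
    for seq in others:
        aln = global_align(center, seq)
        cols, ins = [""] * n, defaultdict(str)
        p = 0
        for c, s in aln.columns():
            if c == "-":
                ins[p] += s
            else:
                cols[p] = s
                p += 1
        aligned_cols.append(cols)
        aligned_ins.append(dict(ins))
    max_ins = [0] * (n + 1)
    for ins in aligned_ins:
        for pos, frag in ins.items():
            max_ins[pos] = max(max_ins[pos], len(frag))

    def expand(cols: list[str], ins: dict[int, str]) -> str:
        out = []
        for p in range(n + 1):
            frag = ins.get(p, "")
            out.append(frag.ljust(max_ins[p], "-"))
            if p < n:
                out.append(cols[p])
        return "".join(out)

    rows = [expand(list(center), {})]
    for cols, ins in zip(aligned_cols, aligned_ins):
        rows.append(expand(cols, ins))
    return rows


def _column_vote(rows: list[str]) -> str:
    n_rows = len(rows)
    out = []
    for col in zip(*rows):
        counts = Counter(col)
        if counts.get("-", 0) * 2 > n_rows:
            continue
        base_counts = {b: c for b, c in counts.items() if b != "-"}
        top = max(base_counts.values())
        winners = sorted(b for b, c in base_counts.items() if c == top)
        out.append(winners[0] if len(winners) == 1 else iupac_code_for(winners))
    return "".join(out)
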