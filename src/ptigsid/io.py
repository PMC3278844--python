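"""FASTA and taxonomy-TSV input/output.

FASTA headers follow the ``ACCESSION_TAXID`` convention (taxid appended to
the accession after the last underscore, e.g. ``GQ248374_129213``).  A
separate taxonomy TSV, when provided, overrides header taxids.
"""

from __future__ import annotations

import re
import warnings
from os import PathLike
from typing import IO, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .records import LEVELS, Region, SequenceRecord, TaxonomyMap

_HEADER_RE = re.compile(r"^(?P<acc>.+)_(?P<taxid>\d+)$")

# description keywords -> region labels (set by write_fasta / annotate output)
_REGION_TAGS = {r.value: r for r in Region if r is not Region.UNKNOWN}


def _parse_header(header_id: str, description: str) -> tuple[str, int, bool]:
    m = _HEADER_RE.match(header_id)
    if m:
        return m.group("acc"), int(m.group("taxid")), False
    return header_id, 0, True


def read_fasta(source: str | PathLike | IO[str]) -> list[SequenceRecord]:
    """Read barcode sequences from FASTA.

    One :class:`SequenceRecord` per entry; the header is parsed as
    ``ACCESSION_TAXID [description]``.  When the taxid suffix is absent the
    taxid is 0 and the record is flagged.  Sequences are uppercased and U is
    normalized to T.  The region is ``unknown`` unless a region tag (e.g.
    ``region=core``) appears in the description.
    """
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(source, "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"FASTA entry {entry.id!r} has an empty sequence")
        accession, taxid, missing = _parse_header(entry.id, entry.description)
        region = Region.UNKNOWN
        m = re.search(r"region=(\S+)", entry.description)
        if m and m.group(1) in _REGION_TAGS:
            region = _REGION_TAGS[m.group(1)]
        records.append(
            SequenceRecord(
                accession=accession,
                taxid=taxid,
                sequence=seq,
                region=region,
                taxid_missing=missing,
            )
        )
    return records


def write_fasta(
    records: Iterable[SequenceRecord], sink: str | PathLike | IO[str]
) -> None:
    """Write records as FASTA with ``ACCESSION_TAXID`` headers, 60-col wrap."""
    out = []
    for rec in records:
        name = rec.accession if rec.taxid_missing else f"{rec.accession}_{rec.taxid}"
        desc = "" if rec.region is Region.UNKNOWN else f"region={rec.region.value}"
        out.append(
            BioSeqRecord(Seq(rec.sequence), id=name, name=name, description=desc)
        )
    SeqIO.write(out, sink, "fasta")


def load_taxonomy(path: str | PathLike | IO[str]) -> TaxonomyMap:
    """Load a taxonomy TSV with columns accession, taxid, then optional
    lineage columns (species, genus, family, order, class, higher_group).

    Non-species lineage columns may hold group taxids; a ``species`` column
    holds the species name.  Duplicate accessions with conflicting taxids are
    an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    if "accession" not in df.columns or "taxid" not in df.columns:
        raise ValueError("taxonomy TSV must have 'accession' and 'taxid' columns")
    tax = TaxonomyMap()
    lineage_cols = [c for c in LEVELS if c in df.columns and c != "species"]
    for d in df.to_dict("records"):
        taxid = int(d["taxid"])
        tax.add_accession(d["accession"], taxid)
        entry = tax.lineage.setdefault(taxid, {"species": taxid})
        for col in lineage_cols:
            val = d.get(col)
            if val is not None and not pd.isna(val):
                entry[col] = int(val)
        name = d.get("species")
        if name is not None and not pd.isna(name):
            tax.species_names[taxid] = name
    return tax


def write_taxonomy(tax: TaxonomyMap, path: str | PathLike | IO[str]) -> None:
    """Write a TaxonomyMap back to the TSV layout read by load_taxonomy."""
    rows = []
    for acc, taxid in tax.accession_to_taxid.items():
        lin = tax.lineage.get(taxid, {})
        rows.append(
            {
                "accession": acc,
                "taxid": taxid,
                "species": tax.species_names.get(taxid, ""),
                "genus": lin.get("genus", ""),
                "family": lin.get("family", ""),
                "order": lin.get("order", ""),
                "class": lin.get("class", ""),
                "higher_group": lin.get("higher_group", ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
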