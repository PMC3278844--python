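"""Core domain types: sequence records, taxonomy, region labels.

The psbA-trnH intergenic spacer (PTIGS) locus is modelled as three parts:
a conserved 5' psbA fragment, the indel-rich core spacer (the unit used for
species identification), and a conserved 3' trnH fragment.  Each barcode
sequence carries an accession and an NCBI-style integer species taxid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

from Bio.Data.IUPACData import ambiguous_dna_values

IUPAC_CODES = frozenset("ACGTMRWSYKVHDBNX")

# base-set -> ambiguity code, e.g. {"A","T"} -> "W"
_CODE_FOR_SET = {frozenset(v): k for k, v in ambiguous_dna_values.items() if k != "X"}

_COMPLEMENT = str.maketrans(
    "ACGTMRWSYKVHDBNX-", "TGCAKYWSRMBDHVNX-"
)


class Region(str, Enum):
    """Which part of the PTIGS locus a sequence represents."""

    FIVE_PRIME = "five_prime_psbA"
    CORE = "core"
    THREE_PRIME = "three_prime_trnH"
    FULL_LOCUS = "full_locus"
    UNKNOWN = "unknown"


def normalize_sequence(seq: str, *, context: str = "sequence") -> str:
    """Uppercase, normalize U->T, and validate IUPAC nucleotide codes.

    Raises ``ValueError`` naming the first offending position otherwise.
    """
    s = seq.upper().replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in IUPAC_CODES:
            raise ValueError(
                f"non-IUPAC character {ch!r} at position {i} in {context}"
            )
    return s


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_code_for(bases) -> str:
    """The single IUPAC code covering a set of bases, e.g. {A,G} -> R."""
    key = frozenset(bases)
    if len(key) == 1:
        return next(iter(key))
    return _CODE_FOR_SET[key]


@dataclass
class SequenceRecord:
    """One barcode sequence with its accession, species taxid and region."""

    accession: str
    taxid: int
    sequence: str
    region: Region = Region.UNKNOWN
    species_name: str | None = None
    taxid_missing: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.accession!r}")
        self.sequence = normalize_sequence(
            self.sequence, context=f"record {self.accession!r}"
        )

    def __len__(self) -> int:
        return len(self.sequence)


# lineage levels, most to least specific
LEVELS = ("species", "genus", "family", "order", "class", "higher_group")


@dataclass
class TaxonomyMap:
    """Accession -> taxid plus a flat named-level lineage per species taxid.

    The lineage is a plain map ``taxid -> {level: group taxid}``; the NCBI
    taxonomy tree itself is not mirrored.
    """

    accession_to_taxid: dict[str, int] = field(default_factory=dict)
    lineage: dict[int, dict[str, int]] = field(default_factory=dict)
    species_names: dict[int, str] = field(default_factory=dict)

    def add_accession(self, accession: str, taxid: int) -> None:
        existing = self.accession_to_taxid.get(accession)
        if existing is not None and existing != taxid:
            raise ValueError(
                f"accession {accession!r} maps to conflicting taxids "
                f"{existing} and {taxid}"
            )
        self.accession_to_taxid[accession] = taxid

    def group_at(self, taxid: int, level: str) -> int | None:
        """Group taxid of a species at a lineage level (species -> itself)."""
        if level not in LEVELS:
            raise ValueError(f"unknown taxonomy level {level!r}")
        if level == "species":
            return taxid
        return self.lineage.get(taxid, {}).get(level)

    def resolve(self, record: SequenceRecord) -> int:
        """Taxid for a record; the taxonomy map wins over the header."""
        mapped = self.accession_to_taxid.get(record.accession)
        if mapped is None:
            return record.taxid
        if record.taxid and mapped != record.taxid:
            warnings.warn(
                f"record {record.accession}: header taxid {record.taxid} "
                f"overridden by taxonomy map taxid {mapped}"
            )
        return mapped
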