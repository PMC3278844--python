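"""Seeded synthetic PTIGS-like datasets.

Emulates the data regime of the psbA-trnH spacer marker: species groups
with at least two individuals each, conserved psbA/trnH flanks, and
indel-rich, length-variable core spacers whose intra-species divergence is
much smaller than the inter-species divergence.  A root core sequence
descends along a family -> genus -> species hierarchy accumulating
substitutions and geometric-length indels at inter-species rates;
individuals within a species diverge at (much lower) intra-species rates.
Flanks derive from one ancestral pair, lightly substituted per individual,
so each dataset's flank sets double as ungapped training alignments for
the profile-HMM module.

Everything is reproducible from the seed, and truth annotations record the
planted 5'/core/3' coordinates of every record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .hmm import AnnotationStatus, LocusAnnotation, Strand
from .io import write_fasta, write_taxonomy
from .records import Region, SequenceRecord, TaxonomyMap

_BASES = np.array(list("ACGT"))

# synthetic taxids live far above real NCBI ones so fixtures cannot collide
TAXID_BASE = 900_000_000


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    Rates are per-base probabilities; ``inter_*`` rates apply on each edge
    of the taxonomy descent (root -> family -> genus -> species) and
    ``intra_*`` rates per individual.  Defaults give the separable regime
    typical of the marker: intra-species divergence ~1%, inter-species
    ~15% per tree edge, cores a few hundred nt with common indels.
    """

    seed: int = 0
    n_families: int = 2
    n_genera_per_family: int = 2
    n_species_per_genus: int = 2
    n_individuals_per_species: int = 3
    core_length_range: tuple[int, int] = (250, 450)
    flank5_length: int = 25
    flank3_length: int = 25
    inter_species_sub_rate: float = 0.15
    inter_species_indel_rate: float = 0.02
    intra_species_sub_rate: float = 0.01
    intra_species_indel_rate: float = 0.002
    ambiguity_rate: float = 0.0
    indel_mean_length: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.core_length_range
        if lo > hi:
            raise ValueError("core_length_range min > max")
        for name in (
            "inter_species_sub_rate",
            "inter_species_indel_rate",
            "intra_species_sub_rate",
            "intra_species_indel_rate",
            "ambiguity_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if (
            self.intra_species_sub_rate > self.inter_species_sub_rate
            or self.intra_species_indel_rate > self.inter_species_indel_rate
        ):
            warnings.warn(
                "intra-species rates exceed inter-species rates; the dataset "
                "will not be species-separable"
            )
        for name in (
            "n_families",
            "n_genera_per_family",
            "n_species_per_genus",
            "n_individuals_per_species",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticDataset:
    """Generated records (full loci), taxonomy, and planted truth."""

    spec: SyntheticSpec
    records: list[SequenceRecord]
    taxonomy: TaxonomyMap
    truth: dict[str, LocusAnnotation]
    flanks5: list[str] = field(default_factory=list)
    flanks3: list[str] = field(default_factory=list)

    def core_records(self) -> list[SequenceRecord]:
        """Core-spacer records cut out of the full loci via the truth."""
        out = []
        for rec in self.records:
            s, e = self.truth[rec.accession].core
            out.append(
                SequenceRecord(
                    accession=rec.accession,
                    taxid=rec.taxid,
                    sequence=rec.sequence[s:e],
                    region=Region.CORE,
                )
            )
        return out

    def write(self, outdir: str | Path) -> None:
        """FASTA + taxonomy TSV + truth coordinate TSV, in the formats the
        rest of the package consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, str(outdir / "loci.fasta"))
        write_fasta(self.core_records(), str(outdir / "cores.fasta"))
        write_taxonomy(self.taxonomy, str(outdir / "taxonomy.tsv"))
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "accession\tfive_start\tfive_end\tcore_start\tcore_end"
                "\tthree_start\tthree_end\n"
            )
            for acc in sorted(self.truth):
                t = self.truth[acc]
                fh.write(
                    f"{acc}\t{t.five_prime[0]}\t{t.five_prime[1]}"
                    f"\t{t.core[0]}\t{t.core[1]}"
                    f"\t{t.three_prime[0]}\t{t.three_prime[1]}\n"
                )


_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def exemplar_trio(
    seed: int = 0, length: int = 100
) -> tuple[SequenceRecord, list[SequenceRecord]]:
    """Synthetic stand-in for the classic worked example of cascade
    refinement: a query whose three best local-alignment hits tie across
    two species, which the P/K2P stage then separates.

    Each target differs from the query by exactly one substitution, so all
    three tie under local-alignment score; the two conspecific targets
    carry transversions and the cross-species target a transition, which
    K2P weighs differently.  Returns ``(query, targets)`` with synthetic
    taxids.
    """
    rng = np.random.default_rng(seed)
    q = _random_seq(rng, length)
    species_a, species_b = TAXID_BASE + 101, TAXID_BASE + 102

    def with_sub(pos: int, table: dict[str, str]) -> str:
        return q[:pos] + table[q[pos]] + q[pos + 1 :]

    query = SequenceRecord("EXQ000001", species_a, q, Region.CORE)
    targets = [
        SequenceRecord("EXT000001", species_a, with_sub(length * 3 // 10, _TRANSVERSION), Region.CORE),
        SequenceRecord("EXT000002", species_a, with_sub(length * 6 // 10, _TRANSVERSION), Region.CORE),
        SequenceRecord("EXT000003", species_b, with_sub(length * 45 // 100, _TRANSITION), Region.CORE),
    ]
    return query, targets


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(
    rng: np.random.Generator,
    seq: str,
    sub_rate: float,
    indel_rate: float,
    indel_mean: float,
) -> str:
    """Substitutions and geometric-length indels at per-base rates."""
    out: list[str] = []
    geom_p = 1.0 / indel_mean if indel_mean > 0 else 1.0
    i = 0
    while i < len(seq):
        ch = seq[i]
        if indel_rate > 0 and rng.random() < indel_rate:
            length = int(rng.geometric(geom_p))
            if rng.random() < 0.5:
                out.append(_random_seq(rng, length))  # insertion before ch
            else:
                i += length  # deletion starting at ch
                continue
        if sub_rate > 0 and rng.random() < sub_rate:
            choices = [b for b in "ACGT" if b != ch]
            out.append(choices[rng.integers(3)])
        else:
            out.append(ch)
        i += 1
    return "".join(out)


def _inject_ambiguity(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    return "".join("N" if rng.random() < rate else ch for ch in seq)


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one dataset; byte-identical for identical specs."""
    rng = np.random.default_rng(spec.seed)
    core_len = int(rng.integers(spec.core_length_range[0], spec.core_length_range[1] + 1))
    root_core = _random_seq(rng, core_len)
    flank5_anc = _random_seq(rng, spec.flank5_length)
    flank3_anc = _random_seq(rng, spec.flank3_length)

    tax = TaxonomyMap()
    higher, class_, order = TAXID_BASE, TAXID_BASE + 1, TAXID_BASE + 2
    next_taxid = TAXID_BASE + 3

    records: list[SequenceRecord] = []
    truth: dict[str, LocusAnnotation] = {}
    flanks5: list[str] = []
    flanks3: list[str] = []
    acc_counter = 1

    inter = (spec.inter_species_sub_rate, spec.inter_species_indel_rate)
    intra = (spec.intra_species_sub_rate, spec.intra_species_indel_rate)

    for _ in range(spec.n_families):
        family_taxid = next_taxid
        next_taxid += 1
        family_core = _mutate(rng, root_core, *inter, spec.indel_mean_length)
        for _ in range(spec.n_genera_per_family):
            genus_taxid = next_taxid
            next_taxid += 1
            genus_core = _mutate(rng, family_core, *inter, spec.indel_mean_length)
            for _ in range(spec.n_species_per_genus):
                species_taxid = next_taxid
                next_taxid += 1
                tax.lineage[species_taxid] = {
                    "species": species_taxid,
                    "genus": genus_taxid,
                    "family": family_taxid,
                    "order": order,
                    "class": class_,
                    "higher_group": higher,
                }
                species_core = _mutate(
                    rng, genus_core, *inter, spec.indel_mean_length
                )
                for _ in range(spec.n_individuals_per_species):
                    core = _mutate(
                        rng, species_core, *intra, spec.indel_mean_length
                    )
                    core = _inject_ambiguity(rng, core, spec.ambiguity_rate)
                    # flanks: substitutions only, so flank sets stay aligned
                    f5 = _mutate(rng, flank5_anc, intra[0], 0.0, 1.0)
                    f3 = _mutate(rng, flank3_anc, intra[0], 0.0, 1.0)
                    acc = f"SYN{acc_counter:06d}"
                    acc_counter += 1
                    tax.add_accession(acc, species_taxid)
                    locus = f5 + core + f3
                    records.append(
                        SequenceRecord(
                            accession=acc,
                            taxid=species_taxid,
                            sequence=locus,
                            region=Region.FULL_LOCUS,
                        )
                    )
                    truth[acc] = LocusAnnotation(
                        sequence_id=acc,
                        strand=Strand.FORWARD,
                        status=AnnotationStatus.FULL,
                        five_prime=(0, len(f5)),
                        core=(len(f5), len(f5) + len(core)),
                        three_prime=(len(f5) + len(core), len(locus)),
                    )
                    flanks5.append(f5)
                    flanks3.append(f3)
    return SyntheticDataset(
        spec=spec,
        records=records,
        taxonomy=tax,
        truth=truth,
        flanks5=flanks5,
        flanks3=flanks3,
    )
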