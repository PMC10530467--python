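"""Low-frequency variant filtering and family segregation structure.

Filters: candidate-panel membership, call quality > ``qual_min``, MAF below
``maf_max`` in *both* population databases (an absent frequency passes — a
variant missing from a database is treated as rare/novel) and, by default,
a heterozygous genotype in at least one affected member.  Carrier sets,
per-member counts, shared-in-affected intersections and same-gene
co-carriage groups (linkage or compound heterozygosity; indistinguishable
without phase) are derived from the genotype columns alone.

All outputs are sorted by (chromosome, position, alt) for reproducibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set

from .errors import ConfigError, InputError
from .variant_io import (
    Consequence,
    GenePanel,
    Genotype,
    Pedigree,
    VariantRecord,
    _chrom_sort_key,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CarrierMatrix",
    "LinkageGroup",
    "genomic_sort_key",
    "apply_frequency_filter",
    "split_by_consequence",
    "carrier_matrix",
    "count_missense_per_affected",
    "shared_in_affected",
    "affected_carrier_counts",
    "linkage_groups",
]


def genomic_sort_key(record: VariantRecord):
    return (*_chrom_sort_key(record.chrom), record.pos, record.alt)


@dataclass
class CarrierMatrix:
    """Per-variant carrier sets (het or hom_alt) over the pedigree."""

    records: List[VariantRecord]
    carriers: Dict[str, Set[str]]
    zygosity: Dict[tuple, Genotype]
    pedigree: Pedigree = field(repr=False)

    def affected_carriers(self, key: str) -> Set[str]:
        return self.carriers[key] & set(self.pedigree.affected_ids)

    def record(self, key: str) -> VariantRecord:
        for rec in self.records:
            if rec.key == key:
                return rec
        raise KeyError(key)


@dataclass(frozen=True)
class LinkageGroup:
    """>=2 same-gene variants co-carried by >=1 member (phase unknown)."""

    gene: str
    variants: tuple  # VariantRecord refs, genomic order
    members: frozenset
    kind: str = "linked_or_compound_het"


def apply_frequency_filter(
    records: Sequence[VariantRecord],
    panel: GenePanel,
    pedigree: Pedigree,
    maf_max: float = 0.04,
    qual_min: float = 30.0,
    require_het_in_affected: bool = True,
) -> List[VariantRecord]:
    """Keep panel variants rare in both databases, well called, het in a patient.

    MAF comparisons are strict (``< maf_max``); quality is strict
    (``> qual_min``).  ``require_het_in_affected`` demands a heterozygous
    genotype in >=1 affected member; hom_alt alone does not satisfy it,
    though hom_alt members still count as carriers downstream.
    """
    if not (0.0 < maf_max <= 1.0):
        raise ConfigError(f"maf_max={maf_max} outside (0, 1]")
    affected = pedigree.affected_ids
    if require_het_in_affected and not affected:
        raise InputError("pedigree has no affected members")

    kept = []
    for rec in records:
        if rec.gene not in panel:
            continue
        if rec.qual is None or rec.qual <= qual_min:
            continue
        if rec.maf_gnomad3 is not None and rec.maf_gnomad3 >= maf_max:
            continue
        if rec.maf_1000g is not None and rec.maf_1000g >= maf_max:
            continue
        if require_het_in_affected and not any(
            rec.genotypes.get(m) == Genotype.HET for m in affected
        ):
            continue
        kept.append(rec)
    kept.sort(key=genomic_sort_key)
    logger.info("frequency filter: %d of %d records retained", len(kept), len(records))
    return kept


def split_by_consequence(records: Sequence[VariantRecord]) -> Dict[str, list]:
    """Partition records into missense and synonymous, preserving order."""
    out = {Consequence.MISSENSE.value: [], Consequence.SYNONYMOUS.value: []}
    for rec in records:
        if rec.consequence is None or rec.consequence.value not in out:
            raise InputError(f"{rec.label}: unknown consequence {rec.consequence!r}")
        out[rec.consequence.value].append(rec)
    return out


def carrier_matrix(records: Sequence[VariantRecord], pedigree: Pedigree) -> CarrierMatrix:
    """Derive carrier sets (het or hom_alt members) per variant."""
    ordered = sorted(records, key=genomic_sort_key)
    carriers: Dict[str, Set[str]] = {}
    zygosity: Dict[tuple, Genotype] = {}
    ped_ids = set(pedigree.ids)
    for rec in ordered:
        stray = set(rec.genotypes) - ped_ids
        if stray:
            raise InputError(
                f"{rec.label}: genotypes for non-pedigree member(s) "
                + ", ".join(sorted(stray))
            )
        carriers[rec.key] = set()
        for member in pedigree.ids:
            gt = rec.genotypes.get(member)
            if gt is None:
                logger.debug("%s: no genotype for %s", rec.label, member)
                gt = Genotype.MISSING
            zygosity[(rec.key, member)] = gt
            if gt.carries_alt:
                carriers[rec.key].add(member)
    return CarrierMatrix(
        records=ordered, carriers=carriers, zygosity=zygosity, pedigree=pedigree
    )


def count_missense_per_affected(
    matrix: CarrierMatrix, pedigree: Pedigree
) -> Dict[str, int]:
    """Count carried missense variants per affected member."""
    counts = {m: 0 for m in pedigree.affected_ids}
    for rec in matrix.records:
        if rec.consequence != Consequence.MISSENSE:
            continue
        for member in matrix.carriers[rec.key]:
            if member not in pedigree.ids:
                raise InputError(f"carrier {member} not in pedigree")
            if member in counts:
                counts[member] += 1
    return counts


def shared_in_affected(
    matrix: CarrierMatrix, pedigree: Pedigree
) -> List[VariantRecord]:
    """Variants carried by every affected member, in genomic order."""
    affected = set(pedigree.affected_ids)
    return [
        rec
        for rec in matrix.records
        if affected and affected <= matrix.carriers[rec.key]
    ]


def affected_carrier_counts(matrix: CarrierMatrix, pedigree: Pedigree) -> Dict[str, int]:
    """Map variant key -> number of affected members carrying it."""
    affected = set(pedigree.affected_ids)
    return {
        rec.key: len(matrix.carriers[rec.key] & affected) for rec in matrix.records
    }


def linkage_groups(
    records: Sequence[VariantRecord], matrix: CarrierMatrix
) -> List[LinkageGroup]:
    """Find groups of >=2 same-gene variants co-carried by >=1 member.

    For each member and gene, the set of that gene's variants the member
    carries forms a candidate group; identical variant sets are merged and
    credited to every member carrying the full set.  Groups whose variant
    set is a strict subset of another group with the same members are
    dropped as redundant.
    """
    by_gene: Dict[str, list] = {}
    for rec in sorted(records, key=genomic_sort_key):
        by_gene.setdefault(rec.gene, []).append(rec)

    groups: Dict[tuple, set] = {}  # variant-key tuple -> members
    for gene, recs in by_gene.items():
        if len(recs) < 2:
            continue
        candidate_sets = set()
        for member in matrix.pedigree.ids:
            carried = tuple(
                r.key for r in recs if member in matrix.carriers.get(r.key, set())
            )
            if len(carried) >= 2:
                candidate_sets.add(carried)
        for keys in candidate_sets:
            members = {
                m
                for m in matrix.pedigree.ids
                if all(m in matrix.carriers[k] for k in keys)
            }
            groups[(gene, keys)] = members

    # drop strict subsets with identical member sets
    result = []
    for (gene, keys), members in groups.items():
        redundant = any(
            other_gene == gene
            and set(keys) < set(other_keys)
            and members == groups[(other_gene, other_keys)]
            for (other_gene, other_keys) in groups
        )
        if redundant:
            continue
        key_to_rec = {r.key: r for r in by_gene[gene]}
        result.append(
            LinkageGroup(
                gene=gene,
                variants=tuple(
                    sorted((key_to_rec[k] for k in keys), key=genomic_sort_key)
                ),
                members=frozenset(members),
            )
        )
    result.sort(key=lambda g: (g.gene, genomic_sort_key(g.variants[0])))
    return result
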