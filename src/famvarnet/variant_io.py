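"""Readers and writers for the standard formats the pipeline touches.

The VCF is the canonical genotype carrier.  Gene symbol, consequence and the
per-database allele frequencies travel either inline (INFO keys written by
:func:`write_vcf`) or via side-car TSV annotation tables loaded into an
:class:`AnnotationStore`.  Coordinates are 1-based, genotypes unphased.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .errors import InputError

__all__ = [
    "Consequence",
    "Genotype",
    "ClinVarCategory",
    "VariantRecord",
    "Member",
    "Pedigree",
    "GenePanel",
    "RegulatoryAnnotation",
    "AnnotationStore",
    "read_ped",
    "read_panel",
    "read_vcf",
    "write_vcf",
    "read_annotation_tables",
]


class Consequence(str, Enum):
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)


class ClinVarCategory(str, Enum):
    NR = "NR"  # not reported
    B = "B"  # benign
    LB = "LB"  # likely benign
    LP = "LP"  # likely pathogenic
    P = "P"  # pathogenic


_ANNOTATED = frozenset(
    {ClinVarCategory.B, ClinVarCategory.LB, ClinVarCategory.LP, ClinVarCategory.P}
)

VariantKey = str


def _norm_protein_change(value: Optional[str]) -> Optional[str]:
    if value is None:
        return None
    value = value.strip()
    if value.startswith("p."):
        value = value[2:]
    return value or None


@dataclass
class VariantRecord:
    """One alternate allele at one site, with annotations and genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: Optional[Consequence] = None
    rsid: Optional[str] = None
    cdna_change: Optional[str] = None
    protein_change: Optional[str] = None
    maf_gnomad3: Optional[float] = None
    maf_1000g: Optional[float] = None
    qual: Optional[float] = None
    clinvar: frozenset = frozenset({ClinVarCategory.NR})
    novel: bool = False
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InputError(f"{self.chrom}:{self.pos} position must be >= 1")
        for name in ("maf_gnomad3", "maf_1000g"):
            maf = getattr(self, name)
            if maf is not None and not (0.0 <= maf <= 1.0):
                raise InputError(f"{self.label}: {name}={maf} outside [0, 1]")
        self.protein_change = _norm_protein_change(self.protein_change)
        if self.rsid is None and not self.novel:
            if self.maf_gnomad3 is not None or self.maf_1000g is not None:
                raise InputError(
                    f"{self.label}: absent rsid requires absent MAFs or novel flag"
                )

    @property
    def key(self) -> VariantKey:
        """Stable lookup key: rsid when known, else gene + protein change."""
        if self.rsid:
            return self.rsid
        return f"{self.gene}:{self.protein_change or self.cdna_change or self.pos}"

    @property
    def label(self) -> str:
        change = self.protein_change or self.cdna_change or f"{self.ref}>{self.alt}"
        return f"{self.gene} {change}"

    @property
    def clinvar_annotated(self) -> bool:
        return bool(self.clinvar & _ANNOTATED)

    def carriers(self) -> set:
        return {m for m, g in self.genotypes.items() if g.carries_alt}


@dataclass(frozen=True)
class Member:
    id: str
    sex: Optional[str] = None
    affected: bool = False
    father: Optional[str] = None
    mother: Optional[str] = None


@dataclass
class Pedigree:
    members: list

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate pedigree member ids: {', '.join(dupes)}")
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in ids:
                    raise InputError(
                        f"member {m.id}: parent {parent} not in pedigree"
                    )

    @property
    def ids(self) -> list:
        return [m.id for m in self.members]

    @property
    def affected_ids(self) -> list:
        return [m.id for m in self.members if m.affected]

    @property
    def unaffected_ids(self) -> list:
        return [m.id for m in self.members if not m.affected]

    def member(self, member_id: str) -> Member:
        for m in self.members:
            if m.id == member_id:
                return m
        raise InputError(f"member {member_id} not in pedigree")


@dataclass(frozen=True)
class GenePanel:
    """Candidate-gene panel; symbols uppercase-normalized, deduplicated."""

    symbols: frozenset

    def __post_init__(self) -> None:
        if not self.symbols:
            raise InputError("gene panel is empty")

    def __contains__(self, symbol: str) -> bool:
        return symbol.upper() in self.symbols

    def __len__(self) -> int:
        return len(self.symbols)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str]) -> "GenePanel":
        return cls(frozenset(s.strip().upper() for s in symbols if s.strip()))


@dataclass(frozen=True)
class RegulatoryAnnotation:
    """Region, splicing-prediction and QTL evidence attached to a variant."""

    key: VariantKey
    region_features: frozenset = frozenset()
    splicing_predictions: frozenset = frozenset()
    eqtl_genes: frozenset = frozenset()
    sqtl_genes: frozenset = frozenset()

    @property
    def has_qtl(self) -> bool:
        return bool(self.eqtl_genes or self.sqtl_genes)


_EMPTY_REGULATORY_FIELDS = dict(
    region_features=frozenset(),
    splicing_predictions=frozenset(),
    eqtl_genes=frozenset(),
    sqtl_genes=frozenset(),
)


def read_ped(path: Union[str, Path]) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file.

    Columns: family, id, father, mother, sex, status.  Status 2 = affected,
    1 = unaffected; 0 / -9 = unknown, treated as unaffected with a warning.
    """
    members = []
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise InputError(
                f"{path}:{lineno}: expected 6 PED columns, got {len(fields)}"
            )
        _, mid, father, mother, sex, status = fields[:6]
        if mid in seen:
            raise InputError(f"{path}:{lineno}: duplicate member id {mid}")
        seen.add(mid)
        if status == "2":
            affected = True
        elif status == "1":
            affected = False
        elif status in ("0", "-9"):
            warnings.warn(
                f"{path}:{lineno}: member {mid} has unknown affection status"
                " ({status}); treating as unaffected".format(status=status)
            )
            affected = False
        else:
            raise InputError(f"{path}:{lineno}: bad affection status {status!r}")
        members.append(
            Member(
                id=mid,
                sex={"1": "male", "2": "female"}.get(sex),
                affected=affected,
                father=None if father == "0" else father,
                mother=None if mother == "0" else mother,
            )
        )
    return Pedigree(members)


def read_panel(path: Union[str, Path]) -> GenePanel:
    """Read a one-symbol-per-line gene panel; '#' comments allowed."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    if not symbols:
        raise InputError(f"{path}: gene panel file contains no symbols")
    return GenePanel.from_symbols(symbols)


# ---------------------------------------------------------------------------
# annotation side-car tables


def _split_set(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    parts = re.split(r"[;,]", str(cell))
    return frozenset(p.strip() for p in parts if p.strip() and p.strip() != "-")


class AnnotationStore:
    """Joined side-car annotation tables, keyed by rsid or gene:protein_change.

    Answers lookups for MAFs, ClinVar categories, predictor scores and
    regulatory/QTL features; records unmatched lookup keys for reporting.
    """

    def __init__(self) -> None:
        self._variants: dict = {}
        self._scores: dict = {}
        self._regulatory: dict = {}
        self.unmatched: set = set()

    # -- lookups ----------------------------------------------------------
    def maf(self, key: VariantKey):
        row = self._variants.get(key)
        if row is None:
            self.unmatched.add(key)
            return None, None
        return row.get("maf_gnomad3"), row.get("maf_1000g")

    def clinvar(self, key: VariantKey) -> frozenset:
        row = self._variants.get(key)
        if row is None or not row.get("clinvar"):
            return frozenset({ClinVarCategory.NR})
        return frozenset(ClinVarCategory(c) for c in row["clinvar"])

    def novel(self, key: VariantKey) -> bool:
        row = self._variants.get(key)
        return bool(row and row.get("novel"))

    def predictor_scores(self, key: VariantKey) -> dict:
        return dict(self._scores.get(key, {}))

    def regulatory(self, key: VariantKey) -> RegulatoryAnnotation:
        return self._regulatory.get(
            key, RegulatoryAnnotation(key=key, **_EMPTY_REGULATORY_FIELDS)
        )

    def score_keys(self) -> list:
        return sorted(self._scores)

    # -- construction -----------------------------------------------------
    @staticmethod
    def _row_key(row: Mapping) -> VariantKey:
        rsid = row.get("rsid")
        if rsid and not pd.isna(rsid) and str(rsid).strip() not in ("", "-"):
            return str(rsid).strip()
        gene = str(row.get("gene", "")).strip()
        change = _norm_protein_change(str(row.get("protein_change", "")).strip())
        if not gene or not change:
            raise InputError(f"annotation row lacks rsid and gene/protein_change: {dict(row)}")
        return f"{gene}:{change}"

    def _insert(self, table: dict, key: VariantKey, value, table_name: str) -> None:
        if key in table and table[key] != value:
            raise InputError(
                f"{table_name}: conflicting duplicate rows for key {key}: "
                f"{table[key]!r} vs {value!r}"
            )
        table[key] = value

    def add_variant_table(self, df: pd.DataFrame, name: str = "variants") -> None:
        for _, row in df.iterrows():
            key = self._row_key(row)
            value = {
                "maf_gnomad3": _opt_float(row.get("maf_gnomad3")),
                "maf_1000g": _opt_float(row.get("maf_1000g")),
                "clinvar": tuple(sorted(_split_set(row.get("clinvar")))),
                "novel": _truthy(row.get("novel")),
            }
            self._insert(self._variants, key, value, name)

    def add_score_table(self, df: pd.DataFrame, name: str = "scores") -> None:
        meta = {"gene", "protein_change", "rsid"}
        tool_cols = [c for c in df.columns if c not in meta]
        for _, row in df.iterrows():
            key = self._row_key(row)
            value = {
                tool: float(row[tool])
                for tool in tool_cols
                if not pd.isna(row[tool])
            }
            self._insert(self._scores, key, value, name)

    def add_regulatory_table(self, df: pd.DataFrame, name: str = "regulatory") -> None:
        for _, row in df.iterrows():
            key = self._row_key(row)
            value = RegulatoryAnnotation(
                key=key,
                region_features=_split_set(row.get("region_features")),
                splicing_predictions=_split_set(row.get("splicing_predictions"))
                - {"none"},
                eqtl_genes=_split_set(row.get("eqtl_genes")),
                sqtl_genes=_split_set(row.get("sqtl_genes")),
            )
            self._insert(self._regulatory, key, value, name)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, str) and value.strip() in ("", "-")):
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    return float(value)


def _truthy(value) -> bool:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return False
    return str(value).strip().lower() in ("1", "true", "yes")


def read_annotation_tables(
    variants: Union[str, Path, None] = None,
    scores: Union[str, Path, None] = None,
    regulatory: Union[str, Path, None] = None,
) -> AnnotationStore:
    """Load side-car TSV tables into one joined :class:`AnnotationStore`.

    Rows are keyed by rsid when present, else by (gene, protein_change).
    Identical duplicate rows are collapsed; conflicting duplicates are fatal.
    """
    store = AnnotationStore()
    if variants is not None:
        store.add_variant_table(pd.read_csv(variants, sep="\t", dtype=str))
    if scores is not None:
        store.add_score_table(pd.read_csv(scores, sep="\t"))
    if regulatory is not None:
        store.add_regulatory_table(pd.read_csv(regulatory, sep="\t", dtype=str))
    return store


# ---------------------------------------------------------------------------
# VCF


def read_vcf(
    path: Union[str, Path],
    pedigree: Pedigree,
    annotations: Optional[AnnotationStore] = None,
) -> list:
    """Read a multi-sample VCF into :class:`VariantRecord` objects.

    One record is produced per alternate allele per site (multiallelic sites
    are split).  Gene/consequence come from the GENE/CONSEQ INFO keys or the
    side-car annotation store; MAF/ClinVar/novel flags come from the store.
    A pedigree member without a sample column is fatal; an unparsable
    genotype is set to missing with a warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [m for m in pedigree.ids if m not in samples]
    if missing:
        raise InputError(
            f"{path}: pedigree member(s) without VCF sample column: "
            + ", ".join(missing)
        )
    sample_idx = {m: samples.index(m) for m in pedigree.ids}

    records = []
    for site in vcf:
        alts = site.ALT or []
        gts = site.genotypes  # [[a0, a1, phased], ...]
        for alt_no, alt in enumerate(alts, start=1):
            genotypes = {}
            for member, idx in sample_idx.items():
                try:
                    a0, a1 = gts[idx][0], gts[idx][1]
                except (IndexError, TypeError):
                    warnings.warn(
                        f"{path}: unparsable genotype for {member} at "
                        f"{site.CHROM}:{site.POS}; set to missing"
                    )
                    genotypes[member] = Genotype.MISSING
                    continue
                if a0 < 0 or a1 < 0:
                    genotypes[member] = Genotype.MISSING
                else:
                    n_alt = int(a0 == alt_no) + int(a1 == alt_no)
                    genotypes[member] = (
                        Genotype.HOM_REF,
                        Genotype.HET,
                        Genotype.HOM_ALT,
                    )[n_alt]

            info = dict(site.INFO)
            gene = info.get("GENE")
            conseq = info.get("CONSEQ")
            rsid = site.ID if site.ID and site.ID != "." else None
            record = VariantRecord(
                chrom=site.CHROM,
                pos=site.POS,
                ref=site.REF,
                alt=alt,
                gene=gene or "",
                consequence=Consequence(conseq) if conseq else None,
                rsid=rsid,
                cdna_change=info.get("CDNA"),
                protein_change=info.get("PCHANGE"),
                qual=site.QUAL,
                novel=rsid is None,
                genotypes=genotypes,
            )
            if annotations is not None:
                mg, mk = annotations.maf(record.key)
                record = replace(
                    record,
                    maf_gnomad3=mg,
                    maf_1000g=mk,
                    clinvar=annotations.clinvar(record.key),
                    novel=record.novel or annotations.novel(record.key),
                )
            if not record.gene:
                raise InputError(
                    f"{path}: no gene symbol for {record.chrom}:{record.pos} "
                    f"{record.ref}>{record.alt} (INFO/GENE or side-car required)"
                )
            records.append(record)
    return records


_GT_FIELD = {
    Genotype.HOM_REF: "0/0",
    Genotype.HET: "0/1",
    Genotype.HOM_ALT: "1/1",
    Genotype.MISSING: "./.",
}


def write_vcf(
    records: Sequence[VariantRecord],
    pedigree: Pedigree,
    path: Union[str, Path],
) -> None:
    """Write records as a biallelic multi-sample VCF 4.2 file."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Coding consequence">',
        '##INFO=<ID=CDNA,Number=1,Type=String,Description="cDNA change">',
        '##INFO=<ID=PCHANGE,Number=1,Type=String,Description="Protein change">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in sorted({r.chrom for r in records}, key=_chrom_sort_key):
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(pedigree.ids)
    lines.append("\t".join(header))
    for rec in records:
        info = [f"GENE={rec.gene}"]
        if rec.consequence:
            info.append(f"CONSEQ={rec.consequence.value}")
        if rec.cdna_change:
            info.append("CDNA=" + rec.cdna_change.replace(" ", ""))
        if rec.protein_change:
            info.append(f"PCHANGE={rec.protein_change}")
        row = [
            rec.chrom,
            str(rec.pos),
            rec.rsid or ".",
            rec.ref,
            rec.alt,
            "." if rec.qual is None else f"{rec.qual:g}",
            "PASS",
            ";".join(info),
            "GT",
        ]
        for member in pedigree.ids:
            row.append(_GT_FIELD[rec.genotypes.get(member, Genotype.MISSING)])
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def _chrom_sort_key(chrom: str):
    c = chrom.removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)
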