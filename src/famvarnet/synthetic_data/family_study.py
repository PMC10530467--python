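"""Packaged six-member thrombophilia family dataset.

A 2-3 generation family (founder I1; brothers II2/II3; married-in II1;
propositus III2 and sibling III1; affected: II2, II3, III2) with 22
low-frequency candidate-panel variants plus higher-frequency and distractor
records, predictor score/category data, regulatory and QTL annotations, and
a mini interaction/term database.  Genomic coordinates and raw predictor
scores are synthetic placeholders chosen to be consistent with the
documented per-variant categories, carrier sets and frequencies; they are
labeled as such in the materialized files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from ..interaction import EdgeDB, Term, TermDB
from ..prioritization import DEFAULT_TOOLS, PredictionMatrix, ToolCutoff
from ..variant_io import (
    AnnotationStore,
    ClinVarCategory,
    Consequence,
    GenePanel,
    Genotype,
    Member,
    Pedigree,
    VariantRecord,
)

__all__ = ["FamilyStudyBundle", "load_family_study", "write_family_study", "PANEL_GENES"]

# 192 candidate genes: hemostasis, platelet biology, inflammation and
# VTE-associated loci.  Count is asserted in tests.
PANEL_GENES = tuple(
    """
    F2 F3 F5 F7 F8 F9 F10 F11 F12 F13A1 F13B FGA FGB FGG VWF
    PROC PROS1 PROZ PROCR SERPINC1 SERPIND1 SERPINA1 SERPINA5 SERPINB2 SERPINE1 SERPINF2
    PLAT PLAU PLAUR PLG THBD TFPI KNG1 KLKB1 KLK13 CPB2 HRG HABP2 GGCX VKORC1
    GP1BA GP1BB GP5 GP6 GP9 ITGA2 ITGA2B ITGB3 PEAR1 P2RY1 P2RY12 TBXA2R TBXAS1
    PTGIS PTGS1 PTGS2 SELP SELE SELL PECAM1 CD36 MPL THPO NBEAL2 ANO6 RASGRP2 STIM1 ORAI1 PLA2G4A
    CRP IL1A IL1B IL1RN IL6 IL6R IL10 IL18 TNF TLR4 CD40 CD40LG SAA1 SAA2 SAA4 MBL2
    C3 C5 CFH ICAM1 VCAM1 NLRP3 MIF CCL2 CXCL8 IL4 IL13 IFNG STAT3 JAK2 NFKB1 PLCG2
    ABO FUT2 TSPAN15 SLC44A2 STXBP5 STX2 VAMP8 KIF26B TMCO1 PSG8 ARID4A NCOA1 UGT1A3
    NQO1 LMOD1 MAST2 SLC4A1 APOH KLK8 KLK11 MPHOSPH9 TC2N ZFPM2 GRK5 OTUD7A
    ANXA2 ANXA5 S100A10 LPA APOE APOB APOA1 LDLR PCSK9 LIPC LPL
    NOS3 EDN1 VEGFA KDR FLT1 ANGPT1 ANGPT2 TEK TIE1 CDH5 THBS1 THBS2
    ADAMTS13 ADAMTS1 MMP2 MMP9 TIMP1 TIMP2 MTHFR MTR MTRR CBS
    HNF4A HNF1A GATA1 GATA2 RUNX1 FLI1 ETV6 NFE2 ZFPM1 MYH9 TUBB1 ITGA6
    HIF1A EPAS1 EPO EPOR HBB VWA1 EMILIN1 FN1 COL18A1 LRP8 SCARA5 DNAJB4
    HPSE PON1 GPX3 SOD1 ALOX12 ALOX5 PTGER3 EPHB4 SH2B3
    """.split()
)

MEMBERS = ("I1", "II1", "II2", "II3", "III1", "III2")
AFFECTED = ("II2", "II3", "III2")

# gene, chrom, pos, ref, alt, rsid, cdna, protein_change, consequence,
# maf_gnomad3, clinvar, het carriers, hom_alt carriers, qual
# The 22 filter-passing low-frequency records come first.
_LOW_FREQ = [
    ("ARID4A", "14", 58100100, "C", "T", "rs146509016", "c.8C>T", "Ala3Val",
     "missense", 4.18819e-5, "NR", ("II1", "III1", "III2"), (), 72),
    ("ARID4A", "14", 58120200, "G", "C", "rs1051029502", "c.2847G>C", "Met949Ile",
     "missense", 6.97876e-6, "NR", ("I1", "II3"), (), 68),
    ("CRP", "1", 159712300, "T", "C", "rs1376711485", "c.182T>C", "Leu61Pro",
     "missense", 6.98295e-6, "NR", ("I1", "II2", "II3", "III1", "III2"), (), 85),
    ("F2", "11", 46750400, "C", "A", "rs199772906", "c.1542C>A", "Asn514Lys",
     "missense", 0.000244325, "NR", ("I1", "II2", "II3", "III2"), (), 90),
    ("JAK2", "9", 4985500, "C", "G", "rs2230723", "c.1177C>G", "Leu393Val",
     "missense", 0.0134624, "B", ("I1", "II2", "II3", "III2"), (), 88),
    ("KLK13", "19", 51050600, "C", "T", "rs34089525", "c.325C>T", "His109Tyr",
     "missense", 0.0217616, "NR", ("II2", "II3", "III1"), (), 77),
    ("NCOA1", "2", 24700700, "A", "G", "rs150066931", "c.3995A>G", "Asn1332Ser",
     "missense", 0.0015095, "NR", ("I1", "II3"), (), 66),
    ("NQO1", "16", 69740800, "C", "T", "rs1131341", "c.415C>T", "Arg139Trp",
     "missense", 0.0255606, "NR", ("I1", "II2", "II3", "III2"), (), 92),
    ("PEAR1", "1", 156890900, "C", "T", "rs77795865", "c.1142C>T", "Ser381Phe",
     "missense", 0.0230726, "NR", ("II2", "II3"), (), 81),
    ("PLAT", "8", 42175000, "C", "T", "rs2020921", "c.490C>T", "Arg164Trp",
     "missense", 0.012879, "NR", ("II3",), (), 86),
    ("PSG8", "19", 43260100, "G", "C", None, "c.26G>C", "Cys9Ser",
     "missense", None, "NR", ("I1", "II2", "II3", "III1", "III2"), (), 74),
    ("SAA2", "11", 18240200, "A", "C", "rs138605229", "c.222A>C", "Glu74Asp",
     "missense", 0.00552043, "NR", ("II1", "III1", "III2"), (), 70),
    ("SERPINA1", "14", 94380300, "C", "T", "rs28931570", "c.187C>T", "Arg63Cys",
     "missense", 0.00151399, "P;LP", ("II2", "III1", "III2"), (), 89),
    ("THBS1", "15", 39580400, "T", "A", None, "c.2703T>A", "Asp901Glu",
     "missense", None, "NR", ("I1", "II2", "III2"), (), 79),
    ("UGT1A3", "2", 233760500, "G", "T", "rs146461519", "c.736G>T", "Val246Leu",
     "missense", 0.00043999, "NR", ("II3",), (), 65),
    ("VWF", "12", 6120600, "G", "A", "rs1800382", "c.4196G>A", "Arg1399His",
     "missense", 0.00895051, "B;LB;LP;P", ("II3",), (), 91),
    # synonymous
    ("KIF26B", "1", 245320700, "C", "T", "rs201717788", "c.507C>T", "Val169=",
     "synonymous", 0.00295131, "NR", ("II1", "III1", "III2"), (), 71),
    ("MPL", "1", 43340800, "G", "A", "rs544064034", "c.1242G>A", "Ser414=",
     "synonymous", 6.98227e-6, "LB", ("II2", "II3", "III2"), (), 83),
    ("PLCG2", "16", 81880900, "T", "C", "rs138637229", "c.1146T>C", "Phe382=",
     "synonymous", 0.0071625, "B;LB", ("II2",), (), 76),
    ("PTGIS", "20", 49510100, "C", "T", "rs61322884", "c.531C>T", "Tyr177=",
     "synonymous", 0.0221135, "NR", ("II3",), (), 69),
    ("SERPIND1", "22", 20770200, "G", "A", "rs35646566", "c.423G>A", "Leu141=",
     "synonymous", 0.0173203, "NR", ("I1", "II3"), (), 80),
    ("TMCO1", "1", 165720300, "C", "T", "rs78363884", "c.486C>T", "Leu162=",
     "synonymous", 0.033832, "B", ("II2",), (), 73),
]

# Higher-frequency functional variants, linkage partners and distractors.
_DISTRACTORS = [
    ("FGB", "4", 154567800, "G", "A", "rs4220", "c.1433G>A", "Arg478Lys",
     "missense", 0.20, "B", ("II1", "II2", "II3", "III2"), (), 95),
    ("IL1A", "2", 112785300, "G", "T", "rs17561", "c.340G>T", "Ala114Ser",
     "missense", 0.30, "B", ("I1",), ("III2",), 93),
    ("PSG8", "19", 43260900, "G", "A", "rs7251234", "c.256G>A", "Gly86Ser",
     "missense", 0.15, "NR", ("II1", "III2"), (), 82),
    ("PSG8", "19", 43261000, "T", "G", "rs7251299", "c.263T>G", "Ile88Arg",
     "missense", 0.12, "NR", ("III2",), (), 78),
    ("THBS1", "15", 39578000, "A", "G", "rs2228261", "c.1567A>G", "Thr523Ala",
     "missense", 0.08, "NR", ("II2", "III2"), (), 84),
    ("THBS1", "15", 39579100, "A", "G", "rs2228262", "c.2099A>G", "Asn700Ser",
     "missense", 0.09, "NR", ("II2", "III2"), (), 87),
    ("SERPINA1", "14", 94381200, "G", "A", "rs709932", "c.374G>A", "Arg125His",
     "missense", 0.05, "NR", ("II2", "III2"), (), 75),
    ("SERPINA1", "14", 94382500, "G", "C", "rs1303", "c.1200G>C", "Glu400Asp",
     "missense", 0.06, "NR", ("II2", "III2"), (), 94),
    ("VWF", "12", 6121500, "G", "C", "rs1800383", "c.4414G>C", "Asp1472His",
     "missense", 0.10, "NR", ("II3",), (), 88),
    ("LMOD1", "1", 201865100, "A", "G", "rs2820312", "c.32A>G", "Val11Ala",
     "missense", 0.40, "NR", ("I1",), ("II2", "II3", "III2"), 90),
    ("KNG1", "3", 186435200, "A", "G", "rs2304456", "c.591A>G", "Ile197Met",
     "missense", 0.05, "NR", ("III2",), (), 81),
    # fails the quality filter
    ("PROC", "2", 128180300, "C", "T", "rs199999001", "c.565C>T", "Arg189Trp",
     "missense", 0.0005, "NR", ("II3",), (), 20),
    # gene not on the candidate panel
    ("TTN", "2", 179400500, "G", "A", "rs371000001", "c.100G>A", "Ala34Thr",
     "missense", 0.001, "NR", ("II2",), (), 80),
    # heterozygous only in unaffected members
    ("PROS1", "3", 93595400, "C", "T", "rs143999002", "c.200C>T", "Ser67Phe",
     "missense", 0.0005, "NR", ("II1", "III1"), (), 80),
]

# Regulatory / QTL annotations keyed by rsid.
_REGULATORY = {
    "rs146509016": dict(region_features="splice_region",
                        splicing_predictions="ESE_disruption"),
    "rs1051029502": dict(splicing_predictions="ESE_disruption"),
    "rs199772906": dict(splicing_predictions="ESE_disruption"),
    "rs2230723": dict(splicing_predictions="new_ESS;ESE_disruption;new_donor"),
    "rs34089525": dict(splicing_predictions="new_ESS", eqtl_genes="IGLON5"),
    "rs544064034": dict(region_features="enhancer", splicing_predictions="none"),
    "rs150066931": dict(splicing_predictions="ESE_disruption"),
    "rs1131341": dict(region_features="splice_region;open_chromatin",
                      splicing_predictions="donor_disruption",
                      eqtl_genes="NOB1;COG4;PDXDC2P",
                      sqtl_genes="NQO1;NOB1;NPIPB14P"),
    "rs77795865": dict(splicing_predictions="none", eqtl_genes="LRRC71"),
    "rs2020921": dict(splicing_predictions="new_ESE;new_donor",
                      eqtl_genes="PLAT;POLB;AP3M2",
                      sqtl_genes="SLC20A2;POLB"),
    "rs138605229": dict(splicing_predictions="ESE_disruption"),
    "rs146461519": dict(splicing_predictions="new_donor"),
    "rs138637229": dict(region_features="CTCF_site", splicing_predictions="new_ESS"),
    "rs61322884": dict(splicing_predictions="ESE_disruption", eqtl_genes="SLC9A8"),
    "rs35646566": dict(region_features="enhancer",
                       splicing_predictions="ESE_disruption",
                       eqtl_genes="AC000089.3"),
    "rs78363884": dict(splicing_predictions="new_ESS", eqtl_genes="RP11-466F5.10"),
}

# REVEL ordering of the 16 low-frequency missense variants and the number of
# tools calling each damaging (out of 15).
_REVEL_AND_VOTES = [
    ("rs1376711485", 0.95, 14),  # CRP Leu61Pro
    ("rs199772906", 0.92, 13),   # F2 Asn514Lys
    ("rs28931570", 0.90, 13),    # SERPINA1 Arg63Cys
    ("THBS1:Asp901Glu", 0.88, 12),
    ("rs1800382", 0.86, 12),     # VWF Arg1399His
    ("rs146509016", 0.72, 10),   # ARID4A Ala3Val
    ("rs1051029502", 0.68, 9),   # ARID4A Met949Ile
    ("rs150066931", 0.61, 8),    # NCOA1 Asn1332Ser
    ("rs146461519", 0.48, 2),    # UGT1A3 Val246Leu
    ("rs2230723", 0.45, 2),      # JAK2 Leu393Val
    ("rs138605229", 0.42, 2),    # SAA2 Glu74Asp
    ("PSG8:Cys9Ser", 0.40, 2),
    ("rs77795865", 0.35, 6),     # PEAR1 Ser381Phe
    ("rs2020921", 0.30, 7),      # PLAT Arg164Trp
    ("rs34089525", 0.22, 5),     # KLK13 His109Tyr
    ("rs1131341", 0.18, 4),      # NQO1 Arg139Trp
]

# Order in which non-REVEL tools join the damaging set as votes grow; the
# first two (SIFT, PhD-SNPg) call nearly every variant damaging.
_VOTE_FILL_ORDER = (
    "SIFT", "PhD-SNPg", "FATHMM-XF", "LRT", "MutationTaster", "PROVEAN",
    "PolyPhen-2", "MutationAssessor", "ClinPred", "DANNCoding", "MetaSVM",
    "VEST4", "MetaLR", "CADD",
)

# protein_a, protein_b, channel, score — combines (prior 0.041) into the
# documented confidence tiers.
_EDGES = [
    ("CRP", "F2", "experimental", 0.62),
    ("CRP", "F2", "database", 0.70),
    ("CRP", "F2", "coexpression", 0.40),
    ("F2", "FGB", "experimental", 0.85),
    ("F2", "FGB", "database", 0.90),
    ("F2", "VWF", "experimental", 0.80),
    ("F2", "VWF", "database", 0.80),
    ("F2", "VWF", "coexpression", 0.30),
    ("PLAT", "VWF", "experimental", 0.75),
    ("PLAT", "VWF", "database", 0.85),
    ("FGB", "THBS1", "experimental", 0.60),
    ("FGB", "THBS1", "coexpression", 0.45),
    ("FGB", "SERPINA1", "experimental", 0.55),
    ("FGB", "SERPINA1", "database", 0.50),
    ("FGB", "VWF", "experimental", 0.70),
    ("FGB", "VWF", "coexpression", 0.35),
    ("CRP", "FGB", "experimental", 0.50),
    ("CRP", "FGB", "database", 0.55),
    ("CRP", "FGB", "cooccurrence", 0.20),
    ("F2", "SERPINA1", "experimental", 0.72),
    ("F2", "SERPINA1", "coexpression", 0.25),
    ("CRP", "VWF", "experimental", 0.65),
    ("CRP", "VWF", "database", 0.40),
    ("CRP", "IL1A", "experimental", 0.60),
    ("CRP", "IL1A", "database", 0.45),
    ("CRP", "IL1A", "coexpression", 0.20),
    ("CRP", "SERPINA1", "experimental", 0.50),
    ("F2", "PLAT", "database", 0.50),
    ("IL1A", "SERPINA1", "coexpression", 0.45),
    ("CRP", "THBS1", "coexpression", 0.20),
    ("F2", "THBS1", "coexpression", 0.30),
    ("FGB", "IL1A", "cooccurrence", 0.18),
]

_TERMS = [
    ("GO:0006953", "acute phase response",
     "CRP F2 SERPINA1 IL1A SAA1 SAA2 MBL2 C3"),
    ("KW-0011", "Acute phase", "CRP F2 SERPINA1 IL1A SAA1 SAA2"),
    ("GOCC:0005577", "fibrinogen complex", "CRP F2 PLAT THBS1 VWF FGB"),
    ("GO:0007596", "blood coagulation",
     "F2 F5 F7 F8 F9 F10 VWF PLAT PROC PROS1 SERPINC1 FGB FGA FGG KNG1 THBD"),
    ("GO:0030168", "platelet activation",
     "PEAR1 THBS1 VWF F2 GP1BA GP6 ITGA2B ITGB3 P2RY12"),
]

NETWORK_ELIGIBLE = frozenset({"CRP", "F2", "SERPINA1", "THBS1", "VWF", "PLAT"})
EXTRA_INCLUDES = {
    "II2": frozenset({"FGB"}),
    "II3": frozenset({"FGB"}),
    "III2": frozenset({"FGB", "IL1A"}),
}
MANUAL_INCLUDES = ("rs4220", "rs17561")  # FGB Arg478Lys, IL1A Ala114Ser
PRIOR = 0.041


@dataclass
class FamilyStudyBundle:
    pedigree: Pedigree
    panel: GenePanel
    records: List[VariantRecord]
    annotations: AnnotationStore
    prediction_matrix: PredictionMatrix
    edge_db: EdgeDB
    term_db: TermDB
    network_eligible: frozenset = NETWORK_ELIGIBLE
    extra_includes: dict = None
    manual_includes: tuple = MANUAL_INCLUDES
    prior: float = PRIOR

    def __post_init__(self):
        if self.extra_includes is None:
            self.extra_includes = {k: set(v) for k, v in EXTRA_INCLUDES.items()}


def _pedigree() -> Pedigree:
    return Pedigree(
        [
            Member("I1", "male", False),
            Member("II1", "female", False),
            Member("II2", "male", True, father="I1"),
            Member("II3", "male", True, father="I1"),
            Member("III1", "female", False, father="II2", mother="II1"),
            Member("III2", "male", True, father="II2", mother="II1"),
        ]
    )


def _records() -> List[VariantRecord]:
    records = []
    for (gene, chrom, pos, ref, alt, rsid, cdna, pchange, conseq, maf, clinvar,
         het, hom, qual) in _LOW_FREQ + _DISTRACTORS:
        genotypes = {m: Genotype.HOM_REF for m in MEMBERS}
        genotypes.update({m: Genotype.HET for m in het})
        genotypes.update({m: Genotype.HOM_ALT for m in hom})
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                gene=gene,
                consequence=Consequence(conseq),
                rsid=rsid,
                cdna_change=cdna,
                protein_change=pchange,
                maf_gnomad3=maf,
                qual=float(qual),
                clinvar=frozenset(
                    ClinVarCategory(c) for c in clinvar.split(";")
                ),
                novel=rsid is None,
                genotypes=genotypes,
            )
        )
    return records


def _score_frame() -> pd.DataFrame:
    """Synthetic probability scores consistent with the vote/rank structure."""
    rng = np.random.default_rng(13809)
    rows = []
    for rank_pos, (key, revel, votes) in enumerate(_REVEL_AND_VOTES, start=1):
        damaging = set(_VOTE_FILL_ORDER[: votes - 1]) | {"REVEL"} \
            if rank_pos <= 8 else set(_VOTE_FILL_ORDER[:votes])
        row = {"key": key}
        for tool in DEFAULT_TOOLS:
            if tool == "REVEL":
                row[tool] = revel
            elif tool in damaging:
                row[tool] = round(float(rng.uniform(0.55, 0.98)), 4)
            else:
                row[tool] = round(float(rng.uniform(0.02, 0.45)), 4)
        rows.append(row)
    return pd.DataFrame(rows)


def _prediction_matrix() -> PredictionMatrix:
    cutoffs = {tool: ToolCutoff(damaging_min=0.5, neutral_max=0.25)
               for tool in DEFAULT_TOOLS}
    return PredictionMatrix.from_table(_score_frame(), cutoffs=cutoffs)


def _annotation_frames(records):
    variant_rows, regulatory_rows = [], []
    for rec in records:
        variant_rows.append(
            {
                "gene": rec.gene,
                "protein_change": rec.protein_change,
                "rsid": rec.rsid or "-",
                "maf_gnomad3": "" if rec.maf_gnomad3 is None else repr(rec.maf_gnomad3),
                "maf_1000g": "",
                "clinvar": ";".join(sorted(c.value for c in rec.clinvar)),
                "novel": "true" if rec.novel else "false",
            }
        )
        reg = _REGULATORY.get(rec.key)
        if reg is not None:
            regulatory_rows.append(
                {
                    "gene": rec.gene,
                    "protein_change": rec.protein_change,
                    "rsid": rec.rsid or "-",
                    "region_features": reg.get("region_features", ""),
                    "splicing_predictions": reg.get("splicing_predictions", ""),
                    "eqtl_genes": reg.get("eqtl_genes", ""),
                    "sqtl_genes": reg.get("sqtl_genes", ""),
                }
            )
    return pd.DataFrame(variant_rows), pd.DataFrame(regulatory_rows)


def _annotation_store(records) -> AnnotationStore:
    store = AnnotationStore()
    variants, regulatory = _annotation_frames(records)
    store.add_variant_table(variants)
    store.add_regulatory_table(regulatory)
    scores = _score_frame().rename(columns={"key": "rsid"})
    # score keys are rsids or gene:protein_change composites; split them back
    scores["gene"] = ""
    scores["protein_change"] = ""
    composite = scores["rsid"].str.contains(":")
    scores.loc[composite, "gene"] = scores.loc[composite, "rsid"].str.split(":").str[0]
    scores.loc[composite, "protein_change"] = (
        scores.loc[composite, "rsid"].str.split(":").str[1]
    )
    scores.loc[composite, "rsid"] = None
    store.add_score_table(scores)
    return store


def _edge_db() -> EdgeDB:
    db = EdgeDB(prior=PRIOR)
    for a, b, channel, score in _EDGES:
        db.add(a, b, channel, score)
    return db


def _term_db() -> TermDB:
    terms = [
        Term(
            term_id=tid,
            label=label,
            category=TermDB.category_for(tid),
            genes=frozenset(genes.split()),
        )
        for tid, label, genes in _TERMS
    ]
    return TermDB(terms, background=set(PANEL_GENES))


def load_family_study() -> FamilyStudyBundle:
    """Build the packaged family-study dataset fully in memory."""
    records = _records()
    return FamilyStudyBundle(
        pedigree=_pedigree(),
        panel=GenePanel.from_symbols(PANEL_GENES),
        records=records,
        annotations=_annotation_store(records),
        prediction_matrix=_prediction_matrix(),
        edge_db=_edge_db(),
        term_db=_term_db(),
    )


def write_family_study(out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Materialize the dataset as plain-text files plus a run config."""
    from ..variant_io import write_vcf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = load_family_study()

    paths = {
        "ped": out / "family.ped",
        "vcf": out / "family.vcf",
        "panel": out / "panel.txt",
        "variants": out / "variants.tsv",
        "scores": out / "scores.tsv",
        "regulatory": out / "regulatory.tsv",
        "edges": out / "edges.tsv",
        "terms": out / "terms.gmt",
        "background": out / "background.txt",
        "config": out / "run.yaml",
    }

    ped_lines = []
    for m in bundle.pedigree.members:
        sex = {"male": "1", "female": "2"}.get(m.sex, "0")
        status = "2" if m.affected else "1"
        ped_lines.append(
            f"FAM1 {m.id} {m.father or 0} {m.mother or 0} {sex} {status}"
        )
    paths["ped"].write_text("\n".join(ped_lines) + "\n")

    write_vcf(
        sorted(bundle.records, key=lambda r: (r.chrom, r.pos)),
        bundle.pedigree,
        paths["vcf"],
    )
    paths["panel"].write_text(
        "# candidate gene panel (n=192)\n" + "\n".join(PANEL_GENES) + "\n"
    )
    variants, regulatory = _annotation_frames(bundle.records)
    variants.to_csv(paths["variants"], sep="\t", index=False)
    regulatory.to_csv(paths["regulatory"], sep="\t", index=False)

    scores = _score_frame().rename(columns={"key": "rsid"})
    scores.insert(0, "gene", "")
    scores.insert(1, "protein_change", "")
    composite = scores["rsid"].str.contains(":")
    scores.loc[composite, "gene"] = scores.loc[composite, "rsid"].str.split(":").str[0]
    scores.loc[composite, "protein_change"] = (
        scores.loc[composite, "rsid"].str.split(":").str[1]
    )
    scores.loc[composite, "rsid"] = "-"
    scores.to_csv(paths["scores"], sep="\t", index=False)

    edge_lines = ["protein_a\tprotein_b\tchannel\tscore"]
    for a, b, channel, score in _EDGES:
        a, b = sorted((a, b))
        edge_lines.append(f"{a}\t{b}\t{channel}\t{score}")
    paths["edges"].write_text("\n".join(edge_lines) + "\n")

    gmt_lines = ["\t".join([tid, label] + genes.split()) for tid, label, genes in _TERMS]
    paths["terms"].write_text("\n".join(gmt_lines) + "\n")
    paths["background"].write_text("\n".join(PANEL_GENES) + "\n")

    config = {
        "paths": {
            "vcf": "family.vcf",
            "ped": "family.ped",
            "panel": "panel.txt",
            "variants_table": "variants.tsv",
            "scores_table": "scores.tsv",
            "regulatory_table": "regulatory.tsv",
            "edge_db": "edges.tsv",
            "term_db": "terms.gmt",
            "background": "background.txt",
        },
        "thresholds": {
            "maf_max": 0.04,
            "qual_min": 30,
            "votes_min": 4,
            "affected_min": 2,
            "protected_rank_max": 8,
            "prior": PRIOR,
            "tier_bounds": [0.15, 0.4, 0.7, 0.9],
        },
        "manual_includes": list(MANUAL_INCLUDES),
        "network_eligible": sorted(NETWORK_ELIGIBLE),
        "extra_includes": {k: sorted(v) for k, v in EXTRA_INCLUDES.items()},
        "out_dir": "results",
        "seed": 0,
    }
    import yaml

    paths["config"].write_text(yaml.safe_dump(config, sort_keys=True))
    return paths
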