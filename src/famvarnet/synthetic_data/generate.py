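"""Seeded synthetic-family generator with a ground-truth manifest.

Produces a pedigree, a multi-sample VCF, side-car annotation tables, a
predictor score matrix driven by a latent deleteriousness variable, and a
channelized edge list — all byte-reproducible for a given seed.  Planted
structure (shared-in-affected variants and compound-heterozygous pairs) is
listed in ``manifest.json`` so analyzers can be validated by round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Union

import numpy as np

from ..errors import ConfigError
from ..prioritization import DEFAULT_TOOLS
from ..variant_io import (
    Consequence,
    Genotype,
    Member,
    Pedigree,
    VariantRecord,
    write_vcf,
)

__all__ = ["SimulationConfig", "generate_family"]

_BASES = ("A", "C", "G", "T")
_CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "experimental",
    "database",
    "coexpression",
)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_members: int = 6
    n_affected: int = 3
    n_panel_genes: int = 30
    n_variants: int = 40
    # MAF mixture: point masses (value, weight) plus a uniform tail on
    # [0, maf_tail_max] carrying the remaining weight.
    maf_point_masses: tuple = ((0.0005, 0.3), (0.01, 0.2))
    maf_tail_max: float = 0.3
    p_shared_in_affected: float = 0.1
    n_compound_het_genes: int = 1
    p_synonymous: float = 0.25
    # latent "true deleteriousness" drives all tool scores; 1 = identical
    # scores across tools, 0 = independent noise.
    predictor_correlation: float = 0.8
    channel_beta: tuple = ((2.0, 4.0),) * len(_CHANNELS)
    n_edges: int = 25
    qual_range: tuple = (40.0, 99.0)
    prior: float = 0.041

    def __post_init__(self) -> None:
        for name in ("p_shared_in_affected", "predictor_correlation", "p_synonymous"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_affected > self.n_members:
            raise ConfigError("n_affected exceeds n_members")
        if self.n_members < 3:
            raise ConfigError("need at least 3 members")
        planted = self.n_shared + 2 * self.n_compound_het_genes
        if planted > self.n_variants:
            raise ConfigError(
                f"cannot plant {planted} variants into n_variants={self.n_variants}"
            )

    @property
    def n_shared(self) -> int:
        return int(round(self.p_shared_in_affected * self.n_variants))


def _make_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Three-generation template: founders I1/I2 and married-in II1; gen II
    children of I1+I2; gen III children of II1+II2."""
    remaining = config.n_members - 2
    n_gen2 = max(1, (remaining + 1) // 2)
    n_gen3 = remaining - n_gen2
    if n_gen3 > 0 and n_gen2 < 2:
        n_gen2, n_gen3 = 2, remaining - 2
    members = [Member("I1", "male"), Member("I2", "female")]
    members.append(Member("II1", "female"))  # married-in founder
    for i in range(2, n_gen2 + 1):
        members.append(Member(f"II{i}", None, father="I1", mother="I2"))
    for i in range(1, n_gen3 + 1):
        members.append(
            Member(f"III{i}", None, father="II2" if n_gen2 >= 2 else "I1",
                   mother="II1")
        )
    members = members[: config.n_members]
    candidates = [m.id for m in members if not m.id.startswith("I1")
                  and not m.id.startswith("I2")] or [m.id for m in members]
    if len(candidates) < config.n_affected:
        candidates = [m.id for m in members]
    affected = set(
        rng.choice(sorted(candidates), size=config.n_affected, replace=False)
    )
    return Pedigree(
        [
            Member(m.id, m.sex, m.id in affected, m.father, m.mother)
            for m in members
        ]
    )


def _sample_maf(config: SimulationConfig, rng: np.random.Generator) -> float:
    u = rng.uniform()
    acc = 0.0
    for value, weight in config.maf_point_masses:
        acc += weight
        if u < acc:
            return value
    return float(rng.uniform(0.0, config.maf_tail_max))


def _aa_change(i: int) -> str:
    return f"Ala{i + 1}Val"


def generate_family(
    config: SimulationConfig, out_dir: Union[str, Path]
) -> Dict[str, object]:
    """Write a complete synthetic input bundle; return paths and the manifest."""
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pedigree = _make_pedigree(config, rng)
    affected = pedigree.affected_ids
    members = pedigree.ids

    genes = [f"SG{i:03d}" for i in range(1, config.n_panel_genes + 1)]
    n_shared = config.n_shared
    compound_genes = genes[: config.n_compound_het_genes]

    records = []
    shared_keys, compound_truth = [], []
    variant_no = 0

    def new_record(gene, maf, conseq, genotypes, qual):
        nonlocal variant_no
        variant_no += 1
        chrom = str((variant_no % 22) + 1)
        ref, alt = rng.choice(_BASES, size=2, replace=False)
        return VariantRecord(
            chrom=chrom,
            pos=10_000 + 137 * variant_no,
            ref=str(ref),
            alt=str(alt),
            gene=gene,
            consequence=conseq,
            rsid=f"rs9{variant_no:06d}",
            protein_change=_aa_change(variant_no),
            maf_gnomad3=round(maf, 6),
            maf_1000g=round(maf, 6),
            qual=float(qual),
            genotypes=genotypes,
        )

    def background_genotypes(maf):
        p_het = min(0.6, 2.0 * maf + 0.05)
        gts = {}
        for m in members:
            u = rng.uniform()
            if u < p_het:
                gts[m] = Genotype.HET
            elif u < p_het + 0.02:
                gts[m] = Genotype.HOM_ALT
            else:
                gts[m] = Genotype.HOM_REF
        # keep planted shared variants unique: never all-affected carriers
        if len(affected) >= 2 and all(gts[a].carries_alt for a in affected):
            gts[affected[-1]] = Genotype.HOM_REF
        return gts

    # planted shared-in-affected variants
    for _ in range(n_shared):
        gene = str(rng.choice(genes[config.n_compound_het_genes:]))
        maf = float(rng.uniform(0.0001, 0.035))
        gts = {m: Genotype.HOM_REF for m in members}
        for a in affected:
            gts[a] = Genotype.HET
        for m in pedigree.unaffected_ids:
            if rng.uniform() < 0.25:
                gts[m] = Genotype.HET
        rec = new_record(gene, maf, Consequence.MISSENSE, gts,
                         rng.uniform(60.0, config.qual_range[1]))
        records.append(rec)
        shared_keys.append(rec.key)

    # planted compound-het pairs: two same-gene variants in one affected carrier
    for gene in compound_genes:
        carrier = str(rng.choice(affected))
        pair = []
        for _ in range(2):
            gts = {m: Genotype.HOM_REF for m in members}
            gts[carrier] = Genotype.HET
            for m in members:
                if m != carrier and rng.uniform() < 0.1:
                    gts[m] = Genotype.HET
            if len(affected) >= 2 and all(gts[a].carries_alt for a in affected):
                spoil = next(a for a in affected if a != carrier)
                gts[spoil] = Genotype.HOM_REF
            rec = new_record(gene, float(rng.uniform(0.0001, 0.035)),
                             Consequence.MISSENSE, gts,
                             rng.uniform(60.0, config.qual_range[1]))
            records.append(rec)
            pair.append(rec.key)
        compound_truth.append({"gene": gene, "variants": pair, "member": carrier})

    # background variants
    n_background = config.n_variants - len(records)
    for _ in range(n_background):
        gene = str(rng.choice(genes[config.n_compound_het_genes:]))
        maf = _sample_maf(config, rng)
        conseq = (
            Consequence.SYNONYMOUS
            if rng.uniform() < config.p_synonymous
            else Consequence.MISSENSE
        )
        records.append(
            new_record(gene, maf, conseq, background_genotypes(maf),
                       rng.uniform(*config.qual_range))
        )

    # predictor scores: latent deleteriousness + per-tool noise
    rho = config.predictor_correlation
    latent = {}
    score_rows = []
    for rec in records:
        if rec.consequence != Consequence.MISSENSE:
            continue
        d = float(rng.uniform())
        latent[rec.key] = round(d, 6)
        row = {"key": rec.key}
        for tool in DEFAULT_TOOLS:
            noise = float(rng.uniform())
            row[tool] = round(rho * d + (1.0 - rho) * noise, 6)
        score_rows.append(row)

    # channelized interaction evidence over random gene pairs
    edges = []
    pair_pool = [
        (genes[i], genes[j])
        for i in range(len(genes))
        for j in range(i + 1, len(genes))
    ]
    n_edges = min(config.n_edges, len(pair_pool))
    chosen = rng.choice(len(pair_pool), size=n_edges, replace=False)
    beta = dict(zip(_CHANNELS, config.channel_beta))
    for idx in sorted(chosen):
        a, b = pair_pool[idx]
        for channel in _CHANNELS:
            if rng.uniform() < 0.4:
                alpha, beta_p = beta[channel]
                raw = float(rng.beta(alpha, beta_p))
                score = config.prior + (1.0 - config.prior) * raw
                edges.append((a, b, channel, round(score, 6)))

    # ---- write files ----------------------------------------------------
    paths = {
        "ped": out / "family.ped",
        "vcf": out / "family.vcf",
        "panel": out / "panel.txt",
        "variants": out / "variants.tsv",
        "scores": out / "scores.tsv",
        "edges": out / "edges.tsv",
        "manifest": out / "manifest.json",
    }
    ped_lines = []
    for m in pedigree.members:
        sex = {"male": "1", "female": "2"}.get(m.sex, "0")
        ped_lines.append(
            f"SIM {m.id} {m.father or 0} {m.mother or 0} {sex} "
            f"{'2' if m.affected else '1'}"
        )
    paths["ped"].write_text("\n".join(ped_lines) + "\n")
    write_vcf(records, pedigree, paths["vcf"])
    paths["panel"].write_text("\n".join(genes) + "\n")

    variant_lines = ["gene\tprotein_change\trsid\tmaf_gnomad3\tmaf_1000g\tclinvar\tnovel"]
    for rec in records:
        variant_lines.append(
            "\t".join(
                [
                    rec.gene,
                    rec.protein_change,
                    rec.rsid,
                    f"{rec.maf_gnomad3:.6g}",
                    f"{rec.maf_1000g:.6g}",
                    "NR",
                    "false",
                ]
            )
        )
    paths["variants"].write_text("\n".join(variant_lines) + "\n")

    score_lines = ["\t".join(["key"] + list(DEFAULT_TOOLS))]
    for row in score_rows:
        score_lines.append(
            "\t".join([row["key"]] + [f"{row[t]:.6f}" for t in DEFAULT_TOOLS])
        )
    paths["scores"].write_text("\n".join(score_lines) + "\n")

    edge_lines = ["protein_a\tprotein_b\tchannel\tscore"]
    for a, b, channel, score in edges:
        edge_lines.append(f"{a}\t{b}\t{channel}\t{score:.6f}")
    paths["edges"].write_text("\n".join(edge_lines) + "\n")

    manifest = {
        "seed": config.seed,
        "n_members": config.n_members,
        "affected": affected,
        "n_variants": len(records),
        "shared_in_affected": sorted(shared_keys),
        "compound_het": compound_truth,
        "latent_deleteriousness": latent,
    }
    paths["manifest"].write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return {"paths": paths, "manifest": manifest, "pedigree": pedigree,
            "records": records}
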