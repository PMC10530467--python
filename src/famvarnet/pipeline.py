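"""Orchestrate filter -> segregation -> rank -> prioritize -> network ->
enrichment as one reproducible run with TSV/JSON outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .config import RunConfig
from .errors import FamvarnetError, PipelineError
from .family_filter import (
    affected_carrier_counts,
    apply_frequency_filter,
    carrier_matrix,
    count_missense_per_affected,
    linkage_groups,
    shared_in_affected,
    split_by_consequence,
)
from .interaction import (
    EdgeDB,
    TermDB,
    build_patient_network,
    build_patient_sets,
    enrich_terms,
)
from .prioritization import (
    PredictionMatrix,
    PrioritizationDecision,
    Status,
    export_heatmap_matrix,
    prioritize,
    rank_by_revel,
)
from .variant_io import (
    Consequence,
    read_annotation_tables,
    read_panel,
    read_ped,
    read_vcf,
)

logger = logging.getLogger(__name__)

STAGES = ("io", "filter", "rank", "prioritize", "network", "enrich")

__all__ = ["run_pipeline", "STAGES"]


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except FamvarnetError as exc:
                raise PipelineError(name, str(exc)) from exc

        return inner

    return wrap


def run_pipeline(config: RunConfig, stop_after: Optional[str] = None) -> dict:
    """Execute the pipeline; write per-stage outputs and a JSON summary.

    ``stop_after`` truncates the run after the named stage (for the
    per-stage CLI subcommands).  Returns the summary dictionary.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise PipelineError("config", f"unknown stage {stop_after!r}")
    try:
        config.validate_paths()
    except FamvarnetError as exc:
        raise PipelineError("config", str(exc)) from exc

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed, "thresholds": {
        "maf_max": config.maf_max,
        "qual_min": config.qual_min,
        "votes_min": config.votes_min,
        "affected_min": config.affected_min,
        "protected_rank_max": config.protected_rank_max,
        "prior": config.prior,
        "tier_bounds": list(config.tier_bounds),
    }}
    logger.info("famvarnet %s: thresholds %s", __version__, summary["thresholds"])

    # -- io ---------------------------------------------------------------
    @_stage("io")
    def stage_io():
        pedigree = read_ped(config.ped)
        panel = read_panel(config.panel)
        annotations = read_annotation_tables(
            variants=config.variants_table,
            scores=config.scores_table,
            regulatory=config.regulatory_table,
        )
        records = read_vcf(config.vcf, pedigree, annotations)
        return pedigree, panel, annotations, records

    pedigree, panel, annotations, records = stage_io()
    summary["n_members"] = len(pedigree.members)
    summary["n_affected"] = len(pedigree.affected_ids)
    summary["n_panel_genes"] = len(panel)
    summary["n_input_records"] = len(records)
    if stop_after == "io":
        return _finish(summary, out_dir)

    # -- filter -----------------------------------------------------------
    @_stage("filter")
    def stage_filter():
        filtered = apply_frequency_filter(
            records, panel, pedigree,
            maf_max=config.maf_max, qual_min=config.qual_min,
        )
        split = split_by_consequence(filtered)
        matrix = carrier_matrix(filtered, pedigree)
        full_matrix = carrier_matrix(records, pedigree)
        missense_matrix = carrier_matrix(split["missense"], pedigree)
        per_affected = count_missense_per_affected(missense_matrix, pedigree)
        shared = shared_in_affected(matrix, pedigree)
        groups = linkage_groups(records, full_matrix)
        _write_filtered(out_dir / "filtered_variants.tsv", filtered, matrix)
        return filtered, split, matrix, full_matrix, per_affected, shared, groups

    filtered, split, matrix, full_matrix, per_affected, shared, groups = stage_filter()
    missense = split["missense"]
    summary["n_filtered"] = len(filtered)
    summary["n_missense"] = len(missense)
    summary["n_synonymous"] = len(split["synonymous"])
    summary["n_filtered_maf_lt_0.001"] = sum(
        1 for r in filtered if r.maf_gnomad3 is not None and r.maf_gnomad3 < 0.001
    )
    summary["missense_per_affected"] = dict(sorted(per_affected.items()))
    summary["shared_in_affected"] = [r.label for r in shared]
    summary["n_shared_missense"] = sum(
        1 for r in shared if r.consequence == Consequence.MISSENSE
    )
    summary["linkage_groups"] = [
        {"gene": g.gene, "variants": [v.label for v in g.variants],
         "members": sorted(g.members)}
        for g in groups
    ]
    if stop_after == "filter":
        return _finish(summary, out_dir)

    # -- rank -------------------------------------------------------------
    @_stage("rank")
    def stage_rank():
        pred = PredictionMatrix.from_store(annotations)
        counts = affected_carrier_counts(matrix, pedigree)
        return pred, rank_by_revel(pred, missense, counts)

    pred_matrix, decisions = stage_rank()
    summary["n_ranked"] = sum(1 for d in decisions if d.rank is not None)
    if stop_after == "rank":
        return _finish(summary, out_dir)

    # -- prioritize -------------------------------------------------------
    @_stage("prioritize")
    def stage_prioritize():
        all_decisions: List[PrioritizationDecision] = list(decisions)
        known = {d.key for d in all_decisions}
        by_key = {r.key: r for r in records}
        full_counts = affected_carrier_counts(full_matrix, pedigree)
        for key in config.manual_includes:
            if key in known:
                continue
            rec = by_key.get(key)
            if rec is None:
                raise PipelineError(
                    "prioritize", f"manual include {key} not found among input variants"
                )
            all_decisions.append(
                PrioritizationDecision(
                    record=rec,
                    revel_score=pred_matrix.score(key, "REVEL"),
                    affected_carriers=full_counts.get(key, 0),
                )
            )
        final = prioritize(
            all_decisions,
            regulatory=annotations,
            manual_includes=config.manual_includes,
            votes_min=config.votes_min,
            affected_min=config.affected_min,
            protected_rank_max=config.protected_rank_max,
        )
        _write_decisions(out_dir / "decisions.tsv", final)
        export_heatmap_matrix(
            pred_matrix,
            [d for d in final if d.rank is not None or d.key not in config.manual_includes],
            out_dir,
            network_eligible=set(config.network_eligible) or None,
        )
        return final

    final_decisions = stage_prioritize()
    prioritized = [d for d in final_decisions if d.status == Status.PRIORITIZED]
    summary["n_prioritized"] = len(prioritized)
    summary["n_manual_included"] = sum(
        1 for d in final_decisions if d.status == Status.MANUAL_INCLUDE
    )
    shared_keys = {r.key for r in shared}
    summary["prioritized_shared_in_affected"] = sorted(
        d.record.label for d in prioritized if d.key in shared_keys
    )
    if stop_after == "prioritize":
        return _finish(summary, out_dir)

    # -- network ----------------------------------------------------------
    @_stage("network")
    def stage_network():
        edge_db = EdgeDB.from_tsv(config.edge_db, prior=config.prior)
        extra = {p: set(genes) for p, genes in config.extra_includes.items()}
        sets = build_patient_sets(
            final_decisions, full_matrix, pedigree,
            set(config.network_eligible), extra,
        )
        networks = {
            patient: build_patient_network(patient, nodes, edge_db)
            for patient, nodes in sorted(sets.items())
        }
        _write_networks(out_dir, networks)
        return sets, networks

    if config.edge_db is None:
        raise PipelineError("network", "no edge_db configured")
    patient_sets, networks = stage_network()
    summary["patient_nodes"] = {
        patient: sorted(nodes) for patient, nodes in sorted(patient_sets.items())
    }
    eligible = set(config.network_eligible)
    summary["network_low_frequency_genes"] = sorted(
        {g for nodes in patient_sets.values() for g in nodes if g in eligible}
    )
    summary["edge_tiers"] = {
        patient: {"-".join(pair): [round(score, 6), tier.value]
                  for pair, score, tier in net.edges}
        for patient, net in networks.items()
    }
    if stop_after == "network":
        return _finish(summary, out_dir)

    # -- enrich -----------------------------------------------------------
    @_stage("enrich")
    def stage_enrich():
        background = set(
            line.strip().upper()
            for line in Path(config.background).read_text().splitlines()
            if line.strip()
        )
        term_db = TermDB.from_gmt(config.term_db, background)
        results = {
            patient: enrich_terms(nodes, term_db)
            for patient, nodes in sorted(patient_sets.items())
        }
        _write_enrichment(out_dir / "enrichment.tsv", results)
        return results

    if config.term_db is None or config.background is None:
        raise PipelineError("enrich", "term_db and background must be configured")
    enrichment = stage_enrich()
    summary["top_terms"] = {
        patient: [
            {"term": r.term_id, "label": r.term_label, "k": r.k,
             "fdr": float(f"{r.fdr:.6g}")}
            for r in results[:3]
        ]
        for patient, results in enrichment.items()
    }
    return _finish(summary, out_dir)


def _finish(summary: dict, out_dir: Path) -> dict:
    (out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary


def _write_filtered(path: Path, records, matrix) -> None:
    lines = ["variant\tgene\tchrom\tpos\tconsequence\tmaf_gnomad3\tqual\tcarriers\taffected_carriers"]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.label,
                    rec.gene,
                    rec.chrom,
                    str(rec.pos),
                    rec.consequence.value if rec.consequence else "",
                    "" if rec.maf_gnomad3 is None else f"{rec.maf_gnomad3:.6g}",
                    "" if rec.qual is None else f"{rec.qual:g}",
                    ",".join(sorted(matrix.carriers[rec.key])),
                    ",".join(sorted(matrix.affected_carriers(rec.key))),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_decisions(path: Path, decisions) -> None:
    lines = [
        "variant\tgene\trevel\trank\tquartile\tdamaging_votes\taffected_carriers"
        "\tflag_plus\tflag_star\tstatus\treason"
    ]
    ordered = sorted(
        decisions,
        key=lambda d: (d.rank is None, d.rank if d.rank is not None else 0, d.record.gene),
    )
    for d in ordered:
        lines.append(
            "\t".join(
                [
                    d.record.label,
                    d.record.gene,
                    "" if d.revel_score is None else f"{d.revel_score:.4f}",
                    "" if d.rank is None else str(d.rank),
                    "" if d.quartile is None else str(d.quartile),
                    str(d.damaging_votes),
                    str(d.affected_carriers),
                    "+" if d.flag_plus else "",
                    "*" if d.flag_star else "",
                    d.status.value if d.status else "",
                    d.reason,
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def _write_networks(out_dir: Path, networks: Dict[str, object]) -> None:
    for patient, net in networks.items():
        lines = ["protein_a\tprotein_b\tcombined_score\ttier"]
        sif_lines = []
        for (a, b), score, tier in net.edges:
            lines.append(f"{a}\t{b}\t{score:.6f}\t{tier.value}")
            sif_lines.append(f"{a}\tpp\t{b}")
        (out_dir / f"network_{patient}.tsv").write_text("\n".join(lines) + "\n")
        (out_dir / f"network_{patient}.sif").write_text(
            ("\n".join(sif_lines) + "\n") if sif_lines else ""
        )


def _write_enrichment(path: Path, enrichment) -> None:
    lines = ["patient\tterm_id\tlabel\tcategory\tk\tn\tK\tN\tp_value\tfdr"]
    for patient, results in enrichment.items():
        for r in results:
            lines.append(
                "\t".join(
                    [
                        patient, r.term_id, r.term_label, r.category,
                        str(r.k), str(r.n), str(r.K), str(r.N),
                        f"{r.p_value:.6g}", f"{r.fdr:.6g}",
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")
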