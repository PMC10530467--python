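"""Multi-tool deleteriousness consensus, REVEL ranking and rule-based
prioritization of missense variants.

Scores are probability-like values in [0, 1], oriented so that higher means
more damaging (tools with inverted native scales, e.g. SIFT, are flipped at
ingestion via ``PredictionMatrix.from_table(invert_tools=...)``).  Each tool
has a (neutral_max, damaging_min) cutoff pair: score >= damaging_min is
damaging, <= neutral_max neutral, in between moderate, absent missing.

A variant is flagged "+" when it is carried by at least ``affected_min``
affected members and called damaging by at least ``votes_min`` tools; it is
flagged "*" when the vote threshold holds together with eQTL/sQTL or ClinVar
evidence.  Final status is prioritized when either flag holds or when the
variant ranks within the protected top positions of the REVEL ordering —
only tail-ranked, low-evidence variants are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Union

import pandas as pd

from .errors import ConfigError, InputError
from .variant_io import (
    AnnotationStore,
    Consequence,
    RegulatoryAnnotation,
    VariantRecord,
)

__all__ = [
    "DEFAULT_TOOLS",
    "Category",
    "ToolCutoff",
    "PredictionMatrix",
    "PrioritizationDecision",
    "Status",
    "categorize_scores",
    "damaging_vote_count",
    "rank_by_revel",
    "prioritize",
    "export_heatmap_matrix",
]

# 14 named tools plus one configurable slot (default CADD).
DEFAULT_TOOLS = (
    "ClinPred",
    "DANNCoding",
    "MetaSVM",
    "REVEL",
    "VEST4",
    "FATHMM-XF",
    "MetaLR",
    "PhD-SNPg",
    "LRT",
    "MutationAssessor",
    "MutationTaster",
    "PROVEAN",
    "PolyPhen-2",
    "SIFT",
    "CADD",
)

REVEL = "REVEL"


class Category(str, Enum):
    NEUTRAL = "neutral"
    MODERATE = "moderate"
    DAMAGING = "damaging"
    MISSING = "missing"


class Status(str, Enum):
    PRIORITIZED = "prioritized"
    NOT_PRIORITIZED = "not_prioritized"
    MANUAL_INCLUDE = "manual_include"


@dataclass(frozen=True)
class ToolCutoff:
    """Category thresholds for one tool on the common [0, 1] orientation."""

    damaging_min: float = 0.5
    neutral_max: float = 0.25

    def __post_init__(self) -> None:
        if self.damaging_min < self.neutral_max:
            raise ConfigError(
                f"damaging_min {self.damaging_min} < neutral_max {self.neutral_max}"
            )


@dataclass
class PredictionMatrix:
    """variants x tools probability-like scores with per-tool cutoffs."""

    tools: tuple = DEFAULT_TOOLS
    scores: Dict[tuple, float] = field(default_factory=dict)  # (key, tool) -> score
    cutoffs: Dict[str, ToolCutoff] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool in self.tools:
            self.cutoffs.setdefault(tool, ToolCutoff())

    def score(self, key: str, tool: str) -> Optional[float]:
        return self.scores.get((key, tool))

    def set_score(self, key: str, tool: str, value: float) -> None:
        if tool not in self.tools:
            raise ConfigError(f"unknown tool {tool!r}")
        self.scores[(key, tool)] = value

    def variant_keys(self) -> list:
        return sorted({k for (k, _t) in self.scores})

    @classmethod
    def from_table(
        cls,
        table: Union[str, Path, pd.DataFrame],
        tools: Sequence[str] = DEFAULT_TOOLS,
        cutoffs: Optional[Mapping[str, ToolCutoff]] = None,
        invert_tools: Iterable[str] = (),
    ) -> "PredictionMatrix":
        """Build from a TSV/DataFrame with a ``key`` column plus tool columns.

        ``invert_tools`` lists tools whose native scale runs opposite to the
        common orientation; their scores are mapped s -> 1 - s.
        """
        if not isinstance(table, pd.DataFrame):
            table = pd.read_csv(table, sep="\t")
        matrix = cls(tools=tuple(tools), cutoffs=dict(cutoffs or {}))
        invert = set(invert_tools)
        for _, row in table.iterrows():
            key = row["key"]
            for tool in tools:
                if tool in table.columns and not pd.isna(row[tool]):
                    s = float(row[tool])
                    matrix.scores[(key, tool)] = 1.0 - s if tool in invert else s
        return matrix

    @classmethod
    def from_store(
        cls,
        store: AnnotationStore,
        tools: Sequence[str] = DEFAULT_TOOLS,
        cutoffs: Optional[Mapping[str, ToolCutoff]] = None,
    ) -> "PredictionMatrix":
        matrix = cls(tools=tuple(tools), cutoffs=dict(cutoffs or {}))
        for key in store.score_keys():
            for tool, value in store.predictor_scores(key).items():
                if tool in matrix.tools:
                    matrix.scores[(key, tool)] = value
        return matrix


def categorize_scores(matrix: PredictionMatrix) -> Dict[tuple, Category]:
    """Map every (variant, tool) score to a category via the tool's cutoffs."""
    categories: Dict[tuple, Category] = {}
    for (key, tool), score in matrix.scores.items():
        if not (0.0 <= score <= 1.0):
            raise InputError(
                f"score {score} for tool {tool} on variant {key} outside [0, 1]"
            )
        cut = matrix.cutoffs[tool]
        if score >= cut.damaging_min:
            categories[(key, tool)] = Category.DAMAGING
        elif score <= cut.neutral_max:
            categories[(key, tool)] = Category.NEUTRAL
        else:
            categories[(key, tool)] = Category.MODERATE
    return categories


def damaging_vote_count(
    categories: Mapping[tuple, Category], key: str, tools: Sequence[str] = DEFAULT_TOOLS
) -> int:
    """Number of tools calling the variant damaging; missing tools count 0."""
    return sum(
        1 for tool in tools if categories.get((key, tool)) == Category.DAMAGING
    )


@dataclass
class PrioritizationDecision:
    record: VariantRecord
    revel_score: Optional[float] = None
    rank: Optional[int] = None
    quartile: Optional[int] = None
    damaging_votes: int = 0
    affected_carriers: int = 0
    flag_plus: bool = False
    flag_star: bool = False
    status: Optional[Status] = None
    reason: str = ""

    @property
    def key(self) -> str:
        return self.record.key


def rank_by_revel(
    matrix: PredictionMatrix,
    records: Sequence[VariantRecord],
    affected_carriers: Optional[Mapping[str, int]] = None,
) -> List[PrioritizationDecision]:
    """Order missense variants by descending REVEL score.

    Ties break by (damaging votes desc, gene symbol asc).  Variants without
    a REVEL score are appended in input order with no rank; quartiles are
    assigned by rank position over the ranked variants.
    """
    for rec in records:
        if rec.consequence != Consequence.MISSENSE:
            raise InputError(f"{rec.label}: only missense variants can be ranked")
    categories = categorize_scores(matrix)
    decisions = []
    for rec in records:
        votes = damaging_vote_count(categories, rec.key, matrix.tools)
        decisions.append(
            PrioritizationDecision(
                record=rec,
                revel_score=matrix.score(rec.key, REVEL),
                damaging_votes=votes,
                affected_carriers=(affected_carriers or {}).get(rec.key, 0),
            )
        )
    ranked = [d for d in decisions if d.revel_score is not None]
    unranked = [d for d in decisions if d.revel_score is None]
    ranked.sort(key=lambda d: (-d.revel_score, -d.damaging_votes, d.record.gene))
    n = len(ranked)
    for pos, dec in enumerate(ranked, start=1):
        dec.rank = pos
        dec.quartile = (pos - 1) * 4 // n + 1
    return ranked + unranked


def prioritize(
    decisions: Sequence[PrioritizationDecision],
    regulatory: Optional[AnnotationStore] = None,
    manual_includes: Sequence[str] = (),
    votes_min: int = 4,
    affected_min: int = 2,
    protected_rank_max: Optional[int] = 8,
    star_benign_counts: bool = True,
) -> List[PrioritizationDecision]:
    """Apply the +/* evidence rules and assign a final status to each decision.

    status = prioritized when flag_plus or flag_star holds, or when the
    variant ranks within the top ``protected_rank_max`` positions (only
    tail-ranked low-evidence variants are subject to exclusion; set
    ``protected_rank_max=None`` for a strictly flag-based rule).
    ``manual_includes`` (variant keys) receive status manual_include
    regardless of flags; an include absent from the input is fatal.
    ``star_benign_counts`` controls whether benign/likely-benign ClinVar
    records satisfy the "annotated in ClinVar" arm of the * flag.
    """
    known = {d.key for d in decisions}
    missing = [k for k in manual_includes if k not in known]
    if missing:
        raise InputError(
            "manual include(s) not found among input variants: " + ", ".join(missing)
        )
    from .variant_io import ClinVarCategory

    star_cats: Set[ClinVarCategory] = {ClinVarCategory.LP, ClinVarCategory.P}
    if star_benign_counts:
        star_cats |= {ClinVarCategory.B, ClinVarCategory.LB}

    out = []
    for dec in decisions:
        reg = (
            regulatory.regulatory(dec.key)
            if regulatory is not None
            else RegulatoryAnnotation(key=dec.key)
        )
        flag_plus = dec.affected_carriers >= affected_min and dec.damaging_votes >= votes_min
        flag_star = dec.damaging_votes >= votes_min and (
            reg.has_qtl or bool(dec.record.clinvar & star_cats)
        )
        reasons = []
        if flag_plus:
            reasons.append("plus:carriers+votes")
        if flag_star:
            reasons.append("star:votes+functional")
        top_ranked = (
            protected_rank_max is not None
            and dec.rank is not None
            and dec.rank <= protected_rank_max
        )
        if dec.key in manual_includes:
            status, reason = Status.MANUAL_INCLUDE, "manual_include"
        elif flag_plus or flag_star:
            status, reason = Status.PRIORITIZED, "+".join(reasons)
        elif top_ranked:
            status, reason = Status.PRIORITIZED, f"top_rank<= {protected_rank_max}"
        else:
            status, reason = Status.NOT_PRIORITIZED, "low_evidence"
        out.append(
            replace(
                dec,
                flag_plus=flag_plus,
                flag_star=flag_star,
                status=status,
                reason=reason,
            )
        )
    return out


def export_heatmap_matrix(
    matrix: PredictionMatrix,
    decisions: Sequence[PrioritizationDecision],
    out_dir: Union[str, Path],
    network_eligible: Optional[Set[str]] = None,
) -> tuple:
    """Write the probability panel and the category panel as TSV files.

    Rows follow rank order (unranked last); columns are the tools plus the
    +/*/delta flag columns.  Output is deterministic and byte-stable.
    Returns the two paths (scores, categories).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    categories = categorize_scores(matrix)
    ordered = sorted(
        decisions, key=lambda d: (d.rank is None, d.rank if d.rank is not None else 0)
    )
    header = ["variant", "gene", "rank"] + list(matrix.tools) + ["plus", "star", "delta"]

    def flag_cols(dec: PrioritizationDecision) -> list:
        delta = (
            dec.status in (Status.PRIORITIZED, Status.MANUAL_INCLUDE)
            and network_eligible is not None
            and dec.record.gene not in network_eligible
        )
        return [
            "+" if dec.flag_plus else "",
            "*" if dec.flag_star else "",
            "D" if delta else "",
        ]

    score_lines = ["\t".join(header)]
    cat_lines = ["\t".join(header)]
    for dec in ordered:
        base = [dec.record.label, dec.record.gene, "" if dec.rank is None else str(dec.rank)]
        srow, crow = list(base), list(base)
        for tool in matrix.tools:
            s = matrix.score(dec.key, tool)
            srow.append("" if s is None else f"{s:.4f}")
            crow.append(categories.get((dec.key, tool), Category.MISSING).value)
        flags = flag_cols(dec)
        score_lines.append("\t".join(srow + flags))
        cat_lines.append("\t".join(crow + flags))

    scores_path = out_dir / "heatmap_scores.tsv"
    cats_path = out_dir / "heatmap_categories.tsv"
    scores_path.write_text("\n".join(score_lines) + "\n")
    cats_path.write_text("\n".join(cat_lines) + "\n")
    return scores_path, cats_path
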