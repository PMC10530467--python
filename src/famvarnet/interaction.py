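"""Per-patient protein sets, evidence-channel score combination and term
enrichment against a packaged mini interaction database.

Channel scores are combined with the prior-corrected noisy-OR: each channel
score s is corrected to s' = (s - p) / (1 - p) against the prior p, the
corrected scores are unioned u = 1 - prod(1 - s'), and the union is mapped
back to combined = u * (1 - p) + p.  With a single channel the combined
score equals that channel's score exactly; with no channels it equals the
prior.  Combined scores are tiered at 0.15 / 0.4 / 0.7 / 0.9 (half-open,
lower bound inclusive).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .family_filter import CarrierMatrix
from .prioritization import PrioritizationDecision, Status
from .variant_io import Pedigree

__all__ = [
    "CHANNELS",
    "DEFAULT_PRIOR",
    "Tier",
    "EdgeEvidence",
    "EdgeDB",
    "PatientNetwork",
    "TermDB",
    "EnrichmentResult",
    "combine_channel_scores",
    "classify_tier",
    "build_patient_sets",
    "build_patient_network",
    "enrich_terms",
]

CHANNELS = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "experimental",
    "database",
    "coexpression",
    "textmining",
)

DEFAULT_PRIOR = 0.041

TIER_BOUNDS = (0.15, 0.4, 0.7, 0.9)


class Tier(str, Enum):
    BELOW_LOW = "below_low"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    HIGHEST = "highest"


@dataclass(frozen=True)
class EdgeEvidence:
    """Per-channel interaction evidence for one unordered protein pair."""

    protein_a: str
    protein_b: str
    channel_scores: tuple  # ((channel, score), ...) sorted by channel
    prior: float = DEFAULT_PRIOR

    def __post_init__(self) -> None:
        if self.protein_a > self.protein_b:
            raise InputError(
                f"pair ({self.protein_a}, {self.protein_b}) not lexicographic"
            )
        if not (0.0 <= self.prior < 1.0):
            raise InputError(f"prior {self.prior} outside [0, 1)")
        for channel, score in self.channel_scores:
            if channel not in CHANNELS:
                raise InputError(f"unknown evidence channel {channel!r}")
            if not (0.0 <= score <= 1.0):
                raise InputError(
                    f"channel {channel} score {score} outside [0, 1] for "
                    f"({self.protein_a}, {self.protein_b})"
                )

    @classmethod
    def make(
        cls,
        a: str,
        b: str,
        scores: Mapping[str, float],
        prior: float = DEFAULT_PRIOR,
    ) -> "EdgeEvidence":
        a, b = sorted((a, b))
        return cls(a, b, tuple(sorted(scores.items())), prior)

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.protein_a, self.protein_b)


def combine_channel_scores(evidence: EdgeEvidence) -> float:
    """Integrate channel scores into one combined confidence (noisy-OR)."""
    p = evidence.prior
    survival = 1.0
    for channel, score in evidence.channel_scores:
        if score < p:
            warnings.warn(
                f"channel {channel} score {score} below prior {p} for "
                f"{evidence.pair}; channel dropped"
            )
            continue
        survival *= 1.0 - (score - p) / (1.0 - p)
    union = 1.0 - survival
    return union * (1.0 - p) + p


def classify_tier(
    combined_score: float, bounds: Sequence[float] = TIER_BOUNDS
) -> Tier:
    """Half-open confidence bins with inclusive lower bounds."""
    if not (0.0 <= combined_score <= 1.0):
        raise InputError(f"combined score {combined_score} outside [0, 1]")
    low, medium, high, highest = bounds
    if combined_score >= highest:
        return Tier.HIGHEST
    if combined_score >= high:
        return Tier.HIGH
    if combined_score >= medium:
        return Tier.MEDIUM
    if combined_score >= low:
        return Tier.LOW
    return Tier.BELOW_LOW


class EdgeDB:
    """Mini interaction database: unordered pair -> EdgeEvidence."""

    def __init__(self, prior: float = DEFAULT_PRIOR) -> None:
        self.prior = prior
        self._edges: Dict[Tuple[str, str], Dict[str, float]] = {}

    def add(self, a: str, b: str, channel: str, score: float) -> None:
        pair = tuple(sorted((a, b)))
        self._edges.setdefault(pair, {})[channel] = score

    def lookup(self, a: str, b: str) -> Optional[EdgeEvidence]:
        pair = tuple(sorted((a, b)))
        scores = self._edges.get(pair)
        if scores is None:
            return None
        return EdgeEvidence.make(*pair, scores=scores, prior=self.prior)

    def pairs(self) -> list:
        return sorted(self._edges)

    @classmethod
    def from_tsv(cls, path: Union[str, Path], prior: float = DEFAULT_PRIOR) -> "EdgeDB":
        """Read a `protein_a  protein_b  channel  score` TSV edge list."""
        db = cls(prior=prior)
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            db.add(row["protein_a"], row["protein_b"], row["channel"], float(row["score"]))
        return db


@dataclass
class PatientNetwork:
    patient: str
    nodes: frozenset
    edges: list  # [(pair, combined_score, tier), ...] deterministic order

    def edge(self, a: str, b: str):
        pair = tuple(sorted((a, b)))
        for p, score, tier in self.edges:
            if p == pair:
                return score, tier
        return None


def build_patient_sets(
    decisions: Sequence[PrioritizationDecision],
    matrix: CarrierMatrix,
    pedigree: Pedigree,
    network_eligible: Set[str],
    extra_includes: Optional[Mapping[str, Set[str]]] = None,
) -> Dict[str, frozenset]:
    """Per affected patient: genes of carried, network-eligible prioritized
    variants, plus any explicit per-patient extra symbols."""
    decided_genes = {
        d.record.gene
        for d in decisions
        if d.status in (Status.PRIORITIZED, Status.MANUAL_INCLUDE)
    }
    missing = set(network_eligible) - {d.record.gene for d in decisions}
    if missing:
        raise InputError(
            "network-eligible gene(s) absent from decisions: "
            + ", ".join(sorted(missing))
        )
    extra_includes = extra_includes or {}
    sets = {}
    for patient in pedigree.affected_ids:
        nodes = set()
        for dec in decisions:
            if dec.status not in (Status.PRIORITIZED, Status.MANUAL_INCLUDE):
                continue
            if dec.record.gene not in network_eligible:
                continue
            if patient in matrix.carriers.get(dec.key, set()):
                nodes.add(dec.record.gene)
        nodes |= set(extra_includes.get(patient, set()))
        sets[patient] = frozenset(nodes)
    return sets


def build_patient_network(
    patient: str, nodes: Set[str], edge_db: EdgeDB
) -> PatientNetwork:
    """Connect every node pair present in the edge DB; score and tier each."""
    ordered = sorted(nodes)
    edges = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            evidence = edge_db.lookup(a, b)
            if evidence is None:
                continue
            score = combine_channel_scores(evidence)
            edges.append(((a, b), score, classify_tier(score)))
    return PatientNetwork(patient=patient, nodes=frozenset(nodes), edges=edges)


# ---------------------------------------------------------------------------
# term enrichment


@dataclass(frozen=True)
class Term:
    term_id: str
    label: str
    category: str  # GO-BP, GO-CC, keyword
    genes: frozenset


class TermDB:
    """GMT-style term database with a declared background gene universe."""

    CATEGORY_PREFIXES = (("GOCC:", "GO-CC"), ("GO:", "GO-BP"), ("KW-", "keyword"))

    def __init__(self, terms: Sequence[Term], background: Set[str]) -> None:
        self.terms = list(terms)
        self.background = frozenset(background)

    @classmethod
    def category_for(cls, term_id: str) -> str:
        for prefix, category in cls.CATEGORY_PREFIXES:
            if term_id.startswith(prefix):
                return category
        return "other"

    @classmethod
    def from_gmt(
        cls, path: Union[str, Path], background: Set[str]
    ) -> "TermDB":
        """Read `term_id<TAB>label<TAB>gene...` lines."""
        terms = []
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}: GMT line needs id, label, >=1 gene: {line!r}")
            term_id, label = fields[0], fields[1]
            terms.append(
                Term(
                    term_id=term_id,
                    label=label,
                    category=cls.category_for(term_id),
                    genes=frozenset(g.strip().upper() for g in fields[2:] if g.strip()),
                )
            )
        return cls(terms, background)


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_label: str
    category: str
    k: int  # overlap
    n: int  # query size
    K: int  # term size within background
    N: int  # background size
    p_value: float
    fdr: float


def enrich_terms(
    nodes: Set[str],
    term_db: TermDB,
    min_overlap: int = 1,
) -> List[EnrichmentResult]:
    """Hypergeometric upper-tail enrichment with BH FDR within each category.

    Every query node must belong to the declared background.  Results are
    sorted by (fdr, p, term id) ascending.
    """
    nodes = {g.upper() for g in nodes}
    stray = nodes - term_db.background
    if stray:
        raise InputError(
            "query gene(s) not in declared background: " + ", ".join(sorted(stray))
        )
    N = len(term_db.background)
    n = len(nodes)
    raw = []
    for term in term_db.terms:
        genes = term.genes & term_db.background
        K = len(genes)
        k = len(nodes & genes)
        if k < min_overlap:
            continue
        p = float(hypergeom.sf(k - 1, N, K, n))
        raw.append((term, k, K, min(p, 1.0)))

    results: List[EnrichmentResult] = []
    for category in sorted({t.category for (t, _k, _K, _p) in raw}):
        group = [item for item in raw if item[0].category == category]
        pvals = [p for (_t, _k, _K, p) in group]
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        for (term, k, K, p), fdr in zip(group, fdrs):
            results.append(
                EnrichmentResult(
                    term_id=term.term_id,
                    term_label=term.label,
                    category=category,
                    k=k,
                    n=n,
                    K=K,
                    N=N,
                    p_value=p,
                    fdr=float(min(max(fdr, p), 1.0)),
                )
            )
    results.sort(key=lambda r: (r.fdr, r.p_value, r.term_id))
    return results
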