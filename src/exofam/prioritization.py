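"""Candidate scoring and ranking.

Deleteriousness is an ensemble majority vote over prediction-tool calls:
deleterious counts 1, ambiguous 0.5, tolerated and missing 0, and a variant
is deleterious iff the score strictly exceeds half the tool count.  Gene
evidence (phenotype-matched disease association, relevant-tissue expression,
genic intolerance) contributes an additive score.  Candidates are ranked
lexicographically over (deleterious, vote score, gene evidence, conservation)
with the variant key as a deterministic tie-break.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .filtering import FunnelReport
from .io_formats.models import (
    AnnotationRecord,
    FormatError,
    GeneEvidence,
    Pedigree,
    ToolCall,
    variant_key_str,
)

__all__ = [
    "VOTE_WEIGHTS",
    "DeleteriousnessVote",
    "EvidenceWeights",
    "RankedCandidate",
    "vote_deleteriousness",
    "score_gene_evidence",
    "rank_candidates",
    "build_report",
]

VOTE_WEIGHTS = {
    ToolCall.DELETERIOUS: 1.0,
    ToolCall.AMBIGUOUS: 0.5,
    ToolCall.TOLERATED: 0.0,
    ToolCall.MISSING: 0.0,
}


@dataclass(frozen=True)
class DeleteriousnessVote:
    variant_key: Optional[tuple]
    score: float
    n_tools: int
    is_deleterious: bool


@dataclass(frozen=True)
class EvidenceWeights:
    """Additive weights for the three gene-evidence criteria.

    ``rvis_max_percentile`` is inclusive: a gene at exactly the cut-off still
    counts as intolerant.
    """

    disease_association: float = 1.0
    tissue_expression: float = 1.0
    rvis: float = 1.0
    rvis_max_percentile: float = 25.0
    min_expression_rank: int = 2  # medium


@dataclass
class RankedCandidate:
    variant_key: tuple
    gene: str
    vote: DeleteriousnessVote
    conserved: bool
    gene_evidence_score: float
    composite_rank: int = 0
    models: list = field(default_factory=list)


def vote_deleteriousness(
    tool_calls: Sequence[ToolCall],
    n_tools: int = 10,
    variant_key: Optional[tuple] = None,
) -> DeleteriousnessVote:
    """Weighted ensemble vote; deleterious iff score > n_tools / 2 (strict).

    Missing tool calls count 0 and the denominator is not renormalised.
    """
    if len(tool_calls) != n_tools:
        raise FormatError(
            f"expected {n_tools} tool calls, got {len(tool_calls)}"
        )
    score = sum(VOTE_WEIGHTS[ToolCall(c)] for c in tool_calls)
    return DeleteriousnessVote(
        variant_key=variant_key,
        score=score,
        n_tools=n_tools,
        is_deleterious=score > n_tools / 2.0,
    )


def score_gene_evidence(
    gene: str,
    evidence: Optional[GeneEvidence],
    phenotype_terms: Iterable[str] = (),
    relevant_tissues: Optional[Iterable[str]] = None,
    weights: EvidenceWeights = EvidenceWeights(),
) -> float:
    """Additive gene score; each criterion contributes 0 when its evidence
    is missing.

    ``relevant_tissues`` of ``None`` lets any tissue satisfy the expression
    criterion.
    """
    if evidence is None:
        return 0.0
    score = 0.0
    terms = set(phenotype_terms)
    if terms and (evidence.disease_associations & terms):
        score += weights.disease_association
    tissues = (
        evidence.tissue_expression
        if relevant_tissues is None
        else {
            t: lvl
            for t, lvl in evidence.tissue_expression.items()
            if t in set(relevant_tissues)
        }
    )
    if any(lvl.rank >= weights.min_expression_rank for lvl in tissues.values()):
        score += weights.tissue_expression
    if (
        evidence.rvis_percentile is not None
        and evidence.rvis_percentile <= weights.rvis_max_percentile
    ):
        score += weights.rvis
    return score


def rank_candidates(
    candidates: Sequence[AnnotationRecord],
    votes: Optional[Mapping[tuple, DeleteriousnessVote]] = None,
    gene_scores: Optional[Mapping[str, float]] = None,
    models: Optional[Mapping[tuple, list]] = None,
    n_tools: int = 10,
) -> list[RankedCandidate]:
    """Rank candidate annotations; rank 1 is the best candidate.

    Sort key: deleterious first, then vote score, gene evidence score and
    conservation (all descending), with the variant key as final tie-break.
    When ``votes`` is omitted they are computed from each annotation's tool
    calls; absent gene scores default to 0.
    """
    votes = dict(votes or {})
    gene_scores = dict(gene_scores or {})
    models = dict(models or {})
    ranked = []
    for ann in candidates:
        vote = votes.get(ann.variant_key) or vote_deleteriousness(
            ann.tool_calls, n_tools=n_tools, variant_key=ann.variant_key
        )
        ranked.append(
            RankedCandidate(
                variant_key=ann.variant_key,
                gene=ann.gene,
                vote=vote,
                conserved=ann.conserved_region,
                gene_evidence_score=gene_scores.get(ann.gene, 0.0),
                models=list(models.get(ann.variant_key, [])),
            )
        )
    ranked.sort(
        key=lambda c: (
            not c.vote.is_deleterious,
            -c.vote.score,
            -c.gene_evidence_score,
            not c.conserved,
            c.variant_key,
        )
    )
    for i, c in enumerate(ranked, start=1):
        c.composite_rank = i
    return ranked


def build_report(
    funnel: FunnelReport,
    ranked: Sequence[RankedCandidate],
    pedigree: Pedigree,
    truth_key: Optional[tuple] = None,
) -> dict:
    """JSON-serialisable run report: funnel table, per-candidate evidence
    breakdown, and a planted-truth comparison when a truth key is given."""
    report: dict = {
        "pedigree": {
            "n_samples": len(pedigree),
            "n_affected": len(pedigree.affected),
            "samples": pedigree.sample_ids,
        },
        "funnel": funnel.as_rows(),
        "candidates": [
            {
                "rank": c.composite_rank,
                "variant": variant_key_str(c.variant_key),
                "gene": c.gene,
                "vote_score": c.vote.score,
                "n_tools": c.vote.n_tools,
                "is_deleterious": c.vote.is_deleterious,
                "conserved": c.conserved,
                "gene_evidence_score": c.gene_evidence_score,
                "models": [str(getattr(m, "value", m)) for m in c.models],
            }
            for c in ranked
        ],
    }
    if not ranked:
        report["empty_result"] = {
            "message": "no candidate variant survived the cascade"
        }
    if truth_key is not None:
        rank = next(
            (
                c.composite_rank
                for c in ranked
                if tuple(c.variant_key) == tuple(truth_key)
            ),
            None,
        )
        report["truth"] = {
            "planted_variant": variant_key_str(tuple(truth_key)),
            "recovered_at_rank": rank,
        }
    return report


def funnel_table(report: dict) -> str:
    """Human-readable fixed-width funnel table for a build_report dict."""
    lines = [f"{'stage':<28}{'in':>10}{'out':>10}"]
    for row in report["funnel"]:
        lines.append(
            f"{row['stage']:<28}{row['variants_in']:>10}{row['variants_out']:>10}"
        )
    return "\n".join(lines)


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
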