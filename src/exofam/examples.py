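"""Hard-coded worked-example fixtures for the X-linked hypoparathyroidism
kindred analysis: the four surviving candidate variants with their published
per-database frequencies and prediction-tool outcomes."""

from __future__ import annotations

from .io_formats.models import (
    AnnotationRecord,
    Effect,
    ExpressionLevel,
    GeneEvidence,
    ToolCall,
)

__all__ = ["candidate_annotations", "candidate_gene_evidence", "FHL1_KEY"]

FHL1_KEY = ("X", 135292485, "C", "T")

_TOLERATED_10 = [ToolCall.TOLERATED] * 10


def candidate_annotations() -> list[AnnotationRecord]:
    """The four homozygous-recessive/X-linked candidate variants.

    The FHL1 missense variant is called deleterious by 8 of 10 tools with
    one ambiguous call (ensemble score 8.5/10), sits in a conserved region,
    and carries allele frequencies of 0.0005 (ExAC) and 0.0006 (ESP) while
    being absent from the 1000 Genomes set.  The other three candidates are
    deleterious by none of the tools.
    """
    fhl1 = AnnotationRecord(
        variant_key=FHL1_KEY,
        gene="FHL1",
        effect=Effect.EXONIC_NONSYNONYMOUS,
        hgvs_c="c.C283T",
        hgvs_p="p.R95W",
        db_frequencies={"exac": 0.0005, "esp": 0.0006, "kg": None},
        tool_calls=[ToolCall.DELETERIOUS] * 8
        + [ToolCall.AMBIGUOUS, ToolCall.TOLERATED],
        conserved_region=True,
    )
    znf366 = AnnotationRecord(
        variant_key=("5", 71803123, "A", "G"),
        gene="ZNF366",
        effect=Effect.EXONIC_NONSYNONYMOUS,
        hgvs_c="c.A58G",
        hgvs_p="p.K20E",
        db_frequencies={"exac": 0.004, "esp": 0.003, "kg": 0.002},
        tool_calls=list(_TOLERATED_10),
        conserved_region=False,
    )
    coro1b = AnnotationRecord(
        variant_key=("11", 67205428, "G", "A"),
        gene="CORO1B",
        effect=Effect.EXONIC_NONSYNONYMOUS,
        hgvs_c="c.G1252A",
        hgvs_p="p.A418T",
        db_frequencies={"exac": 0.006, "esp": None, "kg": 0.005},
        tool_calls=list(_TOLERATED_10),
        conserved_region=False,
    )
    znf208 = AnnotationRecord(
        variant_key=("19", 22155933, "T", "C"),
        gene="ZNF208",
        effect=Effect.EXONIC_NONSYNONYMOUS,
        hgvs_c="c.T986C",
        hgvs_p="p.I329T",
        db_frequencies={"exac": 0.007, "esp": 0.008, "kg": None},
        tool_calls=list(_TOLERATED_10),
        conserved_region=False,
    )
    return [fhl1, znf366, coro1b, znf208]


def candidate_gene_evidence() -> dict[str, GeneEvidence]:
    """Minimal gene-level evidence for the four candidate genes."""
    return {
        "FHL1": GeneEvidence(
            gene="FHL1",
            disease_associations=frozenset({"myopathy", "muscular_dystrophy"}),
            tissue_expression={
                "skeletal_muscle": ExpressionLevel.HIGH,
                "heart": ExpressionLevel.HIGH,
            },
            rvis_percentile=20.0,
        ),
        "ZNF366": GeneEvidence(gene="ZNF366"),
        "CORO1B": GeneEvidence(gene="CORO1B"),
        "ZNF208": GeneEvidence(gene="ZNF208"),
    }
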