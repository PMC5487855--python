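"""Pedigree-aware inheritance-model predicates.

Three models are implemented: de novo (with a low-coverage confidence flag),
homozygous autosomal recessive, and X-linked recessive.  Missing genotypes
never count as evidence for consistency: under the default strict policy a
missing call in a constrained sample vetoes the model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

from .io_formats.models import (
    Affection,
    FormatError,
    Genotype,
    Pedigree,
    SampleInfo,
    Sex,
    VariantRecord,
    variant_key_str,
)

__all__ = [
    "Model",
    "Assessment",
    "SegregationResult",
    "ModelCandidate",
    "check_de_novo",
    "check_autosomal_recessive_hom",
    "check_x_linked_recessive",
    "select_candidates",
]


class Model(str, enum.Enum):
    DE_NOVO = "de_novo"
    AUTOSOMAL_RECESSIVE_HOM = "autosomal_recessive_hom"
    X_LINKED_RECESSIVE = "x_linked_recessive"


class Assessment(str, enum.Enum):
    CONSISTENT = "consistent"
    VIOLATES = "violates"
    MISSING_DATA = "missing_data"


@dataclass
class SegregationResult:
    variant_key: tuple
    model: Model
    consistent: bool
    low_confidence: bool = False
    per_sample_assessment: dict[str, Assessment] = field(default_factory=dict)


@dataclass
class ModelCandidate:
    """A variant consistent with at least one requested inheritance model."""

    variant: VariantRecord
    models: list[Model]
    results: dict[Model, SegregationResult] = field(default_factory=dict)


def _genotype_of(variant: VariantRecord, sample_id: str) -> Genotype:
    return variant.genotypes.get(sample_id, Genotype.MISSING)


def _finalize(
    variant: VariantRecord,
    model: Model,
    assessment: dict[str, Assessment],
    strict_missing: bool,
    low_confidence: bool = False,
) -> SegregationResult:
    has_violation = Assessment.VIOLATES in assessment.values()
    has_missing = Assessment.MISSING_DATA in assessment.values()
    consistent = not has_violation and not (strict_missing and has_missing)
    return SegregationResult(
        variant_key=variant.key,
        model=model,
        consistent=consistent,
        low_confidence=consistent and low_confidence,
        per_sample_assessment=assessment,
    )


def check_de_novo(
    variant: VariantRecord,
    pedigree: Pedigree,
    min_alt_depth: int = 5,
    strict_missing: bool = True,
) -> SegregationResult:
    """De novo in the proband: proband carries the alternate allele while
    parents and all siblings are called non-carriers.

    ``low_confidence`` is set when the proband's alt-allele coverage is
    strictly below ``min_alt_depth`` (default 5x).
    """
    proband = pedigree.proband()
    if proband.sample_id not in variant.genotypes:
        raise FormatError(
            f"proband {proband.sample_id!r} has no genotype for "
            f"{variant_key_str(variant.key)}"
        )
    assessment: dict[str, Assessment] = {}
    pg = _genotype_of(variant, proband.sample_id)
    if pg is Genotype.MISSING:
        assessment[proband.sample_id] = Assessment.MISSING_DATA
    else:
        assessment[proband.sample_id] = (
            Assessment.CONSISTENT if pg.carries_alt else Assessment.VIOLATES
        )

    relatives = {
        sid
        for sid in (proband.father_id, proband.mother_id)
        if sid is not None
    }
    relatives |= {s.sample_id for s in pedigree.siblings_of(proband.sample_id)}
    for sid in sorted(relatives):
        g = _genotype_of(variant, sid)
        if g is Genotype.MISSING:
            assessment[sid] = Assessment.MISSING_DATA
        else:
            assessment[sid] = (
                Assessment.VIOLATES if g.carries_alt else Assessment.CONSISTENT
            )

    depth = variant.alt_depth.get(proband.sample_id, 0)
    return _finalize(
        variant,
        Model.DE_NOVO,
        assessment,
        strict_missing,
        low_confidence=depth < min_alt_depth,
    )


def check_autosomal_recessive_hom(
    variant: VariantRecord,
    pedigree: Pedigree,
    strict_missing: bool = True,
) -> SegregationResult:
    """Homozygous recessive: affecteds hom_alt, unaffected parents of an
    affected (obligate carriers) het, no unaffected hom_alt."""
    assessment: dict[str, Assessment] = {}
    obligate_carriers: set[str] = set()
    for s in pedigree.affected:
        for pid in (s.father_id, s.mother_id):
            if pid is not None and pedigree[pid].affected is not Affection.AFFECTED:
                obligate_carriers.add(pid)

    for s in pedigree:
        g = _genotype_of(variant, s.sample_id)
        if g is Genotype.MISSING:
            assessment[s.sample_id] = Assessment.MISSING_DATA
            continue
        if s.affected is Affection.AFFECTED:
            ok = g is Genotype.HOM_ALT
        elif s.sample_id in obligate_carriers:
            ok = g is Genotype.HET
        else:
            ok = g is not Genotype.HOM_ALT
        assessment[s.sample_id] = (
            Assessment.CONSISTENT if ok else Assessment.VIOLATES
        )
    return _finalize(
        variant, Model.AUTOSOMAL_RECESSIVE_HOM, assessment, strict_missing
    )


def check_x_linked_recessive(
    variant: VariantRecord,
    pedigree: Pedigree,
    strict_missing: bool = True,
    affected_female_veto: bool = False,
    par_regions: Sequence[Tuple[int, int]] = (),
) -> SegregationResult:
    """X-linked recessive: affected males hemizygous-alt, their mothers
    carriers, no unaffected male hemizygous-alt, no unaffected female
    homozygous-alt.

    Affected females do not veto by default (``affected_female_veto``)
    because mild expression in carrier females need not follow the
    hemizygous pattern; with the flag set they must be het or hom_alt.
    """
    if not variant.is_x(par_regions):
        raise FormatError(
            f"x-linked check called on non-X variant "
            f"{variant_key_str(variant.key)}"
        )
    assessment: dict[str, Assessment] = {}
    carrier_mothers = {
        s.mother_id
        for s in pedigree.affected_males
        if s.mother_id is not None
    }

    for s in pedigree:
        g = _genotype_of(variant, s.sample_id)
        affected = s.affected is Affection.AFFECTED
        if s.sex is Sex.FEMALE and affected and not affected_female_veto:
            # exempt from the model; never vetoes, missing data tolerated
            assessment[s.sample_id] = Assessment.CONSISTENT
            continue
        if g is Genotype.MISSING:
            assessment[s.sample_id] = Assessment.MISSING_DATA
            continue
        if s.sex is Sex.MALE:
            ok = (g is Genotype.HEMI_ALT) if affected else (g is not Genotype.HEMI_ALT)
        elif affected:
            ok = g in (Genotype.HET, Genotype.HOM_ALT)
        elif s.sample_id in carrier_mothers:
            ok = g in (Genotype.HET, Genotype.HOM_ALT)
        else:
            ok = g is not Genotype.HOM_ALT
        assessment[s.sample_id] = (
            Assessment.CONSISTENT if ok else Assessment.VIOLATES
        )
    return _finalize(
        variant, Model.X_LINKED_RECESSIVE, assessment, strict_missing
    )


def select_candidates(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    models: Sequence[Model] = (
        Model.AUTOSOMAL_RECESSIVE_HOM,
        Model.X_LINKED_RECESSIVE,
    ),
    min_alt_depth: int = 5,
    strict_missing: bool = True,
    affected_female_veto: bool = False,
    par_regions: Sequence[Tuple[int, int]] = (),
) -> tuple[list[ModelCandidate], tuple[str, int, int]]:
    """Union of variants consistent under any requested model, each tagged
    with the model(s) it satisfies, plus a funnel row for the stage."""
    models = [Model(m) for m in models]
    candidates: list[ModelCandidate] = []
    for v in variants:
        hits: dict[Model, SegregationResult] = {}
        for model in models:
            if model is Model.DE_NOVO:
                res = check_de_novo(v, pedigree, min_alt_depth, strict_missing)
            elif model is Model.AUTOSOMAL_RECESSIVE_HOM:
                res = check_autosomal_recessive_hom(v, pedigree, strict_missing)
            else:
                if not v.is_x(par_regions):
                    continue
                res = check_x_linked_recessive(
                    v,
                    pedigree,
                    strict_missing,
                    affected_female_veto,
                    par_regions,
                )
            if res.consistent:
                hits[model] = res
        if hits:
            candidates.append(
                ModelCandidate(variant=v, models=list(hits), results=hits)
            )
    row = ("segregation", len(variants), len(candidates))
    return candidates, row
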