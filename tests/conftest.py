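from __future__ import annotations

import pytest

from exofam.io_formats.models import (
    Affection,
    Genotype,
    Pedigree,
    SampleInfo,
    Sex,
    VariantRecord,
)
from exofam.synthetic import family_pedigree, trio_pedigree


@pytest.fixture
def family() -> Pedigree:
    return family_pedigree()


@pytest.fixture
def trio() -> Pedigree:
    return trio_pedigree()


def make_variant(
    pedigree: Pedigree,
    chrom: str = "1",
    pos: int = 1000,
    ref: str = "C",
    alt: str = "T",
    default: Genotype = Genotype.HOM_REF,
    alt_depth: dict | None = None,
    qc_flags: frozenset = frozenset(),
    **genotypes: str,
) -> VariantRecord:
    """Build a variant with every pedigree sample genotyped.

    On chrX the male default becomes hemi_ref; keyword overrides use
    genotype value strings (e.g. proband="hemi_alt").
    """
    gts = {}
    for s in pedigree:
        if chrom in ("X", "chrX") and s.sex is Sex.MALE:
            base = (
                Genotype.HEMI_REF
                if default is Genotype.HOM_REF
                else default
            )
        else:
            base = default
        gts[s.sample_id] = base
    for sid, g in genotypes.items():
        gts[sid] = Genotype(g)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=gts,
        alt_depth=alt_depth or {},
        qc_flags=qc_flags,
    )
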