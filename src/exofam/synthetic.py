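"""Synthetic cohorts, sequence contexts, network fixtures and assay tables
with known ground truth.

Cohorts contain background variants with Mendelian-consistent genotypes and
an optional planted causal variant whose genotype pattern exactly satisfies
its inheritance model and whose annotations survive the full filter cascade
(rare in every database, amino-acid changing, deleterious by a majority of
tools).  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filtering import FilterConfig, find_mononucleotide_runs, find_tandem_repeats, repeat_adjacent
from .io_formats.models import (
    QC_FLAGS,
    Affection,
    AnnotationRecord,
    EdgeList,
    Effect,
    FormatError,
    Genotype,
    Pedigree,
    SampleInfo,
    Sex,
    ToolCall,
    VariantRecord,
)

__all__ = [
    "CohortSpec",
    "AssaySpec",
    "TruthRecord",
    "Cohort",
    "HomopolymerCase",
    "family_pedigree",
    "trio_pedigree",
    "generate_cohort",
    "generate_homopolymer_contexts",
    "generate_network_fixture",
    "generate_assay_table",
    "NETWORK_SEEDS",
]

DB_NAMES = ("exac", "esp", "kg")
_BASES = "ACGT"


# ---------------------------------------------------------------------------
# pedigree templates


def family_pedigree() -> Pedigree:
    """Nine-member nuclear family: two parents, six sons (the first the
    affected proband) and one mildly affected daughter."""
    children = []
    children.append(
        SampleInfo("proband", "father", "mother", Sex.MALE, Affection.AFFECTED)
    )
    for i in range(2, 7):
        children.append(
            SampleInfo(
                f"brother{i}", "father", "mother", Sex.MALE, Affection.UNAFFECTED
            )
        )
    children.append(
        SampleInfo("sister", "father", "mother", Sex.FEMALE, Affection.AFFECTED)
    )
    return Pedigree(
        [
            SampleInfo("father", None, None, Sex.MALE, Affection.UNAFFECTED),
            SampleInfo("mother", None, None, Sex.FEMALE, Affection.UNAFFECTED),
            *children,
        ]
    )


def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            SampleInfo("father", None, None, Sex.MALE, Affection.UNAFFECTED),
            SampleInfo("mother", None, None, Sex.FEMALE, Affection.UNAFFECTED),
            SampleInfo("proband", "father", "mother", Sex.MALE, Affection.AFFECTED),
        ]
    )


_TEMPLATES = {"fig1_family": family_pedigree, "trio": trio_pedigree}


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    pedigree_template: str = "fig1_family"
    n_background_variants: int = 1000
    planted_model: str = "x_linked_recessive"
    rare_fraction: float = 0.2
    tool_count: int = 10
    genotyping_error_rate: float = 0.0
    indel_fraction: float = 0.1
    qc_flag_rate: float = 0.05
    de_novo_alt_depth: int = 3
    seed: int = 0
    custom_pedigree: Optional[Pedigree] = None

    def __post_init__(self) -> None:
        if self.planted_model not in (
            "de_novo",
            "autosomal_recessive_hom",
            "x_linked_recessive",
            "none",
        ):
            raise ValueError(f"unknown planted model {self.planted_model!r}")
        if not (0.0 <= self.rare_fraction <= 1.0):
            raise ValueError("rare_fraction must be in [0, 1]")
        if not (0.0 <= self.genotyping_error_rate <= 0.05):
            raise ValueError("genotyping_error_rate must be in [0, 0.05]")
        if self.n_background_variants < 0 or self.tool_count < 1:
            raise ValueError("sizes must be positive")


@dataclass(frozen=True)
class TruthRecord:
    variant_key: Optional[tuple]
    model: Optional[str]
    gene: Optional[str]

    @property
    def empty(self) -> bool:
        return self.variant_key is None


@dataclass
class Cohort:
    """Generated cohort; iterates as (pedigree, variants, annotations, truth)
    so callers can unpack the four primary components directly."""

    pedigree: Pedigree
    variants: list[VariantRecord]
    annotations: list[AnnotationRecord]
    truth: TruthRecord
    contexts: dict = field(default_factory=dict)
    seed: int = 0

    def __iter__(self):
        return iter((self.pedigree, self.variants, self.annotations, self.truth))


def _draw_frequency(rng: np.random.Generator, rare: bool) -> float:
    if rare:
        # log-uniform in (1e-5, 1e-2)
        return float(10 ** rng.uniform(-5, -2))
    # common variants: Beta-shaped mass above 1%
    return float(0.01 + (1.0 - 0.01) * rng.beta(1.2, 4.0))


def _hwe_female(rng: np.random.Generator, af: float) -> Genotype:
    n_alt = rng.binomial(1, af) + rng.binomial(1, af)
    return (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)[n_alt]


def _transmit_maternal(rng: np.random.Generator, gt: Genotype) -> int:
    if gt is Genotype.HOM_ALT:
        return 1
    if gt is Genotype.HET:
        return int(rng.integers(0, 2))
    return 0


def _sample_genotypes(
    rng: np.random.Generator, pedigree: Pedigree, af: float, on_x: bool
) -> dict[str, Genotype]:
    """Founders from allele frequency (HWE), children by transmission."""
    alleles: dict[str, tuple] = {}
    genotypes: dict[str, Genotype] = {}
    for s in pedigree:
        if s.is_founder:
            if on_x and s.sex is Sex.MALE:
                a = int(rng.binomial(1, af))
                alleles[s.sample_id] = (a,)
            else:
                a1, a2 = int(rng.binomial(1, af)), int(rng.binomial(1, af))
                alleles[s.sample_id] = (a1, a2)
    for s in pedigree:
        if s.is_founder:
            continue
        father = alleles.get(s.father_id) if s.father_id else None
        mother = alleles.get(s.mother_id) if s.mother_id else None
        if father is None or mother is None:
            raise FormatError(
                f"sample {s.sample_id!r} has an ungenotyped parent"
            )
        maternal = mother[int(rng.integers(0, len(mother)))]
        if on_x:
            if s.sex is Sex.MALE:
                alleles[s.sample_id] = (maternal,)
            else:
                alleles[s.sample_id] = (father[0], maternal)
        else:
            paternal = father[int(rng.integers(0, len(father)))]
            alleles[s.sample_id] = (paternal, maternal)
    for s in pedigree:
        a = alleles[s.sample_id]
        if on_x and s.sex is Sex.MALE:
            genotypes[s.sample_id] = (
                Genotype.HEMI_ALT if a[0] else Genotype.HEMI_REF
            )
        else:
            n_alt = sum(a)
            genotypes[s.sample_id] = (
                Genotype.HOM_REF,
                Genotype.HET,
                Genotype.HOM_ALT,
            )[n_alt]
    return genotypes


def _apply_genotype_errors(
    rng: np.random.Generator,
    genotypes: dict[str, Genotype],
    pedigree: Pedigree,
    rate: float,
    on_x: bool,
) -> None:
    if rate <= 0:
        return
    for s in pedigree:
        if rng.random() >= rate:
            continue
        male_x = on_x and s.sex is Sex.MALE
        states = (
            [Genotype.HEMI_REF, Genotype.HEMI_ALT, Genotype.MISSING]
            if male_x
            else [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING]
        )
        current = genotypes[s.sample_id]
        choices = [g for g in states if g is not current]
        genotypes[s.sample_id] = choices[int(rng.integers(0, len(choices)))]


def _alt_depths(
    rng: np.random.Generator, genotypes: dict[str, Genotype]
) -> dict[str, int]:
    depths = {}
    for sid, gt in genotypes.items():
        if gt.carries_alt:
            depths[sid] = int(20 + rng.integers(0, 41))
        else:
            depths[sid] = 0
    return depths


def _random_snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[int(rng.integers(0, 4))]
    alt = rng.choice([b for b in _BASES if b != ref])
    return ref, str(alt)


_EFFECTS = [
    Effect.EXONIC_NONSYNONYMOUS,
    Effect.EXONIC_SYNONYMOUS,
    Effect.SPLICING,
    Effect.OTHER,
]
_EFFECT_P = [0.25, 0.15, 0.05, 0.55]


def _background_tool_calls(
    rng: np.random.Generator, n_tools: int
) -> list[ToolCall]:
    out = []
    for _ in range(n_tools):
        r = rng.random()
        if r < 0.10:
            out.append(ToolCall.DELETERIOUS)
        elif r < 0.15:
            out.append(ToolCall.AMBIGUOUS)
        elif r < 0.20:
            out.append(ToolCall.MISSING)
        else:
            out.append(ToolCall.TOLERATED)
    return out


def _majority_deleterious_calls(n_tools: int) -> list[ToolCall]:
    """A call vector that is clearly deleterious by majority vote while
    containing one ambiguous and one tolerated call when room allows."""
    if n_tools >= 3:
        return (
            [ToolCall.DELETERIOUS] * (n_tools - 2)
            + [ToolCall.AMBIGUOUS, ToolCall.TOLERATED]
        )
    return [ToolCall.DELETERIOUS] * n_tools


def _clean_flank(rng: np.random.Generator, length: int, config: FilterConfig) -> str:
    """Random sequence with no adjacent run/repeat anywhere (resampled)."""
    while True:
        seq = "".join(_BASES[int(i)] for i in rng.integers(0, 4, size=length))
        if not find_mononucleotide_runs(seq, config.homopolymer_min_run) and not find_tandem_repeats(
            seq,
            config.repeat_min_unit,
            config.repeat_max_unit,
            config.repeat_min_copies,
        ):
            return seq


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a pedigree, variant cohort, annotations and truth record.

    Identical spec + seed yields identical output.  The planted variant,
    when requested, exactly satisfies its model's genotype pattern and
    survives every filter stage.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.pedigree_template == "custom":
        if spec.custom_pedigree is None:
            raise FormatError("custom template requires custom_pedigree")
        pedigree = spec.custom_pedigree
    else:
        try:
            pedigree = _TEMPLATES[spec.pedigree_template]()
        except KeyError:
            raise FormatError(
                f"unknown pedigree template {spec.pedigree_template!r}"
            ) from None

    config = FilterConfig()
    chroms = [str(c) for c in range(1, 23)] + ["X"]
    used_positions: set[tuple[str, int]] = set()
    variants: list[VariantRecord] = []
    annotations: list[AnnotationRecord] = []
    contexts: dict[tuple, str] = {}

    def fresh_position(chrom: str) -> int:
        while True:
            pos = int(rng.integers(10_000, 50_000_000))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                return pos

    for i in range(spec.n_background_variants):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = fresh_position(chrom)
        on_x = chrom == "X"
        is_indel = rng.random() < spec.indel_fraction
        if is_indel:
            flank = _clean_flank(rng, 2 * config.flank_window + 1, config)
            if rng.random() < 0.5:
                # plant a homopolymer run right of the locus
                run_len = int(rng.integers(6, 10))
                base = _BASES[int(rng.integers(0, 4))]
                w = config.flank_window
                flank = flank[: w + 1] + base * run_len + flank[w + 1 + run_len :]
            ref = flank[config.flank_window] + flank[config.flank_window + 1]
            alt = flank[config.flank_window]
            if rng.random() < 0.5:  # insertion instead of deletion
                ref, alt = alt, ref
        else:
            ref, alt = _random_snv(rng)

        rare = rng.random() < spec.rare_fraction
        af = _draw_frequency(rng, rare)
        genotypes = _sample_genotypes(rng, pedigree, af, on_x)
        _apply_genotype_errors(
            rng, genotypes, pedigree, spec.genotyping_error_rate, on_x
        )
        qc_flags = frozenset()
        if rng.random() < spec.qc_flag_rate:
            qc_flags = frozenset({sorted(QC_FLAGS)[int(rng.integers(0, 5))]})
        v = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            genotypes=genotypes,
            alt_depth=_alt_depths(rng, genotypes),
            qc_flags=qc_flags,
        )
        db_freq: dict[str, Optional[float]] = {}
        for db in DB_NAMES:
            if rng.random() < 0.85:
                jitter = float(np.exp(rng.normal(0.0, 0.1)))
                db_freq[db] = min(af * jitter, 1.0)
            else:
                db_freq[db] = None
        ann = AnnotationRecord(
            variant_key=v.key,
            gene=f"GENE{int(rng.integers(0, max(10, spec.n_background_variants // 3))):05d}",
            effect=_EFFECTS[
                int(rng.choice(len(_EFFECTS), p=_EFFECT_P))
            ],
            db_frequencies=db_freq,
            tool_calls=_background_tool_calls(rng, spec.tool_count),
            conserved_region=bool(rng.random() < 0.3),
            is_indel=is_indel,
        )
        variants.append(v)
        annotations.append(ann)
        if is_indel:
            contexts[v.key] = flank

    truth = TruthRecord(None, None, None)
    if spec.planted_model != "none":
        v, ann, gene = _planted_variant(rng, spec, pedigree, fresh_position)
        variants.append(v)
        annotations.append(ann)
        truth = TruthRecord(v.key, spec.planted_model, gene)

    return Cohort(
        pedigree=pedigree,
        variants=variants,
        annotations=annotations,
        truth=truth,
        contexts=contexts,
        seed=spec.seed,
    )


def _planted_variant(
    rng: np.random.Generator,
    spec: CohortSpec,
    pedigree: Pedigree,
    fresh_position,
) -> tuple[VariantRecord, AnnotationRecord, str]:
    model = spec.planted_model
    genotypes: dict[str, Genotype] = {}
    alt_depth: dict[str, int] = {}
    if model == "x_linked_recessive":
        if not pedigree.affected_males:
            raise FormatError(
                "x_linked_recessive planting requires an affected male"
            )
        chrom = "X"
        gene = "FHL1"
        proband = pedigree.affected_males[0]
        for s in pedigree:
            if s.sample_id == proband.sample_id:
                genotypes[s.sample_id] = Genotype.HEMI_ALT
            elif s.sample_id == proband.mother_id:
                genotypes[s.sample_id] = Genotype.HET
            elif s.sex is Sex.MALE:
                genotypes[s.sample_id] = Genotype.HEMI_REF
            else:
                genotypes[s.sample_id] = Genotype.HOM_REF
    elif model == "de_novo":
        chrom = "7"
        gene = "CAUSAL_DN"
        proband = pedigree.proband()
        for s in pedigree:
            genotypes[s.sample_id] = (
                Genotype.HET
                if s.sample_id == proband.sample_id
                else Genotype.HOM_REF
            )
    else:  # autosomal_recessive_hom
        chrom = "2"
        gene = "CAUSAL_AR"
        affected_ids = {s.sample_id for s in pedigree.affected}
        parent_ids = {
            pid
            for s in pedigree.affected
            for pid in (s.father_id, s.mother_id)
            if pid is not None
        }
        for s in pedigree:
            if s.sample_id in affected_ids:
                genotypes[s.sample_id] = Genotype.HOM_ALT
            elif s.sample_id in parent_ids:
                genotypes[s.sample_id] = Genotype.HET
            else:
                genotypes[s.sample_id] = (
                    Genotype.HET if rng.random() < 0.5 else Genotype.HOM_REF
                )
    pos = fresh_position(chrom)
    ref, alt = "C", "T"
    for sid, gt in genotypes.items():
        if gt.carries_alt:
            alt_depth[sid] = int(20 + rng.integers(0, 41))
        else:
            alt_depth[sid] = 0
    if model == "de_novo":
        alt_depth[pedigree.proband().sample_id] = spec.de_novo_alt_depth
    v = VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        genotypes=genotypes,
        alt_depth=alt_depth,
        qc_flags=frozenset(),
    )
    ann = AnnotationRecord(
        variant_key=v.key,
        gene=gene,
        effect=Effect.EXONIC_NONSYNONYMOUS,
        hgvs_c="c.C283T" if gene == "FHL1" else "",
        hgvs_p="p.R95W" if gene == "FHL1" else "",
        db_frequencies={"exac": 0.0005, "esp": 0.0006, "kg": None},
        tool_calls=_majority_deleterious_calls(spec.tool_count),
        conserved_region=True,
        is_indel=False,
    )
    return v, ann, gene


# ---------------------------------------------------------------------------
# homopolymer / repeat contexts


@dataclass(frozen=True)
class HomopolymerCase:
    context: str
    ref: str
    alt: str
    expected_flag: bool
    kind: str

    def __iter__(self):
        return iter((self.context, (self.ref, self.alt), self.expected_flag))


def generate_homopolymer_contexts(
    n: int, seed: int = 0, config: FilterConfig = FilterConfig()
) -> list[HomopolymerCase]:
    """Labelled indel contexts: positives with an adjacent run (length >=
    ``homopolymer_min_run``) or tandem repeat, negatives including the exact
    run-length boundary and runs too far away to count as adjacent.

    The context convention places the base at the variant position at index
    ``config.flank_window``; the indel is a 1-bp deletion of the following
    base.
    """
    if n < 1:
        raise FormatError("n must be >= 1")
    rng = np.random.default_rng(seed)
    w = config.flank_window
    kinds = [
        ("run_above_boundary", True),
        ("run_at_boundary_negative", False),
        ("run_at_boundary_positive", True),
        ("tandem_repeat", True),
        ("clean_negative", False),
        ("distant_run_negative", False),
    ]
    cases = []
    for i in range(n):
        kind, expected = kinds[i % len(kinds)]
        # resample until the spliced flank does not perturb the intended
        # label (e.g. a boundary-length run accidentally extended by a
        # matching flank base)
        while True:
            base = _BASES[int(rng.integers(0, 4))]
            other = str(rng.choice([b for b in _BASES if b != base]))
            flank = _clean_flank(rng, 2 * w + 1, config)
            if kind == "run_above_boundary":
                run = base * int(rng.integers(config.homopolymer_min_run, 10))
                ctx = flank[: w + 2] + run + flank[w + 2 + len(run) :]
            elif kind == "run_at_boundary_negative":
                run = base * (config.homopolymer_min_run - 1)
                ctx = flank[: w + 2] + run + flank[w + 2 + len(run) :]
            elif kind == "run_at_boundary_positive":
                run = base * config.homopolymer_min_run
                ctx = flank[: w + 2] + run + flank[w + 2 + len(run) :]
            elif kind == "tandem_repeat":
                unit = base + other
                rep = unit * int(rng.integers(config.repeat_min_copies, 5))
                ctx = flank[: w + 2] + rep + flank[w + 2 + len(rep) :]
            elif kind == "clean_negative":
                ctx = flank
            else:  # distant run at the far window edge: too far to count
                run = base * config.homopolymer_min_run
                ctx = run + flank[len(run) :]
            ctx = ctx[: 2 * w + 1]
            if repeat_adjacent(ctx, w + 1, 1, config) == expected:
                break
        cases.append(
            HomopolymerCase(
                context=ctx,
                ref=ctx[w] + ctx[w + 1],
                alt=ctx[w],
                expected_flag=expected,
                kind=kind,
            )
        )
    return cases


# ---------------------------------------------------------------------------
# network fixture


NETWORK_SEEDS = frozenset(
    {
        "FHL1",
        "PTH",
        "CALC1",
        "PTHRP",
        "TBX1",
        "GCM2",
        "CASR",
        "AIRE",
        "GNA11",
        "GATA3",
        "GNAS",
        "TRPM6",
    }
)


def generate_network_fixture() -> tuple[EdgeList, frozenset]:
    """Hard-coded PPI skeleton: twelve seed proteins, the STAT4 bridge
    between FHL1 and GATA3, the AKAP12-FLNA bridge between FHL1 and CASR,
    direct seed-seed edges, and distractor nodes touching at most one seed."""
    edges = EdgeList.from_pairs(
        [
            ("FHL1", "STAT4", "ppi"),
            ("STAT4", "GATA3", "ppi"),
            ("FHL1", "AKAP12", "ppi"),
            ("AKAP12", "FLNA", "ppi"),
            ("FLNA", "CASR", "ppi"),
            # direct seed-seed interactions
            ("CASR", "GNA11", "ppi"),
            ("PTH", "PTHRP", "ppi"),
            ("GCM2", "GATA3", "ppi"),
            # distractors: at most one seed neighbour each
            ("FHL1", "DSTR1", "ppi"),
            ("DSTR1", "DSTR2", "ppi"),
            ("PTH", "DSTR3", "ppi"),
            ("DSTR4", "DSTR5", "ppi"),
        ]
    )
    return edges, NETWORK_SEEDS


# ---------------------------------------------------------------------------
# assay tables


@dataclass(frozen=True)
class AssaySpec:
    assay: str
    groups: tuple = (("control", 1.0), ("treated", 0.55))
    n_replicates: int = 3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.assay not in ("qpcr", "luciferase", "calcium"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


_QPCR_REFERENCE_CT = 15.0
_QPCR_BASE_CT = 20.0
_LUC_BASE = 1000.0
_CA_SLOPE = 0.04
_CA_INTERCEPT = 0.05
CALCIUM_STANDARDS = (0.0, 5.0, 10.0, 25.0)


def generate_assay_table(spec: AssaySpec) -> pd.DataFrame:
    """Long-format assay table whose recoverable effect equals true_effect.

    qpcr: target and reference Ct values; the expected 2^-ddCt fold change
    of each group versus the first (control) group equals
    ``true_effect / control_effect``.  luciferase: firefly/Renilla pairs
    with expected normalised ratio equal to true_effect.  calcium: a
    standard series on a known line plus pooled-sample readings whose pool
    concentration equals true_effect.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    if spec.assay == "qpcr":
        for group, effect in spec.groups:
            if effect <= 0:
                raise ValueError("qpcr true_effect must be positive")
            for rep in range(1, spec.n_replicates + 1):
                ref_ct = _QPCR_REFERENCE_CT + rng.normal(0.0, spec.noise_sd)
                tgt_ct = (
                    _QPCR_BASE_CT
                    - math.log2(effect)
                    + rng.normal(0.0, spec.noise_sd)
                )
                rows.append(("qpcr", group, rep, "reference", max(ref_ct, 1e-6)))
                rows.append(("qpcr", group, rep, "target", max(tgt_ct, 1e-6)))
    elif spec.assay == "luciferase":
        for group, effect in spec.groups:
            for rep in range(1, spec.n_replicates + 1):
                renilla = _LUC_BASE + rng.normal(0.0, spec.noise_sd)
                firefly = _LUC_BASE * effect + rng.normal(0.0, spec.noise_sd)
                rows.append(
                    ("luciferase", group, rep, "renilla", max(renilla, 1e-6))
                )
                rows.append(
                    ("luciferase", group, rep, "firefly", max(firefly, 1e-6))
                )
    else:  # calcium
        for rep in range(1, spec.n_replicates + 1):
            for conc in CALCIUM_STANDARDS:
                reading = (
                    _CA_SLOPE * conc
                    + _CA_INTERCEPT
                    + rng.normal(0.0, spec.noise_sd)
                )
                rows.append(
                    ("calcium", "standard", rep, repr(conc), max(reading, 0.0))
                )
        for group, effect in spec.groups:
            for rep in range(1, spec.n_replicates + 1):
                reading = (
                    _CA_SLOPE * effect
                    + _CA_INTERCEPT
                    + rng.normal(0.0, spec.noise_sd)
                )
                rows.append(("calcium", group, rep, "pool", max(reading, 0.0)))
    return pd.DataFrame(
        rows, columns=["assay", "group", "replicate", "target", "value"]
    )
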