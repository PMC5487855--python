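"""Pre-segregation variant filter cascade.

Stages, applied in fixed order with a funnel report:

1. QC-flag exclusion (flags carried from the upstream caller).
2. Homopolymer/repeat-adjacent indel exclusion (SNVs always pass).
3. Population allele-frequency exclusion — a variant is removed iff ANY
   database it is present in reports a frequency strictly above the active
   threshold (1% monogenic, 10% polygenic/pharmacologic); absence from all
   databases is evidence of rarity and passes.
4. Effect-class retention (amino-acid-changing by default).

Each stage is an independent predicate, so the surviving set equals the
intersection of the per-stage passing sets; only funnel counts depend on
stage order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Union

from .io_formats.models import (
    QC_FLAGS,
    AnnotationRecord,
    Effect,
    FormatError,
    VariantRecord,
    variant_key_str,
)

__all__ = [
    "FilterConfig",
    "FunnelStage",
    "FunnelReport",
    "qc_filter",
    "homopolymer_indel_filter",
    "frequency_filter",
    "effect_filter",
    "run_filter_cascade",
    "repeat_adjacent",
    "find_mononucleotide_runs",
    "find_tandem_repeats",
]

ContextProvider = Union[Callable[[VariantRecord], str], Mapping, None]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds and rule parameters for the filter cascade.

    ``homopolymer_min_run`` of 6 encodes "longer than five bases"; repeats
    are short tandem repeats with a non-mononucleotide unit of 2-6 bp and at
    least 3 copies.  "Adjacent" means the run/repeat lies within
    ``adjacency_tol`` bases of the indel's normalised locus.
    """

    mode: str = "monogenic"
    monogenic_max_af: float = 0.01
    polygenic_max_af: float = 0.10
    homopolymer_min_run: int = 6
    repeat_min_unit: int = 2
    repeat_max_unit: int = 6
    repeat_min_copies: int = 3
    flank_window: int = 10
    adjacency_tol: int = 1
    excluded_qc_flags: frozenset = QC_FLAGS
    retained_effects: frozenset = frozenset({Effect.EXONIC_NONSYNONYMOUS})

    def __post_init__(self) -> None:
        if self.mode not in ("monogenic", "polygenic_pharmacologic"):
            raise ValueError(f"unknown filter mode {self.mode!r}")
        if not (0.0 < self.monogenic_max_af < self.polygenic_max_af <= 1.0):
            raise ValueError(
                "need 0 < monogenic_max_af < polygenic_max_af <= 1, got "
                f"{self.monogenic_max_af} / {self.polygenic_max_af}"
            )
        if self.homopolymer_min_run < 2:
            raise ValueError("homopolymer_min_run must be >= 2")

    @property
    def max_af(self) -> float:
        return (
            self.monogenic_max_af
            if self.mode == "monogenic"
            else self.polygenic_max_af
        )


@dataclass(frozen=True)
class FunnelStage:
    name: str
    variants_in: int
    variants_out: int

    def __post_init__(self) -> None:
        if self.variants_out > self.variants_in:
            raise ValueError(
                f"funnel stage {self.name!r} grew: "
                f"{self.variants_in} -> {self.variants_out}"
            )


@dataclass
class FunnelReport:
    """Ordered per-stage record of surviving-variant counts."""

    stages: list[FunnelStage] = field(default_factory=list)
    candidates: list = field(default_factory=list)

    def add_stage(self, name: str, variants_in: int, variants_out: int) -> None:
        if self.stages and variants_in != self.stages[-1].variants_out:
            raise ValueError(
                f"funnel stage {name!r} input {variants_in} does not chain to "
                f"previous output {self.stages[-1].variants_out}"
            )
        self.stages.append(FunnelStage(name, variants_in, variants_out))

    def as_rows(self) -> list[dict]:
        return [
            {
                "stage": s.name,
                "variants_in": s.variants_in,
                "variants_out": s.variants_out,
            }
            for s in self.stages
        ]


# ---------------------------------------------------------------------------
# sequence-context scanning


def find_mononucleotide_runs(seq: str, min_run: int) -> list[tuple[int, int]]:
    """Half-open [start, end) intervals of mononucleotide runs >= min_run."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i, j))
        i = j
    return runs


def find_tandem_repeats(
    seq: str, min_unit: int = 2, max_unit: int = 6, min_copies: int = 3
) -> list[tuple[int, int]]:
    """Half-open intervals of tandem repeats with a non-mononucleotide unit.

    A repeat at ``s`` with unit length ``u`` covers ``copies * u`` bases where
    ``copies`` is the maximal number of exact consecutive unit copies.
    Maximal intervals only (a repeat interval contained in another reported
    interval for the same unit length is dropped).
    """
    n = len(seq)
    intervals: set[tuple[int, int]] = set()
    for u in range(min_unit, max_unit + 1):
        for s in range(0, n - u * min_copies + 1):
            unit = seq[s : s + u]
            if len(set(unit)) < 2:
                continue  # mononucleotide units belong to the homopolymer rule
            copies = 1
            while seq[s + copies * u : s + (copies + 1) * u] == unit:
                copies += 1
            if copies >= min_copies:
                intervals.add((s, s + copies * u))
    # drop intervals strictly contained in another
    out = []
    for iv in intervals:
        if not any(
            o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals
        ):
            out.append(iv)
    return sorted(out)


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap in bases between half-open intervals (0 = overlap or abutting)."""
    return max(a[0] - b[1], b[0] - a[1], 0)


def repeat_adjacent(
    context: str,
    indel_index: int,
    indel_span: int,
    config: FilterConfig = FilterConfig(),
) -> bool:
    """True iff a homopolymer run or tandem repeat lies within
    ``config.adjacency_tol`` bases of the indel locus.

    ``indel_index``/``indel_span`` give the half-open affected interval in
    context coordinates (deletion: the deleted bases; insertion: the
    two bases flanking the insertion point).
    """
    locus = (indel_index, indel_index + indel_span)
    for run in find_mononucleotide_runs(context, config.homopolymer_min_run):
        if _interval_gap(run, locus) <= config.adjacency_tol:
            return True
    for rep in find_tandem_repeats(
        context,
        config.repeat_min_unit,
        config.repeat_max_unit,
        config.repeat_min_copies,
    ):
        if _interval_gap(rep, locus) <= config.adjacency_tol:
            return True
    return False


def indel_locus_in_context(
    variant: VariantRecord, flank_window: int
) -> tuple[int, int]:
    """Affected half-open interval in a context string where the base at
    ``variant.pos`` sits at index ``flank_window``."""
    anchor = flank_window
    if len(variant.ref) > len(variant.alt):  # deletion
        k = len(variant.ref) - len(variant.alt)
        return (anchor + 1, anchor + 1 + k)
    # insertion: the junction between the anchor base and the next base
    return (anchor, anchor + 2)


# ---------------------------------------------------------------------------
# filter stages


def qc_filter(
    variants: Sequence[VariantRecord],
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Drop variants whose qc_flags intersect the excluded set."""
    return [v for v in variants if not (v.qc_flags & config.excluded_qc_flags)]


def _context_for(variant: VariantRecord, provider: ContextProvider) -> str:
    if provider is None:
        raise FormatError(
            f"indel {variant_key_str(variant.key)} requires a sequence "
            f"context but no context provider was supplied"
        )
    if callable(provider):
        ctx = provider(variant)
    else:
        ctx = provider.get(variant.key)
    if ctx is None:
        raise FormatError(
            f"no sequence context for indel {variant_key_str(variant.key)}"
        )
    return ctx


def homopolymer_indel_filter(
    variants: Sequence[VariantRecord],
    context_provider: ContextProvider,
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Exclude indels adjacent to homopolymer runs or tandem repeats.

    SNVs always pass.  The provider must return at least the reference base
    at the variant position plus ``flank_window`` bases on each side.
    """
    out = []
    for v in variants:
        if not v.is_indel:
            out.append(v)
            continue
        ctx = _context_for(v, context_provider)
        if len(ctx) < 2 * config.flank_window + 1:
            raise FormatError(
                f"context for {variant_key_str(v.key)} shorter than "
                f"2*flank_window+1 = {2 * config.flank_window + 1}"
            )
        start, end = indel_locus_in_context(v, config.flank_window)
        if not repeat_adjacent(ctx, start, end - start, config):
            out.append(v)
    return out


def _annotation_index(
    annotations: Sequence[AnnotationRecord],
) -> dict[tuple, AnnotationRecord]:
    return {a.variant_key: a for a in annotations}


def _lookup(
    variant: VariantRecord, index: Mapping[tuple, AnnotationRecord]
) -> AnnotationRecord:
    ann = index.get(variant.key)
    if ann is None:
        raise FormatError(
            f"no annotation for variant {variant_key_str(variant.key)}"
        )
    return ann


def frequency_filter(
    variants: Sequence[VariantRecord],
    annotations: Sequence[AnnotationRecord],
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Exclude a variant iff any present database frequency exceeds the
    active threshold (strict ``>``); absent-everywhere variants pass."""
    index = _annotation_index(annotations)
    out = []
    for v in variants:
        ann = _lookup(v, index)
        if not any(f > config.max_af for f in ann.present_frequencies.values()):
            out.append(v)
    return out


def effect_filter(
    variants: Sequence[VariantRecord],
    annotations: Sequence[AnnotationRecord],
    config: FilterConfig = FilterConfig(),
) -> list[VariantRecord]:
    """Retain only variants whose effect class is in the configured set."""
    index = _annotation_index(annotations)
    return [
        v for v in variants if _lookup(v, index).effect in config.retained_effects
    ]


def run_filter_cascade(
    variants: Sequence[VariantRecord],
    annotations: Sequence[AnnotationRecord],
    config: FilterConfig = FilterConfig(),
    context_provider: ContextProvider = None,
) -> tuple[list[VariantRecord], FunnelReport]:
    """Apply qc -> homopolymer -> frequency -> effect, recording the funnel."""
    report = FunnelReport()
    current = list(variants)

    stages: list[tuple[str, Callable]] = [
        ("qc_flags", lambda vs: qc_filter(vs, config)),
        (
            "homopolymer_repeat_indels",
            lambda vs: homopolymer_indel_filter(vs, context_provider, config),
        ),
        ("allele_frequency", lambda vs: frequency_filter(vs, annotations, config)),
        ("effect_class", lambda vs: effect_filter(vs, annotations, config)),
    ]
    for name, fn in stages:
        n_in = len(current)
        current = fn(current)
        report.add_stage(name, n_in, len(current))
    report.candidates = [v.key for v in current]
    return current, report
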