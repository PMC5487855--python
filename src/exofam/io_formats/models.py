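"""Core domain types shared by every pipeline stage.

All coordinates are 1-based inclusive (VCF convention).  Chromosome X is
accepted as ``"X"`` or ``"chrX"`` and normalised internally; pseudoautosomal
regions are configurable and default to empty.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "FormatError",
    "Sex",
    "Affection",
    "Genotype",
    "Effect",
    "ToolCall",
    "ExpressionLevel",
    "QC_FLAGS",
    "SampleInfo",
    "Pedigree",
    "VariantRecord",
    "AnnotationRecord",
    "GeneEvidence",
    "EdgeList",
    "GeneSetCollection",
    "normalize_chrom",
    "is_x_chromosome",
    "variant_key_str",
]


class FormatError(ValueError):
    """Raised when an input file or record violates its documented contract."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Genotype(str, enum.Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    HEMI_REF = "hemi_ref"
    HEMI_ALT = "hemi_alt"
    MISSING = "missing"

    @property
    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT, Genotype.HEMI_ALT)

    @property
    def is_called(self) -> bool:
        return self is not Genotype.MISSING


class Effect(str, enum.Enum):
    EXONIC_NONSYNONYMOUS = "exonic_nonsynonymous"
    EXONIC_SYNONYMOUS = "exonic_synonymous"
    SPLICING = "splicing"
    OTHER = "other"


class ToolCall(str, enum.Enum):
    DELETERIOUS = "deleterious"
    TOLERATED = "tolerated"
    AMBIGUOUS = "ambiguous"
    MISSING = "missing"


class ExpressionLevel(str, enum.Enum):
    NOT_DETECTED = "not_detected"
    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"

    @property
    def rank(self) -> int:
        return _EXPR_RANK[self]


_EXPR_RANK = {
    ExpressionLevel.NOT_DETECTED: 0,
    ExpressionLevel.LOW: 1,
    ExpressionLevel.MEDIUM: 2,
    ExpressionLevel.HIGH: 3,
}

#: QC flags carried over from the upstream caller's FILTER column.
QC_FLAGS = frozenset(
    {
        "low_base_quality",
        "low_mapping_quality",
        "strand_bias",
        "aberrant_read_position",
        "ref_alt_quality_discrepancy",
    }
)

VariantKey = Tuple[str, int, str, str]


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and uppercase X/Y/MT names."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper() if c.lower() in ("x", "y", "mt", "m") else c


def is_x_chromosome(
    chrom: str,
    pos: Optional[int] = None,
    par_regions: Sequence[Tuple[int, int]] = (),
) -> bool:
    """True for non-pseudoautosomal chrX.  ``par_regions`` are 1-based inclusive."""
    if normalize_chrom(chrom) != "X":
        return False
    if pos is not None:
        for start, end in par_regions:
            if start <= pos <= end:
                return False
    return True


def variant_key_str(key: VariantKey) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass(frozen=True)
class SampleInfo:
    """One pedigree member; parent ids of ``None`` mark founders."""

    sample_id: str
    father_id: Optional[str]
    mother_id: Optional[str]
    sex: Sex
    affected: Affection

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """Validated collection of :class:`SampleInfo` records.

    Raises :class:`FormatError` on duplicate sample ids, dangling parent
    references, or ancestry cycles.
    """

    def __init__(self, samples: Iterable[SampleInfo]):
        self.samples: list[SampleInfo] = list(samples)
        self._by_id = {}
        for s in self.samples:
            if s.sample_id in self._by_id:
                raise FormatError(f"duplicate sample id {s.sample_id!r} in pedigree")
            self._by_id[s.sample_id] = s
        for s in self.samples:
            for label, pid in (("father", s.father_id), ("mother", s.mother_id)):
                if pid is not None and pid not in self._by_id:
                    raise FormatError(
                        f"sample {s.sample_id!r}: {label} id {pid!r} not in pedigree"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # DFS colouring over the parent relation; a back edge is a cycle.
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {sid: WHITE for sid in self._by_id}

        def visit(sid: str) -> None:
            colour[sid] = GREY
            s = self._by_id[sid]
            for pid in (s.father_id, s.mother_id):
                if pid is None:
                    continue
                if colour[pid] == GREY:
                    raise FormatError(f"sample {sid!r} is its own ancestor")
                if colour[pid] == WHITE:
                    visit(pid)
            colour[sid] = BLACK

        for sid in self._by_id:
            if colour[sid] == WHITE:
                visit(sid)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[SampleInfo]:
        return iter(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> SampleInfo:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise KeyError(f"sample {sample_id!r} not in pedigree") from None

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Pedigree) and self.samples == other.samples

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def affected(self) -> list[SampleInfo]:
        return [s for s in self.samples if s.affected is Affection.AFFECTED]

    @property
    def affected_males(self) -> list[SampleInfo]:
        return [s for s in self.affected if s.sex is Sex.MALE]

    def proband(self) -> SampleInfo:
        """The first affected sample in file order (affected males first)."""
        males = self.affected_males
        if males:
            return males[0]
        aff = self.affected
        if not aff:
            raise FormatError("pedigree contains no affected sample")
        return aff[0]

    def siblings_of(self, sample_id: str) -> list[SampleInfo]:
        s = self[sample_id]
        if s.is_founder:
            return []
        return [
            o
            for o in self.samples
            if o.sample_id != sample_id
            and not o.is_founder
            and o.father_id == s.father_id
            and o.mother_id == s.mother_id
        ]


@dataclass
class VariantRecord:
    """A biallelic called variant with per-sample genotypes and alt depths."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, Genotype]
    alt_depth: dict[str, int] = field(default_factory=dict)
    qc_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise FormatError("ref and alt alleles must be non-empty")
        unknown = set(self.qc_flags) - QC_FLAGS
        if unknown:
            raise FormatError(f"unknown qc flags: {sorted(unknown)}")
        self.qc_flags = frozenset(self.qc_flags)

    @property
    def key(self) -> VariantKey:
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def is_x(self, par_regions: Sequence[Tuple[int, int]] = ()) -> bool:
        return is_x_chromosome(self.chrom, self.pos, par_regions)

    def validate_against(self, pedigree: Pedigree) -> None:
        for sid, gt in self.genotypes.items():
            if sid not in pedigree:
                raise FormatError(
                    f"genotype sample {sid!r} absent from pedigree "
                    f"(variant {variant_key_str(self.key)})"
                )
            hemi = gt in (Genotype.HEMI_REF, Genotype.HEMI_ALT)
            if hemi and not (pedigree[sid].sex is Sex.MALE and self.is_x()):
                raise FormatError(
                    f"hemizygous genotype for {sid!r} outside male/chrX "
                    f"(variant {variant_key_str(self.key)})"
                )
        for sid, d in self.alt_depth.items():
            if d < 0:
                raise FormatError(f"negative alt depth for {sid!r}")


@dataclass
class AnnotationRecord:
    """Per-variant annotation: gene, effect class, frequencies, tool calls.

    ``db_frequencies`` maps database name to allele frequency; ``None`` means
    the variant is absent from that database (evidence of rarity, never 0).
    """

    variant_key: VariantKey
    gene: str
    effect: Effect
    hgvs_c: str = ""
    hgvs_p: str = ""
    db_frequencies: dict[str, Optional[float]] = field(default_factory=dict)
    tool_calls: list[ToolCall] = field(default_factory=list)
    conserved_region: bool = False
    is_indel: bool = False
    extras: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for db, f in self.db_frequencies.items():
            if f is not None and not (0.0 <= f <= 1.0):
                raise FormatError(
                    f"frequency {f} for database {db!r} outside [0, 1] "
                    f"(variant {variant_key_str(self.variant_key)})"
                )

    @property
    def present_frequencies(self) -> dict[str, float]:
        return {db: f for db, f in self.db_frequencies.items() if f is not None}

    @property
    def max_present_frequency(self) -> Optional[float]:
        present = self.present_frequencies
        return max(present.values()) if present else None


@dataclass
class GeneEvidence:
    """Gene-level evidence used by candidate prioritisation."""

    gene: str
    disease_associations: frozenset[str] = frozenset()
    tissue_expression: dict[str, ExpressionLevel] = field(default_factory=dict)
    rvis_percentile: Optional[float] = None

    def __post_init__(self) -> None:
        if self.rvis_percentile is not None and not (
            0.0 <= self.rvis_percentile <= 100.0
        ):
            raise FormatError(
                f"RVIS percentile {self.rvis_percentile} outside [0, 100]"
            )
        self.disease_associations = frozenset(self.disease_associations)


class EdgeList:
    """Undirected simple graph as a set of node pairs with optional labels."""

    def __init__(self) -> None:
        self._edges: dict[frozenset, str] = {}

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[Tuple[str, str]] | Iterable[Tuple[str, str, str]]
    ) -> "EdgeList":
        el = cls()
        for pair in pairs:
            el.add(*pair)
        return el

    def add(self, a: str, b: str, label: str = "") -> None:
        if a == b:
            raise FormatError(f"self-loop {a!r}-{b!r} not allowed in edge list")
        key = frozenset((a, b))
        # first label wins; duplicate undirected edges collapse
        self._edges.setdefault(key, label)

    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return frozenset(pair) in self._edges

    def __eq__(self, other: object) -> bool:
        return isinstance(other, EdgeList) and self._edges == other._edges

    def label(self, a: str, b: str) -> str:
        return self._edges[frozenset((a, b))]

    @property
    def nodes(self) -> set:
        out: set = set()
        for key in self._edges:
            out |= key
        return out

    def pairs(self) -> list[Tuple[str, str, str]]:
        """Edges as sorted ``(a, b, label)`` triples with a < b."""
        out = []
        for key, label in self._edges.items():
            a, b = sorted(key)
            out.append((a, b, label))
        return sorted(out)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for a, b, label in self.pairs():
            g.add_edge(a, b, label=label)
        return g


class GeneSetCollection(dict):
    """Mapping of set name -> frozenset of gene symbols (GMT semantics)."""

    def __init__(
        self,
        sets: Mapping[str, Iterable[str]] = (),
        descriptions: Optional[Mapping[str, str]] = None,
    ):
        super().__init__()
        self.descriptions: dict[str, str] = {}
        items = sets.items() if isinstance(sets, Mapping) else sets
        for name, genes in items:
            self.add(name, genes, (descriptions or {}).get(name, ""))

    def add(self, name: str, genes: Iterable[str], description: str = "") -> None:
        if name in self:
            raise FormatError(f"duplicate gene-set name {name!r}")
        self[name] = frozenset(genes)
        self.descriptions[name] = description

    @property
    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for genes in self.values():
            out |= genes
        return out
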