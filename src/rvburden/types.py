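"""Core domain types shared across the pipeline.

Coordinate convention: all internal coordinates are 0-based half-open
(:class:`GenomicRegion`). VCF positions (1-based) are converted at the
readers; a variant at VCF position ``p`` overlaps region ``[s, e)`` iff
``s < p <= e``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional


class Group(enum.Enum):
    CASE = "CASE"
    CONTROL = "CONTROL"


class Sex(enum.Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"
    UNKNOWN = "UNKNOWN"


class Genotype(enum.Enum):
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    HEMI = "HEMI"


class FunctionalClass(enum.Enum):
    STOP_GAIN = "stop_gain"
    FRAMESHIFT = "frameshift"
    CORE_SPLICE = "core_splice"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    NONCODING_EXONIC = "noncoding_exonic"
    OTHER = "other"


#: Functional classes collapsed as loss-of-function.
LOF_CLASSES = frozenset(
    {FunctionalClass.STOP_GAIN, FunctionalClass.FRAMESHIFT, FunctionalClass.CORE_SPLICE}
)


class VariantCategory(enum.Enum):
    """Damage category used by the burden tests; mutually exclusive."""

    LOF = "lof"
    DAMAGING_MISSENSE = "damaging_missense"
    SPLICE_REG = "splice_reg"


#: Broad variant class used as the per-subject normalisation denominator for
#: each category ("all variants of that type", e.g. all missense variants).
BROAD_CLASS = {
    VariantCategory.LOF: "lof",
    VariantCategory.DAMAGING_MISSENSE: "missense",
    VariantCategory.SPLICE_REG: "splice_reg",
}


class NcRnaKind(enum.Enum):
    LINCRNA = "lincRNA"
    MIRNA = "miRNA"


VariantKey = tuple  # (chrom: str, pos: int, ref: str, alt: str)


@dataclass(frozen=True)
class Subject:
    id: str
    group: Group
    sex: Sex = Sex.UNKNOWN


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start >= self.end:
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    def contains_vcf_pos(self, chrom: str, pos: int) -> bool:
        """Whether a 1-based VCF position falls inside this region."""
        return chrom == self.chrom and self.start < pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class VariantCall:
    subject_id: str
    chrom: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    genotype: Genotype
    high_quality: bool = True

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class VariantAnnotation:
    """Functional annotation of a variant, consumed from an external table.

    ``population_afs`` maps database name -> allele frequency; a database in
    which the variant was never observed is simply absent (downstream rarity
    checks treat absence as frequency 0). ``deleterious_calls`` holds one
    boolean per deleteriousness prediction tool and is mandatory (length 7 by
    default) for missense variants. ``splicing_score`` is a predicted change
    in exon inclusion; negative values mean reduced inclusion.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    genes: tuple[str, ...]
    functional_class: FunctionalClass
    population_afs: dict[str, float] = field(default_factory=dict)
    deleterious_calls: Optional[tuple[bool, ...]] = None
    splicing_score: Optional[float] = None

    def __post_init__(self) -> None:
        for db, af in self.population_afs.items():
            if not 0.0 <= af <= 1.0:
                raise ValueError(f"allele frequency {af} for {db} outside [0, 1]")
        if (
            self.functional_class is FunctionalClass.MISSENSE
            and self.deleterious_calls is None
        ):
            raise ValueError(
                f"missense variant {self.key} lacks deleteriousness tool calls"
            )

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A subject's call joined to its annotation, with an assigned category."""

    call: VariantCall
    annotation: VariantAnnotation
    category: VariantCategory

    @property
    def subject_id(self) -> str:
        return self.call.subject_id

    @property
    def genes(self) -> tuple[str, ...]:
        return self.annotation.genes


@dataclass(frozen=True)
class GeneSet:
    name: str
    source: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class PrsSnpRecord:
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str
    log_or: float
    assoc_p: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"effect == other allele at {self.chrom}:{self.pos}")
        if not 0.0 < self.assoc_p <= 1.0:
            raise ValueError(
                f"assoc_p {self.assoc_p} at {self.chrom}:{self.pos} outside (0, 1]"
            )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.effect_allele)


@dataclass(frozen=True)
class NcRnaGene:
    id: str
    kind: NcRnaKind
    regions: tuple[GenomicRegion, ...]
    conservation: float
    per_base_conservation: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        regs = sorted(self.regions)
        for a, b in zip(regs, regs[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping regions within ncRNA gene {self.id}")
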