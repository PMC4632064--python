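"""Variant prioritization: quality, rarity, category assignment, exclusions.

Qualifying variants are high-quality, rare in every population database,
and fall into one of three disjoint damage categories:

* **LoF** — stop-gain/nonsense, frameshift, core splice site;
* **damaging missense** — missense called deleterious by a consensus of
  prediction tools (default at least 5 of 7);
* **splicing regulatory** — predicted to reduce exon inclusion (score at or
  below a negative cutoff), outside the core-splice LoF definition.

Variants in the configured intact 22q11.2 interval and on chromosome X are
set aside into per-subject tallies rather than entering the burden analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .types import (
    AnnotatedVariant,
    BROAD_CLASS,
    FunctionalClass,
    GenomicRegion,
    GeneSet,
    LOF_CLASSES,
    VariantAnnotation,
    VariantCall,
    VariantCategory,
    VariantKey,
)

#: Default rarity threshold (alternate-allele frequency, strict upper bound).
RARITY_THRESHOLD = 0.01
#: Default splicing-regulatory cutoff (percent-units of exon inclusion change).
SPLICE_SCORE_CUTOFF = -5.0
#: Default deleteriousness consensus: >= K of N tools.
CONSENSUS_K = 5
#: Default hg19 span of the typically deleted 22q11.2 interval (configurable).
DEFAULT_22Q11_REGION = GenomicRegion("chr22", 18_900_000, 21_500_000)

_X_CHROMS = frozenset({"chrX", "X", "x", "chrx"})


class MissingAnnotationError(KeyError):
    """A variant call has no matching annotation row."""

    def __init__(self, keys: Sequence[VariantKey]):
        self.keys = list(keys)
        super().__init__(f"{len(self.keys)} call(s) lack annotations, e.g. {self.keys[:5]}")


def is_rare(annotation: VariantAnnotation, threshold: float = RARITY_THRESHOLD) -> bool:
    """True iff every *observed* database frequency is strictly below threshold.

    A variant absent from all databases is vacuously rare.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"rarity threshold {threshold} outside (0, 1]")
    return all(af < threshold for af in annotation.population_afs.values())


def assign_category(
    annotation: VariantAnnotation,
    splice_threshold: float = SPLICE_SCORE_CUTOFF,
    consensus_k: int = CONSENSUS_K,
) -> VariantCategory | None:
    """Assign the damage category, or None if the variant qualifies for none.

    Precedence when a variant satisfies several rules: LoF, then damaging
    missense, then splicing regulatory.
    """
    if annotation.functional_class in LOF_CLASSES:
        return VariantCategory.LOF
    if annotation.functional_class is FunctionalClass.MISSENSE:
        if annotation.deleterious_calls is None:
            raise ValueError(f"missense variant {annotation.key} lacks tool calls")
        if sum(annotation.deleterious_calls) >= consensus_k:
            return VariantCategory.DAMAGING_MISSENSE
    if annotation.splicing_score is not None and annotation.splicing_score <= splice_threshold:
        return VariantCategory.SPLICE_REG
    return None


@dataclass
class PrioritizedVariantSet:
    """Outcome of prioritization: retained variants, exclusion tallies, totals.

    ``totals_category`` counts retained variants per (subject, category);
    ``totals_class`` counts, per subject and broad variant class ("lof",
    "missense", "splice_reg"), *all* high-quality rare variants of that
    class in the retained scope — e.g. all missense, damaging or not —
    which serves as the percent-normalisation denominator.
    """

    retained: list[AnnotatedVariant] = field(default_factory=list)
    region22q11_tally: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    chrx_tally: dict[str, list[AnnotatedVariant]] = field(default_factory=dict)
    totals_category: dict[tuple[str, VariantCategory], int] = field(default_factory=dict)
    totals_class: dict[tuple[str, str], int] = field(default_factory=dict)
    n_discarded: int = 0
    n_input: int = 0

    def class_total(self, subject_id: str, category: VariantCategory) -> int:
        return self.totals_class.get((subject_id, BROAD_CLASS[category]), 0)

    def recount(self) -> dict[tuple[str, VariantCategory], int]:
        """Independent recount of ``totals_category`` from the retained list."""
        counts: dict[tuple[str, VariantCategory], int] = {}
        for av in self.retained:
            k = (av.subject_id, av.category)
            counts[k] = counts.get(k, 0) + 1
        return counts


def _broad_classes_of(
    annotation: VariantAnnotation, category: VariantCategory | None
) -> tuple[str, ...]:
    """Broad classes a variant contributes to as a normalisation denominator.

    A missense variant that ends up categorized as splicing regulatory is
    still a missense variant, so it feeds both the "missense" and the
    "splice_reg" denominators; this keeps every in-set count bounded by its
    own denominator.
    """
    classes: list[str] = []
    if annotation.functional_class in LOF_CLASSES:
        classes.append("lof")
    if annotation.functional_class is FunctionalClass.MISSENSE:
        classes.append("missense")
    if category is VariantCategory.SPLICE_REG:
        classes.append("splice_reg")
    return tuple(classes)


def prioritize(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    regions_22q11: Sequence[GenomicRegion] = (DEFAULT_22Q11_REGION,),
    rarity_threshold: float = RARITY_THRESHOLD,
    splice_threshold: float = SPLICE_SCORE_CUTOFF,
    consensus_k: int = CONSENSUS_K,
) -> PrioritizedVariantSet:
    """Apply quality, rarity, category and exclusion rules to a cohort's calls.

    Every input call lands in exactly one of: retained, 22q11.2 tally,
    X tally, or discarded (low quality, common, or uncategorized). Only
    high-quality, rare, categorized variants enter retained or the tallies.
    """
    missing = [c.key for c in calls if c.key not in annotations]
    if missing:
        raise MissingAnnotationError(missing)

    pvs = PrioritizedVariantSet(n_input=len(calls))
    for call in calls:
        ann = annotations[call.key]
        if not call.high_quality or not is_rare(ann, rarity_threshold):
            pvs.n_discarded += 1
            continue
        category = assign_category(ann, splice_threshold, consensus_k)
        if category is None:
            pvs.n_discarded += 1
            continue
        av = AnnotatedVariant(call=call, annotation=ann, category=category)
        if call.chrom in _X_CHROMS:
            pvs.chrx_tally.setdefault(call.subject_id, []).append(av)
            continue
        if any(r.contains_vcf_pos(call.chrom, call.pos) for r in regions_22q11):
            pvs.region22q11_tally.setdefault(call.subject_id, []).append(av)
            continue
        pvs.retained.append(av)
        key = (call.subject_id, category)
        pvs.totals_category[key] = pvs.totals_category.get(key, 0) + 1
        for broad in _broad_classes_of(ann, category):
            ckey = (call.subject_id, broad)
            pvs.totals_class[ckey] = pvs.totals_class.get(ckey, 0) + 1

    # denominators must also count rare hq missense that fail the tool
    # consensus (they carry no category and were discarded above)
    for call in calls:
        ann = annotations[call.key]
        if not call.high_quality or not is_rare(ann, rarity_threshold):
            continue
        if assign_category(ann, splice_threshold, consensus_k) is not None:
            continue
        if call.chrom in _X_CHROMS or any(
            r.contains_vcf_pos(call.chrom, call.pos) for r in regions_22q11
        ):
            continue
        for broad in _broad_classes_of(ann, None):
            ckey = (call.subject_id, broad)
            pvs.totals_class[ckey] = pvs.totals_class.get(ckey, 0) + 1
    return pvs


def restrict_to(gene_set: GeneSet, restriction: frozenset[str] | set[str]) -> GeneSet | None:
    """Intersect a gene set with a restriction list (e.g. DGCR8-affected genes).

    Returns the restricted set named ``<name>|restricted``, or None when the
    intersection is empty (GeneSet forbids empty membership).
    """
    if not restriction:
        raise ValueError("restriction gene list is empty")
    inter = gene_set.genes & frozenset(g.upper() for g in restriction)
    if not inter:
        return None
    return GeneSet(name=f"{gene_set.name}|restricted", source=gene_set.source, genes=inter)
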