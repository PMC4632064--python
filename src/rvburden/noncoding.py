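"""Burden of rare variants in noncoding RNA genes.

lincRNA burden is counted as *distinct genes hit* per subject (a subject
with several qualifying variants in one gene counts it once), with the
formal test restricted to the most conserved genes (top decile of the
catalog's regional conservation score, ceiling rule with tie inclusion).
miRNA genes, being short, are tallied under a broadened rarity threshold
(<5%) and tested only when the data can support a test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree

from .burden import BurdenTestResult, one_sided_t_test, ratio_of_means
from .prioritize import RARITY_THRESHOLD, is_rare
from .types import (
    Group,
    NcRnaGene,
    NcRnaKind,
    Subject,
    VariantAnnotation,
    VariantCall,
    VariantKey,
)

logger = logging.getLogger(__name__)

#: Default conservation restriction: top decile of the catalog.
CONSERVED_FRACTION = 0.10
#: Broadened rarity threshold for miRNA variants.
MIRNA_RARITY_THRESHOLD = 0.05
#: Minimum cohort-wide qualifying miRNA variants for a burden test.
MIRNA_MIN_TOTAL = 5


@dataclass(frozen=True)
class NcBurdenRow:
    subject_id: str
    group: Group
    n_lincrna_genes_hit: int
    n_conserved_lincrna_genes_hit: int
    n_mirna_variants: int


def rank_conserved(catalog: Sequence[NcRnaGene], fraction: float = CONSERVED_FRACTION) -> set[str]:
    """Ids of the top ``fraction`` most conserved genes (ceil; ties included)."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    if not catalog:
        raise ValueError("catalog is empty")
    ranked = sorted(catalog, key=lambda g: g.conservation, reverse=True)
    k = math.ceil(fraction * len(ranked))
    cut = ranked[k - 1].conservation
    return {g.id for g in ranked if g.conservation >= cut}


def _build_tree(catalog: Sequence[NcRnaGene], kind: NcRnaKind) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in catalog:
        if g.kind is not kind:
            continue
        for r in g.regions:
            trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, g)
    return trees


def _qualifying(
    call: VariantCall,
    annotations: Mapping[VariantKey, VariantAnnotation],
    rarity_threshold: float,
) -> bool:
    if not call.high_quality:
        return False
    ann = annotations.get(call.key)
    if ann is None:
        raise KeyError(f"call {call.key} has no annotation")
    return is_rare(ann, rarity_threshold)


def lincrna_burden(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    catalog: Sequence[NcRnaGene],
    conserved_set: set[str],
    subjects: Sequence[Subject],
    rarity_threshold: float = RARITY_THRESHOLD,
    per_base_cutoff: Optional[float] = None,
) -> tuple[dict[str, tuple[int, int]], Optional[BurdenTestResult]]:
    """Distinct lincRNA genes hit per subject, full catalog and conserved subset.

    Returns ``{subject: (n_genes_hit, n_conserved_genes_hit)}`` and the
    one-sided burden test (case > control) on the conserved-subset counts,
    or None when the conserved set is empty. ``per_base_cutoff`` optionally
    additionally requires the variant position's nucleotide-level
    conservation (when the catalog carries per-base scores) to reach the
    cutoff.
    """
    trees = _build_tree(catalog, NcRnaKind.LINCRNA)
    genes_hit: dict[str, set[str]] = {s.id: set() for s in subjects}
    for call in calls:
        tree = trees.get(call.chrom)
        overlapping = tree[call.pos - 1] if tree is not None else ()
        if not overlapping or call.subject_id not in genes_hit:
            continue
        if not _qualifying(call, annotations, rarity_threshold):
            continue
        for iv in overlapping:
            gene = iv.data
            pb = gene.per_base_conservation
            if (
                per_base_cutoff is not None
                and pb is not None
                and pb.get(call.pos, -math.inf) < per_base_cutoff
            ):
                continue
            genes_hit[call.subject_id].add(gene.id)

    rows = {
        sid: (len(hits), len(hits & conserved_set)) for sid, hits in genes_hit.items()
    }
    if not conserved_set:
        logger.warning("conserved lincRNA set is empty; burden test skipped")
        return rows, None
    case = [rows[s.id][1] for s in subjects if s.group is Group.CASE]
    control = [rows[s.id][1] for s in subjects if s.group is Group.CONTROL]
    t, p = one_sided_t_test(case, control)
    result = BurdenTestResult(
        gene_set="lincRNA|conserved_top_decile",
        category=None,
        restricted=True,
        total_n=len(conserved_set),
        n_case_genes=len(
            {g for s in subjects if s.group is Group.CASE
             for g in (genes_hit[s.id] & conserved_set)}
        ),
        mean_case=float(np.mean(case)),
        mean_control=float(np.mean(control)),
        t_statistic=t,
        p_one_sided=p,
        effect_ratio=ratio_of_means(case, control),
        degenerate=not math.isfinite(t),
    )
    return rows, result


def mirna_tally(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    catalog: Sequence[NcRnaGene],
    subjects: Sequence[Subject],
    rarity_threshold: float = MIRNA_RARITY_THRESHOLD,
    min_total: int = MIRNA_MIN_TOTAL,
) -> tuple[dict[str, int], str, Optional[tuple[float, float]]]:
    """Per-subject qualifying miRNA variant counts and a test/tally decision.

    The burden test is attempted only when both groups have at least one
    subject with a nonzero count and the cohort-wide total reaches
    ``min_total``; otherwise the decision is "tally-only" (mirroring data
    too sparse to support testing). Returns (counts, decision, (t, p)|None).
    """
    trees = _build_tree(catalog, NcRnaKind.MIRNA)
    counts = {s.id: 0 for s in subjects}
    for call in calls:
        tree = trees.get(call.chrom)
        if tree is None or not tree[call.pos - 1]:
            continue
        if _qualifying(call, annotations, rarity_threshold) and call.subject_id in counts:
            counts[call.subject_id] += 1
    case = [counts[s.id] for s in subjects if s.group is Group.CASE]
    control = [counts[s.id] for s in subjects if s.group is Group.CONTROL]
    total = sum(counts.values())
    if total >= min_total and any(c > 0 for c in case) and any(c > 0 for c in control):
        t, p = one_sided_t_test(case, control)
        return counts, "tested", (t, p)
    return counts, "tally-only", None


def run_noncoding_analysis(
    calls: Sequence[VariantCall],
    annotations: Mapping[VariantKey, VariantAnnotation],
    catalog: Sequence[NcRnaGene],
    subjects: Sequence[Subject],
    conserved_fraction: float = CONSERVED_FRACTION,
    lincrna_rarity: float = RARITY_THRESHOLD,
    mirna_rarity: float = MIRNA_RARITY_THRESHOLD,
) -> tuple[list[NcBurdenRow], Optional[BurdenTestResult], str, Optional[tuple[float, float]]]:
    """Full noncoding stage: conservation ranking, lincRNA burden, miRNA tally."""
    lincrnas = [g for g in catalog if g.kind is NcRnaKind.LINCRNA]
    conserved = rank_conserved(lincrnas, conserved_fraction) if lincrnas else set()
    linc_rows, linc_test = lincrna_burden(
        calls, annotations, catalog, conserved, subjects, lincrna_rarity
    )
    mirna_counts, decision, mirna_test = mirna_tally(
        calls, annotations, catalog, subjects, mirna_rarity
    )
    rows = [
        NcBurdenRow(
            subject_id=s.id,
            group=s.group,
            n_lincrna_genes_hit=linc_rows[s.id][0],
            n_conserved_lincrna_genes_hit=linc_rows[s.id][1],
            n_mirna_variants=mirna_counts[s.id],
        )
        for s in subjects
    ]
    return rows, linc_test, decision, mirna_test
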