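"""Polygenic risk scoring from whole-genome calls and reference intervals.

Risk-score SNPs are matched per subject either to a variant call
(coordinates and alleles must agree; the effect-allele dosage a in
{0, 1, 2} comes from the genotype) or to a reference interval (a span
confidently called homozygous reference, matched by coordinate overlap).
Only SNPs resolved in *every* subject are scored. The per-subject score at
an association-p threshold is S = sum_j a_j * beta_j over the SNPs in the
threshold subset, with beta_j = ln(OR_j). Thresholded score sets (including
the >0.5 / >0.9 negative-control bins) are compared between groups with a
one-sided t test, a one-sided Wilcoxon rank-sum test, and the maximum
correctly-predicted percentage over a score-threshold sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .burden import one_sided_t_test
from .types import GenomicRegion, Genotype, Group, PrsSnpRecord, Subject, VariantCall

logger = logging.getLogger(__name__)

#: Association-p subsets used by default: three risk bins and two
#: negative-control bins, (rule, threshold) with rule "le" (inclusive) or
#: "gt" (strict), labelled exactly as printed.
DEFAULT_THRESHOLDS: tuple[tuple[str, str, float], ...] = (
    ("p<=0.001", "le", 0.001),
    ("p<=0.0001", "le", 0.0001),
    ("p<=0.00001", "le", 0.00001),
    ("p>0.5", "gt", 0.5),
    ("p>0.9", "gt", 0.9),
)

#: Exact Wilcoxon enumeration up to this combined sample size; normal
#: approximation with tie correction beyond.
EXACT_WILCOXON_MAX_N = 20


@dataclass
class PrsPanel:
    records: list[PrsSnpRecord]
    callable_snps: list[PrsSnpRecord]  # resolved in every subject
    allele_counts: dict[tuple[str, tuple[str, int, str]], int]  # (subject, snp key) -> 0/1/2


@dataclass(frozen=True)
class PrsScore:
    subject_id: str
    threshold_label: str
    score: float
    n_snps: int


@dataclass
class PrsComparison:
    threshold_label: str
    n_snps: int
    mean_case: float
    mean_control: float
    t_statistic: float
    t_p: float
    wilcoxon_p: float
    max_correct_pct: float
    threshold_at_max: Optional[float] = None


_DOSAGE = {Genotype.HET: 1, Genotype.HOM_ALT: 2, Genotype.HEMI: 1}


def match_panel(
    calls: Sequence[VariantCall],
    reference_intervals: Mapping[str, Sequence[GenomicRegion]],
    records: Sequence[PrsSnpRecord],
    subjects: Sequence[Subject],
    reference_base: Callable[[str, int], str] | None = None,
) -> PrsPanel:
    """Resolve each risk SNP in each subject and keep the fully callable set.

    Resolution per (subject, SNP): a high-quality variant call at the SNP's
    coordinates whose {ref, alt} equal {effect, other} gives the effect-allele
    dosage of the genotype; otherwise a reference interval containing the
    position asserts homozygous reference, giving dosage 2 if the effect
    allele is the reference base and 0 if it is the alternate. Without a
    ``reference_base`` lookup the other_allele is assumed to be the
    reference base (the usual effect/other = A1/A2 table convention).
    A call at the position with non-matching alleles leaves the SNP
    unresolved for that subject (logged, not an error).
    """
    calls_by_site: dict[tuple[str, str, int], list[VariantCall]] = {}
    for c in calls:
        calls_by_site.setdefault((c.subject_id, c.chrom, c.pos), []).append(c)

    allele_counts: dict[tuple[str, tuple[str, int, str]], int] = {}
    resolved_in_all: list[PrsSnpRecord] = []
    for rec in records:
        per_subject: dict[str, int] = {}
        ref_base = reference_base(rec.chrom, rec.pos) if reference_base else rec.other_allele
        for s in subjects:
            site_calls = [
                c for c in calls_by_site.get((s.id, rec.chrom, rec.pos), []) if c.high_quality
            ]
            if site_calls:
                matching = [
                    c for c in site_calls
                    if {c.ref, c.alt} == {rec.effect_allele, rec.other_allele}
                ]
                if not matching:
                    logger.debug(
                        "SNP %s:%d unresolved for %s: alleles do not match",
                        rec.chrom, rec.pos, s.id,
                    )
                    per_subject = {}
                    break
                c = matching[0]
                alt_dose = _DOSAGE[c.genotype]
                a = alt_dose if c.alt == rec.effect_allele else 2 - alt_dose
            else:
                intervals = reference_intervals.get(s.id, ())
                if not any(r.contains_vcf_pos(rec.chrom, rec.pos) for r in intervals):
                    per_subject = {}
                    break
                a = 2 if rec.effect_allele == ref_base else 0
            per_subject[s.id] = a
        if len(per_subject) == len(subjects):
            resolved_in_all.append(rec)
            for sid, a in per_subject.items():
                allele_counts[(sid, rec.key)] = a
    return PrsPanel(records=list(records), callable_snps=resolved_in_all, allele_counts=allele_counts)


def subset_by_threshold(
    records: Sequence[PrsSnpRecord], rule: str, tau: float
) -> list[PrsSnpRecord]:
    """SNPs with assoc_p <= tau (rule "le") or assoc_p > tau (rule "gt")."""
    if not 0.0 < tau < 1.0:
        raise ValueError(f"threshold {tau} outside (0, 1)")
    if rule == "le":
        return [r for r in records if r.assoc_p <= tau]
    if rule == "gt":
        return [r for r in records if r.assoc_p > tau]
    raise ValueError(f"unknown threshold rule {rule!r}")


def score_subjects(
    panel: PrsPanel,
    subset: Sequence[PrsSnpRecord],
    subjects: Sequence[Subject],
    threshold_label: str = "",
) -> list[PrsScore]:
    """Per-subject score S_i = sum_j a_ij * beta_j over the subset.

    The sum is accumulated in sorted SNP-key order so the result is
    independent of input ordering.
    """
    callable_keys = {r.key for r in panel.callable_snps}
    used = sorted((r for r in subset if r.key in callable_keys), key=lambda r: r.key)
    scores = []
    for s in subjects:
        total = 0.0
        for rec in used:
            total += panel.allele_counts[(s.id, rec.key)] * rec.log_or
        scores.append(PrsScore(subject_id=s.id, threshold_label=threshold_label, score=total, n_snps=len(used)))
    return scores


def max_correct_percentage(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    balanced: bool = True,
) -> tuple[float, Optional[float]]:
    """Maximum correctly-predicted percentage over a score-threshold sweep.

    Candidate thresholds are midpoints of adjacent distinct scores (plus the
    all-case / all-control extremes); a subject scoring above the threshold
    is predicted a case. ``balanced`` (default) averages the per-group
    percent correct; the flag disables balancing in favour of overall
    accuracy. Returns (percentage, threshold achieving it).
    """
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    all_scores = np.unique(np.concatenate([x, y]))
    if all_scores.size == 1:
        return 50.0, None
    mids = (all_scores[:-1] + all_scores[1:]) / 2.0
    candidates = np.concatenate([[all_scores[0] - 1.0], mids, [all_scores[-1] + 1.0]])
    best, best_thr = -1.0, None
    for thr in candidates:
        case_correct = float((x > thr).mean())
        control_correct = float((y <= thr).mean())
        if balanced:
            pct = 50.0 * (case_correct + control_correct)
        else:
            n = len(x) + len(y)
            pct = 100.0 * ((x > thr).sum() + (y <= thr).sum()) / n
        if pct > best:
            best, best_thr = pct, float(thr)
    return best, best_thr


def compare_groups(
    scores: Sequence[PrsScore],
    subjects: Sequence[Subject],
    balanced: bool = True,
) -> PrsComparison:
    """Group comparison of one threshold bin's scores (case > control).

    Wilcoxon rank-sum: exact null enumeration for combined n <= 20 without
    ties, normal approximation with tie correction otherwise.
    """
    by_id = {sc.subject_id: sc for sc in scores}
    case = [by_id[s.id].score for s in subjects if s.group is Group.CASE]
    control = [by_id[s.id].score for s in subjects if s.group is Group.CONTROL]
    if not case or not control:
        raise ValueError("both groups must be non-empty")
    label = scores[0].threshold_label if scores else ""
    n_snps = scores[0].n_snps if scores else 0
    if len(set(case + control)) == 1:
        pct, thr = 50.0, None
        t_stat, t_p, w_p = 0.0, 0.5, 0.5
    else:
        t_stat, t_p = one_sided_t_test(case, control)
        has_ties = len(set(case + control)) < len(case) + len(control)
        method = "exact" if (len(case) + len(control) <= EXACT_WILCOXON_MAX_N and not has_ties) else "asymptotic"
        w_p = float(stats.mannwhitneyu(case, control, alternative="greater", method=method).pvalue)
        pct, thr = max_correct_percentage(case, control, balanced=balanced)
    return PrsComparison(
        threshold_label=label,
        n_snps=n_snps,
        mean_case=float(np.mean(case)),
        mean_control=float(np.mean(control)),
        t_statistic=t_stat,
        t_p=t_p,
        wilcoxon_p=w_p,
        max_correct_pct=pct,
        threshold_at_max=thr,
    )


def run_prs_analysis(
    calls: Sequence[VariantCall],
    reference_intervals: Mapping[str, Sequence[GenomicRegion]],
    records: Sequence[PrsSnpRecord],
    subjects: Sequence[Subject],
    thresholds: Sequence[tuple[str, str, float]] = DEFAULT_THRESHOLDS,
    reference_base: Callable[[str, int], str] | None = None,
) -> tuple[PrsPanel, dict[str, list[PrsScore]], list[PrsComparison]]:
    """Match the panel once, then score and compare per threshold bin."""
    panel = match_panel(calls, reference_intervals, records, subjects, reference_base)
    all_scores: dict[str, list[PrsScore]] = {}
    comparisons: list[PrsComparison] = []
    for label, rule, tau in thresholds:
        subset = subset_by_threshold(panel.callable_snps, rule, tau)
        scores = score_subjects(panel, subset, subjects, threshold_label=label)
        all_scores[label] = scores
        comparisons.append(compare_groups(scores, subjects))
    return panel, all_scores, comparisons
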