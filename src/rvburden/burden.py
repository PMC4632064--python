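"""Case/control gene-set burden testing.

Per subject and variant category, the burden in a gene set is the count
``k`` of qualifying variants whose gene annotation intersects the set.
Burdens are percent-normalised before testing:

    b = 100 * k / K,

where ``K`` is the subject's genome-wide count of all variants of that
broad class (e.g. all rare missense variants), correcting for overall
variant load. Group comparison uses a one-sided (case > control)
pooled-variance two-sample t test. Gene sets nominally significant for at
least one category are then tested jointly across the three categories
with a two-sample Hotelling T-square test, and effect sizes are reported
as the between-group ratio of mean absolute variant counts ("nc" when the
control group carries no variants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .prioritize import PrioritizedVariantSet, restrict_to
from .types import GeneSet, Group, Subject, VariantCategory

#: Screening thresholds: nominal one-sided p below which a gene set enters
#: the joint (Hotelling) stage, per variant category.
SCREEN_P_MISSENSE = 0.05
SCREEN_P_LOF_SPLICE = 0.10
#: Display rule: a gene set is "portrayed" when some nominal p < 0.05 and the
#: set has fewer than this many genes.
DISPLAY_MAX_GENES = 2000
DISPLAY_P = 0.05


@dataclass
class BurdenMatrix:
    gene_set: GeneSet
    category: VariantCategory
    counts: dict[str, int]      # subject -> k (variants in set)
    totals: dict[str, int]      # subject -> K (genome-wide broad-class count)
    percents: dict[str, float]  # subject -> 100 * k / K (0 when K == 0)


@dataclass
class BurdenTestResult:
    gene_set: str
    category: Optional[VariantCategory]  # None for non-categorical (ncRNA) burdens
    restricted: bool
    total_n: int                 # genes in the (possibly restricted) set
    n_case_genes: int            # distinct set genes hit in the case group
    mean_case: float             # raw per-subject count means, as displayed
    mean_control: float
    t_statistic: float
    p_one_sided: float
    effect_ratio: Optional[float]  # None encodes "nc" (control mean zero)
    degenerate: bool = False


@dataclass
class JointBurdenResult:
    gene_set: str
    t2: float
    f_statistic: float
    df1: int
    df2: int
    p_value: float
    categories: tuple[VariantCategory, ...] = (
        VariantCategory.LOF,
        VariantCategory.DAMAGING_MISSENSE,
        VariantCategory.SPLICE_REG,
    )


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled covariance is singular; carries the offending variable indices."""

    def __init__(self, indices: Sequence[int]):
        self.indices = list(indices)
        super().__init__(
            f"singular pooled covariance; zero-variance or dependent variable "
            f"indices: {self.indices} (drop degenerate categories and rerun)"
        )


def burden_matrix(
    pvs: PrioritizedVariantSet,
    gene_set: GeneSet,
    category: VariantCategory,
    subjects: Sequence[Subject],
) -> BurdenMatrix:
    """Per-subject in-set counts, genome-wide denominators, and percents.

    A variant is counted once per subject even when it is annotated to two
    genes of the set.
    """
    counts = {s.id: 0 for s in subjects}
    for av in pvs.retained:
        if av.category is category and any(g in gene_set.genes for g in av.genes):
            counts[av.subject_id] = counts.get(av.subject_id, 0) + 1
    totals = {s.id: pvs.class_total(s.id, category) for s in subjects}
    percents = {
        sid: (100.0 * counts[sid] / totals[sid]) if totals[sid] > 0 else 0.0
        for sid in counts
    }
    return BurdenMatrix(gene_set=gene_set, category=category, counts=counts, totals=totals, percents=percents)


def one_sided_t_test(
    case_values: Sequence[float],
    control_values: Sequence[float],
    welch: bool = False,
) -> tuple[float, float]:
    """One-sided two-sample t test, alternative: case mean > control mean.

    Pooled-variance (Student) by default; Welch by flag. Degenerate inputs
    (zero pooled variance) yield p = 0.5 for equal means, else p -> 0 or 1
    by the sign of the mean difference.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two values per group")
    diff = x.mean() - y.mean()
    if welch:
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        se2 = v1 / n1 + v2 / n2
        if se2 == 0.0:
            return _degenerate_t(diff)
        t = diff / math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
        if sp2 == 0.0:
            return _degenerate_t(diff)
        t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), float(stats.t.sf(t, df))


def _degenerate_t(diff: float) -> tuple[float, float]:
    if diff == 0.0:
        return 0.0, 0.5
    return (math.inf, 0.0) if diff > 0 else (-math.inf, 1.0)


def ratio_of_means(
    case_counts: Sequence[float], control_counts: Sequence[float]
) -> Optional[float]:
    """Between-group ratio of mean absolute variant counts; None = "nc"."""
    mc = float(np.mean(case_counts))
    mn = float(np.mean(control_counts))
    if mn == 0.0:
        return None
    return mc / mn


def screen_gene_sets(
    results: Sequence[BurdenTestResult],
    p_missense: float = SCREEN_P_MISSENSE,
    p_lof_splice: float = SCREEN_P_LOF_SPLICE,
) -> list[str]:
    """Gene sets whose burden is nominally significant for >= 1 category.

    Thresholds (strict <): ``p_missense`` for damaging missense,
    ``p_lof_splice`` for LoF and splicing regulatory. Order of first
    qualification is preserved, duplicates removed.
    """
    passed: list[str] = []
    for r in results:
        thr = p_missense if r.category is VariantCategory.DAMAGING_MISSENSE else p_lof_splice
        if r.p_one_sided < thr and r.gene_set not in passed:
            passed.append(r.gene_set)
    return passed


def hotelling_t2(
    case_matrix: np.ndarray,
    control_matrix: np.ndarray,
    gene_set: str = "",
) -> JointBurdenResult:
    """Two-sample Hotelling T-square test on per-subject burden vectors.

    T2 = (n1*n2/(n1+n2)) * d' S^-1 d, with d the mean-difference vector and
    S the pooled covariance; the p-value comes from the exact F transform
    F = ((n1+n2-p-1) / (p*(n1+n2-2))) * T2 ~ F(p, n1+n2-p-1).
    """
    x = np.atleast_2d(np.asarray(case_matrix, dtype=float))
    y = np.atleast_2d(np.asarray(control_matrix, dtype=float))
    n1, p = x.shape
    n2, p2 = y.shape
    if p != p2:
        raise ValueError("case and control matrices differ in variable count")
    if n1 + n2 - 2 < p:
        raise ValueError(f"too few subjects ({n1}+{n2}) for {p} variables")
    d = x.mean(axis=0) - y.mean(axis=0)
    s = ((n1 - 1) * np.cov(x, rowvar=False, ddof=1).reshape(p, p)
         + (n2 - 1) * np.cov(y, rowvar=False, ddof=1).reshape(p, p)) / (n1 + n2 - 2)
    zero_var = [int(i) for i in range(p) if s[i, i] == 0.0]
    if zero_var or np.linalg.matrix_rank(s) < p:
        raise SingularCovarianceError(zero_var if zero_var else list(range(p)))
    t2 = float(n1 * n2 / (n1 + n2) * d @ np.linalg.solve(s, d))
    df1, df2 = p, n1 + n2 - p - 1
    f = (df2 / (p * (n1 + n2 - 2))) * t2
    p_value = float(stats.f.sf(f, df1, df2))
    return JointBurdenResult(gene_set=gene_set, t2=t2, f_statistic=float(f), df1=df1, df2=df2, p_value=p_value)


@dataclass
class BurdenAnalysisResult:
    """Full result table of the burden analysis."""

    univariate: list[BurdenTestResult] = field(default_factory=list)
    joint: list[JointBurdenResult] = field(default_factory=list)
    screened: list[str] = field(default_factory=list)
    displayed: list[str] = field(default_factory=list)
    skipped_joint: dict[str, str] = field(default_factory=dict)


def _split_by_group(
    values: Mapping[str, float], subjects: Sequence[Subject]
) -> tuple[list[float], list[float]]:
    case = [values[s.id] for s in subjects if s.group is Group.CASE]
    control = [values[s.id] for s in subjects if s.group is Group.CONTROL]
    return case, control


def _test_one(
    pvs: PrioritizedVariantSet,
    gs: GeneSet,
    category: VariantCategory,
    subjects: Sequence[Subject],
    restricted: bool,
    welch: bool,
) -> BurdenTestResult:
    bm = burden_matrix(pvs, gs, category, subjects)
    case_pct, control_pct = _split_by_group(bm.percents, subjects)
    case_k, control_k = _split_by_group(bm.counts, subjects)
    t, p = one_sided_t_test(case_pct, control_pct, welch=welch)
    case_ids = {s.id for s in subjects if s.group is Group.CASE}
    hit_genes = {
        g
        for av in pvs.retained
        if av.category is category and av.subject_id in case_ids
        for g in av.genes
        if g in gs.genes
    }
    return BurdenTestResult(
        gene_set=gs.name,
        category=category,
        restricted=restricted,
        total_n=len(gs),
        n_case_genes=len(hit_genes),
        mean_case=float(np.mean(case_k)),
        mean_control=float(np.mean(control_k)),
        t_statistic=t,
        p_one_sided=p,
        effect_ratio=ratio_of_means(case_k, control_k),
        degenerate=not math.isfinite(t),
    )


def run_burden_analysis(
    pvs: PrioritizedVariantSet,
    gene_sets: Sequence[GeneSet],
    subjects: Sequence[Subject],
    restriction: Optional[frozenset[str]] = None,
    p_missense: float = SCREEN_P_MISSENSE,
    p_lof_splice: float = SCREEN_P_LOF_SPLICE,
    hotelling_scale: str = "percent",
    drop_degenerate: bool = False,
    welch: bool = False,
    display_max_genes: int = DISPLAY_MAX_GENES,
) -> BurdenAnalysisResult:
    """Univariate burden tests for every gene set (and restricted twin),
    screening, and the joint Hotelling stage for screened sets.

    ``hotelling_scale`` selects percent-normalised ("percent") or raw-count
    ("count") per-subject vectors for the joint test. With
    ``drop_degenerate`` a zero-variance category is removed (lowering the
    dimension) instead of raising.
    """
    if hotelling_scale not in ("percent", "count"):
        raise ValueError(f"unknown hotelling_scale {hotelling_scale!r}")
    result = BurdenAnalysisResult()
    all_sets: list[tuple[GeneSet, bool]] = []
    for gs in gene_sets:
        all_sets.append((gs, False))
        if restriction:
            rgs = restrict_to(gs, restriction)
            if rgs is not None:
                all_sets.append((rgs, True))

    for gs, is_restricted in all_sets:
        for category in VariantCategory:
            result.univariate.append(
                _test_one(pvs, gs, category, subjects, is_restricted, welch)
            )

    result.screened = screen_gene_sets(result.univariate, p_missense, p_lof_splice)
    by_name = {gs.name: gs for gs, _ in all_sets}
    for name in result.screened:
        gs = by_name[name]
        vectors = []
        cats = []
        for category in VariantCategory:
            bm = burden_matrix(pvs, gs, category, subjects)
            vals = bm.percents if hotelling_scale == "percent" else {k: float(v) for k, v in bm.counts.items()}
            case_v, control_v = _split_by_group(vals, subjects)
            vectors.append((case_v, control_v))
            cats.append(category)
        x = np.column_stack([v[0] for v in vectors])
        y = np.column_stack([v[1] for v in vectors])
        try:
            jr = hotelling_t2(x, y, gene_set=name)
            jr.categories = tuple(cats)
        except SingularCovarianceError as exc:
            if not drop_degenerate:
                result.skipped_joint[name] = str(exc)
                continue
            keep = [i for i in range(x.shape[1]) if i not in exc.indices]
            if not keep:
                result.skipped_joint[name] = "all categories degenerate"
                continue
            try:
                jr = hotelling_t2(x[:, keep], y[:, keep], gene_set=name)
            except SingularCovarianceError as exc2:
                result.skipped_joint[name] = str(exc2)
                continue
            jr.categories = tuple(cats[i] for i in keep)
        result.joint.append(jr)

    seen: set[str] = set()
    for r in result.univariate:
        if r.p_one_sided < DISPLAY_P and r.total_n < display_max_genes and r.gene_set not in seen:
            seen.add(r.gene_set)
            result.displayed.append(r.gene_set)
    return result
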