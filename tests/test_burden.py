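"""Burden statistics: t test, ratio of means, screening, Hotelling T-square."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.spatial.distance import mahalanobis

from rvburden.burden import (
    BurdenTestResult,
    SingularCovarianceError,
    burden_matrix,
    hotelling_t2,
    one_sided_t_test,
    ratio_of_means,
    run_burden_analysis,
    screen_gene_sets,
)
from rvburden.prioritize import prioritize
from rvburden.types import VariantCategory


# ---------------------------------------------------------------------------
# one-sided pooled t


def test_t_test_hand_computed_example():
    # pooled variance 78/7, se = sp*sqrt(1/2), t = 5/2.3605 -> 2.118;
    # upper tail of Student t with 7 df -> 0.0359
    t, p = one_sided_t_test([10, 12, 14, 16, 18, 20], [8, 10, 12])
    assert t == pytest.approx(2.118, abs=1e-3)
    assert p == pytest.approx(0.0359, abs=5e-4)


def test_t_test_symmetric_null_point():
    t, p = one_sided_t_test([1.0, 2.0, 3.0], [1.0, 3.0, 2.0])
    assert t == 0.0 and p == 0.5


def test_t_test_wrong_direction_has_large_p():
    _, p = one_sided_t_test([0, 1, 2], [1, 2, 3])
    assert p > 0.5


def test_t_test_degenerate_zero_variance():
    assert one_sided_t_test([2, 2, 2], [2, 2, 2]) == (0.0, 0.5)
    t, p = one_sided_t_test([3, 3, 3], [2, 2, 2])
    assert math.isinf(t) and p == 0.0
    t, p = one_sided_t_test([1, 1, 1], [2, 2, 2])
    assert p == 1.0


@given(
    case=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
    control=st.lists(st.floats(-50, 50), min_size=2, max_size=8),
)
def test_t_test_matches_scipy_reference(case, control):
    """Cross-check the pooled implementation against scipy's Student t test."""
    if np.var(case, ddof=1) == 0 and np.var(control, ddof=1) == 0:
        return  # scipy returns nan on zero pooled variance; our convention differs
    t, p = one_sided_t_test(case, control)
    ref = stats.ttest_ind(case, control, equal_var=True, alternative="greater")
    assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
    assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# ratio of means


def test_ratio_of_means_published_rows():
    # case total 54 over 6 subjects vs control total 15 over 3 -> 1.80
    assert ratio_of_means([9] * 6, [5] * 3) == pytest.approx(1.80)
    assert ratio_of_means([8, 9, 10, 9, 8, 10], [4, 5, 6]) == pytest.approx(1.80)


def test_ratio_of_means_nc_when_control_zero():
    assert ratio_of_means([1, 2, 3], [0, 0, 0]) is None
    assert ratio_of_means([0, 0], [0, 0]) is None


def test_ratio_of_means_identity():
    assert ratio_of_means([2, 4], [3, 3]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# screening


def _res(name, category, p):
    return BurdenTestResult(
        gene_set=name, category=category, restricted=False, total_n=10,
        n_case_genes=1, mean_case=1, mean_control=1, t_statistic=0.0,
        p_one_sided=p, effect_ratio=1.0,
    )


def test_screen_thresholds_by_category():
    results = [
        _res("A", VariantCategory.DAMAGING_MISSENSE, 0.009),  # passes at <0.05
        _res("B", VariantCategory.LOF, 0.128),                # fails at <0.10
        _res("C", VariantCategory.LOF, 0.047),                # passes at <0.10
        _res("D", VariantCategory.DAMAGING_MISSENSE, 0.07),   # fails at <0.05
        _res("D", VariantCategory.SPLICE_REG, 0.09),          # rescues D at <0.10
    ]
    assert screen_gene_sets(results) == ["A", "C", "D"]


def test_screen_all_null_is_empty():
    results = [_res("A", c, 1.0) for c in VariantCategory]
    assert screen_gene_sets(results) == []


# ---------------------------------------------------------------------------
# Hotelling T-square


def test_hotelling_reduces_to_squared_t_in_1d():
    rng = np.random.default_rng(3)
    x = rng.normal(1.0, 1.0, size=(6, 1))
    y = rng.normal(0.0, 1.0, size=(3, 1))
    jr = hotelling_t2(x, y)
    t, _ = one_sided_t_test(x.ravel(), y.ravel())
    assert jr.t2 == pytest.approx(t**2, rel=1e-12)
    two_sided = 2 * min(stats.t.sf(t, 7), stats.t.cdf(t, 7))
    assert jr.p_value == pytest.approx(two_sided, abs=1e-10)


def test_hotelling_equal_means_gives_zero():
    x = np.array([[1.0, 2.0], [3.0, 1.0], [2.0, 3.0], [2.0, 2.0]])
    y = x.copy()
    jr = hotelling_t2(x, y)
    assert jr.t2 == pytest.approx(0.0, abs=1e-12)
    assert jr.p_value == pytest.approx(1.0)


def test_hotelling_matches_direct_mahalanobis_oracle():
    """T2 equals the squared Mahalanobis distance of the group means under
    the pooled covariance scaled by (1/n1 + 1/n2), computed independently."""
    rng = np.random.default_rng(12)
    x = rng.normal(0.5, 1.0, size=(6, 3))
    y = rng.normal(0.0, 1.0, size=(3, 3))
    n1, n2, p = 6, 3, 3
    s = ((n1 - 1) * np.cov(x, rowvar=False) + (n2 - 1) * np.cov(y, rowvar=False)) / (n1 + n2 - 2)
    dist = mahalanobis(x.mean(axis=0), y.mean(axis=0), np.linalg.inv(s * (1 / n1 + 1 / n2)))
    jr = hotelling_t2(x, y)
    assert jr.t2 == pytest.approx(dist**2, rel=1e-10)
    assert (jr.df1, jr.df2) == (p, n1 + n2 - p - 1)
    f = ((n1 + n2 - p - 1) / (p * (n1 + n2 - 2))) * jr.t2
    assert jr.p_value == pytest.approx(stats.f.sf(f, p, n1 + n2 - p - 1))


def test_hotelling_singular_covariance_names_indices():
    x = np.column_stack([np.ones(5), np.random.default_rng(0).normal(size=5)])
    y = np.column_stack([np.ones(4), np.random.default_rng(1).normal(size=4)])
    with pytest.raises(SingularCovarianceError) as exc:
        hotelling_t2(x, y)
    assert exc.value.indices == [0]


# ---------------------------------------------------------------------------
# full analysis on fixtures


def test_scale_invariance_of_percent_normalisation(cohort_bundle):
    """Doubling every subject's k and K leaves percents, t, p, ratio as-is
    (ratio is on raw counts, so it scales out too)."""
    from rvburden.burden import one_sided_t_test as t_test

    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    gs = b.gene_sets[0]
    bm = burden_matrix(pvs, gs, VariantCategory.DAMAGING_MISSENSE, b.subjects)
    case = [s.id for s in b.subjects if s.group.name == "CASE"]
    control = [s.id for s in b.subjects if s.group.name == "CONTROL"]
    pct = lambda k, K: 100.0 * k / K if K else 0.0
    for c in (1, 3, 10):
        scaled = {sid: pct(c * bm.counts[sid], c * bm.totals[sid]) for sid in bm.counts}
        assert scaled == pytest.approx(bm.percents)
    t1, p1 = t_test([bm.percents[s] for s in case], [bm.percents[s] for s in control])
    t2_, p2 = t_test(
        [pct(5 * bm.counts[s], 5 * bm.totals[s]) for s in case],
        [pct(5 * bm.counts[s], 5 * bm.totals[s]) for s in control],
    )
    assert (t1, p1) == pytest.approx((t2_, p2))


def test_burden_matrix_counts_variant_once_across_set_genes(worked_bundle):
    """A variant annotated to two genes of the same set adds 1, not 2."""
    from dataclasses import replace

    b = worked_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    gs = next(s for s in b.gene_sets if s.name == "NEURON_PROJECTION")
    av = next(
        av for av in pvs.retained
        if av.category is VariantCategory.DAMAGING_MISSENSE and av.genes[0] in gs.genes
    )
    two_genes = replace(av, annotation=replace(av.annotation, genes=(av.genes[0], "NP_G2")))
    pvs.retained[pvs.retained.index(av)] = two_genes
    bm = burden_matrix(pvs, gs, VariantCategory.DAMAGING_MISSENSE, b.subjects)
    oracle = sum(
        1
        for x in pvs.retained
        if x.subject_id == av.subject_id
        and x.category is VariantCategory.DAMAGING_MISSENSE
        and any(g in gs.genes for g in x.genes)
    )
    assert bm.counts[av.subject_id] == oracle
    pvs.retained[pvs.retained.index(two_genes)] = av  # restore shared fixture


def test_burden_matrix_brute_force_recount(cohort_bundle):
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    for gs in b.gene_sets:
        for cat in VariantCategory:
            bm = burden_matrix(pvs, gs, cat, b.subjects)
            for s in b.subjects:
                k = sum(
                    1
                    for av in pvs.retained
                    if av.subject_id == s.id and av.category is cat
                    and any(g in gs.genes for g in av.genes)
                )
                assert bm.counts[s.id] == k


def test_run_burden_analysis_enriched_set_is_screened(cohort_bundle):
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    res = run_burden_analysis(pvs, b.gene_sets, b.subjects, restriction=b.dgcr8_genes)
    assert "NEURON_PROJECTION" in res.screened
    names = {r.gene_set for r in res.univariate}
    assert "NEURON_PROJECTION|restricted" in names
    assert all(j.gene_set in res.screened for j in res.joint)


def test_run_burden_analysis_empty_collection(cohort_bundle):
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    res = run_burden_analysis(pvs, [], b.subjects)
    assert res.univariate == [] and res.joint == [] and res.screened == []
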