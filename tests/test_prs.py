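"""PRS matching, threshold subsets, scoring, and group comparison."""

import math

import pytest

from rvburden.prs import (
    DEFAULT_THRESHOLDS,
    compare_groups,
    match_panel,
    max_correct_percentage,
    score_subjects,
    subset_by_threshold,
    PrsPanel,
    PrsScore,
)
from rvburden.types import (
    GenomicRegion,
    Genotype,
    Group,
    PrsSnpRecord,
    Subject,
    VariantCall,
)


def _rec(pos, effect="A", other="G", log_or=0.1, p=0.001):
    return PrsSnpRecord("chr2", pos, effect, other, log_or, p)


def _subjects(n_case=2, n_control=1):
    return [Subject(f"SCZ{i}", Group.CASE) for i in range(n_case)] + [
        Subject(f"NP{i}", Group.CONTROL) for i in range(n_control)
    ]


SPAN = {"": [GenomicRegion("chr2", 0, 10_000)]}


def _intervals(subjects):
    return {s.id: SPAN[""] for s in subjects}


# ---------------------------------------------------------------------------
# matching


def test_dosage_from_genotype_and_reference_interval():
    subjects = _subjects(2, 1)
    # effect allele is the alternate: HET -> 1, HOM_ALT -> 2, homref -> 0
    calls = [
        VariantCall("SCZ0", "chr2", 100, "G", "A", Genotype.HET),
        VariantCall("SCZ1", "chr2", 100, "G", "A", Genotype.HOM_ALT),
    ]
    panel = match_panel(calls, _intervals(subjects), [_rec(100)], subjects)
    assert [r.pos for r in panel.callable_snps] == [100]
    key = panel.callable_snps[0].key
    assert panel.allele_counts[("SCZ0", key)] == 1
    assert panel.allele_counts[("SCZ1", key)] == 2
    assert panel.allele_counts[("NP0", key)] == 0


def test_reference_interval_gives_two_when_effect_is_reference():
    subjects = _subjects(1, 1)
    rec = _rec(100, effect="G", other="A")
    # with a genome lookup naming G the reference base, homref spans carry 2
    panel = match_panel([], _intervals(subjects), [rec], subjects,
                        reference_base=lambda chrom, pos: "G")
    assert panel.allele_counts[("SCZ0", rec.key)] == 2
    # under the default table convention (other_allele = reference) the same
    # span carries 0 effect alleles
    panel0 = match_panel([], _intervals(subjects), [rec], subjects)
    assert panel0.allele_counts[("SCZ0", rec.key)] == 0


def test_effect_on_ref_with_het_call_counts_remaining_alleles():
    subjects = _subjects(1, 0) + [Subject("NP0", Group.CONTROL)]
    rec = _rec(100, effect="G", other="A")
    calls = [VariantCall("SCZ0", "chr2", 100, "G", "A", Genotype.HET)]
    panel = match_panel(calls, _intervals(subjects), [rec], subjects)
    assert panel.allele_counts[("SCZ0", rec.key)] == 1  # one G left


def test_unresolved_in_one_subject_drops_snp_for_all():
    subjects = _subjects(2, 1)
    intervals = _intervals(subjects)
    intervals["SCZ1"] = []  # no call, no interval -> unresolved
    panel = match_panel([], intervals, [_rec(100)], subjects)
    assert panel.callable_snps == []
    assert panel.allele_counts == {}


def test_allele_mismatch_leaves_snp_unresolved():
    subjects = _subjects(1, 1)
    calls = [VariantCall("SCZ0", "chr2", 100, "G", "T", Genotype.HET)]  # T not in panel
    panel = match_panel(calls, _intervals(subjects), [_rec(100)], subjects)
    assert panel.callable_snps == []


# ---------------------------------------------------------------------------
# threshold subsets


def test_subset_rules_inclusive_and_strict():
    recs = [_rec(1, p=0.0005), _rec(2, p=0.005), _rec(3, p=0.95), _rec(4, p=0.001)]
    assert {r.pos for r in subset_by_threshold(recs, "le", 0.001)} == {1, 4}
    assert {r.pos for r in subset_by_threshold(recs, "gt", 0.9)} == {3}
    assert subset_by_threshold([], "le", 0.5) == []


def test_threshold_subsets_are_nested(cohort_bundle):
    recs = cohort_bundle.prs_records
    subsets = [
        {r.key for r in subset_by_threshold(recs, "le", tau)}
        for tau in (0.00001, 0.0001, 0.001)
    ]
    assert subsets[0] <= subsets[1] <= subsets[2]


def test_default_threshold_labels_match_published_bins():
    assert [t[0] for t in DEFAULT_THRESHOLDS] == [
        "p<=0.001", "p<=0.0001", "p<=0.00001", "p>0.5", "p>0.9",
    ]


# ---------------------------------------------------------------------------
# scoring


def _panel_with_counts(subjects, recs, counts):
    allele_counts = {
        (s.id, r.key): counts[s.id][i] for s in subjects for i, r in enumerate(recs)
    }
    return PrsPanel(records=list(recs), callable_snps=list(recs), allele_counts=allele_counts)


def test_score_arithmetic():
    subjects = [Subject("S1", Group.CASE)]
    recs = [_rec(1, log_or=math.log(1.2)), _rec(2, log_or=math.log(0.9))]
    panel = _panel_with_counts(subjects, recs, {"S1": [2, 1]})
    (score,) = score_subjects(panel, recs, subjects)
    assert score.score == pytest.approx(2 * math.log(1.2) + math.log(0.9), abs=1e-9)
    assert score.n_snps == 2


def test_score_zero_counts_and_linearity():
    subjects = [Subject("S1", Group.CASE)]
    recs = [_rec(1, log_or=0.3), _rec(2, log_or=-0.1)]
    zero = _panel_with_counts(subjects, recs, {"S1": [0, 0]})
    assert score_subjects(zero, recs, subjects)[0].score == 0.0
    panel = _panel_with_counts(subjects, recs, {"S1": [1, 2]})
    (s1,) = score_subjects(panel, recs, subjects)
    doubled = [PrsSnpRecord(r.chrom, r.pos, r.effect_allele, r.other_allele, 2 * r.log_or, r.assoc_p) for r in recs]
    panel2 = _panel_with_counts(subjects, doubled, {"S1": [1, 2]})
    (s2,) = score_subjects(panel2, doubled, subjects)
    assert s2.score == pytest.approx(2 * s1.score)


def test_score_invariant_to_snp_order():
    subjects = _subjects(1, 1)
    recs = [_rec(i, log_or=0.01 * i, p=0.0001) for i in range(1, 30)]
    counts = {s.id: [(i + hash(s.id)) % 3 for i in range(29)] for s in subjects}
    panel = _panel_with_counts(subjects, recs, counts)
    fwd = score_subjects(panel, recs, subjects)
    rev = score_subjects(panel, list(reversed(recs)), subjects)
    for a, b in zip(fwd, rev):
        assert a.score == b.score  # bit-identical


# ---------------------------------------------------------------------------
# group comparison


def _scores(values, subjects, label="t"):
    return [
        PrsScore(s.id, label, v, 1) for s, v in zip(subjects, values)
    ]


def test_complete_separation_exact_wilcoxon():
    """6 cases all above 3 controls: one arrangement of C(9,3) = 84 is as
    extreme, so the one-sided exact p is 1/84."""
    subjects = _subjects(6, 3)
    scores = _scores([4, 5, 6, 7, 8, 9, 1, 2, 3], subjects)
    cmp = compare_groups(scores, subjects)
    assert cmp.wilcoxon_p == pytest.approx(1 / 84, abs=1e-12)
    assert cmp.max_correct_pct == 100.0


def test_max_correct_percentage_balanced_sweep():
    # threshold 2.5: 6/6 cases and 2/3 controls correct -> (100 + 66.7)/2
    pct, thr = max_correct_percentage([3, 4, 5, 6, 7, 8], [1, 2, 6.5])
    assert pct == pytest.approx(100 * (1 + 2 / 3) / 2, abs=1e-9)
    assert thr == pytest.approx(2.5)


def test_identical_scores_are_uninformative():
    subjects = _subjects(2, 2)
    cmp = compare_groups(_scores([1.0, 1.0, 1.0, 1.0], subjects), subjects)
    assert cmp.max_correct_pct == 50.0
    assert cmp.t_p == 0.5 and cmp.wilcoxon_p == 0.5


def test_ties_fall_back_to_corrected_normal_approximation():
    subjects = _subjects(3, 3)
    cmp = compare_groups(_scores([2, 2, 3, 1, 2, 2], subjects), subjects)
    assert 0.0 < cmp.wilcoxon_p < 1.0
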