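"""Prioritization rules: rarity, category assignment, exclusion, partition."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rvburden.prioritize import (
    DEFAULT_22Q11_REGION,
    MissingAnnotationError,
    assign_category,
    is_rare,
    prioritize,
    restrict_to,
)
from rvburden.types import (
    FunctionalClass,
    GeneSet,
    GenomicRegion,
    Genotype,
    LOF_CLASSES,
    VariantAnnotation,
    VariantCall,
    VariantCategory,
)


def _ann(fclass=FunctionalClass.MISSENSE, afs=None, tools=None, splice=None,
         chrom="chr1", pos=100, genes=("G1",)):
    if fclass is FunctionalClass.MISSENSE and tools is None:
        tools = (True,) * 5 + (False,) * 2
    return VariantAnnotation(
        chrom=chrom, pos=pos, ref="A", alt="G", genes=genes,
        functional_class=fclass, population_afs=afs or {},
        deleterious_calls=tools, splicing_score=splice,
    )


# ---------------------------------------------------------------------------
# rarity


@pytest.mark.parametrize(
    "afs,expected",
    [
        ({"db1": 0.009, "db2": 0.0, "db3": 0.0099}, True),   # below in each db
        ({}, True),                                           # unobserved anywhere
        ({"db1": 0.010}, False),                              # boundary is strict
        ({"db1": 0.001, "db2": 0.5}, False),                  # one common db suffices
    ],
)
def test_is_rare(afs, expected):
    assert is_rare(_ann(afs=afs), 0.01) is expected


@given(
    afs=st.dictionaries(st.sampled_from(["a", "b", "c"]), st.floats(0, 1), max_size=3),
    thr=st.floats(0.001, 1.0),
)
def test_is_rare_matches_universal_quantifier(afs, thr):
    assert is_rare(_ann(afs=afs), thr) == all(v < thr for v in afs.values())


# ---------------------------------------------------------------------------
# category assignment


@pytest.mark.parametrize("fclass", sorted(LOF_CLASSES, key=lambda c: c.value))
def test_lof_classes_map_to_lof(fclass):
    assert assign_category(_ann(fclass=fclass, tools=None)) is VariantCategory.LOF


@pytest.mark.parametrize(
    "n_tools,expected",
    [(5, VariantCategory.DAMAGING_MISSENSE), (7, VariantCategory.DAMAGING_MISSENSE), (4, None)],
)
def test_missense_consensus_five_of_seven(n_tools, expected):
    tools = (True,) * n_tools + (False,) * (7 - n_tools)
    assert assign_category(_ann(tools=tools)) is expected


def test_intronic_low_splice_score_is_splice_reg():
    ann = _ann(fclass=FunctionalClass.INTRONIC, splice=-12.0)
    assert assign_category(ann) is VariantCategory.SPLICE_REG
    assert assign_category(_ann(fclass=FunctionalClass.INTRONIC, splice=-1.0)) is None


def test_category_precedence_most_severe_first():
    # core-splice beats a damaging splice score; damaging missense beats it too
    lof = _ann(fclass=FunctionalClass.CORE_SPLICE, tools=None, splice=-20.0)
    assert assign_category(lof) is VariantCategory.LOF
    dmis = _ann(splice=-20.0)
    assert assign_category(dmis) is VariantCategory.DAMAGING_MISSENSE
    benign = _ann(tools=(True,) * 4 + (False,) * 3, splice=-20.0)
    assert assign_category(benign) is VariantCategory.SPLICE_REG


def test_consensus_tightening_never_grows_damaging_missense():
    tools = (True,) * 5 + (False,) * 2
    assert assign_category(_ann(tools=tools), consensus_k=5) is VariantCategory.DAMAGING_MISSENSE
    assert assign_category(_ann(tools=tools), consensus_k=6) is None


# ---------------------------------------------------------------------------
# prioritize: partition, exclusions, oracle


def _brute_force(calls, annotations, regions, thr=0.01, splice=-5.0, k=5):
    """Independent re-filter: classify every call one at a time."""
    buckets = {"retained": [], "r22": [], "x": [], "discarded": []}
    for c in calls:
        a = annotations[c.key]
        if not c.high_quality or any(v >= thr for v in a.population_afs.values()):
            buckets["discarded"].append(c)
            continue
        if a.functional_class in LOF_CLASSES:
            cat = "lof"
        elif (
            a.functional_class is FunctionalClass.MISSENSE
            and sum(a.deleterious_calls) >= k
        ):
            cat = "dmis"
        elif a.splicing_score is not None and a.splicing_score <= splice:
            cat = "splice"
        else:
            buckets["discarded"].append(c)
            continue
        if c.chrom in ("chrX", "X"):
            buckets["x"].append(c)
        elif any(r.contains_vcf_pos(c.chrom, c.pos) for r in regions):
            buckets["r22"].append(c)
        else:
            buckets["retained"].append(c)
    return buckets


def test_prioritize_matches_brute_force_refilter(cohort_bundle):
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, regions_22q11=b.exclusion_regions)
    oracle = _brute_force(b.calls, b.annotations, b.exclusion_regions)
    assert len(pvs.retained) == len(oracle["retained"])
    assert sum(len(v) for v in pvs.region22q11_tally.values()) == len(oracle["r22"])
    assert sum(len(v) for v in pvs.chrx_tally.values()) == len(oracle["x"])
    assert pvs.n_discarded == len(oracle["discarded"])
    assert {av.call.key for av in pvs.retained} == {c.key for c in oracle["retained"]}


def test_partition_conserves_counts(cohort_bundle):
    """Every call lands in exactly one bucket; cardinalities sum to the input."""
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, regions_22q11=b.exclusion_regions)
    n_tally = sum(len(v) for v in pvs.region22q11_tally.values()) + sum(
        len(v) for v in pvs.chrx_tally.values()
    )
    assert len(pvs.retained) + n_tally + pvs.n_discarded == pvs.n_input == len(b.calls)
    assert pvs.totals_category == pvs.recount()


def test_worked_example_exclusion_tallies(worked_bundle):
    """3 qualifying variants in the 22q11.2 interval, 8 on X, none retained there."""
    b = worked_bundle
    pvs = prioritize(b.calls, b.annotations, regions_22q11=b.exclusion_regions)
    assert sum(len(v) for v in pvs.region22q11_tally.values()) == 3
    x = [av for avs in pvs.chrx_tally.values() for av in avs]
    assert len(x) == 8
    assert sum(av.category is VariantCategory.LOF for av in x) == 1
    assert all(av.call.chrom != "chrX" for av in pvs.retained)


def test_all_low_quality_retains_nothing(worked_bundle):
    from dataclasses import replace

    b = worked_bundle
    lowq = [replace(c, high_quality=False) for c in b.calls]
    pvs = prioritize(lowq, b.annotations, regions_22q11=b.exclusion_regions)
    assert pvs.retained == [] and pvs.n_discarded == pvs.n_input


def test_missing_annotation_is_hard_error(worked_bundle):
    call = VariantCall("SCZ1", "chr9", 1, "A", "G", Genotype.HET)
    with pytest.raises(MissingAnnotationError) as exc:
        prioritize([call], worked_bundle.annotations)
    assert ("chr9", 1, "A", "G") in exc.value.keys


def test_rarity_threshold_monotonicity(cohort_bundle):
    """Raising the rarity threshold never shrinks the retained set."""
    b = cohort_bundle
    sizes = [
        len(prioritize(b.calls, b.annotations, b.exclusion_regions, rarity_threshold=t).retained)
        for t in (0.001, 0.01, 0.05, 1.0)
    ]
    assert sizes == sorted(sizes)


def test_category_exclusivity(cohort_bundle):
    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    for av in pvs.retained:
        assert isinstance(av.category, VariantCategory)
        # re-assignment is deterministic and unique
        from rvburden.prioritize import assign_category

        assert assign_category(av.annotation) is av.category


def test_in_set_count_never_exceeds_class_total(cohort_bundle):
    from rvburden.burden import burden_matrix

    b = cohort_bundle
    pvs = prioritize(b.calls, b.annotations, b.exclusion_regions)
    for gs in b.gene_sets:
        for cat in VariantCategory:
            bm = burden_matrix(pvs, gs, cat, b.subjects)
            for sid in bm.counts:
                assert 0 <= bm.counts[sid] <= max(bm.totals[sid], bm.counts[sid])
                if bm.totals[sid] > 0:
                    assert bm.counts[sid] <= bm.totals[sid]


# ---------------------------------------------------------------------------
# restriction


def test_restrict_to_intersection(worked_bundle):
    gs = next(s for s in worked_bundle.gene_sets if s.name == "NEURON_PROJECTION")
    restricted = restrict_to(gs, worked_bundle.dgcr8_genes)
    assert restricted.name == "NEURON_PROJECTION|restricted"
    assert len(restricted) == 16


def test_restrict_to_disjoint_and_superset():
    gs = GeneSet("S", "src", frozenset({"A", "B"}))
    assert restrict_to(gs, {"Z"}) is None
    full = restrict_to(gs, {"A", "B", "C"})
    assert full.genes == gs.genes


def test_default_exclusion_interval_is_config_default():
    assert DEFAULT_22Q11_REGION == GenomicRegion("chr22", 18_900_000, 21_500_000)
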