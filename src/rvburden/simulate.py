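"""Synthetic cohort generation.

Emulates the statistical structure the burden pipeline assumes: a small
two-group cohort (default 6 cases vs 3 controls) whose per-subject
genome-wide qualifying-variant totals are Poisson with means matching the
observed study-scale averages (13.8 LoF and 94.3 missense variants per
subject), configurable case:control rate ratios inside named gene sets, a
biallelic risk-SNP panel with Hardy-Weinberg genotypes and an optional
case-specific effect-allele frequency shift confined to the low
association-p SNPs, and a noncoding-RNA catalog with Beta-distributed
conservation scores. Coordinates live on a toy genome with a designated
excluded 22q11.2-like interval and an X chromosome so the exclusion logic
is exercised; positions carry no signal.

A fixed seed yields byte-identical output files.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as rvio
from .types import (
    FunctionalClass,
    GenomicRegion,
    Genotype,
    GeneSet,
    Group,
    NcRnaGene,
    NcRnaKind,
    PrsSnpRecord,
    Sex,
    Subject,
    VariantAnnotation,
    VariantCall,
    VariantKey,
)

#: Allele-frequency databases emulated in the annotation table.
AF_DATABASES = ("kg", "esp", "exac", "inhouse1", "inhouse2")

_BASES = ("A", "C", "G", "T")

#: Toy-genome interval excluded as the intact 22q11.2 region (hg19-like span).
EXCLUSION_REGION = GenomicRegion("chr22", 18_900_000, 21_500_000)

_CATEGORIES = ("lof", "damaging_missense", "splice_reg")


def _default_sets() -> dict[str, int]:
    return {"NEURON_PROJECTION": 53, "SYNAPTIC_PATHWAYS": 15}


def _default_base_rates() -> dict[str, float]:
    # per-subject control-group means of in-set qualifying variants,
    # anchored to the study-scale control means (5.0 damaging missense in a
    # ~50-gene neurofunctional set, 0.33 LoF, ~1 splicing regulatory)
    return {"lof": 0.33, "damaging_missense": 5.0, "splice_reg": 1.0}


@dataclass
class SyntheticConfig:
    """Full parameterization of a simulated cohort."""

    n_case: int = 6
    n_control: int = 3
    seed: int = 0
    lof_rate: float = 13.8            # genome-wide qualifying LoF / subject
    missense_rate: float = 94.3       # genome-wide rare missense / subject
    splice_rate: float = 10.0         # genome-wide splicing-regulatory / subject
    damaging_fraction: float = 0.3    # share of missense passing the 5-of-7 consensus
    geneset_sizes: dict[str, int] = field(default_factory=_default_sets)
    geneset_effect: dict[str, float] = field(default_factory=dict)  # name -> case:control ratio
    geneset_base_rates: dict[str, float] = field(default_factory=_default_base_rates)
    region22_rate: float = 0.5        # qualifying variants inside the excluded interval
    chrx_rate: float = 1.0            # qualifying variants on the X chromosome
    low_quality_rate: float = 0.0     # decoy non-PASS variants / subject
    common_rate: float = 0.0          # decoy common (AF >= 1%) variants / subject
    prs_n_snps: int = 400
    prs_causal_fraction: float = 0.1
    prs_freq_shift: float = 0.0       # added to causal effect-allele freq in cases
    n_lincrna: int = 40
    n_mirna: int = 15
    lincrna_hit_rates: tuple[float, float] = (2.0, 1.3)  # (case, control) genes hit
    mirna_variant_rate: float = 0.1
    conservation_beta: tuple[float, float] = (2.0, 5.0)
    nb_dispersion: Optional[float] = None  # None = Poisson; else NB with this size
    n_background_genes: int = 400
    dgcr8_fraction: float = 0.3       # share of each set in the restriction list

    def validate(self) -> None:
        for name in self.geneset_effect:
            if name not in self.geneset_sizes:
                raise ValueError(f"geneset_effect names unknown set {name!r}")
        for r in self.geneset_effect.values():
            if r <= 0:
                raise ValueError("rate ratios must be positive")
        for v in (self.lof_rate, self.missense_rate, self.splice_rate,
                  self.region22_rate, self.chrx_rate, self.mirna_variant_rate):
            if v < 0:
                raise ValueError("rates must be non-negative")
        if not 0.0 <= self.damaging_fraction <= 1.0:
            raise ValueError("damaging_fraction must be in [0, 1]")
        bg = self._background_means()
        for cls, mean in bg.items():
            if mean < 0:
                raise ValueError(
                    f"in-set base rates exceed the genome-wide {cls} rate "
                    f"(background mean {mean:.2f} < 0)"
                )

    def _background_means(self) -> dict[str, float]:
        n_sets = len(self.geneset_sizes)
        base = self.geneset_base_rates
        return {
            "lof": self.lof_rate - n_sets * base["lof"],
            "damaging_missense": self.missense_rate * self.damaging_fraction
            - n_sets * base["damaging_missense"],
            "benign_missense": self.missense_rate * (1.0 - self.damaging_fraction),
            "splice_reg": self.splice_rate - n_sets * base["splice_reg"],
        }


@dataclass
class SyntheticBundle:
    """In-memory synthetic inputs, mirroring exactly what the readers load."""

    config: SyntheticConfig
    subjects: list[Subject]
    calls: list[VariantCall]
    annotations: dict[VariantKey, VariantAnnotation]
    gene_sets: list[GeneSet]
    exclusion_regions: list[GenomicRegion]
    prs_records: list[PrsSnpRecord]
    reference_intervals: dict[str, list[GenomicRegion]]
    catalog: list[NcRnaGene]
    dgcr8_genes: frozenset[str]


# ---------------------------------------------------------------------------
# count-level sampling (fast path used by calibration tests)


def _draw_count(rng: np.random.Generator, mean: float, dispersion: Optional[float]) -> int:
    if mean <= 0:
        return 0
    if dispersion is None:
        return int(rng.poisson(mean))
    # negative binomial parameterized by size (dispersion) and mean
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def sample_counts(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, dict]:
    """Draw the per-subject count layer only (no variant materialization).

    Returns, per subject id: in-set counts per (gene set, category),
    background counts per broad class, and the implied genome-wide class
    totals (background + in-set, so totals always recount exactly).
    """
    config.validate()
    bg_means = config._background_means()
    subjects = [(f"SCZ{i + 1}", True) for i in range(config.n_case)] + [
        (f"NP{i + 1}", False) for i in range(config.n_control)
    ]
    out: dict[str, dict] = {"subjects": subjects, "in_set": {}, "background": {}, "class_totals": {}}
    for sid, is_case in subjects:
        in_set = {}
        for name in config.geneset_sizes:
            r = config.geneset_effect.get(name, 1.0) if is_case else 1.0
            in_set[name] = {
                cat: _draw_count(rng, config.geneset_base_rates[cat] * r, config.nb_dispersion)
                for cat in _CATEGORIES
            }
        background = {
            cls: _draw_count(rng, mean, config.nb_dispersion) for cls, mean in bg_means.items()
        }
        set_sums = {cat: sum(in_set[name][cat] for name in in_set) for cat in _CATEGORIES}
        out["in_set"][sid] = in_set
        out["background"][sid] = background
        out["class_totals"][sid] = {
            "lof": background["lof"] + set_sums["lof"],
            "missense": background["damaging_missense"]
            + background["benign_missense"]
            + set_sums["damaging_missense"],
            "splice_reg": background["splice_reg"] + set_sums["splice_reg"],
        }
    return out


# ---------------------------------------------------------------------------
# variant materialization


class _VariantFactory:
    """Materializes annotated calls on the toy genome with unique keys."""

    def __init__(self, rng: Optional[np.random.Generator]):
        self.rng = rng
        self.calls: list[VariantCall] = []
        self.annotations: dict[VariantKey, VariantAnnotation] = {}
        self._next_pos: dict[str, int] = {}

    def _pos(self, chrom: str, start: int = 1_000) -> int:
        pos = self._next_pos.get(chrom, start)
        self._next_pos[chrom] = pos + 3
        return pos

    def _alleles(self) -> tuple[str, str]:
        if self.rng is None:
            return "A", "G"
        i = int(self.rng.integers(0, 4))
        j = (i + 1 + int(self.rng.integers(0, 3))) % 4
        return _BASES[i], _BASES[j]

    def _afs(self, lo: float = 0.0, hi: float = 0.009) -> dict[str, float]:
        if self.rng is None:
            return {"kg": 0.001}
        afs = {}
        for db in AF_DATABASES:
            if self.rng.random() < 0.5:
                afs[db] = round(float(self.rng.uniform(lo, hi)), 6)
        return afs

    def add(
        self,
        subject_id: str,
        chrom: str,
        genes: tuple[str, ...],
        fclass: FunctionalClass,
        n_deleterious: Optional[int] = None,
        splicing_score: Optional[float] = None,
        afs: Optional[dict[str, float]] = None,
        high_quality: bool = True,
        pos_start: int = 1_000,
    ) -> VariantCall:
        pos = self._pos(chrom, pos_start)
        ref, alt = self._alleles()
        tools = None
        if fclass is FunctionalClass.MISSENSE:
            k = n_deleterious if n_deleterious is not None else 0
            flags = [True] * k + [False] * (rvio.N_TOOLS - k)
            if self.rng is not None:
                self.rng.shuffle(flags)
            tools = tuple(flags)
        ann = VariantAnnotation(
            chrom=chrom, pos=pos, ref=ref, alt=alt, genes=genes,
            functional_class=fclass,
            population_afs=self._afs() if afs is None else afs,
            deleterious_calls=tools,
            splicing_score=splicing_score,
        )
        call = VariantCall(
            subject_id=subject_id, chrom=chrom, pos=pos, ref=ref, alt=alt,
            genotype=Genotype.HET, high_quality=high_quality,
        )
        self.calls.append(call)
        self.annotations[ann.key] = ann
        return call


def _lof_class(rng: Optional[np.random.Generator]) -> FunctionalClass:
    classes = (FunctionalClass.STOP_GAIN, FunctionalClass.FRAMESHIFT, FunctionalClass.CORE_SPLICE)
    if rng is None:
        return classes[0]
    return classes[int(rng.integers(0, 3))]


def _add_category_variant(
    fac: _VariantFactory,
    rng: np.random.Generator,
    sid: str,
    chrom: str,
    gene: str,
    category: str,
    splice_cutoff: float = -5.0,
) -> None:
    if category == "lof":
        fac.add(sid, chrom, (gene,), _lof_class(rng))
    elif category == "damaging_missense":
        fac.add(sid, chrom, (gene,), FunctionalClass.MISSENSE,
                n_deleterious=5 + int(rng.integers(0, 3)))
    elif category == "benign_missense":
        fac.add(sid, chrom, (gene,), FunctionalClass.MISSENSE,
                n_deleterious=int(rng.integers(0, 5)))
    elif category == "splice_reg":
        fac.add(sid, chrom, (gene,), FunctionalClass.INTRONIC,
                splicing_score=round(float(rng.uniform(-30.0, splice_cutoff - 1.0)), 3))
    else:  # pragma: no cover
        raise ValueError(category)


def generate_cohort(config: SyntheticConfig) -> SyntheticBundle:
    """Generate the complete synthetic input bundle for one cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counts = sample_counts(config, rng)

    subjects = [
        Subject(id=sid, group=Group.CASE if is_case else Group.CONTROL,
                sex=Sex.FEMALE if i % 2 else Sex.MALE)
        for i, (sid, is_case) in enumerate(counts["subjects"])
    ]

    # gene universe
    set_genes: dict[str, list[str]] = {}
    for name, size in config.geneset_sizes.items():
        set_genes[name] = [f"{name}_G{j + 1}" for j in range(size)]
    background_genes = [f"BG_G{j + 1}" for j in range(config.n_background_genes)]
    gene_sets = [
        GeneSet(name=name, source="synthetic", genes=frozenset(genes))
        for name, genes in set_genes.items()
    ]
    dgcr8: set[str] = set()
    for name, genes in set_genes.items():
        n_pick = max(1, int(round(config.dgcr8_fraction * len(genes))))
        dgcr8.update(rng.choice(genes, size=n_pick, replace=False).tolist())

    fac = _VariantFactory(rng)
    for sid, _is_case in counts["subjects"]:
        for name, per_cat in counts["in_set"][sid].items():
            for cat, n in per_cat.items():
                for _ in range(n):
                    gene = set_genes[name][int(rng.integers(0, len(set_genes[name])))]
                    _add_category_variant(fac, rng, sid, "chr1", gene, cat)
        for cls, n in counts["background"][sid].items():
            for _ in range(n):
                gene = background_genes[int(rng.integers(0, len(background_genes)))]
                _add_category_variant(fac, rng, sid, "chr1", gene, cls)
        # excluded-scope qualifying variants
        for _ in range(_draw_count(rng, config.region22_rate, None)):
            gene = f"R22_G{int(rng.integers(1, 30))}"
            _add_category_variant(fac, rng, sid, "chr22", gene, "damaging_missense")
        for _ in range(_draw_count(rng, config.chrx_rate, None)):
            gene = f"X_G{int(rng.integers(1, 30))}"
            cat = "lof" if rng.random() < 0.15 else "damaging_missense"
            _add_category_variant(fac, rng, sid, "chrX", gene, cat)
        # decoys exercising the discard path
        for _ in range(_draw_count(rng, config.low_quality_rate, None)):
            fac.add(sid, "chr1", (background_genes[0],), FunctionalClass.MISSENSE,
                    n_deleterious=7, high_quality=False)
        for _ in range(_draw_count(rng, config.common_rate, None)):
            fac.add(sid, "chr1", (background_genes[0],), FunctionalClass.MISSENSE,
                    n_deleterious=7,
                    afs={db: round(float(rng.uniform(0.02, 0.5)), 4) for db in AF_DATABASES})

    # 22q11.2 variants must fall inside the excluded interval
    _shift_into_region(fac, "chr22", EXCLUSION_REGION)

    prs_records, ref_intervals = _generate_prs(config, rng, fac, counts["subjects"])
    catalog = _generate_catalog(config, rng, fac, counts["subjects"])

    return SyntheticBundle(
        config=config,
        subjects=subjects,
        calls=fac.calls,
        annotations=fac.annotations,
        gene_sets=gene_sets,
        exclusion_regions=[EXCLUSION_REGION],
        prs_records=prs_records,
        reference_intervals=ref_intervals,
        catalog=catalog,
        dgcr8_genes=frozenset(dgcr8),
    )


def _shift_into_region(fac: _VariantFactory, chrom: str, region: GenomicRegion) -> None:
    """Relocate all calls on ``chrom`` to positions inside ``region``."""
    offset = region.start + 1_000
    remap: dict[int, int] = {}
    new_calls = []
    for c in fac.calls:
        if c.chrom != chrom or region.contains_vcf_pos(c.chrom, c.pos):
            new_calls.append(c)
            continue
        if c.pos not in remap:
            remap[c.pos] = offset
            offset += 3
        old_key = c.key
        c = replace(c, pos=remap[c.pos])
        ann = fac.annotations.pop(old_key)
        ann = replace(ann, pos=c.pos)
        fac.annotations[ann.key] = ann
        new_calls.append(c)
    fac.calls = new_calls


def _generate_prs(
    config: SyntheticConfig,
    rng: np.random.Generator,
    fac: _VariantFactory,
    subjects: Sequence[tuple[str, bool]],
) -> tuple[list[PrsSnpRecord], dict[str, list[GenomicRegion]]]:
    records: list[PrsSnpRecord] = []
    n = config.prs_n_snps
    n_causal = int(round(config.prs_causal_fraction * n))
    causal = np.zeros(n, dtype=bool)
    if n_causal:
        causal[rng.choice(n, size=n_causal, replace=False)] = True
    freqs = rng.uniform(0.2, 0.8, size=n)
    for j in range(n):
        pos = 1_000 * (j + 1)
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(0, 3))) % 4]
        if causal[j]:
            assoc_p = float(rng.uniform(1e-8, 1e-3))
            log_or = math.log(float(rng.uniform(1.05, 1.3)))
        else:
            assoc_p = float(rng.uniform(1e-3, 1.0))
            log_or = math.log(float(rng.uniform(0.8, 1.25)))
        # effect allele is the alternate; other allele is the reference base
        records.append(PrsSnpRecord(chrom="chr2", pos=pos, effect_allele=alt,
                                    other_allele=ref, log_or=log_or, assoc_p=assoc_p))
        # annotate the site so the call/annotation join stays total (common
        # frequency, so the variant never enters the rare-variant analyses)
        ann = VariantAnnotation(
            chrom="chr2", pos=pos, ref=ref, alt=alt, genes=(),
            functional_class=FunctionalClass.INTERGENIC,
            population_afs={"kg": round(float(freqs[j]), 6)},
        )
        fac.annotations[ann.key] = ann
        for sid, is_case in subjects:
            f = freqs[j] + (config.prs_freq_shift if (is_case and causal[j]) else 0.0)
            f = min(max(f, 0.01), 0.99)
            dose = int(rng.binomial(2, f))
            if dose == 0:
                continue
            fac.calls.append(VariantCall(
                subject_id=sid, chrom="chr2", pos=pos, ref=ref, alt=alt,
                genotype=Genotype.HET if dose == 1 else Genotype.HOM_ALT,
            ))
    span = GenomicRegion("chr2", 0, 1_000 * (n + 2))
    ref_intervals = {sid: [span] for sid, _ in subjects}
    return records, ref_intervals


def _generate_catalog(
    config: SyntheticConfig,
    rng: np.random.Generator,
    fac: _VariantFactory,
    subjects: Sequence[tuple[str, bool]],
) -> list[NcRnaGene]:
    a, b = config.conservation_beta
    catalog: list[NcRnaGene] = []
    for j in range(config.n_lincrna):
        start = 10_000 * (j + 1)
        catalog.append(NcRnaGene(
            id=f"LINC{j + 1:04d}", kind=NcRnaKind.LINCRNA,
            regions=(GenomicRegion("chr3", start, start + 1_000),),
            conservation=round(float(rng.beta(a, b)), 6),
        ))
    mirna_base = 10_000 * (config.n_lincrna + 2)
    for j in range(config.n_mirna):
        start = mirna_base + 1_000 * j
        catalog.append(NcRnaGene(
            id=f"MIR{j + 1:04d}", kind=NcRnaKind.MIRNA,
            regions=(GenomicRegion("chr3", start, start + 100),),
            conservation=round(float(rng.beta(a, b)), 6),
        ))

    gene_offsets: dict[str, int] = {}

    def _place(gene: NcRnaGene, sid: str, afs: dict[str, float]) -> None:
        off = gene_offsets.get(gene.id, 0)
        gene_offsets[gene.id] = off + 1
        region = gene.regions[0]
        pos = region.start + 1 + off  # 1-based pos inside [start, end)
        if pos > region.end:
            return  # gene saturated; skip (practically unreachable)
        ref, alt = fac._alleles()
        ann = VariantAnnotation(
            chrom=region.chrom, pos=pos, ref=ref, alt=alt, genes=(gene.id,),
            functional_class=FunctionalClass.NONCODING_EXONIC, population_afs=afs,
        )
        fac.annotations[ann.key] = ann
        fac.calls.append(VariantCall(
            subject_id=sid, chrom=region.chrom, pos=pos, ref=ref, alt=alt,
            genotype=Genotype.HET,
        ))

    case_rate, control_rate = config.lincrna_hit_rates
    lincrnas = [g for g in catalog if g.kind is NcRnaKind.LINCRNA]
    mirnas = [g for g in catalog if g.kind is NcRnaKind.MIRNA]
    for sid, is_case in subjects:
        n_hit = min(_draw_count(rng, case_rate if is_case else control_rate, None), len(lincrnas))
        if n_hit:
            for gi in rng.choice(len(lincrnas), size=n_hit, replace=False):
                _place(lincrnas[int(gi)], sid, {"kg": round(float(rng.uniform(0, 0.009)), 6)})
        for _ in range(_draw_count(rng, config.mirna_variant_rate, None)):
            gene = mirnas[int(rng.integers(0, len(mirnas)))]
            _place(gene, sid, {"kg": round(float(rng.uniform(0.0, 0.045)), 6)})
    return catalog


# ---------------------------------------------------------------------------
# worked example (deterministic fixture mirroring the published group means)


def generate_worked_example() -> SyntheticBundle:
    """Deterministic small bundle reproducing the published ratio-of-means
    column for four damaging-missense gene-set rows, the "nc" convention,
    and the 22q11.2 / X exclusion tallies (3 and 8 variants).
    """
    config = SyntheticConfig(n_case=6, n_control=3, seed=0)
    cases = [f"SCZ{i}" for i in range(1, 7)]
    controls = [f"NP{i}" for i in range(1, 4)]
    subjects = [Subject(id=s, group=Group.CASE) for s in cases] + [
        Subject(id=s, group=Group.CONTROL) for s in controls
    ]

    sets: dict[str, list[str]] = {
        "NEURON_PROJECTION": [f"NP_G{j + 1}" for j in range(53)],
        "SYNAPTIC_PATHWAYS": [f"SY_G{j + 1}" for j in range(15)],
        "ABNORMAL_SENSORY_SYSTEM": [f"AS_G{j + 1}" for j in range(58)],
        "GABAERGIC_SYNAPSE": [f"GA_G{j + 1}" for j in range(7)],
    }
    # DGCR8-restriction: 16 of the 53 neuron-projection genes
    dgcr8 = frozenset(sets["NEURON_PROJECTION"][:16])

    # per-subject in-set damaging-missense counts chosen so group means
    # reproduce the published table: 9.00/5.00, 2.50/1.00, 10.17/8.00,
    # 1.17/0 — and, within neuron projection, restricted sums 16 vs 2
    plan: dict[str, tuple[list[int], list[int]]] = {
        "SYNAPTIC_PATHWAYS": ([2, 3, 2, 3, 2, 3], [1, 1, 1]),
        "ABNORMAL_SENSORY_SYSTEM": ([10, 10, 10, 10, 10, 11], [8, 8, 8]),
        "GABAERGIC_SYNAPSE": ([1, 1, 1, 2, 1, 1], [0, 0, 0]),
    }
    np_total = ([8, 9, 10, 9, 8, 10], [4, 5, 6])
    np_restricted = ([3, 3, 3, 3, 2, 2], [1, 1, 0])

    fac = _VariantFactory(rng=None)

    def _fill(sid: str, genes: list[str], n: int, start_index: int = 0) -> None:
        for j in range(n):
            gene = genes[(start_index + j) % len(genes)]
            fac.add(sid, "chr1", (gene,), FunctionalClass.MISSENSE, n_deleterious=5)

    for idx, sid in enumerate(cases + controls):
        group_i = idx if idx < 6 else idx - 6
        in_case = idx < 6
        # neuron projection: restricted genes first, remainder unrestricted
        nr = np_restricted[0 if in_case else 1][group_i]
        nt = np_total[0 if in_case else 1][group_i]
        _fill(sid, sets["NEURON_PROJECTION"][:16], nr)
        _fill(sid, sets["NEURON_PROJECTION"][16:], nt - nr)
        for name, (case_counts, control_counts) in plan.items():
            _fill(sid, sets[name], (case_counts if in_case else control_counts)[group_i])
        # constant benign-missense background so percents are defined
        for j in range(40):
            fac.add(sid, "chr1", (f"BG_G{j + 1}",), FunctionalClass.MISSENSE, n_deleterious=2)

    # excluded variants reported by the study: 3 damaging missense in the
    # intact 22q11.2 interval, 8 damaging SNVs (7 missense, 1 LoF) on X
    for sid, gene in (("NP1", "DGCR2"), ("NP3", "GNB1L"), ("SCZ1", "TRMT2A")):
        fac.add(sid, "chr22", (gene,), FunctionalClass.MISSENSE, n_deleterious=6,
                pos_start=EXCLUSION_REGION.start + 1_000)
    x_plan = [("NP3", "COL4A6", FunctionalClass.MISSENSE), ("SCZ3", "JADE3", FunctionalClass.MISSENSE),
              ("SCZ6", "KLHL15", FunctionalClass.MISSENSE), ("SCZ6", "LRCH2", FunctionalClass.MISSENSE),
              ("NP3", "PFKFB1", FunctionalClass.MISSENSE), ("NP3", "SLC25A43", FunctionalClass.STOP_GAIN),
              ("SCZ2", "SLITRK2", FunctionalClass.MISSENSE), ("NP1", "TBC1D8B", FunctionalClass.MISSENSE)]
    for sid, gene, fclass in x_plan:
        fac.add(sid, "chrX", (gene,), fclass,
                n_deleterious=6 if fclass is FunctionalClass.MISSENSE else None)

    gene_sets = [GeneSet(name=n, source="worked_example", genes=frozenset(g))
                 for n, g in sets.items()]
    return SyntheticBundle(
        config=config,
        subjects=subjects,
        calls=fac.calls,
        annotations=fac.annotations,
        gene_sets=gene_sets,
        exclusion_regions=[EXCLUSION_REGION],
        prs_records=[],
        reference_intervals={},
        catalog=[],
        dgcr8_genes=dgcr8,
    )


# ---------------------------------------------------------------------------
# file emission


def write_bundle(bundle: SyntheticBundle, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the bundle as the exact file formats the readers consume."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "subjects": out / "subjects.tsv",
        "vcf": out / "calls.vcf",
        "annotations": out / "annotations.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "exclusion_bed": out / "exclusion.bed",
        "catalog": out / "ncrna_catalog.tsv",
    }
    rvio.write_subjects(bundle.subjects, paths["subjects"])
    rvio.write_vcf(bundle.calls, bundle.subjects, paths["vcf"])
    rvio.write_annotations(bundle.annotations, paths["annotations"], af_databases=AF_DATABASES)
    rvio.write_gene_sets(bundle.gene_sets, paths["gene_sets"])
    rvio.write_regions(bundle.exclusion_regions, paths["exclusion_bed"])
    rvio.write_ncrna_catalog(bundle.catalog, paths["catalog"])
    if bundle.dgcr8_genes:
        paths["dgcr8_genes"] = out / "dgcr8_genes.txt"
        paths["dgcr8_genes"].write_text("\n".join(sorted(bundle.dgcr8_genes)) + "\n")
    if bundle.prs_records:
        paths["prs_table"] = out / "prs_snps.tsv"
        rvio.write_prs_table(bundle.prs_records, paths["prs_table"])
        ref_dir = out / "ref_intervals"
        ref_dir.mkdir(exist_ok=True)
        for sid, regions in bundle.reference_intervals.items():
            p = ref_dir / f"{sid}.bed"
            rvio.write_regions(regions, p)
            paths[f"ref_intervals/{sid}"] = p
    return paths
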