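"""Readers and writers for all external inputs.

Formats: subjects TSV (id/group/sex), VCF variant calls (via cyvcf2),
per-variant annotation TSV, GMT gene-set collections, BED regions,
PRS SNP TSV, and a noncoding-RNA catalog TSV. Every reader validates
its input and every parsed structure can be written back losslessly.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

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

logger = logging.getLogger(__name__)

_GROUP_ALIASES = {"CASE": Group.CASE, "SCZ": Group.CASE, "CONTROL": Group.CONTROL, "NP": Group.CONTROL}

#: Number of deleteriousness prediction tools expected in the annotation table.
N_TOOLS = 7


class InputError(ValueError):
    """Malformed or inconsistent external input."""


# ---------------------------------------------------------------------------
# subjects


def read_subjects(path: str | os.PathLike) -> list[Subject]:
    """Read the subject table (TSV with header ``id  group  sex``).

    Group aliases SCZ -> CASE and NP -> CONTROL are accepted. Duplicate ids
    and unknown group labels are hard errors.
    """
    subjects: list[Subject] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_id, i_group = header.index("id"), header.index("group")
        except ValueError as exc:
            raise InputError(f"{path}: missing required subject columns: {exc}")
        i_sex = header.index("sex") if "sex" in header else None
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            sid = fields[i_id]
            if sid in seen:
                raise InputError(f"{path}: duplicate subject id {sid!r}")
            seen.add(sid)
            glabel = fields[i_group].upper()
            if glabel not in _GROUP_ALIASES:
                raise InputError(f"{path}: unknown group label {fields[i_group]!r} for {sid}")
            sex = Sex.UNKNOWN
            if i_sex is not None and i_sex < len(fields) and fields[i_sex]:
                sex = Sex(fields[i_sex].upper())
            subjects.append(Subject(id=sid, group=_GROUP_ALIASES[glabel], sex=sex))
    return subjects


def write_subjects(subjects: Sequence[Subject], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgroup\tsex\n")
        for s in subjects:
            fh.write(f"{s.id}\t{s.group.value}\t{s.sex.value}\n")


# ---------------------------------------------------------------------------
# variant calls (VCF)


def _genotype_for_alt(gt_alleles: Sequence[int], alt_index: int) -> Genotype | None:
    """Classify a sample genotype with respect to one alt allele (1-based index)."""
    called = [a for a in gt_alleles if a >= 0]
    if not called or alt_index not in called:
        return None
    if len(called) == 1:
        return Genotype.HEMI
    if all(a == alt_index for a in called):
        return Genotype.HOM_ALT
    return Genotype.HET


def read_variant_calls(
    paths: Sequence[str | os.PathLike] | str | os.PathLike,
    subjects: Sequence[Subject],
) -> list[VariantCall]:
    """Read per-subject variant calls from one or more VCF files.

    Multi-allelic records are decomposed into one biallelic call per
    (subject, alt allele); a non-PASS FILTER marks the call low quality.
    VCF sample names must all be present in the subject table.
    """
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    known = {s.id for s in subjects}
    calls: list[VariantCall] = []
    for path in paths:
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # noqa: BLE001 - cyvcf2 raises bare exceptions
            raise InputError(f"{path}: malformed VCF: {exc}") from exc
        samples = list(vcf.samples)
        unknown = [s for s in samples if s not in known]
        if unknown:
            raise InputError(f"{path}: VCF samples absent from subject table: {unknown}")
        for lineno, rec in enumerate(vcf, start=1):
            high_quality = rec.FILTER is None  # cyvcf2: None means PASS/'.'
            try:
                genotypes = rec.genotypes
            except Exception as exc:  # noqa: BLE001
                raise InputError(f"{path}: malformed record #{lineno} at {rec.CHROM}:{rec.POS}: {exc}") from exc
            for si, sample in enumerate(samples):
                gt_alleles = [a for a in genotypes[si][:-1]]
                for alt_i, alt in enumerate(rec.ALT, start=1):
                    geno = _genotype_for_alt(gt_alleles, alt_i)
                    if geno is None:
                        continue
                    calls.append(
                        VariantCall(
                            subject_id=sample,
                            chrom=rec.CHROM,
                            pos=rec.POS,
                            ref=rec.REF,
                            alt=alt,
                            genotype=geno,
                            high_quality=high_quality,
                        )
                    )
        vcf.close()
    return calls


_GT_FOR = {Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.HEMI: "1"}


def write_vcf(
    calls: Sequence[VariantCall],
    subjects: Sequence[Subject],
    path: str | os.PathLike,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write calls as a minimal multi-sample VCF (biallelic records).

    Calls sharing a variant key become one record; subjects without a call
    at that key are written homozygous reference.
    """
    sample_ids = [s.id for s in subjects]
    sample_index = {sid: i for i, sid in enumerate(sample_ids)}
    by_key: dict[VariantKey, dict] = {}
    for c in calls:
        entry = by_key.setdefault(c.key, {"genos": {}, "high_quality": c.high_quality})
        entry["genos"][c.subject_id] = c.genotype
        entry["high_quality"] = entry["high_quality"] and c.high_quality
    chroms = sorted({k[0] for k in by_key})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=LowQual,Description="Low quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in chroms:
            length = (contig_lengths or {}).get(chrom, 500_000_000)
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids) + "\n"
        )
        for key in sorted(by_key, key=lambda k: (k[0], k[1], k[2], k[3])):
            chrom, pos, ref, alt = key
            entry = by_key[key]
            filt = "PASS" if entry["high_quality"] else "LowQual"
            gts = ["0/0"] * len(sample_ids)
            for sid, geno in entry["genos"].items():
                gts[sample_index[sid]] = _GT_FOR[geno]
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t{filt}\t.\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path: str | os.PathLike) -> dict[VariantKey, VariantAnnotation]:
    """Read the per-variant annotation table.

    Expected header: ``chrom pos ref alt genes class`` plus ``af_<db>``
    columns (any number), exactly :data:`N_TOOLS` ``tool<i>`` columns, and
    ``splice_score``. Empty AF cells mean "unobserved in that database".
    """
    annotations: dict[VariantKey, VariantAnnotation] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("chrom", "pos", "ref", "alt", "genes", "class"):
            if col not in idx:
                raise InputError(f"{path}: missing annotation column {col!r}")
        af_cols = [(h[3:], i) for i, h in enumerate(header) if h.startswith("af_")]
        tool_cols = [i for i, h in enumerate(header) if h.startswith("tool")]
        if len(tool_cols) != N_TOOLS:
            raise InputError(
                f"{path}: expected {N_TOOLS} deleteriousness tool columns, found {len(tool_cols)}"
            )
        i_splice = idx.get("splice_score")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            try:
                fclass = FunctionalClass(f[idx["class"]].lower())
            except ValueError:
                raise InputError(
                    f"{path}:{lineno}: unknown functional class {f[idx['class']]!r}"
                ) from None
            afs = {db: float(f[i]) for db, i in af_cols if i < len(f) and f[i] != ""}
            tools = tuple(f[i] in ("1", "true", "True", "D") for i in tool_cols) if all(
                i < len(f) and f[i] != "" for i in tool_cols
            ) else None
            splice = None
            if i_splice is not None and i_splice < len(f) and f[i_splice] != "":
                splice = float(f[i_splice])
            ann = VariantAnnotation(
                chrom=f[idx["chrom"]],
                pos=int(f[idx["pos"]]),
                ref=f[idx["ref"]],
                alt=f[idx["alt"]],
                genes=tuple(g for g in f[idx["genes"]].upper().split(",") if g),
                functional_class=fclass,
                population_afs=afs,
                deleterious_calls=tools,
                splicing_score=splice,
            )
            annotations[ann.key] = ann
    return annotations


def write_annotations(
    annotations: Mapping[VariantKey, VariantAnnotation],
    path: str | os.PathLike,
    af_databases: Sequence[str] | None = None,
) -> None:
    if af_databases is None:
        dbs: list[str] = sorted({db for a in annotations.values() for db in a.population_afs})
    else:
        dbs = list(af_databases)
    with open(path, "w") as fh:
        cols = ["chrom", "pos", "ref", "alt", "genes", "class"]
        cols += [f"af_{db}" for db in dbs]
        cols += [f"tool{i}" for i in range(1, N_TOOLS + 1)]
        cols += ["splice_score"]
        fh.write("\t".join(cols) + "\n")
        for key in sorted(annotations, key=lambda k: (k[0], k[1], k[2], k[3])):
            a = annotations[key]
            row = [a.chrom, str(a.pos), a.ref, a.alt, ",".join(a.genes), a.functional_class.value]
            row += ["" if db not in a.population_afs else repr(a.population_afs[db]) for db in dbs]
            if a.deleterious_calls is None:
                row += [""] * N_TOOLS
            else:
                row += ["1" if t else "0" for t in a.deleterious_calls]
            row.append("" if a.splicing_score is None else repr(a.splicing_score))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path: str | os.PathLike) -> list[GeneSet]:
    """Read a GMT file: ``name<TAB>source<TAB>gene1<TAB>gene2...`` per line.

    Symbols are upper-cased; duplicates within a line collapse; a line
    without genes is skipped with a warning; duplicate set names are an error.
    """
    sets: list[GeneSet] = []
    names: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not any(g for g in fields[2:]):
                logger.warning("%s:%d: gene set line with no genes, skipped", path, lineno)
                continue
            name = fields[0]
            if name in names:
                raise InputError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            names.add(name)
            sets.append(
                GeneSet(name=name, source=fields[1], genes=frozenset(g.upper() for g in fields[2:] if g))
            )
    return sets


def write_gene_sets(sets: Sequence[GeneSet], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source] + sorted(gs.genes)) + "\n")


# ---------------------------------------------------------------------------
# regions (BED)


def merge_regions(regions: Iterable[GenomicRegion]) -> list[GenomicRegion]:
    """Merge overlapping (and bookended) regions per chromosome."""
    merged: list[GenomicRegion] = []
    for reg in sorted(regions):
        if merged and merged[-1].chrom == reg.chrom and reg.start <= merged[-1].end:
            last = merged.pop()
            merged.append(GenomicRegion(last.chrom, last.start, max(last.end, reg.end)))
        else:
            merged.append(reg)
    return merged


def read_regions(path: str | os.PathLike) -> list[GenomicRegion]:
    """Read a 3+ column BED file (0-based half-open); overlaps are merged."""
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise InputError(f"{path}:{lineno}: BED line with <3 columns")
            try:
                reg = GenomicRegion(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            regions.append(reg)
    return merge_regions(regions)


def write_regions(regions: Sequence[GenomicRegion], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for r in sorted(regions):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# PRS SNP table


def read_prs_table(path: str | os.PathLike) -> list[PrsSnpRecord]:
    """Read the risk-score SNP table.

    Columns: ``chrom pos effect_allele other_allele or assoc_p`` (an
    ``log_or`` column is accepted in place of ``or``). Records are
    de-duplicated on (chrom, pos, effect_allele); the same position with
    conflicting alleles is a hard error.
    """
    records: list[PrsSnpRecord] = []
    seen: dict[tuple[str, int, str], PrsSnpRecord] = {}
    by_pos: dict[tuple[str, int], tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("chrom", "pos", "effect_allele", "other_allele", "assoc_p"):
            if col not in idx:
                raise InputError(f"{path}: missing PRS column {col!r}")
        if "or" not in idx and "log_or" not in idx:
            raise InputError(f"{path}: missing PRS effect column ('or' or 'log_or')")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            log_or = float(f[idx["log_or"]]) if "log_or" in idx else math.log(float(f[idx["or"]]))
            try:
                rec = PrsSnpRecord(
                    chrom=f[idx["chrom"]],
                    pos=int(f[idx["pos"]]),
                    effect_allele=f[idx["effect_allele"]].upper(),
                    other_allele=f[idx["other_allele"]].upper(),
                    log_or=log_or,
                    assoc_p=float(f[idx["assoc_p"]]),
                )
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            pos_key = (rec.chrom, rec.pos)
            alleles = (rec.effect_allele, rec.other_allele)
            if pos_key in by_pos and by_pos[pos_key] != alleles:
                raise InputError(
                    f"{path}:{lineno}: conflicting alleles at {rec.chrom}:{rec.pos}"
                )
            by_pos[pos_key] = alleles
            if rec.key not in seen:
                seen[rec.key] = rec
                records.append(rec)
    return records


def write_prs_table(records: Sequence[PrsSnpRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\teffect_allele\tother_allele\tlog_or\tassoc_p\n")
        for r in records:
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.effect_allele}\t{r.other_allele}\t{r.log_or!r}\t{r.assoc_p!r}\n"
            )


# ---------------------------------------------------------------------------
# noncoding RNA catalog


def read_ncrna_catalog(path: str | os.PathLike) -> list[NcRnaGene]:
    """Read the ncRNA catalog TSV (``id kind chrom start end conservation``).

    A gene may span several rows (one per exon region); its conservation
    score must agree across rows.
    """
    rows: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for col in ("id", "kind", "chrom", "start", "end", "conservation"):
            if col not in idx:
                raise InputError(f"{path}: missing catalog column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            gid = f[idx["id"]]
            try:
                kind = NcRnaKind(f[idx["kind"]])
                reg = GenomicRegion(f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]]))
            except ValueError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from exc
            cons = float(f[idx["conservation"]])
            if gid not in rows:
                rows[gid] = {"kind": kind, "regions": [], "conservation": cons}
                order.append(gid)
            elif rows[gid]["conservation"] != cons or rows[gid]["kind"] != kind:
                raise InputError(f"{path}:{lineno}: inconsistent rows for gene {gid!r}")
            rows[gid]["regions"].append(reg)
    return [
        NcRnaGene(
            id=gid,
            kind=rows[gid]["kind"],
            regions=tuple(sorted(rows[gid]["regions"])),
            conservation=rows[gid]["conservation"],
        )
        for gid in order
    ]


def write_ncrna_catalog(genes: Sequence[NcRnaGene], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id\tkind\tchrom\tstart\tend\tconservation\n")
        for g in genes:
            for r in g.regions:
                fh.write(f"{g.id}\t{g.kind.value}\t{r.chrom}\t{r.start}\t{r.end}\t{g.conservation!r}\n")
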