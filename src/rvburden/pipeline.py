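"""Configuration-driven end-to-end runs and report writing.

A run executes: prioritization -> coding gene-set burden (with optional
DGCR8 restriction) -> screening -> joint Hotelling stage -> power
projection -> polygenic risk score -> noncoding burden, and writes
deterministic TSV/JSON reports plus a manifest of every parameter, the
seed, and input checksums. PRS and noncoding stages are optional and are
skipped (with a log line) when their inputs are not configured.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import io as rvio
from . import noncoding as nc
from . import prs as prs_mod
from .burden import (
    BurdenAnalysisResult,
    DISPLAY_MAX_GENES,
    SCREEN_P_LOF_SPLICE,
    SCREEN_P_MISSENSE,
    run_burden_analysis,
)
from .power import cohens_d, power_table
from .prioritize import (
    CONSENSUS_K,
    DEFAULT_22Q11_REGION,
    RARITY_THRESHOLD,
    SPLICE_SCORE_CUTOFF,
    prioritize,
)
from .types import Group, VariantCategory

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Validated run configuration (paths plus all module parameters)."""

    subjects: str
    vcf: list[str]
    annotations: str
    gene_sets: str
    output_dir: str
    exclusion_bed: Optional[str] = None
    dgcr8_genes: Optional[str] = None
    prs_table: Optional[str] = None
    reference_intervals_dir: Optional[str] = None
    ncrna_catalog: Optional[str] = None
    rarity_threshold: float = RARITY_THRESHOLD
    mirna_rarity_threshold: float = nc.MIRNA_RARITY_THRESHOLD
    consensus_k: int = CONSENSUS_K
    splice_score_cutoff: float = SPLICE_SCORE_CUTOFF
    screen_p_missense: float = SCREEN_P_MISSENSE
    screen_p_lof_splice: float = SCREEN_P_LOF_SPLICE
    hotelling_scale: str = "percent"
    drop_degenerate: bool = False
    welch: bool = False
    display_max_genes: int = DISPLAY_MAX_GENES
    conserved_fraction: float = nc.CONSERVED_FRACTION
    power_n_grid: list[int] = field(default_factory=lambda: [20, 50, 100])
    power_alpha: float = 0.05
    power_sided: str = "one"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict[str, Any] = {}
        flat.update(raw.get("inputs", {}))
        params = dict(raw.get("params", {}))
        power = params.pop("power", {})
        flat.update(params)
        for k, v in power.items():
            flat[f"power_{k}"] = v
        if "output_dir" in raw:
            flat["output_dir"] = raw["output_dir"]
        if "seed" in raw:
            flat["seed"] = raw["seed"]
        vcf = flat.get("vcf")
        if isinstance(vcf, str):
            flat["vcf"] = [vcf]
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def validate(self) -> None:
        for label in ("subjects", "annotations", "gene_sets"):
            p = getattr(self, label)
            if not Path(p).exists():
                raise FileNotFoundError(f"config input {label!r}: no such file {p}")
        for p in self.vcf:
            if not Path(p).exists():
                raise FileNotFoundError(f"config input vcf: no such file {p}")
        for label in ("exclusion_bed", "dgcr8_genes", "prs_table", "ncrna_catalog"):
            p = getattr(self, label)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {label!r}: no such file {p}")
        if self.hotelling_scale not in ("percent", "count"):
            raise ValueError(f"hotelling_scale must be percent|count")
        if self.power_sided not in ("one", "two"):
            raise ValueError("power.sided must be one|two")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute all configured stages; returns the in-memory result bundle
    and writes the report files under ``config.output_dir``."""
    config.validate()

    try:
        subjects = rvio.read_subjects(config.subjects)
        calls = rvio.read_variant_calls(config.vcf, subjects)
        annotations = rvio.read_annotations(config.annotations)
        gene_sets = rvio.read_gene_sets(config.gene_sets)
        regions = (
            rvio.read_regions(config.exclusion_bed)
            if config.exclusion_bed
            else [DEFAULT_22Q11_REGION]
        )
        restriction = None
        if config.dgcr8_genes:
            restriction = frozenset(
                g.strip().upper()
                for g in Path(config.dgcr8_genes).read_text().splitlines()
                if g.strip()
            )
    except Exception as exc:
        raise PipelineStageError("input", exc) from exc

    try:
        pvs = prioritize(
            calls,
            annotations,
            regions_22q11=regions,
            rarity_threshold=config.rarity_threshold,
            splice_threshold=config.splice_score_cutoff,
            consensus_k=config.consensus_k,
        )
    except Exception as exc:
        raise PipelineStageError("prioritize", exc) from exc
    n_22q11 = sum(len(v) for v in pvs.region22q11_tally.values())
    n_x = sum(len(v) for v in pvs.chrx_tally.values())
    logger.info(
        "prioritize: %d calls in, %d retained, %d excluded-22q11, %d excluded-X, %d discarded",
        pvs.n_input, len(pvs.retained), n_22q11, n_x, pvs.n_discarded,
    )

    try:
        burden_res = run_burden_analysis(
            pvs, gene_sets, subjects,
            restriction=restriction,
            p_missense=config.screen_p_missense,
            p_lof_splice=config.screen_p_lof_splice,
            hotelling_scale=config.hotelling_scale,
            drop_degenerate=config.drop_degenerate,
            welch=config.welch,
            display_max_genes=config.display_max_genes,
        )
    except Exception as exc:
        raise PipelineStageError("burden", exc) from exc
    logger.info(
        "burden: %d gene-set/category tests, %d screened, %d joint",
        len(burden_res.univariate), len(burden_res.screened), len(burden_res.joint),
    )

    power_df = _power_stage(config, pvs, burden_res, gene_sets, subjects, restriction)

    prs_out = None
    if config.prs_table:
        try:
            records = rvio.read_prs_table(config.prs_table)
            ref_intervals = {}
            if config.reference_intervals_dir:
                for s in subjects:
                    p = Path(config.reference_intervals_dir) / f"{s.id}.bed"
                    ref_intervals[s.id] = rvio.read_regions(p) if p.exists() else []
            panel, scores, comparisons = prs_mod.run_prs_analysis(
                calls, ref_intervals, records, subjects
            )
            prs_out = {"panel": panel, "scores": scores, "comparisons": comparisons}
            logger.info(
                "prs: %d SNPs in table, %d callable in all subjects",
                len(records), len(panel.callable_snps),
            )
        except Exception as exc:
            raise PipelineStageError("prs", exc) from exc
    else:
        logger.info("prs: no SNP table configured, stage skipped")

    noncoding_out = None
    if config.ncrna_catalog:
        try:
            catalog = rvio.read_ncrna_catalog(config.ncrna_catalog)
            rows, linc_test, decision, mirna_test = nc.run_noncoding_analysis(
                calls, annotations, catalog, subjects,
                conserved_fraction=config.conserved_fraction,
                lincrna_rarity=config.rarity_threshold,
                mirna_rarity=config.mirna_rarity_threshold,
            )
            noncoding_out = {
                "rows": rows, "lincrna_test": linc_test,
                "mirna_decision": decision, "mirna_test": mirna_test,
            }
            logger.info("noncoding: %d catalog genes, miRNA decision: %s", len(catalog), decision)
        except Exception as exc:
            raise PipelineStageError("noncoding", exc) from exc
    else:
        logger.info("noncoding: no catalog configured, stage skipped")

    results = {
        "subjects": subjects,
        "pvs": pvs,
        "burden": burden_res,
        "power": power_df,
        "prs": prs_out,
        "noncoding": noncoding_out,
        "funnel": {
            "n_input": pvs.n_input, "n_retained": len(pvs.retained),
            "n_excluded_22q11": n_22q11, "n_excluded_x": n_x,
            "n_discarded": pvs.n_discarded,
        },
    }
    write_report(results, config)
    return results


def _power_stage(config, pvs, burden_res, gene_sets, subjects, restriction):
    """Cohen's d per screened set and category (percent scale) -> power grid."""
    from .burden import burden_matrix
    from .prioritize import restrict_to

    by_name = {gs.name: gs for gs in gene_sets}
    if restriction:
        for gs in gene_sets:
            rgs = restrict_to(gs, restriction)
            if rgs is not None:
                by_name[rgs.name] = rgs
    effect_sizes = []
    for name in burden_res.screened:
        gs = by_name[name]
        for category in VariantCategory:
            bm = burden_matrix(pvs, gs, category, subjects)
            case = [bm.percents[s.id] for s in subjects if s.group is Group.CASE]
            control = [bm.percents[s.id] for s in subjects if s.group is Group.CONTROL]
            est = cohens_d(case, control)
            if est.defined:
                effect_sizes.append((f"{name}:{category.value}", est.d))
    return power_table(
        effect_sizes, config.power_n_grid, alpha=config.power_alpha, sided=config.power_sided
    )


# ---------------------------------------------------------------------------
# report writing


def _fmt(x: Optional[float], decimals: int) -> str:
    if x is None:
        return "nc"
    if isinstance(x, float) and not math.isfinite(x):
        return "inf" if x > 0 else "-inf"
    return f"{x:.{decimals}f}"


def write_report(results: dict[str, Any], config: RunConfig) -> dict[str, Path]:
    """Write deterministic TSV/JSON reports; display rounding is 2 decimals
    for means/ratios and 3 for p-values; "nc" marks a non-calculable ratio."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    burden: BurdenAnalysisResult = results["burden"]
    paths["burden"] = out / "burden.tsv"
    with open(paths["burden"], "w") as fh:
        fh.write(
            "gene_set\trestricted\tcategory\ttotal_n\tn_case_genes\t"
            "mean_case\tmean_control\tp_nominal_one_sided\teffect_ratio\tdisplayed\n"
        )
        for r in burden.univariate:
            fh.write(
                f"{r.gene_set}\t{int(r.restricted)}\t{r.category.value if r.category else ''}\t"
                f"{r.total_n}\t{r.n_case_genes}\t{_fmt(r.mean_case, 2)}\t{_fmt(r.mean_control, 2)}\t"
                f"{_fmt(r.p_one_sided, 3)}\t{_fmt(r.effect_ratio, 2)}\t"
                f"{int(r.gene_set in burden.displayed)}\n"
            )

    paths["joint"] = out / "joint.tsv"
    with open(paths["joint"], "w") as fh:
        fh.write("gene_set\tt2\tf\tdf1\tdf2\tp\tcategories\n")
        for j in burden.joint:
            cats = ",".join(c.value for c in j.categories)
            fh.write(
                f"{j.gene_set}\t{_fmt(j.t2, 3)}\t{_fmt(j.f_statistic, 3)}\t"
                f"{j.df1}\t{j.df2}\t{_fmt(j.p_value, 3)}\t{cats}\n"
            )

    power_df = results["power"]
    paths["power"] = out / "power.tsv"
    pdf = power_df.copy()
    if len(pdf):
        pdf["d"] = pdf["d"].map(lambda v: f"{v:.2f}")
        pdf["power"] = pdf["power"].map(lambda v: f"{v:.4f}")
    pdf.to_csv(paths["power"], sep="\t", index=False)

    if results.get("prs"):
        paths["prs"] = out / "prs.tsv"
        with open(paths["prs"], "w") as fh:
            fh.write(
                "threshold\tn_snps\tmean_case\tmean_control\tt_p\twilcoxon_p\tmax_correct_pct\n"
            )
            for c in results["prs"]["comparisons"]:
                fh.write(
                    f"{c.threshold_label}\t{c.n_snps}\t{_fmt(c.mean_case, 2)}\t"
                    f"{_fmt(c.mean_control, 2)}\t{_fmt(c.t_p, 3)}\t{_fmt(c.wilcoxon_p, 3)}\t"
                    f"{_fmt(c.max_correct_pct, 1)}\n"
                )
        paths["prs_scores"] = out / "prs_scores.tsv"
        with open(paths["prs_scores"], "w") as fh:
            fh.write("subject\tthreshold\tscore\tn_snps\n")
            for label in sorted(results["prs"]["scores"]):
                for sc in results["prs"]["scores"][label]:
                    fh.write(f"{sc.subject_id}\t{label}\t{sc.score:.6f}\t{sc.n_snps}\n")

    if results.get("noncoding"):
        paths["noncoding"] = out / "noncoding.tsv"
        with open(paths["noncoding"], "w") as fh:
            fh.write(
                "subject\tgroup\tlincrna_genes_hit\tconserved_lincrna_genes_hit\tmirna_variants\n"
            )
            for row in results["noncoding"]["rows"]:
                fh.write(
                    f"{row.subject_id}\t{row.group.value}\t{row.n_lincrna_genes_hit}\t"
                    f"{row.n_conserved_lincrna_genes_hit}\t{row.n_mirna_variants}\n"
                )

    summary = {
        "funnel": results["funnel"],
        "screened_gene_sets": burden.screened,
        "displayed_gene_sets": burden.displayed,
        "joint": [
            {"gene_set": j.gene_set, "t2": round(j.t2, 6), "p": round(j.p_value, 6),
             "df1": j.df1, "df2": j.df2}
            for j in burden.joint
        ],
        "skipped_joint": burden.skipped_joint,
        "note": "p-values are nominal; no correction for multiple comparisons is applied",
    }
    if results.get("noncoding"):
        lt = results["noncoding"]["lincrna_test"]
        summary["noncoding"] = {
            "mirna_decision": results["noncoding"]["mirna_decision"],
            "lincrna_conserved_p": None if lt is None else round(lt.p_one_sided, 6),
            "lincrna_conserved_effect_ratio": (
                None if lt is None or lt.effect_ratio is None else round(lt.effect_ratio, 6)
            ),
        }
    if results.get("prs"):
        summary["prs"] = [
            {"threshold": c.threshold_label, "n_snps": c.n_snps,
             "t_p": round(c.t_p, 6), "wilcoxon_p": round(c.wilcoxon_p, 6),
             "max_correct_pct": round(c.max_correct_pct, 3)}
            for c in results["prs"]["comparisons"]
        ]
    paths["summary"] = out / "results.json"
    paths["summary"].write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")

    manifest = {"parameters": _manifest_params(config), "inputs": _checksums(config)}
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return paths


def _manifest_params(config: RunConfig) -> dict[str, Any]:
    return asdict(config)


def _checksums(config: RunConfig) -> dict[str, str]:
    sums = {}
    files = [config.subjects, config.annotations, config.gene_sets, *config.vcf]
    for opt in (config.exclusion_bed, config.dgcr8_genes, config.prs_table, config.ncrna_catalog):
        if opt:
            files.append(opt)
    for f in files:
        h = hashlib.sha256(Path(f).read_bytes()).hexdigest()
        sums[str(f)] = h
    return sums
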