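"""End-to-end orchestration of the editing-loss analysis.

``run_full_analysis`` sequences the stages — filter, cohort comparison,
editing indices, annotation + per-gene contrasts, lineage comparison,
RBP ratio screen, panel fold changes — writing each stage's output as TSV
into the run directory together with a JSON manifest.  Stages communicate
through files only, so any stage can be re-run or tested in isolation; a
stage failure writes a FAILED marker naming the stage and re-raises.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotation import annotate_sites, annotation_frame, composition_summary
from .comparison import common_sites, compare_site_counts
from .expression import fpkm, panel_anova, panel_fold_change, ratio_screen
from .filtering import FilterConfig, build_presence, filter_sites
from .indices import (
    gene_index_frame,
    genome_wide_index,
    per_gene_index,
    site_index,
    site_index_frame,
)
from .io import (
    read_count_matrix,
    read_edit_table,
    read_feature_intervals,
    read_marker_table,
    write_edit_table,
    write_results,
)
from .lineage import lineage_editing_comparison, lineage_table, select_lineage_genes

logger = logging.getLogger("aluedit")

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """File-level description of one analysis run."""

    control_tables: list[str]
    case_tables: list[str]
    outdir: str
    control_label: str = "control"
    case_label: str = "case"
    gene_bed: str | None = None
    repeat_bed: str | None = None
    marker_csv: str | None = None
    counts_tsv: str | None = None
    gene_lengths_tsv: str | None = None
    cohort_map: dict[str, str] = field(default_factory=dict)
    rbp_genes_txt: str | None = None
    panel_files: dict[str, str] = field(default_factory=dict)
    min_reads_exclusive: int = 5
    min_ratio_exclusive: float = 0.05
    min_samples_inclusive: int = 2
    min_sites_per_gene_exclusive: int = 5
    pct_ratio_threshold: float = 10.0
    ratio_cutoff_low: float = 0.5
    ratio_cutoff_high: float = 2.0
    n_permutations: int = 10_000
    seed: int = 0
    normalize_chroms: bool = False
    strict_strand: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def filter_config(self) -> FilterConfig:
        return FilterConfig(
            min_reads_exclusive=self.min_reads_exclusive,
            min_ratio_exclusive=self.min_ratio_exclusive,
            min_samples_inclusive=self.min_samples_inclusive,
        )


def _read_gene_list(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]


def run_full_analysis(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the report directory.

    Optional stages (lineage, expression screens) are skipped with a logged
    warning when their inputs are not configured.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "outputs": [],
        "skipped": [],
    }
    stage = "setup"
    try:
        # ------------------------------------------------------------ filter
        stage = "filter"
        fcfg = cfg.filter_config
        filtered_dir = outdir / "filtered"
        filtered_dir.mkdir(exist_ok=True)
        cohorts: dict[str, list] = {}
        count_rows = []
        for label, paths in (
            (cfg.control_label, cfg.control_tables),
            (cfg.case_label, cfg.case_tables),
        ):
            tables = []
            for i, path in enumerate(paths):
                sample_id = Path(path).stem.removeprefix("edits_") or f"{label}_{i+1}"
                raw = read_edit_table(
                    path, sample_id, label, normalize_chroms=cfg.normalize_chroms
                )
                filt = filter_sites(raw, fcfg)
                write_edit_table(filt, filtered_dir / f"{sample_id}.tsv")
                count_rows.append(
                    {"sample": sample_id, "cohort": label,
                     "n_raw": len(raw), "n_filtered": len(filt)}
                )
                tables.append(filt)
            cohorts[label] = tables
        _emit(pd.DataFrame(count_rows), outdir / "filtered_site_counts.tsv", manifest)

        # ----------------------------------------------------------- compare
        stage = "compare"
        pres_ctrl = build_presence(cohorts[cfg.control_label])
        pres_case = build_presence(cohorts[cfg.case_label])
        report = common_sites(pres_ctrl, pres_case)
        _emit(report.to_frame(), outdir / "common_sites.tsv", manifest)
        chi_common = compare_site_counts(len(report.a_only), len(report.b_only))

        # ------------------------------------------------------------- index
        stage = "index"
        recs_ctrl = site_index(pres_ctrl, fcfg)
        recs_case = site_index(pres_case, fcfg)
        ranked_ctrl, total_ctrl = genome_wide_index(recs_ctrl)
        ranked_case, total_case = genome_wide_index(recs_case)
        _emit(site_index_frame(ranked_ctrl),
              outdir / f"site_index_{cfg.control_label}.tsv", manifest)
        _emit(site_index_frame(ranked_case),
              outdir / f"site_index_{cfg.case_label}.tsv", manifest)
        chi_index = compare_site_counts(len(recs_ctrl), len(recs_case))
        summary = pd.DataFrame(
            [
                {"cohort": cfg.control_label, "n_index_sites": len(recs_ctrl),
                 "genome_wide_index": total_ctrl,
                 "n_common_only": len(report.a_only),
                 "n_shared": len(report.shared),
                 "chi2_common_sites": chi_common.statistic,
                 "p_common_sites": chi_common.p,
                 "chi2_index_sites": chi_index.statistic,
                 "p_index_sites": chi_index.p},
                {"cohort": cfg.case_label, "n_index_sites": len(recs_case),
                 "genome_wide_index": total_case,
                 "n_common_only": len(report.b_only),
                 "n_shared": len(report.shared),
                 "chi2_common_sites": chi_common.statistic,
                 "p_common_sites": chi_common.p,
                 "chi2_index_sites": chi_index.statistic,
                 "p_index_sites": chi_index.p},
            ]
        )
        _emit(summary, outdir / "genome_index_summary.tsv", manifest)

        # ---------------------------------------------------------- annotate
        stage = "annotate"
        annotations = {}
        if cfg.gene_bed or cfg.repeat_bed:
            features = read_feature_intervals(
                cfg.gene_bed, cfg.repeat_bed, normalize_chroms=cfg.normalize_chroms
            )
            all_keys = sorted(
                {r.site for r in recs_ctrl} | {r.site for r in recs_case}
            )
            annotations = annotate_sites(
                all_keys, features, strict_strand=cfg.strict_strand
            )
            _emit(annotation_frame(annotations),
                  outdir / "site_annotation.tsv", manifest)
            if annotations:
                comp = composition_summary(annotations)
                _emit(pd.DataFrame([comp]),
                      outdir / "annotation_composition.tsv", manifest)
            gene_records = per_gene_index(
                recs_case, recs_ctrl, annotations,
                min_sites_per_gene_exclusive=cfg.min_sites_per_gene_exclusive,
            )
            _emit(gene_index_frame(gene_records),
                  outdir / "gene_index.tsv", manifest)
        else:
            _skip("annotate", "no gene/repeat interval files configured", manifest)

        # ----------------------------------------------------------- lineage
        stage = "lineage"
        if cfg.marker_csv and annotations:
            markers = read_marker_table(cfg.marker_csv)
            gene_sets = select_lineage_genes(
                markers, ratio_threshold_exclusive=cfg.pct_ratio_threshold
            )
            # lineage analysis sums site indices per gene with no
            # minimum-site gene filter; missing genes score zero
            all_gene = per_gene_index(
                recs_case, recs_ctrl, annotations, min_sites_per_gene_exclusive=0
            )
            ctrl_map = {g.gene_id: g.index_control for g in all_gene}
            case_map = {g.gene_id: g.index_case for g in all_gene}
            comparisons = lineage_editing_comparison(
                gene_sets, ctrl_map, case_map,
                n_control=len(cfg.control_tables), n_case=len(cfg.case_tables),
            )
            _emit(lineage_table(comparisons),
                  outdir / "lineage_comparison.tsv", manifest)
        else:
            _skip("lineage", "marker table or annotations unavailable", manifest)

        # ----------------------------------------------------- ratio screen
        stage = "express"
        counts = lengths = None
        if cfg.counts_tsv and cfg.cohort_map:
            counts = read_count_matrix(cfg.counts_tsv, cohort_map=cfg.cohort_map)
            if cfg.rbp_genes_txt:
                screened = ratio_screen(
                    counts, _read_gene_list(cfg.rbp_genes_txt), cfg.cohort_map,
                    control_label=cfg.control_label, case_label=cfg.case_label,
                    cutoff_low=cfg.ratio_cutoff_low,
                    cutoff_high=cfg.ratio_cutoff_high,
                )
                _emit(screened, outdir / "ratio_screen.tsv", manifest)
            else:
                _skip("express", "no RBP gene list configured", manifest)
        else:
            _skip("express", "no count matrix / cohort map configured", manifest)

        # ------------------------------------------------------------ panels
        stage = "panels"
        if counts is not None and cfg.panel_files:
            panels = {
                name: _read_gene_list(path)
                for name, path in cfg.panel_files.items()
            }
            if cfg.gene_lengths_tsv:
                lengths = pd.read_csv(
                    cfg.gene_lengths_tsv, sep="\t", index_col=0
                ).iloc[:, 0]
                values = fpkm(counts, lengths)
            else:
                values = counts.astype(float)
            fc = panel_fold_change(
                values, panels, cfg.cohort_map,
                control_label=cfg.control_label, case_label=cfg.case_label,
                n_permutations=cfg.n_permutations, seed=cfg.seed,
            )
            _emit(fc, outdir / "panel_fold_change.tsv", manifest)
            anova_rows = []
            for name, genes in panels.items():
                res = panel_anova(
                    values, genes, cfg.cohort_map,
                    control_label=cfg.control_label, case_label=cfg.case_label,
                )
                anova_rows.append(
                    {"panel": name,
                     "F_cohort": res["cohort"].statistic,
                     "p_cohort": res["cohort"].p,
                     "F_gene": res["gene"].statistic,
                     "p_gene": res["gene"].p}
                )
            _emit(pd.DataFrame(anova_rows), outdir / "panel_anova.tsv", manifest)
        else:
            _skip("panels", "no count matrix / panel gene lists configured",
                  manifest)

    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _emit(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    write_results(df, path)
    manifest["outputs"].append(path.name)
    logger.info("wrote %s (%d rows)", path.name, len(df))


def _skip(stage: str, reason: str, manifest: dict) -> None:
    manifest["skipped"].append({"stage": stage, "reason": reason})
    logger.warning("skipping stage %s: %s", stage, reason)
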