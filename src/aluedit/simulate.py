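"""Seeded generator of every pipeline input with known ground truth.

The generator emulates the statistical structure of a two-cohort editing
study: genes carry clustered editing sites (mostly inside Alu elements in
introns and UTRs), each site has a true edit/read ratio drawn from a Beta
distribution, read depth is negative-binomial, and observed edits are
binomial draws — a site is reported only when at least one edited read is
sampled, as an editing caller would.  Case-cohort editing loss is a single
multiplicative retention factor on the edit probability (uniform loss
across lineages), with optional per-lineage overrides to simulate localized
loss instead.  Expression matrices carry configurable fold changes on
designated ISG / NF-kB panels in case samples and an optional RBP
"knockdown" factor applied to a subset of case samples.

All randomness derives from one integer seed via independent child streams,
so every output is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    EditSite,
    FeatureIntervals,
    MarkerRecord,
    SampleEditTable,
    write_edit_table,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimExpression",
    "RBP_GENES",
    "simulate_truth",
    "simulate_cohorts",
    "simulate_expression",
    "write_input_bundle",
]

#: RNA-binding proteins whose knockdown reduces genome-wide A-to-I editing.
RBP_GENES = ("ADAR", "ADARB1", "XRCC6", "FXR1", "DDX5", "U2AF2", "ILF3", "SBDS")

#: Cell lineages of the brain vasculature used to name simulated clusters.
LINEAGE_NAMES = (
    "astrocyte", "BEC_arterial", "BEC_capillary", "BEC_venous", "ependymal",
    "microglia_macrophage", "meningeal_fibroblast", "neuron",
    "oligodendrocyte", "OPC", "pericyte", "perivascular_fibroblast",
    "smooth_muscle", "T_cell",
)

_SITE_SPACING = 400  # bases between simulated sites; keeps feature/Alu
                     # intervals (±50 / ±150) from engulfing neighbours


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for one simulated study.

    Cohort sizes default to 7 + 7 (the deeply affected vasculature design);
    per-site true ratios are Beta(2, 5) (mean ≈ 0.29, the bulk of sites
    well above the 0.05 inclusion threshold), depth is negative binomial
    with mean 60 and size 8, and sites cluster ~10 per gene with ~90% of
    them inside Alu elements.  ``retention`` multiplies case-cohort edit
    probabilities (1.0 = no loss; 0.5 = the substantial-loss regime).
    """

    n_control: int = 7
    n_case: int = 7
    n_genes: int = 200
    sites_per_gene_mean: float = 10.0
    sites_per_gene_dispersion: float | None = None  # None -> Poisson
    intergenic_fraction: float = 0.05
    alu_fraction: float = 0.9
    feature_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"intron": 0.60, "3UTR": 0.25, "5UTR": 0.05, "ncRNA": 0.10}
    )
    depth_mean: float = 60.0
    depth_size: float = 8.0
    ratio_alpha: float = 2.0
    ratio_beta: float = 5.0
    retention: float = 1.0
    lineage_retention: Mapping[str, float] = field(default_factory=dict)
    n_lineages: int = 4
    markers_per_lineage: int = 25
    # expression model
    n_background_genes: int = 2000
    isg_panel_size: int = 25
    nfkb_panel_size: int = 25
    panel_fold: Mapping[str, float] = field(
        default_factory=lambda: {"ISG": 1.0, "NFKB": 1.0}
    )
    rbp_factor: float = 1.0
    n_rbp_affected_case_samples: int = 0
    expr_baseline_mean: float = 500.0
    expr_baseline_sigma: float = 0.5
    expr_nb_size: float = 100.0
    control_label: str = "NCI"
    case_label: str = "AD"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        for name in ("n_control", "n_case", "n_genes", "n_lineages",
                     "markers_per_lineage"):
            if getattr(self, name) < 1:
                problems.append(f"{name} must be >= 1")
        for name in ("sites_per_gene_mean", "depth_mean", "depth_size",
                     "ratio_alpha", "ratio_beta", "expr_baseline_mean",
                     "expr_baseline_sigma", "expr_nb_size"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        for name in ("alu_fraction", "intergenic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                problems.append(f"{name} must lie in [0, 1]")
        if not 0.0 < self.retention <= 1.0:
            problems.append("retention must lie in (0, 1]")
        for lin, r in self.lineage_retention.items():
            if not 0.0 < r <= 1.0:
                problems.append(f"lineage_retention[{lin}] must lie in (0, 1]")
        if abs(sum(self.feature_class_probs.values()) - 1.0) > 1e-9:
            problems.append("feature_class_probs must sum to 1")
        if self.n_lineages * self.markers_per_lineage > self.n_genes:
            problems.append(
                "n_lineages * markers_per_lineage exceeds n_genes"
            )
        if self.n_rbp_affected_case_samples > self.n_case:
            problems.append("n_rbp_affected_case_samples exceeds n_case")
        if self.rbp_factor <= 0:
            problems.append("rbp_factor must be > 0")
        if self.seed < 0:
            problems.append("seed must be non-negative")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _lineage_names(cfg: SimConfig) -> list[str]:
    if cfg.n_lineages <= len(LINEAGE_NAMES):
        return list(LINEAGE_NAMES[: cfg.n_lineages])
    extra = [f"lineage_{i:02d}" for i in range(len(LINEAGE_NAMES), cfg.n_lineages)]
    return list(LINEAGE_NAMES) + extra


@dataclass
class SimTruth:
    """Everything the generator knows about the world it sampled."""

    config: SimConfig
    features: FeatureIntervals
    sites: pd.DataFrame  # chrom,pos,strand,edit_type,gene,lineage,feature_class,in_alu,p_control,p_case
    lineage_genes: dict[str, list[str]]
    markers: list[MarkerRecord]


def simulate_truth(cfg: SimConfig) -> SimTruth:
    """Draw gene structures, site placements and true edit ratios.

    Deterministic given the config seed: identical configs produce
    byte-identical truth tables.
    """
    rng = _rng(cfg, 0)
    lineages = _lineage_names(cfg)
    genes = [f"G{i + 1:04d}" for i in range(cfg.n_genes)]
    lineage_genes: dict[str, list[str]] = {name: [] for name in lineages}
    gene_lineage: dict[str, str | None] = {}
    for i, gene in enumerate(genes):
        if i < cfg.n_lineages * cfg.markers_per_lineage:
            lin = lineages[i % cfg.n_lineages]
            lineage_genes[lin].append(gene)
            gene_lineage[gene] = lin
        else:
            gene_lineage[gene] = None

    if cfg.sites_per_gene_dispersion is None:
        n_sites = rng.poisson(cfg.sites_per_gene_mean, size=cfg.n_genes)
    else:
        size = cfg.sites_per_gene_dispersion
        n_sites = rng.negative_binomial(
            size, size / (size + cfg.sites_per_gene_mean), size=cfg.n_genes
        )
    n_sites = np.maximum(n_sites, 1)

    features = FeatureIntervals()
    class_names = list(cfg.feature_class_probs)
    class_probs = np.array([cfg.feature_class_probs[c] for c in class_names])
    chroms = [f"chr{i}" for i in range(1, 8)]
    cursors = {c: 1000 for c in chroms}
    rows: list[dict] = []
    alu_counter = 0

    def _emit_site(chrom: str, pos: int, gene: str | None, lineage: str | None,
                   feature_class: str, in_alu: bool) -> None:
        nonlocal alu_counter
        strand = "+" if rng.random() < 0.5 else "-"
        edit_type = "AG" if strand == "+" else "TC"
        p_control = float(rng.beta(cfg.ratio_alpha, cfg.ratio_beta))
        retention = cfg.lineage_retention.get(lineage, cfg.retention) if lineage else cfg.retention
        if gene is not None:
            features.add_gene_feature(
                chrom, pos - 51, pos + 50, gene, feature_class, strand
            )
        if in_alu:
            alu_counter += 1
            features.add_repeat(
                chrom, pos - 151, pos + 150, f"AluY_{alu_counter}", "Alu", strand
            )
        rows.append(
            {
                "chrom": chrom, "pos": pos, "strand": strand,
                "edit_type": edit_type, "gene": gene, "lineage": lineage,
                "feature_class": feature_class if gene else "intergenic",
                "in_alu": in_alu,
                "p_control": p_control, "p_case": p_control * retention,
            }
        )

    for gi, gene in enumerate(genes):
        chrom = chroms[gi % len(chroms)]
        start = cursors[chrom]
        s = int(n_sites[gi])
        classes = rng.choice(len(class_names), size=s, p=class_probs)
        for j in range(s):
            pos = start + j * _SITE_SPACING + int(rng.integers(0, 100))
            _emit_site(
                chrom, pos, gene, gene_lineage[gene],
                class_names[int(classes[j])],
                bool(rng.random() < cfg.alu_fraction),
            )
        cursors[chrom] = start + s * _SITE_SPACING + 2000

    n_genic = int(n_sites.sum())
    if cfg.intergenic_fraction > 0:
        n_inter = int(round(
            n_genic * cfg.intergenic_fraction / (1.0 - cfg.intergenic_fraction)
        ))
        for j in range(n_inter):
            pos = 1000 + j * _SITE_SPACING + int(rng.integers(0, 100))
            _emit_site("chr8", pos, None, None, "intergenic",
                       bool(rng.random() < cfg.alu_fraction))

    markers: list[MarkerRecord] = []
    for lin in lineages:
        for gene in lineage_genes[lin]:
            pct1 = float(rng.uniform(0.2, 0.9))
            ratio = float(rng.uniform(12.0, 40.0))
            markers.append(MarkerRecord(gene, lin, pct1, round(pct1 / ratio, 6)))
    # distractor rows: genuinely expressed but not lineage-restricted
    for gene in genes[cfg.n_lineages * cfg.markers_per_lineage:]:
        lin = lineages[int(rng.integers(0, len(lineages)))]
        pct1 = float(rng.uniform(0.1, 0.6))
        ratio = float(rng.uniform(0.5, 8.0))
        pct2 = min(1.0, pct1 / ratio)
        markers.append(MarkerRecord(gene, lin, pct1, round(pct2, 6)))

    sites = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SimTruth(
        config=cfg, features=features, sites=sites,
        lineage_genes={k: sorted(v) for k, v in lineage_genes.items()},
        markers=markers,
    )


def simulate_cohorts(truth: SimTruth) -> dict[str, list[SampleEditTable]]:
    """Sample per-sample edit tables from the truth.

    Per sample and site: reads ~ NegBin(depth) floored at 1, edits ~
    Binomial(reads, true ratio); the site appears in the table only when at
    least one edited read was drawn.  Tables are unfiltered caller output —
    threshold filtering is a downstream step.
    """
    cfg = truth.config
    rng = _rng(cfg, 1)
    sites = truth.sites
    chrom = sites["chrom"].to_numpy()
    pos = sites["pos"].to_numpy()
    strand = sites["strand"].to_numpy()
    edit_type = sites["edit_type"].to_numpy()
    nb_p = cfg.depth_size / (cfg.depth_size + cfg.depth_mean)
    cohorts: dict[str, list[SampleEditTable]] = {}
    for label, n_samples, p_col in (
        (cfg.control_label, cfg.n_control, "p_control"),
        (cfg.case_label, cfg.n_case, "p_case"),
    ):
        p_true = sites[p_col].to_numpy(dtype=float)
        tables = []
        for i in range(n_samples):
            reads = np.maximum(
                rng.negative_binomial(cfg.depth_size, nb_p, size=len(sites)), 1
            )
            edits = rng.binomial(reads, p_true)
            table = SampleEditTable(sample_id=f"{label}_{i + 1}", cohort_label=label)
            for k in np.flatnonzero(edits >= 1):
                site = EditSite(
                    chrom=str(chrom[k]), pos=int(pos[k]), strand=str(strand[k]),
                    edit_type=str(edit_type[k]), edits=int(edits[k]),
                    reads=int(reads[k]),
                )
                table.sites[site.key] = site
            tables.append(table)
        cohorts[label] = tables
    return cohorts


@dataclass
class SimExpression:
    """Simulated count matrix with its ground-truth effect structure."""

    counts: pd.DataFrame  # genes x samples
    gene_lengths: pd.Series
    cohorts: dict[str, str]  # sample -> cohort label
    panels: dict[str, list[str]]
    rbp_genes: list[str]
    rbp_affected_samples: list[str]


def simulate_expression(cfg: SimConfig) -> SimExpression:
    """Negative-binomial count matrix with panel and RBP effects.

    Case samples scale ISG / NF-kB panel genes by the configured folds;
    the RBP knockdown factor applies to the first
    ``n_rbp_affected_case_samples`` case samples only.
    """
    rng = _rng(cfg, 2)
    panels = {
        "ISG": [f"ISG{i + 1:02d}" for i in range(cfg.isg_panel_size)],
        "NFKB": [f"NFKB{i + 1:02d}" for i in range(cfg.nfkb_panel_size)],
    }
    rbp = list(RBP_GENES)
    background = [f"BG{i + 1:03d}" for i in range(cfg.n_background_genes)]
    genes = rbp + panels["ISG"] + panels["NFKB"] + background
    base = cfg.expr_baseline_mean * np.exp(
        rng.normal(0.0, cfg.expr_baseline_sigma, size=len(genes))
    )
    lengths = pd.Series(
        rng.integers(500, 5000, size=len(genes)), index=genes, name="length"
    )
    control_samples = [f"{cfg.control_label}_{i + 1}" for i in range(cfg.n_control)]
    case_samples = [f"{cfg.case_label}_{i + 1}" for i in range(cfg.n_case)]
    affected = case_samples[: cfg.n_rbp_affected_case_samples]
    fold = pd.DataFrame(1.0, index=genes, columns=control_samples + case_samples)
    fold.loc[panels["ISG"], case_samples] = cfg.panel_fold.get("ISG", 1.0)
    fold.loc[panels["NFKB"], case_samples] = cfg.panel_fold.get("NFKB", 1.0)
    if affected:
        fold.loc[rbp, affected] = cfg.rbp_factor
    mean = fold.mul(base, axis=0)
    size = cfg.expr_nb_size
    counts = pd.DataFrame(
        rng.negative_binomial(size, size / (size + mean.to_numpy())),
        index=genes, columns=fold.columns,
    )
    cohorts = {s: cfg.control_label for s in control_samples}
    cohorts.update({s: cfg.case_label for s in case_samples})
    return SimExpression(
        counts=counts, gene_lengths=lengths, cohorts=cohorts, panels=panels,
        rbp_genes=rbp, rbp_affected_samples=affected,
    )


def write_input_bundle(
    truth: SimTruth,
    cohorts: Mapping[str, Sequence[SampleEditTable]],
    expression: SimExpression,
    outdir: str | Path,
) -> dict:
    """Write a complete, file-based input bundle the pipeline can consume.

    Returns the run-configuration dictionary (also written as run.yaml).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = truth.config

    table_paths: dict[str, list[str]] = {}
    for label, tables in cohorts.items():
        paths = []
        for table in tables:
            path = outdir / f"edits_{table.sample_id}.tsv"
            write_edit_table(table, path)
            paths.append(str(path))
        table_paths[label] = paths

    with open(outdir / "gene_features.bed", "w") as fh:
        sites = truth.sites
        genic = sites[sites["gene"].notna()]
        for row in genic.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos - 51}\t{row.pos + 50}\t"
                f"{row.gene}|{row.feature_class}\t0\t{row.strand}\n"
            )
    with open(outdir / "repeats.bed", "w") as fh:
        k = 0
        for row in truth.sites.itertuples(index=False):
            if row.in_alu:
                k += 1
                fh.write(
                    f"{row.chrom}\t{row.pos - 151}\t{row.pos + 150}\t"
                    f"AluY_{k}\tAlu\t{row.strand}\n"
                )

    pd.DataFrame(truth.markers).rename(columns={"gene_id": "gene"}).to_csv(
        outdir / "markers.csv", index=False
    )

    expression.counts.rename_axis("gene").to_csv(outdir / "counts.tsv", sep="\t")
    expression.gene_lengths.rename_axis("gene").to_frame().to_csv(
        outdir / "gene_lengths.tsv", sep="\t"
    )
    for panel, genes in expression.panels.items():
        (outdir / f"panel_{panel}.txt").write_text("\n".join(genes) + "\n")
    (outdir / "rbp_genes.txt").write_text("\n".join(expression.rbp_genes) + "\n")

    run_cfg = {
        "control_label": cfg.control_label,
        "case_label": cfg.case_label,
        "control_tables": table_paths[cfg.control_label],
        "case_tables": table_paths[cfg.case_label],
        "gene_bed": str(outdir / "gene_features.bed"),
        "repeat_bed": str(outdir / "repeats.bed"),
        "marker_csv": str(outdir / "markers.csv"),
        "counts_tsv": str(outdir / "counts.tsv"),
        "gene_lengths_tsv": str(outdir / "gene_lengths.tsv"),
        "cohort_map": dict(expression.cohorts),
        "rbp_genes_txt": str(outdir / "rbp_genes.txt"),
        "panel_files": {
            panel: str(outdir / f"panel_{panel}.txt")
            for panel in expression.panels
        },
        "outdir": str(outdir / "results"),
        "seed": cfg.seed,
    }
    with open(outdir / "run.yaml", "w") as fh:
        yaml.safe_dump(run_cfg, fh, sort_keys=True)
    return run_cfg
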