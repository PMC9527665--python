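"""Gene-panel expression screens.

Two screens mirror the cohort expression analyses around editing loss:

* a per-sample ratio screen of RNA-binding-protein (RBP) genes — each
  sample's expression divided by the control-cohort mean, categorised as
  under (< 0.5), normal, or over (> 2.0);
* a panel-level fold-change screen of interferon-stimulated (ISG) and
  NF-kB-regulated gene sets — per-gene log2 ratio of case/control mean
  FPKM with a label-permutation p-value, Benjamini-Hochberg adjustment, and
  a two-way (gene x cohort) ANOVA across each panel.

Fold changes here are transparent normalized ratios of cohort means rather
than a shrinkage-based differential-expression fit.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import TestResult, anova_two_way, bh_adjust

__all__ = ["fpkm", "ratio_screen", "panel_fold_change", "panel_anova"]


def fpkm(
    counts: pd.DataFrame,
    gene_lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    fpkm = count * 1e9 / (gene_length_bases * library_size); library sizes
    default to the column totals of ``counts``.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths[lengths.isna()].index.tolist()[:5]
        raise ValueError(f"genes without lengths: {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    totals = counts.sum(axis=0) if library_sizes is None else library_sizes.reindex(counts.columns)
    if totals.isna().any() or (totals <= 0).any():
        raise ValueError("library sizes must be positive for every sample")
    return counts.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def _split_cohorts(
    columns: Sequence[str],
    cohorts: Mapping[str, str],
    control_label: str,
    case_label: str,
) -> tuple[list[str], list[str]]:
    missing = sorted(set(cohorts) - set(columns))
    if missing:
        raise ValueError(f"samples in cohort map absent from matrix: {missing}")
    control = [s for s in columns if cohorts.get(s) == control_label]
    case = [s for s in columns if cohorts.get(s) == case_label]
    if not control or not case:
        raise ValueError("both cohorts must contain at least one sample")
    return control, case


def ratio_screen(
    expr: pd.DataFrame,
    genes: Sequence[str],
    cohorts: Mapping[str, str],
    control_label: str = "control",
    case_label: str = "case",
    cutoff_low: float = 0.5,
    cutoff_high: float = 2.0,
) -> pd.DataFrame:
    """Per-sample expression relative to the control-cohort mean.

    Categories use strict inequalities: under iff ratio < cutoff_low, over
    iff ratio > cutoff_high.  Genes whose control mean is zero are flagged
    unevaluable rather than dropped.
    """
    control, case = _split_cohorts(expr.columns, cohorts, control_label, case_label)
    rows = []
    for gene in genes:
        if gene not in expr.index:
            rows.append(
                {"gene": gene, "sample": None, "cohort": None, "ratio": None,
                 "category": "missing", "evaluable": False}
            )
            continue
        ctrl_mean = float(expr.loc[gene, control].mean())
        for sample in control + case:
            if ctrl_mean == 0.0:
                rows.append(
                    {"gene": gene, "sample": sample, "cohort": cohorts[sample],
                     "ratio": None, "category": "unevaluable", "evaluable": False}
                )
                continue
            ratio = float(expr.loc[gene, sample]) / ctrl_mean
            if ratio < cutoff_low:
                category = "under"
            elif ratio > cutoff_high:
                category = "over"
            else:
                category = "normal"
            rows.append(
                {"gene": gene, "sample": sample, "cohort": cohorts[sample],
                 "ratio": ratio, "category": category, "evaluable": True}
            )
    return pd.DataFrame(
        rows, columns=["gene", "sample", "cohort", "ratio", "category", "evaluable"]
    )


def panel_fold_change(
    expr: pd.DataFrame,
    panels: Mapping[str, Sequence[str]],
    cohorts: Mapping[str, str],
    control_label: str = "control",
    case_label: str = "case",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene log2 case/control mean ratio with permutation p and BH FDR.

    The reported effect is log2(mean_case / mean_control) of the expression
    values (typically FPKM) with a delta-method standard error.  The
    p-value permutes cohort labels and compares the absolute difference in
    cohort means of log2(x + 1), a statistic that stays finite when a
    permuted group mean is zero.  BH adjustment runs across all panel genes
    screened in the call; ``fdr_flag`` marks adjusted p > 0.05.
    """
    control, case = _split_cohorts(expr.columns, cohorts, control_label, case_label)
    rng = np.random.default_rng(seed)
    gene_rows = []
    all_samples = control + case
    n_ctrl = len(control)
    values = expr[all_samples]
    log_values = np.log2(values.to_numpy(dtype=float) + 1.0)
    # one shared set of label permutations across genes
    perm_idx = np.argsort(
        rng.random((n_permutations, len(all_samples))), axis=1
    )
    for panel, genes in panels.items():
        for gene in genes:
            if gene not in expr.index:
                gene_rows.append(
                    {"gene": gene, "panel": panel, "log2_ratio": None, "se": None,
                     "p": None, "missing": True}
                )
                continue
            row = values.loc[gene].to_numpy(dtype=float)
            mean_c = row[:n_ctrl].mean()
            mean_x = row[n_ctrl:].mean()
            n_case = len(row) - n_ctrl
            if mean_c > 0 and mean_x > 0:
                log2_ratio = math.log2(mean_x / mean_c)
                if n_ctrl > 1 and n_case > 1:
                    se_c = row[:n_ctrl].std(ddof=1) / math.sqrt(n_ctrl)
                    se_x = row[n_ctrl:].std(ddof=1) / math.sqrt(n_case)
                    se = math.sqrt(
                        (se_x / mean_x) ** 2 + (se_c / mean_c) ** 2
                    ) / math.log(2)
                else:
                    se = None
            else:
                log2_ratio, se = None, None
            lrow = np.log2(row + 1.0)
            obs = abs(lrow[n_ctrl:].mean() - lrow[:n_ctrl].mean())
            permuted = lrow[perm_idx]
            perm_stat = np.abs(
                permuted[:, n_ctrl:].mean(axis=1) - permuted[:, :n_ctrl].mean(axis=1)
            )
            p = (1.0 + np.sum(perm_stat >= obs - 1e-12)) / (n_permutations + 1.0)
            gene_rows.append(
                {"gene": gene, "panel": panel, "log2_ratio": log2_ratio,
                 "se": se, "p": float(p), "missing": False}
            )
    df = pd.DataFrame(
        gene_rows, columns=["gene", "panel", "log2_ratio", "se", "p", "missing"]
    )
    df["p_adj"] = np.nan
    mask = df["p"].notna()
    if mask.any():
        df.loc[mask, "p_adj"] = bh_adjust(df.loc[mask, "p"].to_numpy())
    df["fdr_flag"] = df["p_adj"] > 0.05
    return df


def panel_anova(
    expr: pd.DataFrame,
    genes: Sequence[str],
    cohorts: Mapping[str, str],
    control_label: str = "control",
    case_label: str = "case",
) -> dict[str, TestResult]:
    """Two-way ANOVA (gene x cohort) on log2(x + 1) expression of a panel.

    Requires a balanced design (equal cohort sizes) with >= 2 genes; the
    cohort factor's F-test is the headline result.
    """
    control, case = _split_cohorts(expr.columns, cohorts, control_label, case_label)
    genes = [g for g in genes if g in expr.index]
    if len(genes) < 2:
        raise ValueError("panel ANOVA needs >= 2 genes present in the matrix")
    values, f_gene, f_cohort = [], [], []
    for gene in genes:
        for sample in control:
            values.append(math.log2(float(expr.loc[gene, sample]) + 1.0))
            f_gene.append(gene)
            f_cohort.append(control_label)
        for sample in case:
            values.append(math.log2(float(expr.loc[gene, sample]) + 1.0))
            f_gene.append(gene)
            f_cohort.append(case_label)
    res = anova_two_way(values, f_gene, f_cohort)
    return {"gene": res["factor_a"], "cohort": res["factor_b"],
            "interaction": res["interaction"]}
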