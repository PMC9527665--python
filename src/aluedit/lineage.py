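"""Cell-lineage editing comparisons driven by single-cell marker genes.

Lineage-defining genes are those detected far more often inside one cluster
than elsewhere (pct1/pct2 strictly above a threshold, 10 by default).  For
each lineage, per-gene editing indices in control and case cohorts form two
vectors with the GENE as the unit of observation; Welch's unpaired t-test
compares them.  Genes without qualifying edit sites contribute an index of
zero rather than being dropped, so a uniform loss of editing does not
delete genes asymmetrically between cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io import MarkerRecord
from .stats import welch_t

__all__ = [
    "LineageComparison",
    "select_lineage_genes",
    "lineage_editing_comparison",
    "lineage_table",
]


def select_lineage_genes(
    markers: Iterable[MarkerRecord],
    ratio_threshold_exclusive: float = 10.0,
) -> dict[str, set[str]]:
    """Genes with pct1/pct2 strictly above the threshold, per lineage.

    pct2 == 0 with pct1 > 0 counts as an infinite ratio and selects the
    gene; pct values outside [0, 1] are rejected.
    """
    markers = list(markers)
    if not markers:
        raise ValueError("marker table is empty")
    selected: dict[str, set[str]] = {}
    for m in markers:
        for label, val in (("pct1", m.pct1), ("pct2", m.pct2)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{label}={val} outside [0,1] for {m.gene_id}")
        selected.setdefault(m.cluster, set())
        ratio = math.inf if m.pct2 == 0 else m.pct1 / m.pct2
        if m.pct1 > 0 and ratio > ratio_threshold_exclusive:
            selected[m.cluster].add(m.gene_id)
    return selected


@dataclass
class LineageComparison:
    lineage: str
    n_control: int
    n_case: int
    genes: list[str]
    control_indices: list[float]
    case_indices: list[float]
    mean_control: float
    sem_control: float
    mean_case: float
    sem_case: float
    p: float | None
    t: float | None
    df: float | None
    testable: bool

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def _mean_sem(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n < 2:
        return mean, float("nan")
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def lineage_editing_comparison(
    gene_sets: Mapping[str, set[str]],
    control_gene_index: Mapping[str, float],
    case_gene_index: Mapping[str, float],
    n_control: int,
    n_case: int,
    min_genes_testable: int = 3,
) -> list[LineageComparison]:
    """Per-lineage Welch comparison of per-gene editing indices.

    Genes absent from an index map score 0 in that cohort.  Lineages with
    fewer than ``min_genes_testable`` genes, or with zero variance in both
    cohorts, are flagged untestable (no p/t/df).
    """
    results = []
    for lineage in sorted(gene_sets):
        genes = sorted(gene_sets[lineage])
        ctrl = [float(control_gene_index.get(g, 0.0)) for g in genes]
        case = [float(case_gene_index.get(g, 0.0)) for g in genes]
        if not genes:
            results.append(
                LineageComparison(
                    lineage, n_control, n_case, [], [], [],
                    float("nan"), float("nan"), float("nan"), float("nan"),
                    None, None, None, False,
                )
            )
            continue
        mean_c, sem_c = _mean_sem(ctrl)
        mean_x, sem_x = _mean_sem(case)
        testable = len(genes) >= min_genes_testable
        p = t = df = None
        if testable:
            try:
                res = welch_t(ctrl, case)
                p, t, df = res.p, res.statistic, res.df
            except ValueError:
                testable = False
        results.append(
            LineageComparison(
                lineage=lineage,
                n_control=n_control,
                n_case=n_case,
                genes=genes,
                control_indices=ctrl,
                case_indices=case,
                mean_control=mean_c,
                sem_control=sem_c,
                mean_case=mean_x,
                sem_case=sem_x,
                p=p,
                t=t,
                df=df,
                testable=testable,
            )
        )
    return results


def lineage_table(comparisons: Iterable[LineageComparison]) -> pd.DataFrame:
    """Tabular summary: one row per lineage with means +/- SEM and Welch stats."""
    rows = []
    for c in comparisons:
        rows.append(
            {
                "cell_type": c.lineage,
                "n_control": c.n_control,
                "n_case": c.n_case,
                "n_genes": c.n_genes,
                "mean_sem_control": f"{c.mean_control:.3g} ± {c.sem_control:.3g}",
                "mean_sem_case": f"{c.mean_case:.3g} ± {c.sem_case:.3g}",
                "P": c.p,
                "t": c.t,
                "df": c.df,
                "testable": c.testable,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_type", "n_control", "n_case", "n_genes",
            "mean_sem_control", "mean_sem_case", "P", "t", "df", "testable",
        ],
    )
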