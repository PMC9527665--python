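"""Per-site, genome-wide and per-gene A-to-I editing indices.

The per-site editing index within a cohort is the mean edit/read ratio over
the samples containing the site multiplied by the number of such samples
(so a site edited at ratio 0.3 in 4 of 7 samples scores 1.2).  The
genome-wide index is the sum of per-site indices; the per-gene index is the
sum over the sites assigned to a gene, and disease/control contrasts are
expressed as log2 ratios of per-gene indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import SiteAnnotation
from .filtering import FilterConfig, PresenceMatrix
from .io import SiteKey

__all__ = [
    "SiteIndexRecord",
    "GeneIndexRecord",
    "site_index",
    "genome_wide_index",
    "per_gene_index",
    "intergenic_index",
    "min_attainable_site_index",
    "site_index_frame",
    "gene_index_frame",
]


@dataclass(frozen=True)
class SiteIndexRecord:
    site: SiteKey
    cohort: str
    n_samples_with_edits: int
    mean_ratio: float

    @property
    def index(self) -> float:
        return self.mean_ratio * self.n_samples_with_edits


@dataclass(frozen=True)
class GeneIndexRecord:
    """Per-gene index in both cohorts with the case/control log2 contrast.

    ``log2_ratio`` is finite iff both indices are positive; otherwise
    ``category`` carries the sentinel ("case_only", "control_only" or
    "both_zero") and log2_ratio is None.
    """

    gene_id: str
    n_sites_case: int
    n_sites_control: int
    index_case: float
    index_control: float

    @property
    def category(self) -> str:
        if self.index_case > 0 and self.index_control > 0:
            return "finite"
        if self.index_case > 0:
            return "case_only"
        if self.index_control > 0:
            return "control_only"
        return "both_zero"

    @property
    def log2_ratio(self) -> float | None:
        if self.category != "finite":
            return None
        return math.log2(self.index_case / self.index_control)


def min_attainable_site_index(cfg: FilterConfig) -> float:
    """Infimum of the per-site index under the inclusion rules.

    Every retained per-sample ratio strictly exceeds
    ``min_ratio_exclusive``, so the mean ratio does too, and a site needs at
    least ``min_samples_inclusive`` samples; the index therefore strictly
    exceeds their product (0.1 with defaults), which is the greatest lower
    bound in the limit.
    """
    return cfg.min_ratio_exclusive * cfg.min_samples_inclusive


def site_index(pres: PresenceMatrix, cfg: FilterConfig) -> list[SiteIndexRecord]:
    """Per-site index records for sites present in enough cohort samples.

    ``mean_ratio`` averages only over the samples containing the site —
    absence is not a ratio of zero.
    """
    records = []
    for key in sorted(pres.site_samples):
        ratios = pres.ratios(key)
        if len(ratios) < cfg.min_samples_inclusive:
            continue
        records.append(
            SiteIndexRecord(
                site=key,
                cohort=pres.cohort_label,
                n_samples_with_edits=len(ratios),
                mean_ratio=sum(ratios) / len(ratios),
            )
        )
    return records


def genome_wide_index(
    records: Sequence[SiteIndexRecord],
) -> tuple[list[SiteIndexRecord], float]:
    """Rank records by descending index and total them across the genome."""
    cohorts = {r.cohort for r in records}
    if len(cohorts) > 1:
        raise ValueError(f"records span multiple cohorts: {sorted(cohorts)}")
    ranked = sorted(records, key=lambda r: (-r.index, r.site))
    return ranked, float(sum(r.index for r in records))


def _gene_of(annotations: Mapping[SiteKey, SiteAnnotation], key: SiteKey) -> str | None:
    ann = annotations.get(key)
    return None if ann is None else ann.gene_id


def per_gene_index(
    case_records: Iterable[SiteIndexRecord],
    control_records: Iterable[SiteIndexRecord],
    annotations: Mapping[SiteKey, SiteAnnotation],
    min_sites_per_gene_exclusive: int = 5,
) -> list[GeneIndexRecord]:
    """Per-gene summed indices and case/control contrasts.

    A gene qualifies when its site count strictly exceeds
    ``min_sites_per_gene_exclusive`` in either cohort.  Sites mapping to no
    gene are intergenic and excluded (see :func:`intergenic_index`).
    """
    per_gene: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for label, records in (("case", case_records), ("control", control_records)):
        for rec in records:
            gene = _gene_of(annotations, rec.site)
            if gene is None:
                continue
            per_gene.setdefault(gene, {"case": 0.0, "control": 0.0})[label] += rec.index
            counts.setdefault(gene, {"case": 0, "control": 0})[label] += 1
    out = []
    for gene in sorted(per_gene):
        n_case = counts[gene]["case"]
        n_control = counts[gene]["control"]
        if max(n_case, n_control) <= min_sites_per_gene_exclusive:
            continue
        out.append(
            GeneIndexRecord(
                gene_id=gene,
                n_sites_case=n_case,
                n_sites_control=n_control,
                index_case=per_gene[gene]["case"],
                index_control=per_gene[gene]["control"],
            )
        )
    return out


def intergenic_index(
    records: Iterable[SiteIndexRecord],
    annotations: Mapping[SiteKey, SiteAnnotation],
) -> float:
    """Summed index of sites assigned to no gene (one cohort's records)."""
    return float(
        sum(r.index for r in records if _gene_of(annotations, r.site) is None)
    )


def site_index_frame(records: Sequence[SiteIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cohort": r.cohort,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "strand": r.site.strand,
                "edit_type": r.site.edit_type,
                "n_samples": r.n_samples_with_edits,
                "mean_ratio": r.mean_ratio,
                "index": r.index,
            }
            for r in records
        ],
        columns=[
            "cohort", "chrom", "pos", "strand", "edit_type",
            "n_samples", "mean_ratio", "index",
        ],
    )


def gene_index_frame(records: Sequence[GeneIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene_id,
                "n_sites_case": r.n_sites_case,
                "n_sites_control": r.n_sites_control,
                "index_case": r.index_case,
                "index_control": r.index_control,
                "log2_ratio": r.log2_ratio,
                "category": r.category,
            }
            for r in records
        ],
        columns=[
            "gene", "n_sites_case", "n_sites_control",
            "index_case", "index_control", "log2_ratio", "category",
        ],
    )
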