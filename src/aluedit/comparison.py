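"""Cohort-level set comparisons of editing sites.

A "common" site in a cohort is one present in every sample of that cohort
(after filtering).  Comparing two cohorts partitions the common sites into
those common to A but not B, common to B but not A, and common to both; the
counts of qualifying sites are compared with a two-cell chi-square
goodness-of-fit test against equal expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .filtering import PresenceMatrix
from .io import SiteKey
from .stats import TestResult, chi2_gof

__all__ = [
    "RankedSite",
    "SharedSite",
    "CommonSiteReport",
    "common_sites",
    "rank_by_ratio",
    "compare_site_counts",
]


@dataclass(frozen=True)
class RankedSite:
    key: SiteKey
    mean_ratio: float


@dataclass(frozen=True)
class SharedSite:
    key: SiteKey
    mean_ratio_a: float
    mean_ratio_b: float


@dataclass
class CommonSiteReport:
    """Partition of cohort-common sites into A-only / B-only / shared."""

    label_a: str
    label_b: str
    a_only: list[RankedSite]
    b_only: list[RankedSite]
    shared: list[SharedSite]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rank, s in enumerate(rank_by_ratio(self.a_only), start=1):
            rows.append(_row(f"{self.label_a}_only", s.key, s.mean_ratio, None, rank))
        for rank, s in enumerate(rank_by_ratio(self.b_only), start=1):
            rows.append(_row(f"{self.label_b}_only", s.key, None, s.mean_ratio, rank))
        shared_ranked = sorted(
            self.shared, key=lambda s: (-s.mean_ratio_a, s.key)
        )
        for rank, s in enumerate(shared_ranked, start=1):
            rows.append(_row("shared", s.key, s.mean_ratio_a, s.mean_ratio_b, rank))
        return pd.DataFrame(
            rows,
            columns=[
                "set", "chrom", "pos", "strand", "edit_type",
                "mean_ratio_A", "mean_ratio_B", "rank",
            ],
        )


def _row(set_name, key, ra, rb, rank):
    return {
        "set": set_name,
        "chrom": key.chrom,
        "pos": key.pos,
        "strand": key.strand,
        "edit_type": key.edit_type,
        "mean_ratio_A": ra,
        "mean_ratio_B": rb,
        "rank": rank,
    }


def _mean(values: Sequence[float]) -> float:
    return sum(values) / len(values)


def common_sites(
    pres_a: PresenceMatrix,
    pres_b: PresenceMatrix,
    n_a: int | None = None,
    n_b: int | None = None,
) -> CommonSiteReport:
    """Partition sites common to all samples of a cohort between two cohorts.

    A site is "in all of A" when every one of the cohort's ``n_a`` samples
    contains it post-filter; "not all of B" covers any presence count below
    ``n_b``, including zero.  Mean ratios are averaged over the samples of
    the qualifying cohort; shared sites report both cohorts separately.
    """
    n_a = pres_a.n_samples if n_a is None else n_a
    n_b = pres_b.n_samples if n_b is None else n_b
    if n_a < 1 or n_b < 1:
        raise ValueError("cohort sizes must be >= 1")
    all_a = {k for k, s in pres_a.site_samples.items() if len(s) == n_a}
    all_b = {k for k, s in pres_b.site_samples.items() if len(s) == n_b}
    a_only = [
        RankedSite(k, _mean(pres_a.ratios(k))) for k in sorted(all_a - all_b)
    ]
    b_only = [
        RankedSite(k, _mean(pres_b.ratios(k))) for k in sorted(all_b - all_a)
    ]
    shared = [
        SharedSite(k, _mean(pres_a.ratios(k)), _mean(pres_b.ratios(k)))
        for k in sorted(all_a & all_b)
    ]
    return CommonSiteReport(
        label_a=pres_a.cohort_label,
        label_b=pres_b.cohort_label,
        a_only=a_only,
        b_only=b_only,
        shared=shared,
    )


def rank_by_ratio(sites: Sequence[RankedSite]) -> list[RankedSite]:
    """Order sites by descending mean ratio; ties break by site ordering."""
    return sorted(sites, key=lambda s: (-s.mean_ratio, s.key))


def compare_site_counts(count_a: int, count_b: int) -> TestResult:
    """Two-cell chi-square goodness-of-fit of site counts vs equal split."""
    if count_a < 0 or count_b < 0:
        raise ValueError("site counts must be non-negative")
    if count_a + count_b == 0:
        raise ValueError("both site counts are zero")
    return chi2_gof([count_a, count_b])
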