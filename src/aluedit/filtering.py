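"""Site-inclusion filters and per-cohort presence structures.

Editing-site calls are noisy at low coverage, so sites enter the analysis
only when total reads exceed a floor and the edit/read ratio exceeds a noise
threshold (both strict inequalities), and downstream indices additionally
require detection in a minimum number of samples within a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .io import SampleEditTable, SiteKey

__all__ = ["FilterConfig", "PresenceMatrix", "filter_sites", "build_presence"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for admitting an edit site into the analysis.

    ``min_reads_exclusive`` and ``min_ratio_exclusive`` are strict lower
    bounds applied per sample; ``min_samples_inclusive`` is the minimum
    number of samples (>=) in one cohort that must contain the site for it
    to contribute to editing indices.
    """

    min_reads_exclusive: int = 5
    min_ratio_exclusive: float = 0.05
    min_samples_inclusive: int = 2

    def __post_init__(self) -> None:
        if self.min_reads_exclusive < 0:
            raise ValueError("min_reads_exclusive must be >= 0")
        if not 0.0 <= self.min_ratio_exclusive < 1.0:
            raise ValueError("min_ratio_exclusive must lie in [0, 1)")
        if self.min_samples_inclusive < 1:
            raise ValueError("min_samples_inclusive must be >= 1")


def filter_sites(table: SampleEditTable, cfg: FilterConfig) -> SampleEditTable:
    """Retain sites with reads > threshold and ratio > threshold.

    Idempotent: filtering an already-filtered table changes nothing.
    """
    out = SampleEditTable(sample_id=table.sample_id, cohort_label=table.cohort_label)
    out.sites = {
        key: site
        for key, site in table.sites.items()
        if site.reads > cfg.min_reads_exclusive
        and site.ratio > cfg.min_ratio_exclusive
    }
    return out


@dataclass
class PresenceMatrix:
    """Which samples of one cohort contain each filtered site, with ratios."""

    cohort_label: str
    sample_ids: tuple[str, ...]
    site_samples: dict[SiteKey, dict[str, float]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def samples_with(self, key: SiteKey) -> set[str]:
        return set(self.site_samples.get(key, ()))

    def ratios(self, key: SiteKey) -> list[float]:
        return list(self.site_samples.get(key, {}).values())


def build_presence(cohort: Sequence[SampleEditTable]) -> PresenceMatrix:
    """Collect per-site sample sets and ratios for one cohort.

    All tables must share one cohort label and must already be filtered; a
    site appears in the matrix iff at least one sample contains it.
    """
    if not cohort:
        raise ValueError("cohort must contain at least one sample table")
    labels = {t.cohort_label for t in cohort}
    if len(labels) > 1:
        raise ValueError(f"mixed cohort labels: {sorted(labels)}")
    sample_ids = tuple(t.sample_id for t in cohort)
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample ids within cohort")
    pres = PresenceMatrix(cohort_label=labels.pop(), sample_ids=sample_ids)
    for table in cohort:
        for key, site in table.sites.items():
            pres.site_samples.setdefault(key, {})[table.sample_id] = site.ratio
    return pres
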