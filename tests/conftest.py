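import numpy as np
import pytest

from aluedit.filtering import FilterConfig
from aluedit.io import EditSite, SampleEditTable


def make_site(chrom="chr1", pos=1000, strand="+", edit_type="AG",
              edits=3, reads=20) -> EditSite:
    return EditSite(chrom=chrom, pos=pos, strand=strand,
                    edit_type=edit_type, edits=edits, reads=reads)


def make_table(sample_id, cohort_label, sites) -> SampleEditTable:
    table = SampleEditTable(sample_id=sample_id, cohort_label=cohort_label)
    for site in sites:
        table.add(site)
    return table


def random_table(rng: np.random.Generator, sample_id, cohort_label,
                 n_sites=20, chroms=("chr1", "chr2")) -> SampleEditTable:
    """A valid random sample table (unique positions, legal counts)."""
    table = SampleEditTable(sample_id=sample_id, cohort_label=cohort_label)
    positions = rng.choice(10_000, size=n_sites, replace=False) + 1
    for pos in positions:
        reads = int(rng.integers(1, 60))
        edits = int(rng.integers(0, reads + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        table.add(
            EditSite(
                chrom=str(rng.choice(chroms)), pos=int(pos), strand=strand,
                edit_type="AG" if strand == "+" else "TC",
                edits=edits, reads=reads,
            )
        )
    return table


@pytest.fixture
def default_filter() -> FilterConfig:
    return FilterConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
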