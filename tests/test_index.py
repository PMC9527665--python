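import math

import numpy as np
import pytest

from aluedit.annotation import SiteAnnotation, annotate_sites
from aluedit.filtering import FilterConfig, build_presence, filter_sites
from aluedit.indices import (
    SiteIndexRecord,
    genome_wide_index,
    intergenic_index,
    min_attainable_site_index,
    per_gene_index,
    site_index,
)
from aluedit.io import SiteKey
from aluedit.simulate import SimConfig, simulate_cohorts, simulate_truth

from conftest import make_site, make_table


def _pres(site_lists, label="NCI"):
    return build_presence(
        [make_table(f"{label}{i}", label, s) for i, s in enumerate(site_lists)]
    )


def _ann(gene_map):
    """Annotation mapping where gene_map[key] may be None (intergenic)."""
    return {
        key: SiteAnnotation(
            site=key,
            feature_class="intron" if gene else "intergenic",
            gene_id=gene,
            in_alu=False,
            repeat_name=None,
        )
        for key, gene in gene_map.items()
    }


def _rec(pos, cohort, n, mean_ratio):
    return SiteIndexRecord(SiteKey("chr1", pos, "+", "AG"), cohort, n, mean_ratio)


class TestSiteIndex:
    def test_mean_times_sample_count(self, default_filter):
        pres = _pres([
            [make_site(pos=100, edits=2, reads=10)],   # 0.2
            [make_site(pos=100, edits=4, reads=10)],   # 0.4
        ])
        (rec,) = site_index(pres, default_filter)
        assert rec.mean_ratio == pytest.approx(0.3)
        assert rec.n_samples_with_edits == 2
        assert rec.index == pytest.approx(0.6)

    def test_single_sample_site_omitted(self, default_filter):
        pres = _pres([
            [make_site(pos=100, edits=2, reads=10)],
            [make_site(pos=200, edits=2, reads=10)],
        ])
        assert site_index(pres, default_filter) == []

    def test_all_indices_exceed_analytic_floor(self, default_filter):
        """Simulated cohorts never emit an index at or below the infimum."""
        cfg = SimConfig(seed=11, retention=0.7, n_genes=50, n_lineages=2, markers_per_lineage=10)
        cohorts = simulate_cohorts(simulate_truth(cfg))
        floor = min_attainable_site_index(default_filter)
        assert floor == pytest.approx(0.1)
        for tables in cohorts.values():
            pres = build_presence([filter_sites(t, default_filter) for t in tables])
            records = site_index(pres, default_filter)
            assert records, "simulation produced no index sites"
            assert all(r.index > floor for r in records)
            assert all(r.index <= r.n_samples_with_edits for r in records)

    def test_duplicating_every_sample_doubles_indices(self, default_filter):
        sites = [
            [make_site(pos=100, edits=2, reads=10), make_site(pos=200, edits=9, reads=10)],
            [make_site(pos=100, edits=4, reads=10)],
        ]
        base = {r.site: r.index for r in site_index(_pres(sites), default_filter)}
        doubled_tables = [
            make_table(f"s{i}", "NCI", s)
            for i, s in enumerate(sites + [list(s) for s in sites])
        ]
        doubled = {
            r.site: r.index
            for r in site_index(build_presence(doubled_tables), default_filter)
        }
        for key, idx in base.items():
            assert doubled[key] == pytest.approx(2 * idx)


class TestGenomeWideIndex:
    def test_total_is_sum(self):
        ranked, total = genome_wide_index([_rec(1, "NCI", 2, 0.3), _rec(2, "NCI", 3, 0.4)])
        assert total == pytest.approx(0.6 + 1.2)
        assert [r.index for r in ranked] == sorted(
            (r.index for r in ranked), reverse=True
        )

    def test_empty_records(self):
        ranked, total = genome_wide_index([])
        assert ranked == [] and total == 0.0

    def test_matches_independent_summation_order(self, rng):
        records = [
            _rec(i + 1, "NCI", int(rng.integers(2, 8)), float(rng.random()))
            for i in range(500)
        ]
        _, total = genome_wide_index(records)
        oracle = math.fsum(sorted(r.index for r in records))
        assert total == pytest.approx(oracle, abs=1e-12)

    def test_mixed_cohorts_rejected(self):
        with pytest.raises(ValueError):
            genome_wide_index([_rec(1, "NCI", 2, 0.3), _rec(2, "AD", 2, 0.3)])


class TestPerGeneIndex:
    def test_log2_ratio_forced_arithmetic(self):
        case = [_rec(p, "AD", 2, r / 2) for p, r in
                [(1, 0.6), (2, 1.2), (3, 0.3), (4, 0.2), (5, 0.2), (6, 0.2)]]
        control = [_rec(p, "NCI", 2, r / 2) for p, r in
                   [(1, 1.2), (2, 2.4), (3, 0.6), (4, 0.4), (5, 0.4), (6, 0.4)]]
        ann = _ann({r.site: "G1" for r in case})
        (rec,) = per_gene_index(case, control, ann)
        assert rec.index_case == pytest.approx(2.7)
        assert rec.index_control == pytest.approx(5.4)
        assert rec.log2_ratio == pytest.approx(-1.0)
        assert rec.category == "finite"

    def test_five_sites_in_both_cohorts_excluded(self):
        case = [_rec(p, "AD", 2, 0.3) for p in range(1, 6)]
        control = [_rec(p, "NCI", 2, 0.3) for p in range(1, 6)]
        ann = _ann({r.site: "G1" for r in case})
        assert per_gene_index(case, control, ann) == []
        # six sites in one cohort is enough
        case6 = case + [_rec(6, "AD", 2, 0.3)]
        ann6 = _ann({r.site: "G1" for r in case6})
        assert len(per_gene_index(case6, control, ann6)) == 1

    def test_zero_control_index_yields_sentinel(self):
        case = [_rec(p, "AD", 2, 0.3) for p in range(1, 8)]
        ann = _ann({r.site: "G1" for r in case})
        (rec,) = per_gene_index(case, [], ann)
        assert rec.category == "case_only"
        assert rec.log2_ratio is None
        assert rec.index_case > 0 and rec.index_control == 0

    def test_gene_plus_intergenic_partition_equals_genome_total(self, default_filter):
        """Unique site->gene assignment partitions the genome-wide total."""
        cfg = SimConfig(seed=7, retention=0.8, n_genes=40, n_lineages=2, markers_per_lineage=10)
        truth = simulate_truth(cfg)
        cohorts = simulate_cohorts(truth)
        label = cfg.control_label
        pres = build_presence(
            [filter_sites(t, default_filter) for t in cohorts[label]]
        )
        records = site_index(pres, default_filter)
        _, total = genome_wide_index(records)
        ann = annotate_sites([r.site for r in records], truth.features)
        gene_records = per_gene_index(
            records, records, ann, min_sites_per_gene_exclusive=0
        )
        genic = sum(r.index_case for r in gene_records)
        assert genic + intergenic_index(records, ann) == pytest.approx(total, abs=1e-9)
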