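import numpy as np
import pytest

from aluedit.annotation import (
    SP6_PROMOTER,
    annotate_sites,
    composition_summary,
    design_edited_template,
    write_templates_fasta,
)
from aluedit.io import FeatureIntervals, SiteKey
from aluedit.simulate import SimConfig, simulate_truth


def _key(pos, chrom="chr1", strand="+"):
    return SiteKey(chrom, pos, strand, "AG")


@pytest.fixture
def store():
    fs = FeatureIntervals()
    fs.add_gene_feature("chr1", 0, 2000, "G1", "intron", "+")
    fs.add_repeat("chr1", 500, 800, "AluSg4", "Alu", "+")
    fs.add_repeat("chr1", 1500, 1600, "L1M", "L1", "+")
    return fs


class TestAnnotateSites:
    def test_alu_inside_intron(self, store):
        ann = annotate_sites([_key(600)], store)[_key(600)]
        assert ann.feature_class == "intron"
        assert ann.gene_id == "G1"
        assert ann.in_alu and ann.repeat_name == "AluSg4"

    def test_non_alu_repeat_does_not_count(self, store):
        ann = annotate_sites([_key(1550)], store)[_key(1550)]
        assert not ann.in_alu and ann.repeat_name is None

    def test_uncovered_position_is_intergenic(self, store):
        ann = annotate_sites([_key(5000)], store)[_key(5000)]
        assert ann.feature_class == "intergenic"
        assert ann.gene_id is None and not ann.in_alu

    def test_utr_takes_precedence_over_intron(self):
        fs = FeatureIntervals()
        fs.add_gene_feature("chr1", 0, 1000, "G1", "intron", "+")
        fs.add_gene_feature("chr1", 400, 600, "G2", "3UTR", "+")
        ann = annotate_sites([_key(500)], fs)[_key(500)]
        assert ann.feature_class == "3UTR" and ann.gene_id == "G2"

    def test_equal_class_tie_breaks_by_nearest_start(self):
        fs = FeatureIntervals()
        fs.add_gene_feature("chr1", 0, 1000, "FAR", "intron", "+")
        fs.add_gene_feature("chr1", 400, 1000, "NEAR", "intron", "+")
        ann = annotate_sites([_key(450)], fs)[_key(450)]
        assert ann.gene_id == "NEAR"

    def test_strict_strand_flag(self, store):
        key = SiteKey("chr1", 600, "-", "TC")
        permissive = annotate_sites([key], store)[key]
        strict = annotate_sites([key], store, strict_strand=True)[key]
        assert permissive.gene_id == "G1" and permissive.in_alu
        assert strict.gene_id is None and not strict.in_alu


class TestComposition:
    def test_alu_fraction(self, store):
        keys = [_key(510 + i) for i in range(9)] + [_key(1900)]
        comp = composition_summary(annotate_sites(keys, store))
        assert comp["fraction_alu"] == pytest.approx(0.9)
        assert comp["fraction_genic"] == pytest.approx(1.0)

    def test_all_intergenic(self):
        comp = composition_summary(annotate_sites([_key(1)], FeatureIntervals()))
        assert comp["fraction_genic"] == 0.0

    def test_fractions_sum_to_one(self, store, rng):
        keys = [_key(int(p)) for p in rng.choice(3000, size=50, replace=False) + 1]
        comp = composition_summary(annotate_sites(keys, store))
        feature_total = sum(
            v for k, v in comp.items()
            if k.startswith("fraction_") and k not in ("fraction_alu", "fraction_genic")
        )
        assert feature_total == pytest.approx(1.0, abs=1e-12)

    def test_empty_annotation_set_rejected(self):
        with pytest.raises(ValueError):
            composition_summary({})

    def test_generator_placement_recovered(self):
        """Annotating generator output recovers its Alu placement fraction."""
        cfg = SimConfig(seed=5, alu_fraction=0.95, n_genes=100)
        truth = simulate_truth(cfg)
        keys = [
            SiteKey(r.chrom, r.pos, r.strand, r.edit_type)
            for r in truth.sites.itertuples(index=False)
        ]
        comp = composition_summary(annotate_sites(keys, truth.features))
        n = len(keys)
        sd = np.sqrt(0.95 * 0.05 / n)
        assert abs(comp["fraction_alu"] - 0.95) < 3 * sd


class TestTemplateDesign:
    def test_single_substitution(self):
        t = design_edited_template("GGAATT", {3})
        assert t.edited_sequence == "GGGATT"
        assert t.unedited_sequence == "GGAATT"
        assert t.edited_construct == SP6_PROMOTER + "GGGATT"

    def test_no_positions_is_identity(self):
        t = design_edited_template("GGAATT", set())
        assert t.edited_sequence == t.unedited_sequence

    def test_non_a_position_rejected_with_position_named(self):
        with pytest.raises(ValueError, match="position 5"):
            design_edited_template("GGAATT", {5})
        with pytest.raises(ValueError, match="position 7"):
            design_edited_template("GGAATT", {7})

    def test_random_sequences_differ_only_at_positions(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            n = int(rng.integers(10, 120))
            seq = "".join(rng.choice(bases, size=n))
            a_positions = [i + 1 for i, b in enumerate(seq) if b == "A"]
            if not a_positions:
                continue
            k = int(rng.integers(1, len(a_positions) + 1))
            chosen = set(rng.choice(a_positions, size=k, replace=False).tolist())
            t = design_edited_template(seq, chosen)
            for i, (u, e) in enumerate(zip(t.unedited_sequence, t.edited_sequence), 1):
                if i in chosen:
                    assert (u, e) == ("A", "G")
                else:
                    assert u == e
            # idempotent: edited positions in the output hold G, so re-editing
            # the edited sequence at untouched A positions changes nothing new
            remaining = set(a_positions) - chosen
            t2 = design_edited_template(t.edited_sequence, remaining)
            assert t2.edited_sequence == design_edited_template(seq, set(a_positions)).edited_sequence

    def test_fasta_export_round_trip(self, tmp_path):
        from Bio import SeqIO

        t = design_edited_template("GGAATT", {3}, name="mdm4_alusg4")
        path = tmp_path / "templates.fasta"
        write_templates_fasta([t], path)
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        assert records["mdm4_alusg4_unedited"] == SP6_PROMOTER + "GGAATT"
        assert records["mdm4_alusg4_edited"] == SP6_PROMOTER + "GGGATT"
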