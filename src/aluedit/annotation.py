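"""Genomic feature and Alu annotation of editing sites, plus in-silico
construction of edited Alu DNA templates.

Each site is classified into a gene feature (3'UTR, 5'UTR, ncRNA, intron) or
intergenic, and flagged as inside an Alu repeat when any covering repeat
interval belongs to the Alu family.  Overlapping gene features resolve by a
fixed precedence (UTRs first, since UTR editing is the biological focus),
then by proximity of the feature start.  Strand is ignored for membership
unless strict-strand mode is requested.

Edited templates mimic A-to-I editing in DNA: the declared adenosines are
replaced by guanosines and a transcription promoter (SP6 by default) is
prepended for synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io import FeatureIntervals, SiteKey

__all__ = [
    "SiteAnnotation",
    "AluTemplate",
    "SP6_PROMOTER",
    "FEATURE_PRECEDENCE",
    "annotate_sites",
    "composition_summary",
    "design_edited_template",
    "write_templates_fasta",
    "annotation_frame",
]

SP6_PROMOTER = "ATTTAGGTGACACTATAG"

#: Smaller value wins when a position lies in several feature classes.
FEATURE_PRECEDENCE = {"3UTR": 0, "5UTR": 1, "ncRNA": 2, "intron": 3}


@dataclass(frozen=True)
class SiteAnnotation:
    site: SiteKey
    feature_class: str  # one of FEATURE_PRECEDENCE keys or "intergenic"
    gene_id: str | None
    in_alu: bool
    repeat_name: str | None

    def __post_init__(self) -> None:
        if (self.feature_class == "intergenic") != (self.gene_id is None):
            raise ValueError("intergenic sites and only those have no gene")


def annotate_sites(
    sites: Iterable[SiteKey],
    features: FeatureIntervals,
    strict_strand: bool = False,
) -> dict[SiteKey, SiteAnnotation]:
    """Point-in-interval classification of each site.

    Precedence on overlap: 3'UTR > 5'UTR > ncRNA > intron; within one class
    the gene whose feature start is nearest to the site wins, with gene id
    as the final deterministic tiebreak.
    """
    out: dict[SiteKey, SiteAnnotation] = {}
    for key in sites:
        hits = features.gene_features_at(key.chrom, key.pos)
        if strict_strand:
            hits = [h for h in hits if h[2] == key.strand]
        if hits:
            gene_id, feature_class, _strand, start1 = min(
                hits,
                key=lambda h: (FEATURE_PRECEDENCE[h[1]], abs(key.pos - h[3]), h[0]),
            )
        else:
            gene_id, feature_class = None, "intergenic"
        repeats = features.repeats_at(key.chrom, key.pos)
        if strict_strand:
            repeats = [r for r in repeats if r[2] == key.strand]
        alu_hits = sorted(name for name, family, _ in repeats if family == "Alu")
        out[key] = SiteAnnotation(
            site=key,
            feature_class=feature_class,
            gene_id=gene_id,
            in_alu=bool(alu_hits),
            repeat_name=alu_hits[0] if alu_hits else None,
        )
    return out


def composition_summary(
    annotations: Mapping[SiteKey, SiteAnnotation],
) -> dict[str, float]:
    """Fractions of sites per feature class, plus Alu and genic fractions."""
    if not annotations:
        raise ValueError("no annotations to summarise")
    n = len(annotations)
    summary: dict[str, float] = {}
    for cls in list(FEATURE_PRECEDENCE) + ["intergenic"]:
        summary[f"fraction_{cls}"] = (
            sum(1 for a in annotations.values() if a.feature_class == cls) / n
        )
    summary["fraction_alu"] = sum(1 for a in annotations.values() if a.in_alu) / n
    summary["fraction_genic"] = 1.0 - summary["fraction_intergenic"]
    return summary


@dataclass(frozen=True)
class AluTemplate:
    """An Alu element and its in-silico edited counterpart."""

    name: str
    unedited_sequence: str
    edited_positions: frozenset[int]  # 1-based within the element
    edited_sequence: str
    promoter: str

    @property
    def unedited_construct(self) -> str:
        return self.promoter + self.unedited_sequence

    @property
    def edited_construct(self) -> str:
        return self.promoter + self.edited_sequence


def design_edited_template(
    unedited: str,
    edited_positions: Iterable[int],
    promoter: str = SP6_PROMOTER,
    name: str = "alu_template",
) -> AluTemplate:
    """Substitute A->G at the declared 1-based positions of an Alu sequence.

    Every declared position must hold an A in the unedited sequence; out of
    range or non-A positions raise with the offending position named.
    """
    unedited = unedited.upper()
    positions = frozenset(int(p) for p in edited_positions)
    seq = list(unedited)
    for p in sorted(positions):
        if not 1 <= p <= len(seq):
            raise ValueError(f"edited position {p} outside sequence of length {len(seq)}")
        if seq[p - 1] != "A":
            raise ValueError(f"position {p} holds {seq[p - 1]}, expected A")
        seq[p - 1] = "G"
    return AluTemplate(
        name=name,
        unedited_sequence=unedited,
        edited_positions=positions,
        edited_sequence="".join(seq),
        promoter=promoter.upper(),
    )


def write_templates_fasta(templates: Sequence[AluTemplate], path) -> None:
    """FASTA export of promoter-prefixed unedited and edited constructs."""
    records = []
    for t in templates:
        records.append(
            SeqRecord(Seq(t.unedited_construct), id=f"{t.name}_unedited", description="")
        )
        records.append(
            SeqRecord(Seq(t.edited_construct), id=f"{t.name}_edited", description="")
        )
    SeqIO.write(records, str(path), "fasta")


def annotation_frame(
    annotations: Mapping[SiteKey, SiteAnnotation],
) -> pd.DataFrame:
    rows = [
        {
            "chrom": a.site.chrom,
            "pos": a.site.pos,
            "strand": a.site.strand,
            "edit_type": a.site.edit_type,
            "feature_class": a.feature_class,
            "gene": a.gene_id,
            "in_alu": a.in_alu,
            "repeat_name": a.repeat_name,
        }
        for a in sorted(annotations.values(), key=lambda a: a.site)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "strand", "edit_type",
            "feature_class", "gene", "in_alu", "repeat_name",
        ],
    )
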