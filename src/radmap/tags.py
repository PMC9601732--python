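"""RAD-tag selection: pair one female- and one male-informative SNP per tag.

A tag is a short (< ``intra_max`` bp, default 1 kb) locus carrying one
ABxAA SNP and one AAxAB SNP, so a single tag is informative for both
parental meioses at essentially one map position.  Adjacent tags are
required to be at least ``inter_min`` bp apart (default 100 kb) so that
crossovers between them are observed at a useful rate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .geno import SegType, SnpRecord

__all__ = ["RadTag", "select_tags", "write_tag_table", "natural_chrom_key"]


@dataclass(frozen=True)
class RadTag:
    """A selected RAD tag.

    ``anchor_pos`` — position of the female-informative SNP, used as the
    tag's single genomic coordinate (the intra-tag span is far below genetic
    resolution).  ``tag_id`` is "RT" plus a serial number that increases
    along the genome (chromosomes in natural order, then position).
    """

    tag_id: str
    chrom: str
    anchor_pos: int
    snp_f: str  # marker_id of the ABxAA SNP
    snp_m: str  # marker_id of the AAxAB SNP
    span: int


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key treating digit runs numerically, so Chr2 < Chr10."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def select_tags(
    snps: Sequence[SnpRecord], intra_max: int = 1000, inter_min: int = 100_000
) -> list[RadTag]:
    """Greedy left-to-right tag selection over filtered 1:1 SNPs.

    Per chromosome, each ABxAA SNP is a candidate anchor; it becomes a tag if
    an AAxAB SNP lies within ``intra_max`` bp and the anchor is at least
    ``inter_min`` bp beyond the previously accepted anchor (the first tag on
    a chromosome is always eligible).  Among qualifying partners the one with
    the smallest span is chosen, ties broken by lower missing fraction, then
    lower position.  Deterministic: identical input yields identical output.
    """
    by_chrom: dict[str, list[SnpRecord]] = {}
    for rec in snps:
        if rec.seg_type in (SegType.ABxAA, SegType.AAxAB):
            by_chrom.setdefault(rec.chrom, []).append(rec)

    tags: list[RadTag] = []
    for chrom in sorted(by_chrom, key=natural_chrom_key):
        recs = sorted(by_chrom[chrom], key=lambda r: (r.pos, r.marker_id))
        females = [r for r in recs if r.seg_type == SegType.ABxAA]
        males = [r for r in recs if r.seg_type == SegType.AAxAB]
        if not females or not males:
            continue
        last_anchor: int | None = None
        for f in females:
            if last_anchor is not None and f.pos - last_anchor < inter_min:
                continue
            partners = [m for m in males if abs(m.pos - f.pos) < intra_max]
            if not partners:
                continue
            m = min(partners, key=lambda m: (abs(m.pos - f.pos), m.missing_fraction, m.pos))
            tags.append(
                RadTag(
                    tag_id="",  # serial assigned below
                    chrom=chrom,
                    anchor_pos=f.pos,
                    snp_f=f.marker_id,
                    snp_m=m.marker_id,
                    span=abs(m.pos - f.pos),
                )
            )
            last_anchor = f.pos

    tags.sort(key=lambda t: (natural_chrom_key(t.chrom), t.anchor_pos))
    return [
        RadTag(
            tag_id=f"RT{i + 1}",
            chrom=t.chrom,
            anchor_pos=t.anchor_pos,
            snp_f=t.snp_f,
            snp_m=t.snp_m,
            span=t.span,
        )
        for i, t in enumerate(tags)
    ]


def write_tag_table(tags: Sequence[RadTag], path: str) -> None:
    """Write the tag table as TSV: tag_id, chrom, anchor_pos, snp_f, snp_m, span."""
    df = pd.DataFrame(
        [(t.tag_id, t.chrom, t.anchor_pos, t.snp_f, t.snp_m, t.span) for t in tags],
        columns=["tag_id", "chrom", "anchor_pos", "snp_f", "snp_m", "span"],
    )
    df.to_csv(path, sep="\t", index=False)
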