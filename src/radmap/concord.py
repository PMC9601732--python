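"""Concordance of a linkage-group order with reference-genome coordinates.

A discordant region (DR) is a local block of consecutive map markers whose
genomic coordinates break collinearity with the rest of the group.  The
definition used here is deterministic and orientation-agnostic: the
*backbone* is the longest strictly monotone (increasing or decreasing)
subsequence of genome positions along the map order, and the DRs are the
maximal runs of consecutive non-backbone markers.  Among equally long
backbones the one keeping the earliest map markers is chosen (first
excluded marker as late as possible).  Markers aligned to a different
chromosome than the group's majority chromosome are excluded from the
analysis and reported separately.

This is the one place where the method's published description is loose —
"discordant region" was never formally defined — so the longest-monotone-
backbone reading is a deliberate, documented interpretation (see
docs/methods.md).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .mapping import LinkageGroup

__all__ = ["DiscordanceReport", "count_discordant", "read_reference_order", "write_discordance_table"]


@dataclass
class DiscordanceReport:
    """Discordant regions of one linkage group against one reference genome."""

    chrom: str  # majority chromosome
    n_dr: int
    n_markers_in_dr: int
    dr_spans: list[tuple[int, int]]  # [start, end] inclusive, indices into aligned map order
    backbone: list[str]  # marker ids kept as the monotone backbone
    aligned: list[str]  # markers on the majority chromosome, in map order
    off_chromosome: list[str]  # markers aligned elsewhere, excluded from DR counting


def _lis_greedy(values: Sequence[float]) -> list[int]:
    """Indices of a longest strictly increasing subsequence.

    Among all maximum-length subsequences, returns the one that keeps the
    earliest positions (equivalently: the first excluded index is as late as
    possible, then the second, and so on).
    """
    n = len(values)
    if n == 0:
        return []
    # f[i]: length of the longest strictly increasing run starting at i
    f = [1] * n
    for i in range(n - 2, -1, -1):
        best = 0
        for j in range(i + 1, n):
            if values[j] > values[i] and f[j] > best:
                best = f[j]
        f[i] = 1 + best
    target = max(f)
    chosen: list[int] = []
    last = float("-inf")
    need = target
    for i in range(n):
        if need == 0:
            break
        if values[i] > last and f[i] >= need:
            chosen.append(i)
            last = values[i]
            need -= 1
    return chosen


def count_discordant(
    lg: LinkageGroup | Sequence[str], genome_pos: Mapping[str, tuple[str, int]]
) -> DiscordanceReport:
    """Count discordant regions of a linkage group against genome coordinates.

    ``genome_pos`` maps marker_id -> (chrom, bp).  The group's majority
    chromosome is determined first; markers mapping elsewhere (or missing
    from ``genome_pos``) are excluded and reported in ``off_chromosome``.
    Requires at least two markers on the majority chromosome.
    """
    order = list(lg.tag_ids) if isinstance(lg, LinkageGroup) else list(lg)
    located = [(m, *genome_pos[m]) for m in order if m in genome_pos]
    if not located:
        raise ValueError("no markers of this group have genome positions")
    majority = Counter(chrom for _, chrom, _ in located).most_common(1)[0][0]
    aligned = [(m, bp) for m, chrom, bp in located if chrom == majority]
    off = [m for m, chrom, _ in located if chrom != majority]
    off += [m for m in order if m not in genome_pos]
    if len(aligned) < 2:
        raise ValueError(f"fewer than two markers on majority chromosome {majority!r}")
    ids = [m for m, _ in aligned]
    bp = [p for _, p in aligned]

    inc = _lis_greedy(bp)
    dec = _lis_greedy([-p for p in bp])
    if len(inc) > len(dec):
        keep = inc
    elif len(dec) > len(inc):
        keep = dec
    else:
        # direction tie: prefer the backbone whose first exclusion is latest
        def first_excluded(sel: list[int]) -> int:
            s = set(sel)
            for i in range(len(bp)):
                if i not in s:
                    return i
            return len(bp)
        keep = inc if first_excluded(inc) >= first_excluded(dec) else dec

    keep_set = set(keep)
    spans: list[tuple[int, int]] = []
    start = None
    for i in range(len(bp)):
        if i not in keep_set:
            if start is None:
                start = i
        elif start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(bp) - 1))

    return DiscordanceReport(
        chrom=majority,
        n_dr=len(spans),
        n_markers_in_dr=sum(e - s + 1 for s, e in spans),
        dr_spans=spans,
        backbone=[ids[i] for i in keep],
        aligned=ids,
        off_chromosome=off,
    )


def read_reference_order(path: str) -> dict[str, tuple[str, int]]:
    """Read a reference marker-order TSV with columns marker_id, chrom, bp."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})
    required = {"marker_id", "chrom", "bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"reference order TSV needs columns {sorted(required)}")
    return {r.marker_id: (r.chrom, int(r.bp)) for r in df.itertuples(index=False)}


def write_discordance_table(
    reports: Mapping[str, Mapping[int, DiscordanceReport]], path: str
) -> pd.DataFrame:
    """Per-LG "n_dr (n_markers)" table, one column per map flavor, plus totals."""
    flavors = list(reports)
    n_lgs = max(len(v) for v in reports.values())
    rows = []
    for lg in range(1, n_lgs + 1):
        row: dict = {"LG": lg}
        for f in flavors:
            rep = reports[f].get(lg)
            row[f] = f"{rep.n_dr} ({rep.n_markers_in_dr})" if rep is not None else ""
        rows.append(row)
    total: dict = {"LG": "Total"}
    for f in flavors:
        total[f] = (
            f"{sum(r.n_dr for r in reports[f].values())} "
            f"({sum(r.n_markers_in_dr for r in reports[f].values())})"
        )
    rows.append(total)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
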