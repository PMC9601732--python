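"""Genotype domain types, segregation-type classification and marker filters.

The mapping strategy implemented by this package works on an outbred F1
cross between two heterozygous parents.  Only markers segregating 1:1 are
used downstream: ``ab x aa`` loci (female parent heterozygous, male
homozygous) are informative for the female meiosis, ``aa x ab`` loci for the
male meiosis.  Progeny at such a locus show two observable classes,
homozygous and heterozygous, which this module codes as small integers so
that downstream linkage arithmetic runs on numpy arrays.

Progeny call coding (used everywhere in the package):

====  =======================================
code  meaning
====  =======================================
0     HOM  — homozygous, the non-informative parent's allele only
1     HET  — heterozygous, carries the informative parent's b allele
-1    MISSING
====  =======================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Genotype",
    "SegType",
    "FilterReason",
    "SnpRecord",
    "FilterReport",
    "HOM",
    "HET",
    "MISSING",
    "classify_segregation",
    "mendelian_filter",
    "filter_markers",
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
]

# progeny call codes
HOM: int = 0
HET: int = 1
MISSING: int = -1


class Genotype(enum.IntEnum):
    """Parental genotype at a biallelic SNP."""

    HOM_REF = 0
    HET = 1
    HOM_ALT = 2
    MISSING = -1


class SegType(str, enum.Enum):
    """Segregation type of a marker in the F1 cross (female x male)."""

    ABxAA = "ABxAA"  # female heterozygous, male homozygous -> female-informative
    AAxAB = "AAxAB"  # male heterozygous, female homozygous -> male-informative
    ABxAB = "ABxAB"  # both heterozygous (not used for mapping here)
    UNINFORMATIVE = "UNINFORMATIVE"


class FilterReason(str, enum.Enum):
    SEGREGATION_DISTORTION = "SEGREGATION_DISTORTION"
    EXCESS_MISSING = "EXCESS_MISSING"
    KEPT = "KEPT"


def classify_segregation(female_gt: Genotype, male_gt: Genotype) -> SegType:
    """Classify a marker's segregation type from the two parental genotypes.

    Total function: any combination involving a missing or double-homozygous
    parent pair that cannot segregate 1:1 or 1:2:1 maps to ``UNINFORMATIVE``.
    """
    female_het = female_gt == Genotype.HET
    male_het = male_gt == Genotype.HET
    if female_gt == Genotype.MISSING or male_gt == Genotype.MISSING:
        return SegType.UNINFORMATIVE
    if female_het and male_het:
        return SegType.ABxAB
    if female_het:
        return SegType.ABxAA
    if male_het:
        return SegType.AAxAB
    return SegType.UNINFORMATIVE


@dataclass
class SnpRecord:
    """One biallelic SNP: coordinates, parental genotypes and progeny calls.

    ``progeny`` is an int8 vector over {0 (HOM), 1 (HET), -1 (MISSING)}; its
    length is the number of progeny in the population.  ``seg_type`` is
    derived from the parental genotypes on construction.
    """

    marker_id: str
    chrom: str
    pos: int
    female_gt: Genotype
    male_gt: Genotype
    progeny: np.ndarray
    seg_type: SegType = field(init=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.marker_id}: pos must be >= 1 (got {self.pos})")
        self.progeny = np.asarray(self.progeny, dtype=np.int8)
        if self.progeny.ndim != 1:
            raise ValueError(f"{self.marker_id}: progeny must be a vector")
        bad = ~np.isin(self.progeny, (HOM, HET, MISSING))
        if bad.any():
            raise ValueError(f"{self.marker_id}: invalid progeny codes {np.unique(self.progeny[bad])}")
        self.seg_type = classify_segregation(self.female_gt, self.male_gt)

    @property
    def n_progeny(self) -> int:
        return self.progeny.size

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.progeny == MISSING))


@dataclass
class FilterReport:
    """Outcome of the Mendelian-segregation / missingness filter for one marker."""

    marker_id: str
    chi2: float
    p_value: float
    missing_fraction: float
    kept: bool
    reason: FilterReason


def mendelian_filter(
    record: SnpRecord, alpha: float = 0.01, missing_max: float = 0.20
) -> FilterReport:
    """Test a 1:1 marker for segregation distortion and excess missingness.

    The chi-square statistic is ``(n_HOM - n_HET)^2 / (n_HOM + n_HET)`` on the
    non-missing calls (1 df, no continuity correction).  A marker is kept iff
    its p-value is >= ``alpha`` and its missing fraction (over all progeny) is
    strictly below ``missing_max``; the 20% missingness bound is inclusive,
    i.e. a marker missing exactly 20% of calls is removed.
    """
    if record.seg_type not in (SegType.ABxAA, SegType.AAxAB):
        raise ValueError(
            f"{record.marker_id}: mendelian_filter applies to 1:1 markers, got {record.seg_type.value}"
        )
    n_hom = int(np.sum(record.progeny == HOM))
    n_het = int(np.sum(record.progeny == HET))
    n_obs = n_hom + n_het
    if n_obs == 0:
        raise ValueError(f"{record.marker_id}: no non-missing progeny calls")
    chi2 = (n_hom - n_het) ** 2 / n_obs
    p_value = float(stats.chi2.sf(chi2, df=1))
    missing_fraction = record.missing_fraction
    excess_missing = missing_fraction >= missing_max
    distorted = p_value < alpha
    kept = not (excess_missing or distorted)
    if kept:
        reason = FilterReason.KEPT
    elif excess_missing:
        reason = FilterReason.EXCESS_MISSING
    else:
        reason = FilterReason.SEGREGATION_DISTORTION
    return FilterReport(
        marker_id=record.marker_id,
        chi2=float(chi2),
        p_value=p_value,
        missing_fraction=missing_fraction,
        kept=kept,
        reason=reason,
    )


def filter_markers(
    records: Iterable[SnpRecord], alpha: float = 0.01, missing_max: float = 0.20
) -> tuple[list[SnpRecord], list[FilterReport]]:
    """Apply :func:`mendelian_filter` to every 1:1 marker.

    Markers that are not 1:1 (``ABxAB``/``UNINFORMATIVE``) are dropped without
    a report — the strategy only maps 1:1 markers.  Returns (kept records,
    reports for every 1:1 marker).
    """
    kept: list[SnpRecord] = []
    reports: list[FilterReport] = []
    for rec in records:
        if rec.seg_type not in (SegType.ABxAA, SegType.AAxAB):
            continue
        rep = mendelian_filter(rec, alpha=alpha, missing_max=missing_max)
        reports.append(rep)
        if rep.kept:
            kept.append(rec)
    return kept, reports


# ---------------------------------------------------------------------------
# input / output
# ---------------------------------------------------------------------------

def _gt_code_from_types(gt_type: int) -> Genotype:
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    return {0: Genotype.HOM_REF, 1: Genotype.HET, 3: Genotype.HOM_ALT}.get(
        gt_type, Genotype.MISSING
    )


def read_vcf(path: str, female: str, male: str) -> list[SnpRecord]:
    """Read biallelic SNPs from a VCF 4.x file.

    ``female`` and ``male`` name the two parental samples; every other sample
    is treated as a progeny individual.  Phased genotype separators are
    accepted but phase is ignored — linkage phase is inferred downstream,
    never trusted from the input.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    for name in (female, male):
        if name not in samples:
            raise ValueError(f"parent sample {name!r} not found in VCF (samples: {samples[:5]}...)")
    i_f = samples.index(female)
    i_m = samples.index(male)
    prog_idx = [i for i in range(len(samples)) if i not in (i_f, i_m)]
    records: list[SnpRecord] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue  # biallelic SNPs only
        gt_types = var.gt_types
        female_gt = _gt_code_from_types(int(gt_types[i_f]))
        male_gt = _gt_code_from_types(int(gt_types[i_m]))
        prog = np.empty(len(prog_idx), dtype=np.int8)
        for j, i in enumerate(prog_idx):
            t = int(gt_types[i])
            if t == 1:
                prog[j] = HET
            elif t in (0, 3):
                prog[j] = HOM
            else:
                prog[j] = MISSING
        marker_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        records.append(
            SnpRecord(
                marker_id=marker_id,
                chrom=var.CHROM,
                pos=int(var.POS),
                female_gt=female_gt,
                male_gt=male_gt,
                progeny=prog,
            )
        )
    return records


_TSV_PARENT = {"a": Genotype.HOM_REF, "h": Genotype.HET, "b": Genotype.HOM_ALT, "-": Genotype.MISSING}
_TSV_CALL = {"a": HOM, "h": HET, "-": MISSING}
_CALL_TSV = {HOM: "a", HET: "h", MISSING: "-"}


def read_genotype_tsv(path: str) -> list[SnpRecord]:
    """Read the simple TSV genotype dialect.

    Columns: marker_id, chrom, pos, female, male, then one column per progeny
    individual.  Calls are coded a (homozygous), h (heterozygous), - (missing).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker_id", "chrom", "pos", "female", "male"]
    if list(df.columns[:5]) != required:
        raise ValueError(f"genotype TSV must start with columns {required}, got {list(df.columns[:5])}")
    records = []
    for row in df.itertuples(index=False):
        vals = tuple(row)  # positional: itertuples mangles arbitrary column names
        calls = np.array([_TSV_CALL[v] for v in vals[5:]], dtype=np.int8)
        records.append(
            SnpRecord(
                marker_id=vals[0],
                chrom=vals[1],
                pos=int(vals[2]),
                female_gt=_TSV_PARENT[vals[3]],
                male_gt=_TSV_PARENT[vals[4]],
                progeny=calls,
            )
        )
    return records


_PARENT_TSV = {Genotype.HOM_REF: "a", Genotype.HET: "h", Genotype.HOM_ALT: "b", Genotype.MISSING: "-"}


def write_genotype_tsv(records: Sequence[SnpRecord], path: str, progeny_names: Sequence[str] | None = None) -> None:
    """Write SNP records in the TSV genotype dialect (round-trips with the reader)."""
    if not records:
        raise ValueError("no records to write")
    n = records[0].n_progeny
    if progeny_names is None:
        progeny_names = [f"P{i + 1}" for i in range(n)]
    rows = []
    for rec in records:
        rows.append(
            [rec.marker_id, rec.chrom, rec.pos, _PARENT_TSV[rec.female_gt], _PARENT_TSV[rec.male_gt]]
            + [_CALL_TSV[int(c)] for c in rec.progeny]
        )
    df = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos", "female", "male"] + list(progeny_names))
    df.to_csv(path, sep="\t", index=False)
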