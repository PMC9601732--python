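"""Synthetic outbred-F1 population generator with full ground truth.

Emulates the statistical structure the integrated-mapping strategy assumes:
two heterozygous parents, RAD tags each carrying one female-informative
(ABxAA) and one male-informative (AAxAB) SNP under 1 kb apart, adjacent
tags at least 100 kb apart, sex-specific recombination (female rates drawn
above male rates by default), random parental linkage phases, symmetric
genotyping error and missing calls.  Gametes are 2-state Markov chains over
intervals (no crossover interference); the Kosambi function is a reporting
transform downstream, exactly as in the mapping workflow.

All randomness flows from a single seed through a counter-based
(Philox) generator, so identical configurations give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .geno import Genotype, SnpRecord
from .tags import RadTag

__all__ = ["SimConfig", "SimTruth", "SimOutput", "simulate_f1", "write_vcf", "write_truth_tables"]

# Default per-interval recombination-fraction sampling ranges.  At ~60 tags
# per chromosome these produce per-LG and total map lengths of the same
# order as a dense outbred tree-mapping design, with the female meiosis
# recombining more than the male on essentially every chromosome.
_DEFAULT_R_FEMALE = (0.03, 0.08)
_DEFAULT_R_MALE = (0.02, 0.06)


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's reference study design."""

    n_progeny: int = 257
    n_chromosomes: int = 19
    tags_per_chromosome: int = 60
    interval_r_female: float | tuple[float, float] | Sequence[float] = _DEFAULT_R_FEMALE
    interval_r_male: float | tuple[float, float] | Sequence[float] = _DEFAULT_R_MALE
    repulsion_fraction: float = 0.5  # P(informative allele switches homolog vs previous marker)
    missing_rate: float = 0.10
    error_rate: float = 0.005  # symmetric HOM<->HET miscall probability per call
    inter_tag_bp: int = 100_000  # minimum anchor spacing
    seed: int = 0

    def validate(self) -> None:
        for name in ("repulsion_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.n_progeny < 1 or self.n_chromosomes < 1 or self.tags_per_chromosome < 1:
            raise ValueError("population dimensions must be positive")
        for name in ("interval_r_female", "interval_r_male"):
            v = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any(v < 0) or np.any(v >= 0.5):
                raise ValueError(f"{name} values must lie in [0, 0.5)")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_file(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("interval_r_female", "interval_r_male"):
            if isinstance(raw.get(key), list):
                raw[key] = tuple(raw[key]) if len(raw[key]) == 2 else raw[key]
        return cls(**raw)


@dataclass
class SimTruth:
    """Ground truth sufficient to recompute every expected statistic."""

    seed: int
    chrom_names: list[str]
    tag_order: dict[str, list[str]]  # true tag order per chromosome
    interval_r_female: dict[str, np.ndarray]
    interval_r_male: dict[str, np.ndarray]
    phase_female: dict[str, np.ndarray]  # homolog carrying the b allele, per tag
    phase_male: dict[str, np.ndarray]
    crossovers_female: dict[str, int] = field(default_factory=dict)  # realized counts
    crossovers_male: dict[str, int] = field(default_factory=dict)

    def total_length_cM(self, map_function) -> dict[str, float]:
        """True map length per flavor under a given map function (e.g. Kosambi)."""
        female = sum(float(np.sum(map_function(r))) for r in self.interval_r_female.values())
        male = sum(float(np.sum(map_function(r))) for r in self.interval_r_male.values())
        integrated = sum(
            float(np.sum(map_function((rf + rm) / 2.0)))
            for rf, rm in zip(self.interval_r_female.values(), self.interval_r_male.values())
        )
        return {"FEMALE": female, "MALE": male, "INTEGRATED": integrated}


@dataclass
class SimOutput:
    records: list[SnpRecord]
    tags: list[RadTag]
    truth: SimTruth
    progeny_names: list[str]


def _sample_interval_r(spec, n_intervals: int, rng: np.random.Generator) -> np.ndarray:
    """Resolve an interval-r spec: scalar = constant, 2-tuple = uniform range,
    length-(M-1) sequence = explicit per-interval values."""
    if np.isscalar(spec):
        return np.full(n_intervals, float(spec))
    if isinstance(spec, tuple) and len(spec) == 2:
        return rng.uniform(spec[0], spec[1], size=n_intervals)
    arr = np.asarray(spec, dtype=float)
    if arr.size == n_intervals:
        return arr.copy()
    if arr.size == 2:  # list form of a range, e.g. loaded from YAML
        return rng.uniform(arr[0], arr[1], size=n_intervals)
    raise ValueError(f"interval r spec of length {arr.size} does not match {n_intervals} intervals")


def _gametes(n: int, r: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, M) matrix of transmitted homolog states, Markov over intervals."""
    m = r.size + 1
    states = np.zeros((n, m), dtype=np.int64)
    states[:, 0] = rng.integers(0, 2, size=n)
    if r.size:
        states[:, 1:] = rng.random((n, r.size)) < r[None, :]
        states = np.cumsum(states, axis=1) % 2
    return states.astype(np.int8)


def simulate_f1(config: SimConfig) -> SimOutput:
    """Simulate SNP records, true RAD tags and full ground truth.

    Each chromosome carries ``tags_per_chromosome`` tags; a tag's
    female-informative SNP sits at the anchor position and its
    male-informative SNP 50–999 bp away.  Female and male gametes are drawn
    independently per progeny; genotyping error (HOM <-> HET swap) is applied
    before missingness, independently per call.
    """
    config.validate()
    rng = np.random.Generator(np.random.Philox(key=config.seed))
    n = config.n_progeny
    m = config.tags_per_chromosome
    records: list[SnpRecord] = []
    tags: list[RadTag] = []
    truth = SimTruth(
        seed=config.seed,
        chrom_names=[],
        tag_order={},
        interval_r_female={},
        interval_r_male={},
        phase_female={},
        phase_male={},
    )
    serial = 0
    for c in range(config.n_chromosomes):
        chrom = f"Chr{c + 1:02d}"
        truth.chrom_names.append(chrom)
        anchors = 200_000 + np.cumsum(
            config.inter_tag_bp + rng.integers(0, 50_000, size=m)
        )
        offsets = rng.integers(50, 1000, size=m)
        r_f = _sample_interval_r(config.interval_r_female, m - 1, rng)
        r_m = _sample_interval_r(config.interval_r_male, m - 1, rng)
        # parental phases: homolog (0/1) carrying the b allele at each tag
        flips_f = rng.random(m) < config.repulsion_fraction
        flips_m = rng.random(m) < config.repulsion_fraction
        phase_f = np.cumsum(flips_f) % 2
        phase_m = np.cumsum(flips_m) % 2
        gam_f = _gametes(n, r_f, rng)
        gam_m = _gametes(n, r_m, rng)
        truth.crossovers_female[chrom] = int(np.sum(gam_f[:, 1:] != gam_f[:, :-1]))
        truth.crossovers_male[chrom] = int(np.sum(gam_m[:, 1:] != gam_m[:, :-1]))
        # progeny carries b at a female SNP iff the transmitted female homolog holds b
        calls_f = (gam_f == phase_f[None, :]).astype(np.int8)
        calls_m = (gam_m == phase_m[None, :]).astype(np.int8)
        chrom_tags: list[str] = []
        for t in range(m):
            serial += 1
            tag_id = f"RT{serial}"
            chrom_tags.append(tag_id)
            snp_f_id = f"{tag_id}_F"
            snp_m_id = f"{tag_id}_M"
            for snp_id, pos, female_gt, male_gt, calls in (
                (snp_f_id, int(anchors[t]), Genotype.HET, Genotype.HOM_REF, calls_f[:, t]),
                (snp_m_id, int(anchors[t] + offsets[t]), Genotype.HOM_REF, Genotype.HET, calls_m[:, t]),
            ):
                obs = calls.copy()
                if config.error_rate > 0:
                    err = rng.random(n) < config.error_rate
                    obs[err] = 1 - obs[err]
                if config.missing_rate > 0:
                    miss = rng.random(n) < config.missing_rate
                    obs[miss] = -1
                records.append(
                    SnpRecord(
                        marker_id=snp_id,
                        chrom=chrom,
                        pos=pos,
                        female_gt=female_gt,
                        male_gt=male_gt,
                        progeny=obs,
                    )
                )
            tags.append(
                RadTag(
                    tag_id=tag_id,
                    chrom=chrom,
                    anchor_pos=int(anchors[t]),
                    snp_f=snp_f_id,
                    snp_m=snp_m_id,
                    span=int(offsets[t]),
                )
            )
        truth.tag_order[chrom] = chrom_tags
        truth.interval_r_female[chrom] = r_f
        truth.interval_r_male[chrom] = r_m
        truth.phase_female[chrom] = phase_f
        truth.phase_male[chrom] = phase_m
    progeny_names = [f"P{i + 1:03d}" for i in range(n)]
    return SimOutput(records=records, tags=tags, truth=truth, progeny_names=progeny_names)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_VCF = {Genotype.HOM_REF: "0/0", Genotype.HET: "0/1", Genotype.HOM_ALT: "1/1", Genotype.MISSING: "./."}
_CALL_VCF = {0: "0/0", 1: "0/1", -1: "./."}


def write_vcf(
    records: Sequence[SnpRecord],
    path: str,
    progeny_names: Sequence[str],
    female: str = "female",
    male: str = "male",
) -> None:
    """Write SNP records as a minimal VCF 4.2 text file (parents first)."""
    chroms: dict[str, int] = {}
    for rec in records:
        chroms[rec.chrom] = max(chroms.get(rec.chrom, 0), rec.pos + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radmap-simgen\n")
        for chrom, length in chroms.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join([female, male, *progeny_names])
            + "\n"
        )
        for rec in sorted(records, key=lambda r: (r.chrom, r.pos)):
            # HOM progeny calls carry the shared parental allele -> REF-homozygous
            gts = [_GT_VCF[rec.female_gt], _GT_VCF[rec.male_gt]]
            gts += [_CALL_VCF[int(c)] for c in rec.progeny]
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.marker_id}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def write_truth_tables(truth: SimTruth, tag_path: str, interval_path: str) -> None:
    """Write ground truth as TSV: tag order, and per-interval female/male r."""
    rows = []
    for chrom in truth.chrom_names:
        for i, tid in enumerate(truth.tag_order[chrom]):
            rows.append((chrom, i + 1, tid,
                         int(truth.phase_female[chrom][i]), int(truth.phase_male[chrom][i])))
    pd.DataFrame(rows, columns=["chrom", "rank", "tag_id", "phase_female", "phase_male"]).to_csv(
        tag_path, sep="\t", index=False
    )
    rows = []
    for chrom in truth.chrom_names:
        rf = truth.interval_r_female[chrom]
        rm = truth.interval_r_male[chrom]
        for i in range(rf.size):
            rows.append((chrom, i + 1, rf[i], rm[i]))
    pd.DataFrame(rows, columns=["chrom", "interval", "r_female", "r_male"]).to_csv(
        interval_path, sep="\t", index=False, float_format="%.6f"
    )
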