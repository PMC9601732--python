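"""Segregation classification, Mendelian filters and genotype I/O."""

import math

import numpy as np
import pytest

from radmap.geno import (
    HET,
    HOM,
    MISSING,
    FilterReason,
    Genotype,
    SegType,
    classify_segregation,
    filter_markers,
    mendelian_filter,
    read_genotype_tsv,
    read_vcf,
    write_genotype_tsv,
)
from radmap.simgen import SimConfig, simulate_f1, write_vcf

from conftest import make_record


@pytest.mark.parametrize(
    "female, male, expected",
    [
        (Genotype.HET, Genotype.HOM_REF, SegType.ABxAA),
        (Genotype.HET, Genotype.HOM_ALT, SegType.ABxAA),
        (Genotype.HOM_REF, Genotype.HET, SegType.AAxAB),
        (Genotype.HOM_ALT, Genotype.HET, SegType.AAxAB),
        (Genotype.HET, Genotype.HET, SegType.ABxAB),
        (Genotype.HOM_REF, Genotype.HOM_REF, SegType.UNINFORMATIVE),
        (Genotype.HOM_REF, Genotype.HOM_ALT, SegType.UNINFORMATIVE),
        (Genotype.MISSING, Genotype.HET, SegType.UNINFORMATIVE),
        (Genotype.HET, Genotype.MISSING, SegType.UNINFORMATIVE),
    ],
)
def test_segregation_classification(female, male, expected):
    assert classify_segregation(female, male) is expected


def test_perfect_1_1_marker_is_kept():
    rec = make_record("m1", [HOM] * 100 + [HET] * 100)
    rep = mendelian_filter(rec)
    assert rep.chi2 == 0.0
    assert rep.p_value == 1.0
    assert rep.kept and rep.reason is FilterReason.KEPT


def test_distorted_marker_is_removed():
    # 80 vs 120: chi2 = 40^2/200 = 8; p from the closed-form df-1 chi-square
    # survival function p = erfc(sqrt(x/2)), an independent route to the value
    rec = make_record("m1", [HOM] * 80 + [HET] * 120)
    rep = mendelian_filter(rec)
    assert rep.chi2 == pytest.approx(8.0)
    assert rep.p_value == pytest.approx(math.erfc(math.sqrt(8.0 / 2.0)), rel=1e-12)
    assert rep.p_value == pytest.approx(0.004678, abs=1e-6)
    assert not rep.kept and rep.reason is FilterReason.SEGREGATION_DISTORTION


def test_excess_missing_marker_is_removed():
    # 52 missing of 257 progeny = 20.2% >= the inclusive 20% ceiling
    calls = [HOM] * 103 + [HET] * 102 + [MISSING] * 52
    rep = mendelian_filter(make_record("m1", calls))
    assert rep.missing_fraction == pytest.approx(52 / 257)
    assert not rep.kept and rep.reason is FilterReason.EXCESS_MISSING
    # exactly at the ceiling is also removed
    calls = [HOM] * 40 + [HET] * 40 + [MISSING] * 20
    assert not mendelian_filter(make_record("m2", calls)).kept


def test_filter_symmetric_under_class_relabeling():
    for n_hom, n_het in [(80, 120), (130, 127), (10, 30)]:
        a = mendelian_filter(make_record("a", [HOM] * n_hom + [HET] * n_het))
        b = mendelian_filter(make_record("b", [HOM] * n_het + [HET] * n_hom))
        assert a.chi2 == b.chi2 and a.p_value == b.p_value and a.kept == b.kept


def test_empty_marker_raises():
    with pytest.raises(ValueError, match="no non-missing"):
        mendelian_filter(make_record("m1", [MISSING] * 10))


def test_filter_applies_only_to_1_1_markers():
    rec = make_record("m1", [HOM] * 50 + [HET] * 50)
    rec.female_gt = Genotype.HET
    rec.male_gt = Genotype.HET
    rec.seg_type = classify_segregation(rec.female_gt, rec.male_gt)
    with pytest.raises(ValueError, match="1:1"):
        mendelian_filter(rec)


def test_distortion_removal_rate_converges_to_alpha():
    """Without true distortion the chi-square filter should reject ~alpha."""
    # single-tag chromosomes so the 2000 markers segregate independently
    sim = simulate_f1(
        SimConfig(n_chromosomes=1000, tags_per_chromosome=1, n_progeny=257,
                  missing_rate=0.0, error_rate=0.0, seed=123)
    )
    _, reports = filter_markers(sim.records, alpha=0.01)
    n = len(reports)
    assert n == 2000
    rate = sum(r.reason is FilterReason.SEGREGATION_DISTORTION for r in reports) / n
    se = math.sqrt(0.01 * 0.99 / n)
    assert abs(rate - 0.01) < 3 * se


def test_tsv_round_trip(tmp_path, noisy_sim):
    path = tmp_path / "geno.tsv"
    write_genotype_tsv(noisy_sim.records, str(path), noisy_sim.progeny_names)
    back = read_genotype_tsv(str(path))
    assert len(back) == len(noisy_sim.records)
    for a, b in zip(noisy_sim.records, back):
        assert a.marker_id == b.marker_id and a.chrom == b.chrom and a.pos == b.pos
        assert a.seg_type is b.seg_type
        np.testing.assert_array_equal(a.progeny, b.progeny)


def test_vcf_round_trip(tmp_path, noisy_sim):
    path = tmp_path / "geno.vcf"
    write_vcf(noisy_sim.records, str(path), noisy_sim.progeny_names)
    back = read_vcf(str(path), female="female", male="male")
    by_id = {r.marker_id: r for r in back}
    assert len(back) == len(noisy_sim.records)
    for rec in noisy_sim.records:
        other = by_id[rec.marker_id]
        assert other.seg_type is rec.seg_type
        assert other.pos == rec.pos
        np.testing.assert_array_equal(rec.progeny, other.progeny)
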