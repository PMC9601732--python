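"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from radmap.geno import Genotype, SnpRecord
from radmap.simgen import SimConfig, simulate_f1


def make_record(marker_id, calls, chrom="Chr01", pos=1000, female_het=True):
    """1:1 SNP record from a call vector (0/1/-1)."""
    return SnpRecord(
        marker_id=marker_id,
        chrom=chrom,
        pos=pos,
        female_gt=Genotype.HET if female_het else Genotype.HOM_REF,
        male_gt=Genotype.HOM_REF if female_het else Genotype.HET,
        progeny=np.asarray(calls, dtype=np.int8),
    )


@pytest.fixture(scope="session")
def small_sim():
    """Three chromosomes, 20 tags each, clean genotypes (no error, no missing)."""
    return simulate_f1(
        SimConfig(
            n_chromosomes=3,
            tags_per_chromosome=20,
            n_progeny=257,
            interval_r_female=0.05,
            interval_r_male=0.05,
            missing_rate=0.0,
            error_rate=0.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def noisy_sim():
    """Two chromosomes at the default noise levels (10% missing, 0.5% error)."""
    return simulate_f1(SimConfig(n_chromosomes=2, tags_per_chromosome=15, seed=7))
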