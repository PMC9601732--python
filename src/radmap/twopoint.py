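"""Two-point linkage analysis for 1:1 (pseudo-testcross) markers.

For two markers scored in the same parental meiosis, each progeny call pair
is either parental or recombinant; the recombination fraction MLE is the
recombinant fraction, folded at 1/2 by re-labelling (linkage phase).  The
LOD score compares the binomial likelihood at the MLE against free
recombination (r = 1/2).

Female (r_f) and male (r_m) recombination fractions are this same
computation applied to female-informative and male-informative marker
pairs; the combined fraction r for a RAD-tag interval pools the recombinant
and informative gamete counts of the two meioses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .geno import MISSING

__all__ = [
    "Phase",
    "TwoPointResult",
    "two_point",
    "two_point_counts",
    "combined_r",
    "pairwise_counts",
    "pairwise_r_lod",
]


class Phase(str, enum.Enum):
    COUPLING = "COUPLING"
    REPULSION = "REPULSION"


@dataclass(frozen=True)
class TwoPointResult:
    r_hat: float  # in [0, 0.5]
    lod: float  # >= 0
    phase: Phase
    n_informative: int


def two_point_counts(calls_a: np.ndarray, calls_b: np.ndarray) -> tuple[int, int]:
    """Raw two-point counts: (R, n) with R = differing call pairs, n = complete pairs."""
    a = np.asarray(calls_a)
    b = np.asarray(calls_b)
    if a.shape != b.shape:
        raise ValueError(f"call vectors differ in length: {a.shape} vs {b.shape}")
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    r_count = int(np.sum(a[ok] != b[ok]))
    return r_count, n


def _lod_from_counts(r_prime: int, n: int) -> float:
    """log10 likelihood ratio of linkage at r̂ = r_prime/n versus r = 1/2."""
    if r_prime == 0:
        return n * np.log10(2.0)
    r_hat = r_prime / n
    return float((n - r_prime) * np.log10(2.0 * (1.0 - r_hat)) + r_prime * np.log10(2.0 * r_hat))


def two_point(calls_a: np.ndarray, calls_b: np.ndarray) -> TwoPointResult:
    """Two-point recombination fraction, LOD and linkage phase.

    Progeny with a missing call at either marker are excluded
    (pairwise-complete deletion).  With R differing pairs out of n,
    r̂ = min(R, n-R)/n and the phase is COUPLING iff R <= n-R (ties count as
    coupling: the labelling is then arbitrary).
    """
    r_count, n = two_point_counts(calls_a, calls_b)
    if n == 0:
        raise ValueError("no informative pairs (every progeny missing at one of the two markers)")
    r_prime = min(r_count, n - r_count)
    phase = Phase.COUPLING if r_count <= n - r_count else Phase.REPULSION
    return TwoPointResult(
        r_hat=r_prime / n,
        lod=_lod_from_counts(r_prime, n),
        phase=phase,
        n_informative=n,
    )


def combined_r(r_f_counts: tuple[int, int], r_m_counts: tuple[int, int]) -> float:
    """Pooled-gamete combined recombination fraction for a tag interval.

    ``r_f_counts`` and ``r_m_counts`` are (recombinants, informative gametes)
    from the female and male components of the same interval, with phases
    already harmonized to coupling.  r = (R_f + R_m) / (n_f + n_m); on
    complete data this equals the two-point r̂ of the merged pseudo-backcross
    matrix.
    """
    r_f, n_f = r_f_counts
    r_m, n_m = r_m_counts
    if n_f + n_m == 0:
        raise ValueError("no informative gametes in either meiosis")
    return (r_f + r_m) / (n_f + n_m)


def pairwise_counts(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised all-pairs two-point counts for an M x N call matrix.

    ``data`` holds one marker per row over {0, 1, -1}.  Returns integer
    matrices (R, n): R[i, j] = differing complete call pairs of markers i and
    j, n[i, j] = complete pairs.  Matches :func:`two_point_counts` pairwise.
    """
    d = np.asarray(data)
    valid = (d != MISSING)
    a = np.where(valid, d, 0).astype(np.float64)
    v = valid.astype(np.float64)
    n = v @ v.T
    ones = a @ a.T  # both-call-1 pairs
    zeros = (v - a) @ (v - a).T  # both-call-0 pairs
    r_count = n - ones - zeros
    return np.rint(r_count).astype(np.int64), np.rint(n).astype(np.int64)


def pairwise_r_lod(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs (r̂, LOD, n) matrices for an M x N call matrix.

    Pairs with n = 0 get r̂ = 0.5 and LOD = 0 (no evidence of linkage).
    The diagonal is not meaningful and is set the same way.
    """
    r_count, n = pairwise_counts(data)
    r_prime = np.minimum(r_count, n - r_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(n > 0, r_prime / np.maximum(n, 1), 0.5)
        lod = np.where(
            r_prime > 0,
            (n - r_prime) * np.log10(2.0 * (1.0 - r_hat)) + r_prime * np.log10(np.maximum(2.0 * r_hat, 1e-300)),
            n * np.log10(2.0),
        )
    lod = np.where(n > 0, lod, 0.0)
    r_hat = np.where(n > 0, r_hat, 0.5)
    np.fill_diagonal(lod, 0.0)
    np.fill_diagonal(r_hat, 0.5)
    return r_hat, lod, n
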