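"""Linkage-phase harmonization and female/male dataset merging.

The central trick of the integrated-map strategy: 1:1 progeny data from one
parental meiosis look exactly like a backcross once every marker's alleles
are labelled consistently with the parental haplotypes.  Along an ordered
linkage group, whenever two adjacent markers sit in repulsion the second
marker's progeny calls are relabelled (HOM <-> HET, i.e. 0 <-> 1), which
leaves every pairwise recombination fraction and LOD unchanged but puts the
whole group in coupling.  The harmonized female and male matrices can then
be stacked into one pseudo-backcross dataset of 2N meioses for integrated
mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .geno import HET, HOM, MISSING, SegType, SnpRecord
from .twopoint import Phase, two_point

__all__ = ["FEMALE", "MALE", "BCMatrix", "bc_matrix_from_records", "harmonize_phases",
           "merge_datasets", "write_bc_matrix", "read_bc_matrix"]

FEMALE: int = 0
MALE: int = 1
_MEIOSIS_LABEL = {FEMALE: "F", MALE: "M"}
_LABEL_MEIOSIS = {"F": FEMALE, "M": MALE}


@dataclass
class BCMatrix:
    """Backcross-coded marker-by-meiosis matrix.

    ``data`` is (n_rows, M) int8 over {0, 1, -1}: 0 = the non-informative
    parent's allele (a), 1 = the informative parent's b allele, -1 missing.
    Each row is one meiosis (one gamete of one parent); ``row_meiosis`` flags
    each row FEMALE (0) or MALE (1).  In a merged matrix rows come in two
    blocks — N female rows then N male rows, same individuals in order —
    and ``phase_flags`` has one row per component (female, male).
    ``phase_flags`` is boolean per marker: True = the column was FLIPPED
    relative to the original input coding.
    """

    marker_ids: list[str]
    data: np.ndarray
    row_meiosis: np.ndarray
    phase_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    individuals: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int8)
        self.row_meiosis = np.asarray(self.row_meiosis, dtype=np.int8)
        m = len(self.marker_ids)
        if self.data.ndim != 2 or self.data.shape[1] != m:
            raise ValueError(f"data shape {self.data.shape} does not match {m} markers")
        if self.row_meiosis.shape != (self.data.shape[0],):
            raise ValueError("row_meiosis length does not match number of rows")
        if self.phase_flags is None:
            self.phase_flags = np.zeros(m, dtype=bool)
        else:
            self.phase_flags = np.asarray(self.phase_flags, dtype=bool)

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_markers(self) -> int:
        return self.data.shape[1]

    @property
    def is_merged(self) -> bool:
        return self.phase_flags.ndim == 2

    def column(self, marker_id: str) -> np.ndarray:
        return self.data[:, self.marker_ids.index(marker_id)]

    def reordered(self, order: Sequence[str]) -> "BCMatrix":
        """Return a copy with columns permuted to ``order`` (same marker set)."""
        if sorted(order) != sorted(self.marker_ids):
            raise ValueError("order must be a permutation of the matrix's markers")
        idx = [self.marker_ids.index(m) for m in order]
        flags = self.phase_flags[..., idx]
        return replace(self, marker_ids=list(order), data=self.data[:, idx],
                       phase_flags=flags)


def bc_matrix_from_records(
    records: Sequence[SnpRecord],
    meiosis: int,
    marker_ids: Sequence[str] | None = None,
    individuals: Sequence[str] | None = None,
) -> BCMatrix:
    """Build a single-meiosis BCMatrix from 1:1 SNP records.

    Progeny calls map directly to backcross coding (HOM -> 0, HET -> 1).
    ``marker_ids`` can rename columns (e.g. tag ids instead of SNP ids).
    All records must be informative for the requested meiosis.
    """
    want = SegType.ABxAA if meiosis == FEMALE else SegType.AAxAB
    for rec in records:
        if rec.seg_type != want:
            raise ValueError(f"{rec.marker_id}: expected {want.value} for this meiosis, got {rec.seg_type.value}")
    data = np.stack([rec.progeny for rec in records], axis=1)
    ids = list(marker_ids) if marker_ids is not None else [r.marker_id for r in records]
    n = data.shape[0]
    return BCMatrix(
        marker_ids=ids,
        data=data,
        row_meiosis=np.full(n, meiosis, dtype=np.int8),
        individuals=list(individuals) if individuals is not None else None,
    )


def harmonize_phases(
    matrix: BCMatrix, order: Sequence[str], ambiguous_r: float = 0.49
) -> BCMatrix:
    """Propagate linkage phase along ``order`` so adjacent pairs are in coupling.

    Walks the order left to right: the first marker keeps its coding; each
    subsequent marker's phase is called against the previous, already
    harmonized marker, and its column is flipped (0 <-> 1, missing fixed) if
    the pair is in repulsion.  A pair with r̂ >= ``ambiguous_r`` gives an
    essentially arbitrary phase call; a warning is raised and the column is
    left unflipped.  Returns a new matrix with columns in ``order``;
    idempotent, and every pairwise (r̂, LOD) is exactly unchanged.
    """
    if matrix.is_merged:
        raise ValueError("harmonize_phases applies to single-meiosis matrices; merge afterwards")
    out = matrix.reordered(order)
    data = out.data.copy()
    flags = out.phase_flags.copy()
    for j in range(1, data.shape[1]):
        prev = data[:, j - 1]
        cur = data[:, j]
        try:
            res = two_point(prev, cur)
        except ValueError as exc:
            raise ValueError(
                f"no informative overlap between markers {order[j - 1]!r} and {order[j]!r}"
            ) from exc
        if res.r_hat >= ambiguous_r:
            if res.phase is Phase.REPULSION:
                warnings.warn(
                    f"ambiguous phase between {order[j - 1]!r} and {order[j]!r} "
                    f"(r̂ = {res.r_hat:.3f}); keeping original coding",
                    stacklevel=2,
                )
            continue
        if res.phase is Phase.REPULSION:
            obs = cur != MISSING
            data[obs, j] = 1 - cur[obs]
            flags[j] = ~flags[j]
    return replace(out, data=data, phase_flags=flags)


def merge_datasets(female: BCMatrix, male: BCMatrix) -> BCMatrix:
    """Stack harmonized female and male matrices into one 2N-row pseudo-backcross.

    Both matrices must cover the same markers (tags) in the same order and
    the same individuals in the same order.  Phase flags are carried per
    component as a (2, M) array: row 0 female, row 1 male.
    """
    if female.marker_ids != male.marker_ids:
        raise ValueError("female and male matrices must share the same marker list in the same order")
    if female.n_rows != male.n_rows:
        raise ValueError(f"individual counts differ: {female.n_rows} female vs {male.n_rows} male rows")
    if (
        female.individuals is not None
        and male.individuals is not None
        and female.individuals != male.individuals
    ):
        raise ValueError("female and male matrices list different individuals")
    data = np.vstack([female.data, male.data])
    row_meiosis = np.concatenate(
        [np.full(female.n_rows, FEMALE, dtype=np.int8), np.full(male.n_rows, MALE, dtype=np.int8)]
    )
    flags = np.vstack([female.phase_flags, male.phase_flags])
    return BCMatrix(
        marker_ids=list(female.marker_ids),
        data=data,
        row_meiosis=row_meiosis,
        phase_flags=flags,
        individuals=female.individuals,
    )


_CODE_TXT = {0: "0", 1: "1", -1: "-"}
_TXT_CODE = {"0": 0, "1": 1, "-": -1}


def write_bc_matrix(matrix: BCMatrix, path: str) -> None:
    """Write a BCMatrix as TSV (bit-exact round trip with :func:`read_bc_matrix`).

    Header comments carry the phase flags; each data row is
    ``individual<TAB>meiosis<TAB>call...`` with calls coded 0/1/-.
    """
    with open(path, "w") as fh:
        if matrix.is_merged:
            fh.write("#phase_female\t" + "\t".join("F" if f else "O" for f in matrix.phase_flags[0]) + "\n")
            fh.write("#phase_male\t" + "\t".join("F" if f else "O" for f in matrix.phase_flags[1]) + "\n")
        else:
            fh.write("#phase\t" + "\t".join("F" if f else "O" for f in matrix.phase_flags) + "\n")
        fh.write("individual\tmeiosis\t" + "\t".join(matrix.marker_ids) + "\n")
        names = matrix.individuals
        if names is None:
            n_ind = matrix.n_rows // (2 if matrix.is_merged else 1)
            names = [f"P{i + 1}" for i in range(n_ind)]
        for i in range(matrix.n_rows):
            ind = names[i % len(names)]
            mei = _MEIOSIS_LABEL[int(matrix.row_meiosis[i])]
            fh.write(ind + "\t" + mei + "\t" + "\t".join(_CODE_TXT[int(c)] for c in matrix.data[i]) + "\n")


def read_bc_matrix(path: str) -> BCMatrix:
    """Read a BCMatrix written by :func:`write_bc_matrix`."""
    phase_f = phase_m = phase = None
    rows: list[list[int]] = []
    meiosis: list[int] = []
    individuals: list[str] = []
    marker_ids: list[str] | None = None
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#phase":
                phase = np.array([p == "F" for p in parts[1:]])
            elif parts[0] == "#phase_female":
                phase_f = np.array([p == "F" for p in parts[1:]])
            elif parts[0] == "#phase_male":
                phase_m = np.array([p == "F" for p in parts[1:]])
            elif parts[0] == "individual":
                marker_ids = parts[2:]
            else:
                individuals.append(parts[0])
                meiosis.append(_LABEL_MEIOSIS[parts[1]])
                rows.append([_TXT_CODE[c] for c in parts[2:]])
    if marker_ids is None:
        raise ValueError(f"{path}: missing header row")
    if phase_f is not None and phase_m is not None:
        flags = np.vstack([phase_f, phase_m])
    else:
        flags = phase
    n = len(rows)
    names = individuals[: n // 2] if flags is not None and flags.ndim == 2 else individuals
    return BCMatrix(
        marker_ids=marker_ids,
        data=np.array(rows, dtype=np.int8),
        row_meiosis=np.array(meiosis, dtype=np.int8),
        phase_flags=flags,
        individuals=names,
    )
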