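"""Multipoint linkage mapping on backcross-coded data.

This module is the in-package replacement for the classical mapping engines:
it orders markers, estimates interval recombination fractions by EM on a
hidden-Markov model of the meiosis, converts them to Kosambi centimorgans,
and compares the multipoint likelihoods of alternative marker orders.

Model.  Each matrix row is one meiosis.  The hidden state at marker i is
which parental homolog was transmitted (two states, prior 1/2 each); the
chain switches state between adjacent markers with the interval's
recombination probability r_i (no interference).  An observed backcross
call identifies the state; a missing call is uninformative (emits 1 for
both states).  Optionally a symmetric miscall probability ``error_rate``
(HOM <-> HET swap) enters the emission, which prevents the map-length
inflation genotyping errors otherwise cause; the default 0 is the exact
error-free model.

Ordering.  The search objective is the adjacent-pair profile
log10-likelihood (precomputed from pairwise-complete two-point counts),
which coincides with the multipoint likelihood on complete data and is the
standard fast surrogate under missingness.  A greedy chain seeds the order;
window-ripple (exhaustive permutation of sliding windows of size <= 5) and
2-opt segment reversals improve it until a full sweep finds nothing better.
Final distances and the reported order log-likelihood always come from the
full multipoint EM fit.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geno import MISSING
from .phasemerge import BCMatrix
from .twopoint import pairwise_counts

__all__ = [
    "kosambi",
    "kosambi_inv",
    "multipoint_log10L",
    "IntervalFit",
    "fit_intervals",
    "estimate_interval_r",
    "order_markers",
    "LinkageGroup",
    "LinkageMapSet",
    "build_group",
    "build_maps",
    "compare_orders",
    "write_map_tsv",
    "write_map_summary",
    "write_loc",
]

_R_MIN = 1e-9
_R_MAX = 0.49999


# ---------------------------------------------------------------------------
# map function
# ---------------------------------------------------------------------------

def kosambi(r):
    """Kosambi map distance in cM: d = 25 ln((1+2r)/(1-2r)), for 0 <= r < 0.5."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("Kosambi distance requires 0 <= r < 0.5")
    out = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(out) if out.ndim == 0 else out


def kosambi_inv(d):
    """Inverse Kosambi: r = tanh(d/50)/2 for d >= 0 cM."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be >= 0")
    out = 0.5 * np.tanh(d / 50.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# multipoint likelihood (forward algorithm, scaled)
# ---------------------------------------------------------------------------

def _ordered_data(matrix: BCMatrix, order: Sequence[str]) -> np.ndarray:
    if list(order) == list(matrix.marker_ids):
        return matrix.data
    return matrix.reordered(list(order)).data


def _emissions(data: np.ndarray, error_rate: float) -> np.ndarray:
    """Emission probabilities, shape (n, M, 2)."""
    n, m = data.shape
    e = np.ones((n, m, 2))
    eps = float(error_rate)
    obs0 = data == 0
    obs1 = data == 1
    e[obs0, 0] = 1.0 - eps
    e[obs0, 1] = eps
    e[obs1, 0] = eps
    e[obs1, 1] = 1.0 - eps
    return e


def multipoint_log10L(
    matrix: BCMatrix,
    order: Sequence[str],
    interval_r: Sequence[float],
    error_rate: float = 0.0,
) -> float:
    """Multipoint log10-likelihood of ``order`` with the given interval r values.

    Sums, over meioses (rows), the log10 forward probability of the 2-state
    transmission chain.  An all-missing row contributes exactly 0; a single
    marker contributes log10(1/2) per row.  If some row is impossible (an
    obligate recombinant across an interval with r = 0 and error_rate = 0)
    the function returns -inf.
    """
    data = _ordered_data(matrix, order)
    n, m = data.shape
    r = np.asarray(interval_r, dtype=float)
    if r.shape != (m - 1,):
        raise ValueError(f"expected {m - 1} interval r values, got {r.shape}")
    if np.any(r < 0) or np.any(r > 0.5):
        raise ValueError("interval r must lie in [0, 0.5]")
    e = _emissions(data, error_rate)
    alpha = 0.5 * e[:, 0, :]
    c = alpha.sum(axis=1)
    if np.any(c == 0.0):
        return float("-inf")
    log10L = np.log10(c)
    alpha /= c[:, None]
    for i in range(1, m):
        ri = r[i - 1]
        a0 = alpha[:, 0] * (1.0 - ri) + alpha[:, 1] * ri
        a1 = alpha[:, 0] * ri + alpha[:, 1] * (1.0 - ri)
        alpha = np.stack([a0, a1], axis=1) * e[:, i, :]
        c = alpha.sum(axis=1)
        if np.any(c == 0.0):
            return float("-inf")
        log10L += np.log10(c)
        alpha /= c[:, None]
    return float(log10L.sum())


# ---------------------------------------------------------------------------
# EM estimation of interval r (and optionally the miscall rate)
# ---------------------------------------------------------------------------

@dataclass
class IntervalFit:
    """Result of the multipoint EM fit along one marker order."""

    order: list[str]
    interval_r: np.ndarray
    error_rate: float
    log10L: float
    n_iter: int
    converged: bool


def _pairwise_adjacent_r(data: np.ndarray) -> np.ndarray:
    """Folded two-point r̂ for each adjacent column pair (pairwise-complete)."""
    m = data.shape[1]
    out = np.empty(m - 1)
    for i in range(m - 1):
        a, b = data[:, i], data[:, i + 1]
        ok = (a != MISSING) & (b != MISSING)
        n = int(ok.sum())
        if n == 0:
            out[i] = 0.25  # no information; neutral starting value
            continue
        rc = int(np.sum(a[ok] != b[ok]))
        out[i] = min(rc, n - rc) / n
    return out


def _em_pass(data, e, r):
    """One forward-backward pass. Returns (log10L, xi_switch, gamma)."""
    n, m = data.shape
    alpha = np.empty((n, m, 2))
    c = np.empty((n, m))
    a = 0.5 * e[:, 0, :]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0, :] = a / c[:, 0][:, None]
    for i in range(1, m):
        ri = r[i - 1]
        prev = alpha[:, i - 1, :]
        a0 = prev[:, 0] * (1.0 - ri) + prev[:, 1] * ri
        a1 = prev[:, 0] * ri + prev[:, 1] * (1.0 - ri)
        a = np.stack([a0, a1], axis=1) * e[:, i, :]
        c[:, i] = a.sum(axis=1)
        alpha[:, i, :] = a / c[:, i][:, None]
    log10L = float(np.log10(c).sum())

    beta = np.ones((n, 2))
    xi = np.empty(m - 1)
    gamma = np.empty((n, m, 2))
    gamma[:, m - 1, :] = alpha[:, m - 1, :]
    for i in range(m - 2, -1, -1):
        ri = r[i]
        eb = e[:, i + 1, :] * beta  # (n, 2)
        # expected switch probability at interval i, per row
        sw = (alpha[:, i, 0] * ri * eb[:, 1] + alpha[:, i, 1] * ri * eb[:, 0]) / c[:, i + 1]
        xi[i] = sw.sum()
        b0 = ((1.0 - ri) * eb[:, 0] + ri * eb[:, 1]) / c[:, i + 1]
        b1 = (ri * eb[:, 0] + (1.0 - ri) * eb[:, 1]) / c[:, i + 1]
        beta = np.stack([b0, b1], axis=1)
        gamma[:, i, :] = alpha[:, i, :] * beta
    return log10L, xi, gamma


def fit_intervals(
    matrix: BCMatrix,
    order: Sequence[str],
    error_rate: float = 0.0,
    estimate_error: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> IntervalFit:
    """EM fit of per-interval r (and optionally the miscall rate) along ``order``.

    Initialization is the pairwise-complete two-point estimate per adjacent
    pair.  With no missing data and the error-free emission model those
    starting values are already the exact MLE and are returned as-is.
    Convergence: |Δ log10L| < ``tol``; non-convergence warns and returns the
    last iterate.
    """
    data = _ordered_data(matrix, order)
    n, m = data.shape
    if m < 2:
        return IntervalFit(list(order), np.empty(0), float(error_rate),
                           multipoint_log10L(matrix, order, [], error_rate), 0, True)
    r = _pairwise_adjacent_r(data)
    eps = float(error_rate)
    if not estimate_error and eps == 0.0 and not np.any(data == MISSING):
        ll = multipoint_log10L(matrix, order, r, 0.0)
        return IntervalFit(list(order), r, 0.0, ll, 0, True)
    if estimate_error and eps == 0.0:
        eps = 0.005  # neutral small starting value for the miscall rate
    r = np.clip(r, _R_MIN, _R_MAX)
    prev_ll = -np.inf
    converged = False
    n_obs = int(np.sum(data != MISSING))
    it = 0
    for it in range(1, max_iter + 1):
        e = _emissions(data, eps)
        ll, xi, gamma = _em_pass(data, e, r)
        if abs(ll - prev_ll) < tol:
            converged = True
            break
        prev_ll = ll
        r = np.clip(xi / n, _R_MIN, _R_MAX)
        if estimate_error:
            # expected miscalls: posterior weight on the state the call contradicts
            err0 = gamma[:, :, 1][data == 0].sum()
            err1 = gamma[:, :, 0][data == 1].sum()
            eps = float(np.clip((err0 + err1) / max(n_obs, 1), 1e-6, 0.2))
    else:
        warnings.warn(f"interval EM did not converge in {max_iter} iterations", stacklevel=2)
    r_out = np.where(r <= 1e-8, 0.0, r)
    ll = multipoint_log10L(matrix, order, r_out, eps if estimate_error else error_rate)
    return IntervalFit(list(order), r_out, eps if estimate_error else float(error_rate),
                       ll, it, converged)


def estimate_interval_r(
    matrix: BCMatrix,
    order: Sequence[str],
    error_rate: float = 0.0,
    estimate_error: bool = False,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> np.ndarray:
    """Interval recombination-fraction MLEs along ``order`` (see :func:`fit_intervals`)."""
    return fit_intervals(matrix, order, error_rate, estimate_error, tol, max_iter).interval_r


# ---------------------------------------------------------------------------
# marker ordering
# ---------------------------------------------------------------------------

def _pair_scores(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adjacent-pair profile log10-likelihood score matrix plus (r̂, LOD-ish) helpers.

    S[i, j] = R' log10 r̂ + (n - R') log10(1 - r̂) with R' = min(R, n-R) and
    r̂ = R'/n on pairwise-complete data; S = 0 when R' = 0.  Pairs with no
    informative overlap get a large negative score so they are never placed
    adjacent if any alternative exists.
    """
    r_count, n = pairwise_counts(data)
    r_prime = np.minimum(r_count, n - r_count)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_hat = np.where(n > 0, r_prime / np.maximum(n, 1), 0.5)
        s = np.where(
            r_prime > 0,
            r_prime * np.log10(np.maximum(r_hat, 1e-300))
            + (n - r_prime) * np.log10(np.maximum(1.0 - r_hat, 1e-300)),
            0.0,
        )
    s = np.where(n > 0, s, -1e6)
    np.fill_diagonal(s, -np.inf)
    lod = np.where((n > 0), (n - r_prime) * np.log10(2 * (1 - r_hat))
                   + np.where(r_prime > 0, r_prime * np.log10(np.maximum(2 * r_hat, 1e-300)), 0.0), 0.0)
    np.fill_diagonal(lod, 0.0)
    return s, r_hat, lod


def _order_score(order: np.ndarray, s: np.ndarray) -> float:
    return float(s[order[:-1], order[1:]].sum())


def _greedy_seed(r_hat: np.ndarray, lod: np.ndarray) -> np.ndarray:
    m = r_hat.shape[0]
    i, j = np.unravel_index(np.argmax(lod), lod.shape)
    chain = [int(i), int(j)]
    placed = {int(i), int(j)}
    while len(chain) < m:
        best = None
        for k in range(m):
            if k in placed:
                continue
            for endpos, end in ((0, chain[0]), (1, chain[-1])):
                key = (r_hat[end, k], -lod[end, k], k, endpos)
                if best is None or key < best:
                    best = key
                    best_k, best_end = k, endpos
        if best_end == 0:
            chain.insert(0, best_k)
        else:
            chain.append(best_k)
        placed.add(best_k)
    return np.array(chain, dtype=np.intp)


def _ripple_sweep(order: np.ndarray, s: np.ndarray, window: int) -> tuple[np.ndarray, bool]:
    m = order.size
    w = min(window, m)
    improved = False
    perms_cache = {k: list(itertools.permutations(range(k))) for k in {w}}
    for start in range(0, m - w + 1):
        seg = order[start : start + w].copy()
        left = order[start - 1] if start > 0 else -1
        right = order[start + w] if start + w < m else -1
        def seg_score(p):
            sc = float(s[p[:-1], p[1:]].sum()) if w > 1 else 0.0
            if left >= 0:
                sc += s[left, p[0]]
            if right >= 0:
                sc += s[p[-1], right]
            return sc
        base = seg_score(seg)
        best_sc, best_p = base, None
        for perm in perms_cache[w]:
            p = seg[list(perm)]
            sc = seg_score(p)
            if sc > best_sc + 1e-9:
                best_sc, best_p = sc, p
        if best_p is not None:
            order[start : start + w] = best_p
            improved = True
    return order, improved


def _two_opt_sweep(order: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, bool]:
    m = order.size
    improved = False
    changed = True
    while changed:
        changed = False
        for i in range(m - 1):
            oi_prev = order[i - 1] if i > 0 else -1
            for j in range(i + 1, m):
                oj_next = order[j + 1] if j + 1 < m else -1
                if oi_prev < 0 and oj_next < 0:
                    continue  # full reversal: same score
                delta = 0.0
                if oi_prev >= 0:
                    delta += s[oi_prev, order[j]] - s[oi_prev, order[i]]
                if oj_next >= 0:
                    delta += s[order[i], oj_next] - s[order[j], oj_next]
                if delta > 1e-9:
                    order[i : j + 1] = order[i : j + 1][::-1]
                    improved = changed = True
                    break
            if changed:
                break
    return order, improved


def _local_search(order: np.ndarray, s: np.ndarray, window: int) -> np.ndarray:
    order = order.copy()
    while True:
        order, imp1 = _ripple_sweep(order, s, window)
        order, imp2 = _two_opt_sweep(order, s)
        if not (imp1 or imp2):
            return order


def order_markers(
    matrix: BCMatrix, seed: int = 0, window: int = 5, n_restarts: int = 2
) -> list[str]:
    """Order the matrix's markers by maximising the adjacent-pair likelihood.

    Deterministic given ``seed``: a greedy chain (grown from the highest-LOD
    pair by appending the nearest unplaced marker to either end) is refined
    by window-ripple and 2-opt; ``n_restarts`` additional searches from
    seeded random shuffles guard against local optima.  The returned order
    is canonically oriented (first marker id lexicographically smaller than
    the last).
    """
    m = matrix.n_markers
    if m <= 2:
        order = list(matrix.marker_ids)
        return order if m < 2 or order[0] <= order[-1] else order[::-1]
    s, r_hat, lod = _pair_scores(matrix.data.T)  # pairwise helpers take markers-by-meioses
    best = _local_search(_greedy_seed(r_hat, lod), s, window)
    best_sc = _order_score(best, s)
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        start = rng.permutation(m).astype(np.intp)
        cand = _local_search(start, s, window)
        sc = _order_score(cand, s)
        if sc > best_sc + 1e-9:
            best, best_sc = cand, sc
    ids = [matrix.marker_ids[i] for i in best]
    if ids[0] > ids[-1]:
        ids = ids[::-1]
    return ids


# ---------------------------------------------------------------------------
# map assembly
# ---------------------------------------------------------------------------

@dataclass
class LinkageGroup:
    """One ordered linkage group with interval r, Kosambi cM and cumulative positions."""

    tag_ids: list[str]
    interval_r: np.ndarray
    interval_cM: np.ndarray
    cum_cM: np.ndarray
    order_log10L: float
    flavor: str  # FEMALE | MALE | INTEGRATED
    error_rate: float = 0.0

    @property
    def n_markers(self) -> int:
        return len(self.tag_ids)

    @property
    def length_cM(self) -> float:
        return float(self.cum_cM[-1]) if self.n_markers else 0.0


@dataclass
class LinkageMapSet:
    """A whole-genome map of one flavor: a list of linkage groups plus totals."""

    groups: list[LinkageGroup]
    flavor: str

    @property
    def total_cM(self) -> float:
        return float(sum(g.length_cM for g in self.groups))

    @property
    def mean_adjacent_cM(self) -> float:
        n_intervals = sum(max(g.n_markers - 1, 0) for g in self.groups)
        return self.total_cM / n_intervals if n_intervals else 0.0


def build_group(
    matrix: BCMatrix,
    order: Sequence[str],
    flavor: str = "INTEGRATED",
    error_rate: float = 0.0,
    estimate_error: bool = False,
) -> LinkageGroup:
    """Fit interval r along ``order`` and assemble a LinkageGroup."""
    fit = fit_intervals(matrix, order, error_rate=error_rate, estimate_error=estimate_error)
    r = np.minimum(fit.interval_r, _R_MAX)
    cm = kosambi(r) if r.size else np.empty(0)
    cum = np.concatenate([[0.0], np.cumsum(cm)]) if len(order) else np.empty(0)
    return LinkageGroup(
        tag_ids=list(order),
        interval_r=r,
        interval_cM=np.atleast_1d(cm) if r.size else np.empty(0),
        cum_cM=cum,
        order_log10L=fit.log10L,
        flavor=flavor,
        error_rate=fit.error_rate,
    )


def build_maps(groups: Sequence[LinkageGroup], flavor: str) -> LinkageMapSet:
    return LinkageMapSet(groups=list(groups), flavor=flavor)


def compare_orders(
    merged: BCMatrix,
    orders: Mapping[str, Sequence[str]],
    error_rate: float = 0.0,
    estimate_error: bool = False,
) -> dict[str, float]:
    """Profile log10-likelihood of each candidate order on the merged data.

    Interval r (and, if requested, the miscall rate) is re-estimated per
    order, so each order is judged at its own best distances — the classical
    "compare" semantics.  All orders must cover the same markers.
    """
    tag_set = sorted(merged.marker_ids)
    out: dict[str, float] = {}
    for name, order in orders.items():
        if sorted(order) != tag_set:
            raise ValueError(f"order {name!r} does not cover the matrix's markers")
        fit = fit_intervals(merged, order, error_rate=error_rate, estimate_error=estimate_error)
        out[name] = fit.log10L
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_map_tsv(maps: Mapping[str, LinkageMapSet], path: str) -> None:
    """Write maps as TSV: flavor, lg_index, tag_id, cum_cM (2 decimals)."""
    rows = []
    for flavor, mapset in maps.items():
        for gi, g in enumerate(mapset.groups, start=1):
            for tid, pos in zip(g.tag_ids, g.cum_cM):
                rows.append((flavor, gi, tid, f"{pos:.2f}"))
    pd.DataFrame(rows, columns=["flavor", "lg_index", "tag_id", "cum_cM"]).to_csv(
        path, sep="\t", index=False
    )


def write_map_summary(maps: Mapping[str, LinkageMapSet], path: str) -> pd.DataFrame:
    """Per-LG marker counts and lengths for each flavor, plus a Total row."""
    flavors = list(maps)
    n_groups = max(len(m.groups) for m in maps.values())
    rows = []
    for gi in range(n_groups):
        row: dict = {"LG": gi + 1}
        counts = {f: maps[f].groups[gi].n_markers for f in flavors if gi < len(maps[f].groups)}
        row["n_markers"] = counts.get(flavors[0], 0)
        for f in flavors:
            row[f"{f}_cM"] = round(maps[f].groups[gi].length_cM, 2) if gi < len(maps[f].groups) else float("nan")
        rows.append(row)
    total = {"LG": "Total", "n_markers": sum(m.n_markers for m in maps[flavors[0]].groups)}
    for f in flavors:
        total[f"{f}_cM"] = round(maps[f].total_cM, 2)
    rows.append(total)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


def write_loc(matrix: BCMatrix, path: str, name: str = "radmap") -> None:
    """Export backcross-coded data in the JoinMap .loc dialect (popt BC1).

    Calls are written a (0), b (1), - (missing); each matrix row is treated
    as one individual of the pseudo-backcross.
    """
    code = {0: "a", 1: "b", -1: "-"}
    with open(path, "w") as fh:
        fh.write(f"name = {name}\npopt = BC1\nnloc = {matrix.n_markers}\nnind = {matrix.n_rows}\n\n")
        for j, mid in enumerate(matrix.marker_ids):
            calls = " ".join(code[int(c)] for c in matrix.data[:, j])
            fh.write(f"{mid}\n {calls}\n")
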