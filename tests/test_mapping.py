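"""Kosambi function, multipoint likelihood, interval EM, ordering, map assembly."""

import itertools
import math

import numpy as np
import pytest

from radmap.geno import MISSING
from radmap.mapping import (
    build_group,
    build_maps,
    compare_orders,
    estimate_interval_r,
    fit_intervals,
    kosambi,
    kosambi_inv,
    multipoint_log10L,
    order_markers,
)
from radmap.phasemerge import FEMALE, MALE, BCMatrix, bc_matrix_from_records, harmonize_phases, merge_datasets
from radmap.simgen import SimConfig, simulate_f1
from radmap.twopoint import two_point


def make_matrix(data, meiosis=FEMALE, ids=None):
    data = np.asarray(data, dtype=np.int8)
    ids = ids or [f"m{i}" for i in range(data.shape[1])]
    return BCMatrix(marker_ids=ids, data=data,
                    row_meiosis=np.full(data.shape[0], meiosis, dtype=np.int8))


def female_matrix(sim, chrom="Chr01"):
    by_id = {r.marker_id: r for r in sim.records}
    tags = [t for t in sim.tags if t.chrom == chrom]
    return bc_matrix_from_records([by_id[t.snp_f] for t in tags], FEMALE,
                                  marker_ids=[t.tag_id for t in tags])


# ---------------------------------------------------------------------------
# Kosambi
# ---------------------------------------------------------------------------

def test_kosambi_values():
    assert kosambi(0.0) == 0.0
    assert kosambi(0.2) == pytest.approx(25 * math.log(1.4 / 0.6), rel=1e-12)
    assert kosambi(0.2) == pytest.approx(21.182, abs=1e-3)


def test_kosambi_round_trip():
    r = np.arange(0.0, 0.4901, 0.01)
    back = kosambi_inv(kosambi(r))
    assert np.max(np.abs(back - r)) < 1e-10


def test_kosambi_rejects_unlinked():
    with pytest.raises(ValueError):
        kosambi(0.5)


# ---------------------------------------------------------------------------
# multipoint likelihood
# ---------------------------------------------------------------------------

def closed_form_log10L(data, order_idx, r):
    """Independent oracle: complete-data likelihood factorizes over intervals."""
    n = data.shape[0]
    total = n * math.log10(0.5)
    for k in range(len(order_idx) - 1):
        a = data[:, order_idx[k]]
        b = data[:, order_idx[k + 1]]
        recomb = int(np.sum(a != b))
        rk = r[k]
        total += recomb * math.log10(rk) + (n - recomb) * math.log10(1 - rk)
    return total


def test_single_marker_likelihood():
    m = make_matrix(np.zeros((40, 1), dtype=np.int8))
    assert multipoint_log10L(m, m.marker_ids, []) == pytest.approx(40 * math.log10(0.5), rel=1e-12)


def test_complete_data_likelihood_matches_closed_form():
    rng = np.random.default_rng(8)
    n, M = 257, 6
    data = rng.integers(0, 2, (n, M)).astype(np.int8)
    m = make_matrix(data)
    r = rng.uniform(0.05, 0.4, M - 1)
    got = multipoint_log10L(m, m.marker_ids, r)
    want = closed_form_log10L(data, list(range(M)), r)
    assert abs(got - want) < 1e-9


def test_all_missing_row_contributes_zero():
    rng = np.random.default_rng(1)
    data = rng.integers(0, 2, (30, 4)).astype(np.int8)
    m1 = make_matrix(data)
    data2 = np.vstack([data, np.full((1, 4), MISSING, dtype=np.int8)])
    m2 = make_matrix(data2)
    r = [0.1, 0.2, 0.3]
    assert multipoint_log10L(m2, m2.marker_ids, r) == pytest.approx(
        multipoint_log10L(m1, m1.marker_ids, r), rel=1e-12
    )


def test_zero_r_with_observed_recombinant_is_minus_inf():
    data = np.array([[0, 1], [0, 0]], dtype=np.int8)
    m = make_matrix(data)
    assert multipoint_log10L(m, m.marker_ids, [0.0]) == float("-inf")


def test_likelihood_invariant_under_reversal_and_row_permutation():
    rng = np.random.default_rng(13)
    data = rng.choice([0, 1, -1], size=(80, 5), p=[0.45, 0.45, 0.1]).astype(np.int8)
    m = make_matrix(data)
    r = [0.05, 0.1, 0.2, 0.3]
    ll = multipoint_log10L(m, m.marker_ids, r)
    rev = multipoint_log10L(m, m.marker_ids[::-1], r[::-1])
    assert ll == pytest.approx(rev, rel=1e-12)
    perm = rng.permutation(80)
    m2 = make_matrix(data[perm])
    assert multipoint_log10L(m2, m2.marker_ids, r) == pytest.approx(ll, rel=1e-12)


# ---------------------------------------------------------------------------
# interval EM
# ---------------------------------------------------------------------------

def test_complete_data_em_equals_two_point_exactly():
    rng = np.random.default_rng(17)
    data = rng.integers(0, 2, (120, 5)).astype(np.int8)
    m = make_matrix(data)
    r = estimate_interval_r(m, m.marker_ids)
    expected = [
        min(int(np.sum(data[:, i] != data[:, i + 1])), 120 - int(np.sum(data[:, i] != data[:, i + 1]))) / 120
        for i in range(4)
    ]
    np.testing.assert_array_equal(r, expected)


def test_em_recovers_r_with_missing_data():
    sim = simulate_f1(
        SimConfig(n_chromosomes=1, tags_per_chromosome=6, n_progeny=10_000,
                  interval_r_female=0.10, interval_r_male=0.10,
                  missing_rate=0.10, error_rate=0.0, seed=3)
    )
    m = female_matrix(sim)
    h = harmonize_phases(m, m.marker_ids)
    r = estimate_interval_r(h, h.marker_ids)
    n_eff = 10_000 * 0.9 * 0.9
    se = math.sqrt(0.1 * 0.9 / n_eff)
    assert np.all(np.abs(r - 0.10) < 3 * se)


def test_zero_r_intervals_give_zero_length_map():
    data = np.tile(np.array([[0], [1]], dtype=np.int8), (20, 4))
    m = make_matrix(data)
    g = build_group(m, m.marker_ids)
    assert g.length_cM == 0.0
    np.testing.assert_array_equal(g.interval_r, np.zeros(3))


# ---------------------------------------------------------------------------
# ordering
# ---------------------------------------------------------------------------

def exhaustive_best_order(data):
    """Oracle: enumerate all orders (up to reversal), score with the
    complete-data profile likelihood."""
    n, M = data.shape
    best_ll, best_perm = -np.inf, None
    for perm in itertools.permutations(range(M)):
        if perm[0] > perm[-1]:
            continue
        r = []
        ok = True
        for k in range(M - 1):
            rec = int(np.sum(data[:, perm[k]] != data[:, perm[k + 1]]))
            rec = min(rec, n - rec)
            r.append(max(rec / n, 1e-12))
        ll = closed_form_log10L_folded(data, perm, r)
        if ll > best_ll:
            best_ll, best_perm = ll, perm
    return best_perm, best_ll


def closed_form_log10L_folded(data, order_idx, r):
    n = data.shape[0]
    total = n * math.log10(0.5)
    for k in range(len(order_idx) - 1):
        a = data[:, order_idx[k]]
        b = data[:, order_idx[k + 1]]
        rec = int(np.sum(a != b))
        rec = min(rec, n - rec)
        if rec:
            total += rec * math.log10(r[k])
        total += (n - rec) * math.log10(1 - r[k])
    return total


def test_two_marker_order_is_canonical():
    data = np.array([[0, 1], [1, 0], [0, 0]], dtype=np.int8)
    m = make_matrix(data, ids=["b", "a"])
    assert order_markers(m, seed=0) == ["a", "b"]


def test_order_matches_exhaustive_search_on_8_markers():
    sim = simulate_f1(
        SimConfig(n_chromosomes=1, tags_per_chromosome=8, n_progeny=500,
                  interval_r_female=0.05, interval_r_male=0.05,
                  missing_rate=0.0, error_rate=0.0, seed=19)
    )
    m = female_matrix(sim)
    got = order_markers(m, seed=0)
    perm, _ = exhaustive_best_order(m.data)
    want = [m.marker_ids[i] for i in perm]
    if want[0] > want[-1]:
        want = want[::-1]
    assert got == want


def test_ordering_invariant_under_column_reversal(small_sim):
    m = female_matrix(small_sim)
    rev = m.reordered(m.marker_ids[::-1])
    assert order_markers(m, seed=0) == order_markers(rev, seed=0)


# ---------------------------------------------------------------------------
# map assembly + order comparison
# ---------------------------------------------------------------------------

def test_build_group_composes_intervals():
    # two intervals with r̂ = 0.1 each -> length 2 * kosambi(0.1)
    n = 100
    rng = np.random.default_rng(23)
    a = rng.integers(0, 2, n).astype(np.int8)
    b = a.copy(); b[:10] ^= 1
    c = b.copy(); c[-10:] ^= 1
    m = make_matrix(np.stack([a, b, c], axis=1))
    g = build_group(m, m.marker_ids)
    assert g.length_cM == pytest.approx(2 * kosambi(0.1), rel=1e-9)
    np.testing.assert_allclose(g.cum_cM, [0.0, kosambi(0.1), 2 * kosambi(0.1)])
    assert g.order_log10L == pytest.approx(
        multipoint_log10L(m, m.marker_ids, g.interval_r), rel=1e-12
    )


def test_single_marker_group_has_zero_length():
    m = make_matrix(np.zeros((10, 1), dtype=np.int8), ids=["only"])
    g = build_group(m, ["only"])
    assert g.length_cM == 0.0 and g.n_markers == 1


def test_mapset_totals():
    m = make_matrix(np.random.default_rng(0).integers(0, 2, (50, 3)).astype(np.int8))
    g = build_group(m, m.marker_ids)
    ms = build_maps([g, g], "FEMALE")
    assert ms.total_cM == pytest.approx(2 * g.length_cM)
    assert ms.mean_adjacent_cM == pytest.approx(ms.total_cM / 4)


def test_sex_specific_rates_order_map_lengths():
    """Female r > male r per interval -> female map longest, integrated between."""
    sim = simulate_f1(
        SimConfig(n_chromosomes=1, tags_per_chromosome=15, n_progeny=257,
                  interval_r_female=0.09, interval_r_male=0.03,
                  missing_rate=0.0, error_rate=0.0, seed=29)
    )
    by_id = {r.marker_id: r for r in sim.records}
    tags = sim.tags
    ids = [t.tag_id for t in tags]
    f = bc_matrix_from_records([by_id[t.snp_f] for t in tags], FEMALE, marker_ids=ids)
    m = bc_matrix_from_records([by_id[t.snp_m] for t in tags], MALE, marker_ids=ids)
    fh = harmonize_phases(f, ids)
    mh = harmonize_phases(m, ids)
    merged = merge_datasets(fh, mh)
    gf = build_group(fh, ids, "FEMALE")
    gm = build_group(mh, ids, "MALE")
    gi = build_group(merged, ids, "INTEGRATED")
    assert gm.length_cM < gi.length_cM < gf.length_cM


def test_compare_orders_properties(small_sim):
    by_id = {r.marker_id: r for r in small_sim.records}
    tags = [t for t in small_sim.tags if t.chrom == "Chr01"]
    ids = [t.tag_id for t in tags]
    f = bc_matrix_from_records([by_id[t.snp_f] for t in tags], FEMALE, marker_ids=ids)
    m = bc_matrix_from_records([by_id[t.snp_m] for t in tags], MALE, marker_ids=ids)
    merged = merge_datasets(harmonize_phases(f, ids), harmonize_phases(m, ids))
    res = compare_orders(merged, {"A": ids, "B": list(ids), "REV": ids[::-1]})
    assert res["A"] == res["B"]  # identical orders, identical likelihood
    assert res["REV"] == pytest.approx(res["A"], rel=1e-12)  # strand symmetry
    swapped = list(ids)
    swapped[5], swapped[6] = swapped[6], swapped[5]
    res2 = compare_orders(merged, {"TRUE": ids, "SWAP": swapped})
    assert res2["TRUE"] > res2["SWAP"]
    with pytest.raises(ValueError, match="does not cover"):
        compare_orders(merged, {"BAD": ids[:-1]})


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def test_map_and_loc_writers(tmp_path):
    import pandas as pd
    from radmap.mapping import write_loc, write_map_summary, write_map_tsv

    rng = np.random.default_rng(7)
    m = make_matrix(rng.integers(0, 2, (30, 3)).astype(np.int8), ids=["t1", "t2", "t3"])
    g = build_group(m, m.marker_ids, "FEMALE")
    maps = {"FEMALE": build_maps([g], "FEMALE")}
    p = tmp_path / "maps.tsv"
    write_map_tsv(maps, str(p))
    df = pd.read_csv(p, sep="\t")
    assert list(df.columns) == ["flavor", "lg_index", "tag_id", "cum_cM"]
    assert list(df["tag_id"]) == ["t1", "t2", "t3"]
    assert df["cum_cM"].iloc[0] == 0.0

    summary = write_map_summary(maps, str(tmp_path / "summary.tsv"))
    assert summary.iloc[-1]["LG"] == "Total"
    assert summary.iloc[-1]["FEMALE_cM"] == round(g.length_cM, 2)

    loc = tmp_path / "data.loc"
    write_loc(m, str(loc), name="demo")
    text = loc.read_text()
    assert "popt = BC1" in text and "nloc = 3" in text and "nind = 30" in text
    assert text.count("\n t") == 0  # marker lines then call lines
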