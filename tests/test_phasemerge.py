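"""Phase harmonization and female/male dataset merging."""

import numpy as np
import pytest

from radmap.phasemerge import (
    FEMALE,
    MALE,
    BCMatrix,
    bc_matrix_from_records,
    harmonize_phases,
    merge_datasets,
    read_bc_matrix,
    write_bc_matrix,
)
from radmap.twopoint import Phase, combined_r, two_point, two_point_counts


def mat(columns, meiosis=FEMALE, ids=None):
    data = np.array(columns, dtype=np.int8).T
    ids = ids or [f"m{i}" for i in range(data.shape[1])]
    return BCMatrix(
        marker_ids=ids,
        data=data,
        row_meiosis=np.full(data.shape[0], meiosis, dtype=np.int8),
    )


def test_coupling_pair_left_unchanged():
    m = mat([[0, 1, 0, 1], [0, 1, 0, 1]])
    h = harmonize_phases(m, m.marker_ids)
    np.testing.assert_array_equal(h.data, m.data)
    assert not h.phase_flags.any()


def test_repulsion_pair_is_flipped():
    # second column is the complement -> flipped back to match the first
    m = mat([[0, 1, 0, 1], [1, 0, 1, 0]])
    h = harmonize_phases(m, m.marker_ids)
    np.testing.assert_array_equal(h.data[:, 1], np.array([0, 1, 0, 1]))
    assert list(h.phase_flags) == [False, True]


def test_flip_propagates_down_the_chain():
    """Adjacent phases C, R, C over 4 markers -> flags O, O, FLIPPED, FLIPPED."""
    base = np.array([0, 1, 0, 1, 1, 0], dtype=np.int8)
    cols = [base, base, 1 - base, 1 - base]  # pairs: coupling, repulsion, coupling
    m = mat([list(c) for c in cols])
    h = harmonize_phases(m, m.marker_ids)
    assert list(h.phase_flags) == [False, False, True, True]
    # oracle: after propagation every adjacent pair is in coupling
    for j in range(1, 4):
        assert two_point(h.data[:, j - 1], h.data[:, j]).phase is Phase.COUPLING


def test_harmonization_preserves_pairwise_statistics_bitwise():
    rng = np.random.default_rng(9)
    data = rng.choice([0, 1, -1], size=(40, 6), p=[0.45, 0.45, 0.1]).astype(np.int8)
    m = BCMatrix(marker_ids=[f"m{i}" for i in range(6)], data=data,
                 row_meiosis=np.zeros(40, dtype=np.int8))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # random columns give ambiguous-phase warnings
        h = harmonize_phases(m, m.marker_ids)
        hh = harmonize_phases(h, h.marker_ids)
    for i in range(6):
        for j in range(i + 1, 6):
            before = two_point(m.data[:, i], m.data[:, j])
            after = two_point(h.data[:, i], h.data[:, j])
            assert before.r_hat == after.r_hat and before.lod == after.lod
    # idempotent: second pass changes nothing
    np.testing.assert_array_equal(h.data, hh.data)
    np.testing.assert_array_equal(h.phase_flags, hh.phase_flags)


def test_double_flip_restores_column():
    base = np.array([0, 1, 0, 1, 1, 0, -1, 1], dtype=np.int8)
    comp = np.where(base == -1, -1, 1 - base).astype(np.int8)
    m = mat([list(base), list(comp)])
    h = harmonize_phases(m, m.marker_ids)  # flips the second column once
    assert h.phase_flags[1]
    obs = h.data[:, 1] != -1
    flipped_back = h.data[:, 1].copy()
    flipped_back[obs] = 1 - flipped_back[obs]
    np.testing.assert_array_equal(flipped_back, m.data[:, 1])  # missing untouched


def test_zero_overlap_pair_raises_with_names():
    m = mat([[0, 1, -1, -1], [-1, -1, 0, 1]], ids=["left", "right"])
    with pytest.raises(ValueError, match="left.*right"):
        harmonize_phases(m, m.marker_ids)


def test_merge_shapes_and_blocks():
    f = mat([[0, 1], [1, 0], [0, 0]], meiosis=FEMALE, ids=["t1", "t2", "t3"])
    m = mat([[1, 1], [0, 1], [0, 0]], meiosis=MALE, ids=["t1", "t2", "t3"])
    merged = merge_datasets(f, m)
    assert merged.data.shape == (4, 3)
    assert list(merged.row_meiosis) == [FEMALE, FEMALE, MALE, MALE]
    assert merged.phase_flags.shape == (2, 3)


def test_merge_rejects_mismatched_inputs():
    f = mat([[0, 1], [1, 0]], meiosis=FEMALE, ids=["t1", "t2"])
    m = mat([[0, 1], [1, 0]], meiosis=MALE, ids=["t2", "t1"])
    with pytest.raises(ValueError, match="marker list"):
        merge_datasets(f, m)
    m2 = mat([[0, 1, 1], [1, 0, 1]], meiosis=MALE, ids=["t1", "t2"])
    with pytest.raises(ValueError, match="counts differ"):
        merge_datasets(f, m2)


def test_two_point_on_merged_equals_pooled_counts():
    """Oracle from the two-point module: pooled counts = merged-matrix r̂."""
    rng = np.random.default_rng(21)
    n = 120
    fa = rng.integers(0, 2, n).astype(np.int8)
    fb = fa.copy(); fb[rng.choice(n, 9, replace=False)] ^= 1
    ma = rng.integers(0, 2, n).astype(np.int8)
    mb = ma.copy(); mb[rng.choice(n, 15, replace=False)] ^= 1
    f = mat([list(fa), list(fb)], meiosis=FEMALE, ids=["t1", "t2"])
    m = mat([list(ma), list(mb)], meiosis=MALE, ids=["t1", "t2"])
    merged = merge_datasets(f, m)
    res = two_point(merged.data[:, 0], merged.data[:, 1])
    pooled = combined_r(two_point_counts(fa, fb), two_point_counts(ma, mb))
    assert res.r_hat == pooled


def test_merging_all_missing_male_rows_is_neutral():
    n = 60
    rng = np.random.default_rng(2)
    fa = rng.integers(0, 2, n).astype(np.int8)
    fb = fa.copy(); fb[:6] ^= 1
    f = mat([list(fa), list(fb)], meiosis=FEMALE, ids=["t1", "t2"])
    m = mat([[-1] * n, [-1] * n], meiosis=MALE, ids=["t1", "t2"])
    merged = merge_datasets(f, m)
    assert two_point(merged.data[:, 0], merged.data[:, 1]).r_hat == two_point(fa, fb).r_hat


def test_bc_matrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(4)
    f = mat(rng.choice([0, 1, -1], size=(3, 10)).tolist(), meiosis=FEMALE, ids=["a", "b", "c"])
    m = mat(rng.choice([0, 1, -1], size=(3, 10)).tolist(), meiosis=MALE, ids=["a", "b", "c"])
    m.phase_flags[1] = True
    merged = merge_datasets(f, m)
    path = tmp_path / "merged.tsv"
    write_bc_matrix(merged, str(path))
    back = read_bc_matrix(str(path))
    assert back.marker_ids == merged.marker_ids
    np.testing.assert_array_equal(back.data, merged.data)
    np.testing.assert_array_equal(back.row_meiosis, merged.row_meiosis)
    np.testing.assert_array_equal(back.phase_flags, merged.phase_flags)
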