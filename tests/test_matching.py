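"""Dictionary matching: argmax contracts, constraints, masking."""

import numpy as np
import pytest

from wt2map import (
    SignalMatrix,
    build_dictionary,
    build_grid,
    make_mask,
    match_constrained,
    match_unconstrained,
    truncate_echoes,
)


def _signal_matrix(rows: np.ndarray) -> SignalMatrix:
    n = rows.shape[0]
    coords = np.column_stack([np.zeros(n, int), np.zeros(n, int), np.arange(n)])
    return SignalMatrix(matrix=rows, voxel_coords=coords,
                        norm=np.linalg.norm(rows, axis=1))


@pytest.fixture(scope="module")
def fast_dictionary(seq17, rect_profile):
    """Full default grid with a hard-pulse profile (fast to simulate)."""
    return build_dictionary(build_grid(), seq17, rect_profile)


class TestUnconstrained:
    def test_dictionary_column_recovered_with_correlation_one(self, fast_dictionary):
        e = 1234
        sig = 37.5 * fast_dictionary.matrix[:, e]  # arbitrary positive scale
        maps = match_unconstrained(_signal_matrix(sig[None]), fast_dictionary, (1, 1, 1))
        wt2, ff, b1 = fast_dictionary.entry_parameters(e)
        assert maps.wt2[0, 0, 0] == wt2
        assert maps.ff[0, 0, 0] == ff
        assert maps.b1[0, 0, 0] == b1
        assert maps.correlation[0, 0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_batching_is_invisible(self, fast_dictionary, rng):
        rows = rng.random((23, 17)) + 0.05
        sm = _signal_matrix(rows)
        a = match_unconstrained(sm, fast_dictionary, (1, 1, 23), batch_size=1)
        b = match_unconstrained(sm, fast_dictionary, (1, 1, 23), batch_size=10_000)
        assert np.array_equal(a.wt2, b.wt2)
        assert np.array_equal(a.ff, b.ff)
        assert np.array_equal(a.b1, b.b1)
        # BLAS blocking may differ with batch shape; scores agree to
        # floating-point rounding
        np.testing.assert_allclose(a.correlation, b.correlation, atol=1e-12)

    def test_off_grid_signal_lands_within_one_step(self, seq17, rect_profile, fast_dictionary):
        """A noiseless signal at wT2 = 45.5 ms, FF = 0.10, B1 = 1 matches
        to within one grid step in wT2 and FF."""
        from wt2map import simulate_voxel_signal

        sig = simulate_voxel_signal(45.5, 0.10, 1.0, seq17, rect_profile)
        maps = match_unconstrained(_signal_matrix(sig[None]), fast_dictionary, (1, 1, 1))
        wt2_step = np.diff(fast_dictionary.grid.wt2_values)[0]
        assert abs(maps.wt2[0, 0, 0] - 45.5) <= wt2_step
        assert abs(maps.ff[0, 0, 0] - 0.10) <= 0.01 + 1e-12

    def test_matrix_product_argmax_equals_exhaustive_search(self, fast_dictionary, rng):
        """The batched GEMM argmax agrees voxel-for-voxel with a brute
        force loop over entries."""
        rows = rng.random((8, 17)) + 0.01
        sm = _signal_matrix(rows)
        maps = match_unconstrained(sm, fast_dictionary, (1, 1, 8), batch_size=3)
        normed = rows / np.linalg.norm(rows, axis=1, keepdims=True)
        for v in range(8):
            scores = [float(normed[v] @ fast_dictionary.matrix[:, e])
                      for e in range(fast_dictionary.n_entries)]
            best = int(np.argmax(scores))
            wt2, ff, b1 = fast_dictionary.entry_parameters(best)
            assert maps.wt2[0, 0, v] == wt2
            assert maps.ff[0, 0, v] == ff
            assert maps.b1[0, 0, v] == b1

    def test_self_recovery_of_all_columns_below_full_fat(self, reduced_dictionary):
        """Matching the dictionary against itself recovers every triple
        with FF < 1 at 17 and at 5 truncated echoes (FF = 1 columns are
        wT2-degenerate by construction)."""
        for d in (reduced_dictionary, truncate_echoes(reduced_dictionary, 5)):
            keep = d.index[:, 1] < 1.0
            sm = _signal_matrix(d.matrix.T[keep])
            maps = match_unconstrained(sm, d, (1, 1, int(keep.sum())))
            recovered = np.column_stack([maps.wt2[0, 0], maps.ff[0, 0], maps.b1[0, 0]])
            assert np.array_equal(recovered, d.index[keep])

    def test_echo_count_mismatch_rejected(self, fast_dictionary, rng):
        sm = _signal_matrix(rng.random((3, 8)))
        with pytest.raises(ValueError, match="echo count"):
            match_unconstrained(sm, fast_dictionary, (1, 1, 3))


class TestConstrained:
    def test_exact_grid_constraint_recovers_column(self, fast_dictionary):
        e = 4321
        wt2, ff, b1 = fast_dictionary.entry_parameters(e)
        sig = fast_dictionary.matrix[:, e]
        maps = match_constrained(_signal_matrix(sig[None]), fast_dictionary,
                                 np.array([ff]), (1, 1, 1))
        assert maps.wt2[0, 0, 0] == wt2
        assert maps.b1[0, 0, 0] == b1
        assert maps.ff[0, 0, 0] == ff

    def test_constraint_quantized_to_nearest_grid_value(self, fast_dictionary, rng):
        sig = rng.random((1, 17)) + 0.1
        maps = match_constrained(_signal_matrix(sig), fast_dictionary,
                                 np.array([0.503]), (1, 1, 1))
        assert maps.ff[0, 0, 0] == pytest.approx(0.50)

    def test_output_ff_equals_quantized_input_everywhere(self, fast_dictionary, rng):
        rows = rng.random((40, 17)) + 0.05
        ff_in = rng.random(40)
        sm = _signal_matrix(rows)
        maps = match_constrained(sm, fast_dictionary, ff_in, (1, 1, 40))
        grid_ff = fast_dictionary.grid.ff_values
        expected = grid_ff[np.abs(ff_in[:, None] - grid_ff).argmin(axis=1)]
        np.testing.assert_array_equal(maps.ff[0, 0], expected)

    def test_nan_constraint_falls_back_to_unconstrained(self, fast_dictionary, rng):
        rows = rng.random((5, 17)) + 0.05
        sm = _signal_matrix(rows)
        constrained = match_constrained(sm, fast_dictionary,
                                        np.full(5, np.nan), (1, 1, 5))
        unconstrained = match_unconstrained(sm, fast_dictionary, (1, 1, 5))
        assert np.array_equal(constrained.wt2, unconstrained.wt2)
        assert np.array_equal(constrained.ff, unconstrained.ff)

    def test_wrong_constraint_length_rejected(self, fast_dictionary, rng):
        sm = _signal_matrix(rng.random((4, 17)) + 0.1)
        with pytest.raises(ValueError, match="constraint"):
            match_constrained(sm, fast_dictionary, np.array([0.1, 0.2]), (1, 1, 4))


class TestMask:
    def test_zero_threshold_keeps_all_nonzero(self):
        img = np.array([[[0.0, 0.2], [0.5, 1.0]]])
        mask = make_mask(img, 0.0)
        assert mask.sum() == 3 and not mask[0, 0, 0]

    def test_uniform_zero_image_warns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            mask = make_mask(np.zeros((2, 4, 4)))
        assert not mask.any()

    def test_recovers_phantom_object_voxels(self, phantom42):
        """At SNR 50 the default threshold keeps >= 99% of true object
        voxels."""
        mask = make_mask(phantom42.mese.volume[..., 0], 0.05)
        obj = phantom42.region_labels > 0
        assert mask[obj].mean() >= 0.99

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            make_mask(np.ones((1, 2, 2)), 1.0)


def test_zero_norm_voxels_excluded_from_signal_matrix():
    vol = np.zeros((1, 2, 2, 4))
    vol[0, 0, 0] = [4, 3, 2, 1]
    sm = SignalMatrix.from_volume(vol)
    assert sm.n_voxels == 1
    np.testing.assert_array_equal(sm.voxel_coords, [[0, 0, 0]])
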