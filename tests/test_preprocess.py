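"""Spillover compensation, hot-pixel filtering and percentile normalization."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spatialimc import (
    ChannelNormalization,
    SpilloverMatrix,
    compensate_cell_table,
    compensate_spillover,
    filter_hot_pixels,
    make_spillover_matrix,
    normalize_percentile,
)


def _random_spillover(rng, n=6, max_frac=0.08):
    m = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < 0.4:
                m[i, j] = rng.uniform(0, max_frac)
    return SpilloverMatrix(m, [f"ch{k}" for k in range(n)])


class TestMakeSpilloverMatrix:
    def test_no_fractions_gives_identity(self):
        sm = make_spillover_matrix(["a", "b", "c"])
        assert np.array_equal(sm.matrix, np.eye(3))

    def test_single_fraction_placed(self):
        sm = make_spillover_matrix(["a", "b", "c"], {("a", "b"): 0.04})
        expected = np.eye(3)
        expected[0, 1] = 0.04
        assert np.array_equal(sm.matrix, expected)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError, match="plausible range"):
            make_spillover_matrix(["a", "b"], {("a", "b"): 0.5})

    def test_unknown_channel(self):
        with pytest.raises(ValueError, match="unknown channel"):
            make_spillover_matrix(["a", "b"], {("a", "zz"): 0.01})


class TestCompensateSpillover:
    def test_identity_is_passthrough(self):
        sm = SpilloverMatrix.identity(["a", "b", "c"])
        v = np.array([[5.0, 0.0, 2.5], [0.0, 0.0, 0.0]])
        assert np.allclose(compensate_spillover(v, sm), v)

    def test_two_channel_exact_solution(self):
        # observed (100, 4) with 4% spill a->b: the linear system solves to
        # (100, 0) exactly, the constraint being inactive
        sm = make_spillover_matrix(["a", "b"], {("a", "b"): 0.04})
        out = compensate_spillover(np.array([100.0, 4.0]), sm)
        assert np.allclose(out, [100.0, 0.0], atol=1e-10)

    def test_two_channel_nnls_case_matches_grid_search(self):
        # observed (0, 4): the unconstrained solution has a negative first
        # component; brute force over a fine non-negative grid confirms the
        # constrained minimizer is (0, 4)
        sm = make_spillover_matrix(["a", "b"], {("a", "b"): 0.04})
        obs = np.array([0.0, 4.0])
        out = compensate_spillover(obs, sm)

        grid = np.linspace(0, 8, 401)
        xx, yy = np.meshgrid(grid, grid, indexing="ij")
        cand = np.stack([xx.ravel(), yy.ravel()], axis=1)
        resid = np.linalg.norm(cand @ sm.matrix - obs, axis=1)
        best = cand[np.argmin(resid)]
        assert np.allclose(out, best, atol=0.03)
        assert np.allclose(out, [0.0, 4.0], atol=1e-10)

    def test_recovery_of_nonnegative_truth(self, rng):
        # 50 random well-conditioned matrices: corrupt then compensate
        for _ in range(50):
            sm = _random_spillover(rng)
            truth = rng.uniform(0, 100, size=(40, sm.n))
            corrupted = truth @ sm.matrix
            rec = compensate_spillover(corrupted, sm)
            err = np.abs(rec - truth).max() / max(truth.max(), 1.0)
            assert err < 1e-6

    def test_nnls_matches_scipy_on_noisy_events(self, rng):
        # quantization pushes unconstrained solutions negative; the batched
        # active-set path must agree with the reference Lawson-Hanson solver
        from scipy.optimize import nnls

        sm = _random_spillover(rng, n=5)
        truth = rng.uniform(0, 30, size=(200, 5))
        truth[rng.random(truth.shape) < 0.6] = 0.0
        corrupted = np.rint(truth @ sm.matrix)
        rec = compensate_spillover(corrupted, sm)
        a = sm.matrix.T
        for i in range(corrupted.shape[0]):
            ref, _ = nnls(a, corrupted[i])
            assert np.allclose(rec[i], ref, atol=1e-6)

    def test_negative_observation_rejected(self):
        sm = SpilloverMatrix.identity(["a", "b"])
        with pytest.raises(ValueError, match="non-negative"):
            compensate_spillover(np.array([-1.0, 0.0]), sm)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular|diagonal"):
            SpilloverMatrix(np.zeros((2, 2)), ["a", "b"])

    def test_dimension_mismatch_rejected(self):
        sm = SpilloverMatrix.identity(["a", "b"])
        with pytest.raises(ValueError, match="channels"):
            compensate_spillover(np.array([1.0, 2.0, 3.0]), sm)

    def test_table_mode(self):
        import pandas as pd

        sm = make_spillover_matrix(["a", "b"], {("a", "b"): 0.04})
        t = pd.DataFrame(
            {
                "cell_id": [1],
                "roi_id": ["r"],
                "centroid_x_um": [0.5],
                "centroid_y_um": [0.5],
                "area_um2": [1.0],
                "mean_m1": [100.0],
                "mean_m2": [4.0],
            }
        )
        out = compensate_cell_table(t, sm, ["m1", "m2"])
        assert out["mean_m2"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_property_roundtrip(self, seed):
        rng = np.random.default_rng(seed)
        sm = _random_spillover(rng, n=4)
        truth = rng.uniform(0, 50, size=(10, 4))
        rec = compensate_spillover(truth @ sm.matrix, sm)
        assert np.allclose(rec, truth, atol=1e-6 * max(1.0, truth.max()))


class TestHotPixelFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 7.0)
        assert np.array_equal(filter_hot_pixels(img, 50), img)

    def test_isolated_spike_removed(self):
        img = np.zeros((10, 10))
        img[4, 4] = 100.0
        out = filter_hot_pixels(img, 50)
        assert out[4, 4] == 0.0
        assert out.sum() == 0.0

    def test_spike_below_threshold_kept(self):
        img = np.zeros((10, 10))
        img[4, 4] = 40.0
        assert filter_hot_pixels(img, 50)[4, 4] == 40.0

    def test_uint16_images_supported(self):
        img = np.zeros((8, 8), dtype=np.uint16)
        img[3, 3] = 500
        out = filter_hot_pixels(img, 50)
        assert out.dtype == np.uint16
        assert out[3, 3] == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_idempotent_and_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.exponential(10, size=(40, 40))
        img[rng.random(img.shape) < 0.02] += 300  # sprinkle hot pixels
        once = filter_hot_pixels(img, 50)
        twice = filter_hot_pixels(once, 50)
        assert np.all(once <= img)
        assert np.array_equal(once, twice)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            filter_hot_pixels(np.zeros((4, 4)), -1)


class TestNormalizePercentile:
    def test_full_range_maps_to_unit_interval(self):
        v = np.arange(101, dtype=float)
        out = normalize_percentile(
            v, ChannelNormalization(low_percentile=0, high_percentile=100, background_threshold=0)
        )
        assert out.max() == 1.0
        assert out.min() == 0.0

    def test_all_zero_channel_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_percentile(np.zeros(50))
        assert np.all(out == 0)

    def test_constant_nonzero_channel_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            out = normalize_percentile(np.full(50, 3.0))
        assert np.all(out == 0)

    def test_count_above_high_percentile(self, rng):
        # of 1000 uniform draws, those above the brute-force 99.5th
        # percentile of the sample map to exactly 1.0
        v = rng.uniform(0.001, 1.0, size=1000)
        spec = ChannelNormalization(high_percentile=99.5, background_threshold=0)
        out = normalize_percentile(v, spec)
        p = np.percentile(v, 99.5)
        assert np.array_equal(out == 1.0, v >= p)
        assert 1 <= (out == 1.0).sum() <= 10

    def test_outputs_bounded_and_monotone(self, rng):
        v = rng.exponential(5, size=500)
        spec = ChannelNormalization(background_threshold=0.1)
        out = normalize_percentile(v, spec)
        assert out.min() >= 0 and out.max() <= 1
        order = np.argsort(v)
        above = out[order] > 0
        assert np.all(np.diff(out[order][above]) >= 0)

    def test_background_threshold_zeroes_small_values(self):
        v = np.array([0.0, 1.0, 2.0, 100.0])
        spec = ChannelNormalization(
            low_percentile=0, high_percentile=100, background_threshold=0.1
        )
        out = normalize_percentile(v, spec)
        assert out[1] == 0.0 and out[2] == 0.0 and out[3] == 1.0

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ChannelNormalization(low_percentile=50, high_percentile=50)
        with pytest.raises(ValueError):
            ChannelNormalization(background_threshold=1.0)
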