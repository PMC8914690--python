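"""Frustum-graph ternary pattern: oracle equivalence and invariances.

The naive per-block reference below re-evaluates the edge comparisons
with scalar arithmetic, independently of the vectorized implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grasptex.frustum import (
    BLOCK_LEN,
    BOTTOM_EDGES,
    CONNECTION_EDGES,
    MAP_ORDER,
    TOP_EDGES,
    block_to_matrix,
    compute_threshold,
    encode_matrix,
    extract_blocks,
    feature_names,
    frustum_features,
    map_signals,
    ternary_bits,
)


def naive_frustum(signal):
    """Brute-force reference: per-block loops, scalar comparisons."""
    signal = np.asarray(signal, dtype=float)
    d = np.std(signal, ddof=1) / 2.0
    n_blocks = signal.size - 48
    maps = {key: [] for key in MAP_ORDER}
    for i in range(n_blocks):
        mat = signal[i : i + 49].reshape(7, 7)
        for tag, edges in (("b", BOTTOM_EDGES), ("t", TOP_EDGES), ("c", CONNECTION_EDGES)):
            code1 = code2 = 0
            for j, ((r1, c1), (r2, c2)) in enumerate(edges):
                a, s = mat[r1 - 1, c1 - 1], mat[r2 - 1, c2 - 1]
                if a - s > d:
                    code1 += 2**j
                if a - s < -d:
                    code2 += 2**j
            maps[f"{tag}1"].append(code1)
            maps[f"{tag}2"].append(code2)
    hists = [np.bincount(maps[key], minlength=64) for key in MAP_ORDER]
    return np.concatenate(hists)


class TestThreshold:
    def test_zero_variance(self):
        assert compute_threshold([5, 5, 5, 5]) == 0.0

    def test_two_points(self):
        assert compute_threshold([0, 2]) == pytest.approx(np.sqrt(2) / 2)

    def test_ramp_sample_std(self):
        # sample std of 1..49 is sqrt(49*50/12) = 14.28869...
        expected = np.sqrt(49 * 50 / 12) / 2
        assert compute_threshold(np.arange(1, 50)) == pytest.approx(expected)

    def test_too_short(self):
        with pytest.raises(ValueError):
            compute_threshold([1.0])


class TestTernaryBits:
    @pytest.mark.parametrize(
        "a, s, d, expected",
        [
            (5, 1, 2, (1, 0)),
            (1, 5, 2, (0, 1)),
            (3, 1, 2, (0, 0)),  # a - s = d boundary -> both zero
            (1, 3, 2, (0, 0)),  # a - s = -d boundary
            (2, 2, 0, (0, 0)),
        ],
    )
    def test_cases(self, a, s, d, expected):
        assert ternary_bits(a, s, d) == expected


class TestBlocks:
    @pytest.mark.parametrize("n, expected", [(49, 1), (50, 2), (200, 152)])
    def test_block_count(self, n, expected):
        assert extract_blocks(np.zeros(n)).shape == (expected, BLOCK_LEN)

    def test_too_short(self):
        with pytest.raises(ValueError):
            extract_blocks(np.zeros(48))

    def test_matrix_row_major_roundtrip(self):
        block = np.arange(1, 50, dtype=float)
        mat = block_to_matrix(block)
        assert mat[0, 0] == 1 and mat[0, 6] == 7 and mat[1, 0] == 8 and mat[6, 6] == 49
        np.testing.assert_array_equal(mat.ravel(), block)

    def test_wrong_block_length(self):
        with pytest.raises(ValueError):
            block_to_matrix(np.zeros(48))


class TestEncodeMatrix:
    def test_constant_matrix_all_zero(self):
        assert encode_matrix(np.full((7, 7), 3.0), 0.0) == (0, 0, 0, 0, 0, 0)

    def test_ramp_block_codes(self):
        """Hand-derived oracle values for the row-major ramp 1..49 at d=0.5."""
        mat = block_to_matrix(np.arange(1, 50, dtype=float))
        assert encode_matrix(mat, 0.5) == (56, 7, 56, 7, 28, 35)

    def test_bit_weighting(self):
        # kernel-1 bottom bits are ordered LSB-first: only edge 1 firing -> 1,
        # only edge 6 firing -> 32
        weights = 2 ** np.arange(6)
        assert (np.array([1, 0, 0, 0, 0, 0]) * weights).sum() == 1
        mat = np.zeros((7, 7))
        # edge 6 of the bottom graph is (4,1)->(1,2): make only it fire
        mat[3, 0] = 10.0
        codes = encode_matrix(mat, 0.5)
        assert codes[0] & 32  # b1 has bit 6 set


class TestMapSignals:
    def test_constant_signal(self):
        maps = map_signals(np.ones(100))
        for key in MAP_ORDER:
            assert maps[key].shape == (52,)
            assert np.all(maps[key] == 0)

    def test_code_range(self, rng):
        maps = map_signals(rng.standard_normal(300))
        for key in MAP_ORDER:
            assert maps[key].min() >= 0 and maps[key].max() <= 63


class TestFrustumFeatures:
    def test_length_and_conservation(self, rng):
        x = rng.standard_normal(260)
        fv = frustum_features(x)
        assert fv.shape == (384,)
        np.testing.assert_array_equal(fv.reshape(6, 64).sum(axis=1), np.full(6, 260 - 48))

    def test_constant_signal_histogram(self):
        fv = frustum_features(np.full(100, 2.5))
        expected = np.zeros(384)
        expected[np.arange(6) * 64] = 52
        np.testing.assert_array_equal(fv, expected)

    def test_oracle_equivalence_many_signals(self, rng):
        """Vectorized implementation equals the brute-force per-block loop."""
        for _ in range(100):
            n = int(rng.integers(49, 501))
            x = rng.standard_normal(n)
            np.testing.assert_array_equal(frustum_features(x), naive_frustum(x))

    @given(
        st.integers(0, 2**32 - 1),
        st.floats(0.1, 50.0),
        st.floats(-100.0, 100.0),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_positive_affine_invariance(self, seed, a, b):
        x = np.random.default_rng(seed).standard_normal(120)
        np.testing.assert_array_equal(frustum_features(a * x + b), frustum_features(x))

    def test_negation_swaps_kernels(self, rng):
        """Negating the input exchanges the kernel-1 and kernel-2 histograms."""
        x = rng.standard_normal(200)
        fv = frustum_features(x).reshape(6, 64)
        fv_neg = frustum_features(-x).reshape(6, 64)
        for pair in (0, 2, 4):  # (b1,b2), (t1,t2), (c1,c2)
            np.testing.assert_array_equal(fv_neg[pair], fv[pair + 1])
            np.testing.assert_array_equal(fv_neg[pair + 1], fv[pair])

    def test_feature_names(self):
        names = feature_names()
        assert len(names) == 384
        assert names[0] == "b1_000" and names[-1] == "c2_063"
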