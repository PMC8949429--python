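"""Unit and property tests of the block-mean + center-symmetric coder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from veincode.features import (
    BlockSpec,
    InvalidBlockSpecError,
    VeinCode,
    block_mean_matrix,
    code_length,
    cs_lbp_tile,
    encode_image,
    neighbor_ring,
    pad_to_multiple,
    tile_partition,
)

from oracles import naive_encode


class TestPadToMultiple:
    def test_exact_multiple_unchanged(self):
        img = np.arange(16).reshape(4, 4)
        out = pad_to_multiple(img, BlockSpec(2, 2))
        assert out.shape == (4, 4)
        assert np.array_equal(out, img)

    def test_pads_rows_with_zeros(self):
        img = np.ones((5, 4)) * 9
        out = pad_to_multiple(img, BlockSpec(2, 2))
        assert out.shape == (6, 4)
        assert np.array_equal(out[:5], img)
        assert np.all(out[5] == 0)

    def test_single_pixel(self):
        out = pad_to_multiple(np.array([[7]]), BlockSpec(3, 3))
        assert out.shape == (3, 3)
        assert out[0, 0] == 7
        assert out.sum() == 7

    def test_invalid_spec_rejected(self):
        with pytest.raises(InvalidBlockSpecError):
            BlockSpec(0, 2)
        with pytest.raises(InvalidBlockSpecError):
            BlockSpec(3, -1)


class TestBlockMeanMatrix:
    @pytest.mark.parametrize(
        "img, spec, expected",
        [
            ([[10, 10], [10, 10]], (2, 2), [[10.0]]),
            ([[0, 4, 8, 12], [0, 4, 8, 12]], (2, 2), [[2.0, 10.0]]),
            # the second 2x2 block of a 3-row image gains a padding row of
            # zeros, halving its mean
            ([[6, 6], [6, 6], [6, 6]], (2, 2), [[6.0], [3.0]]),
        ],
    )
    def test_hand_examples(self, img, spec, expected):
        out = block_mean_matrix(np.array(img), BlockSpec(*spec))
        assert np.allclose(out, expected)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            block_mean_matrix(np.empty((0, 3)), BlockSpec(1, 1))


class TestTilePartition:
    def test_exact_3x3(self):
        M = np.arange(9).reshape(3, 3)
        tiles = tile_partition(M)
        assert tiles.shape == (1, 3, 3)
        assert np.array_equal(tiles[0], M)

    def test_row_major_order(self):
        M = np.arange(18).reshape(3, 6)
        tiles = tile_partition(M)
        assert tiles.shape == (2, 3, 3)
        assert np.array_equal(tiles[0], M[:, :3])
        assert np.array_equal(tiles[1], M[:, 3:])

    def test_boundary_padding(self):
        M = np.ones((4, 4))
        tiles = tile_partition(M)
        assert tiles.shape == (4, 3, 3)
        # bottom-right tile keeps only the single (4,4) matrix entry
        corner = tiles[3]
        assert corner[0, 0] == 1
        assert corner.sum() == 1


class TestNeighborRing:
    def test_clockwise_read_off(self):
        tile = np.array([[1, 2, 3], [8, 0, 4], [7, 6, 5]])
        assert np.array_equal(neighbor_ring(tile), [1, 2, 3, 4, 5, 6, 7, 8])

    def test_center_never_read(self):
        tile = np.zeros((3, 3))
        tile[1, 1] = 99
        assert np.all(neighbor_ring(tile) == 0)

    def test_constant_tile(self):
        assert np.all(neighbor_ring(np.full((3, 3), 5.0)) == 5.0)


class TestCsLbpTile:
    @pytest.mark.parametrize(
        "ring, expected",
        [
            ([3, 3, 3, 3, 3, 3, 3, 3], [1, 1, 1, 1]),  # ties encode 1
            ([1, 2, 3, 4, 5, 6, 7, 8], [0, 0, 0, 0]),
            ([8, 7, 6, 5, 4, 3, 2, 1], [1, 1, 1, 1]),
        ],
    )
    def test_hand_examples(self, ring, expected):
        assert np.array_equal(cs_lbp_tile(np.array(ring)), expected)


class TestEncodeImage:
    def test_constant_image_single_tile(self):
        code = encode_image(np.full((9, 9), 50), BlockSpec(3, 3))
        assert len(code) == 4
        assert np.array_equal(code.bits, [1, 1, 1, 1])

    def test_length_for_raw_database_geometry(self, rng):
        # 513x256 at 3x8 blocks: p=171, q=32 -> 57*11 = 627 tiles -> 2508 bits
        img = rng.integers(0, 256, size=(513, 256))
        assert len(encode_image(img, BlockSpec(3, 8))) == 2508
        assert code_length((513, 256), BlockSpec(3, 8)) == 2508

    def test_affine_intensity_invariance(self, rng):
        img = rng.integers(0, 100, size=(24, 33)).astype(float)
        spec = BlockSpec(3, 4)
        # 1.5*x + 10 stays within [0, 160]: no clipping, order preserved
        assert encode_image(img, spec) == encode_image(1.5 * img + 10.0, spec)

    def test_deterministic(self, rng):
        img = rng.integers(0, 256, size=(30, 30))
        spec = BlockSpec(2, 5)
        assert encode_image(img, spec) == encode_image(img, spec)

    def test_rgb_input_uses_luminance(self, rng):
        gray = rng.integers(0, 256, size=(12, 12))
        rgb = np.repeat(gray[:, :, None], 3, axis=2)
        assert encode_image(rgb, BlockSpec(2, 2)) == encode_image(gray, BlockSpec(2, 2))

    def test_matches_naive_oracle_on_random_images(self, rng):
        for _ in range(100):
            A, B = rng.integers(1, 31, size=2)
            a = int(rng.integers(1, A + 1))
            b = int(rng.integers(1, B + 1))
            img = rng.integers(0, 256, size=(A, B))
            got = encode_image(img, BlockSpec(a, b))
            expected = naive_encode(img, a, b)
            assert np.array_equal(got.bits, expected), (A, B, a, b)
            assert len(got) == code_length((A, B), BlockSpec(a, b))


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    A=st.integers(1, 40), B=st.integers(1, 40),
    a=st.integers(1, 10), b=st.integers(1, 10),
)
def test_length_law(A, B, a, b):
    """L = 4 * ceil(p/3) * ceil(q/3) with p = ceil(A/a), q = ceil(B/b)."""
    img = np.zeros((A, B))
    p = -(-A // a)
    q = -(-B // b)
    assert len(encode_image(img, BlockSpec(a, b))) == 4 * -(-p // 3) * -(-q // 3)


def test_veincode_validation():
    with pytest.raises(ValueError):
        VeinCode([])
    with pytest.raises(ValueError):
        VeinCode([1, 0, 1])  # not a multiple of 4
    with pytest.raises(ValueError):
        VeinCode([1, 0, 2, 0])
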