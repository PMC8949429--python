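"""Block-averaged center-symmetric LBP (BACS-LBP) feature coding.

A grayscale vein image is turned into a fixed-length binary codeword in
four stages:

1. zero-pad the image on the bottom/right so its height and width are
   multiples of the block size ``a x b``;
2. replace each block by its arithmetic mean, giving a ``p x q`` block-mean
   matrix with ``p = ceil(A/a)``, ``q = ceil(B/b)`` (padding zeros are
   included in boundary means);
3. partition the block-mean matrix into non-overlapping 3x3 tiles in
   row-major order, again zero-padding ragged boundaries;
4. encode each tile with the center-symmetric comparison rule -- bit ``j``
   is 1 iff the border neighbour ``n_j`` is >= its diametrically opposite
   neighbour ``n_{j+4}`` -- and concatenate the 4-bit tile codes.

The resulting code has length ``L = 4 * ceil(p/3) * ceil(q/3)`` bits and is
invariant under positive affine intensity maps (no clipping), since only
order relations between block means are used.

Neighbour convention: ``n1..n8`` walk the tile border clockwise starting at
the top-left entry; the tile center is never read.  Codes produced under a
different border ordering are not comparable, so the serialization header
tags this convention (see :mod:`veincode.codecio`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BlockSpec",
    "VeinCode",
    "as_gray",
    "pad_to_multiple",
    "block_mean_matrix",
    "tile_partition",
    "neighbor_ring",
    "cs_lbp_tile",
    "encode_image",
    "code_length",
]

#: version tag of the border-walk convention used by :func:`neighbor_ring`
NEIGHBOR_CONVENTION = "cw-tl-v1"

# (row, col) offsets of n1..n8: clockwise border walk from the top-left
# corner of a 3x3 tile.  The center (1, 1) is deliberately absent.
_RING_INDEX = np.array(
    [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]
)


class InvalidBlockSpecError(ValueError):
    """Block dimensions are not positive integers."""


@dataclass(frozen=True)
class BlockSpec:
    """Pooling block size: ``a`` rows by ``b`` columns of pixels."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not (isinstance(self.a, (int, np.integer)) and isinstance(self.b, (int, np.integer))):
            raise InvalidBlockSpecError(f"block dims must be integers, got {self.a!r}x{self.b!r}")
        if self.a < 1 or self.b < 1:
            raise InvalidBlockSpecError(f"block dims must be >= 1, got {self.a}x{self.b}")

    @classmethod
    def parse(cls, text: str) -> "BlockSpec":
        """Parse an ``AxB`` string such as ``"3x8"`` (rows x cols)."""
        try:
            a, b = text.lower().split("x")
            return cls(int(a), int(b))
        except (ValueError, TypeError) as exc:
            raise InvalidBlockSpecError(f"cannot parse block spec {text!r}; expected 'AxB'") from exc

    def __str__(self) -> str:
        return f"{self.a}x{self.b}"


class VeinCode:
    """Fixed-length binary vein codeword ``x = x1 || x2 || ... || xm``.

    ``bits`` is a 1-D uint8 array of 0/1 values whose length ``L`` is a
    positive multiple of 4 (four bits per 3x3 tile).  Instances are
    immutable and hashable so they can serve as dict keys / set members.
    """

    __slots__ = ("_bits",)

    def __init__(self, bits) -> None:
        arr = np.asarray(bits)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("vein code must be a non-empty 1-D bit sequence")
        if arr.size % 4 != 0:
            raise ValueError(f"vein code length must be a multiple of 4, got {arr.size}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("vein code bits must be 0 or 1")
        arr = arr.astype(np.uint8)
        arr.setflags(write=False)
        object.__setattr__(self, "_bits", arr)

    @property
    def bits(self) -> np.ndarray:
        """Read-only uint8 array of 0/1 values, length ``L``."""
        return self._bits

    def packed(self) -> np.ndarray:
        """MSB-first byte packing, zero-padded to a whole byte."""
        return np.packbits(self._bits)

    @classmethod
    def from_packed(cls, payload: np.ndarray, length: int) -> "VeinCode":
        bits = np.unpackbits(np.asarray(payload, dtype=np.uint8), count=length)
        return cls(bits)

    def __len__(self) -> int:
        return int(self._bits.size)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VeinCode):
            return NotImplemented
        return self._bits.shape == other._bits.shape and bool(
            np.array_equal(self._bits, other._bits)
        )

    def __hash__(self) -> int:
        return hash(self._bits.tobytes())

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        head = "".join(map(str, self._bits[:16]))
        tail = "..." if len(self) > 16 else ""
        return f"VeinCode(L={len(self)}, bits={head}{tail})"


def as_gray(img) -> np.ndarray:
    """Coerce an image to a 2-D float array of intensities in [0, 255].

    RGB(A) input is collapsed with the ITU-R 601 luminance weights; images
    with more than 8 bits of depth are rescaled to the 0..255 range.
    """
    arr = np.asarray(img)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr.astype(np.float64) @ np.array([0.299, 0.587, 0.114])
    elif arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale or 3-D color image, got ndim={arr.ndim}")
    arr = arr.astype(np.float64)
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite intensities")
    if arr.min() < 0:
        raise ValueError("image contains negative intensities")
    if arr.max() > 255:  # >8-bit depth: rescale full range into [0, 255]
        arr = arr * (255.0 / arr.max())
    return arr


def pad_to_multiple(img: np.ndarray, spec: BlockSpec) -> np.ndarray:
    """Zero-pad on the bottom/right to the next multiple of the block size.

    The original pixels are preserved at the top-left; appended entries are
    exactly 0.  An image already sized to a multiple is returned unchanged
    (same array, no copy).
    """
    arr = as_gray(img)
    A, B = arr.shape
    pad_r = (-A) % spec.a
    pad_c = (-B) % spec.b
    if pad_r == 0 and pad_c == 0:
        return arr
    return np.pad(arr, ((0, pad_r), (0, pad_c)), mode="constant", constant_values=0)


def block_mean_matrix(img: np.ndarray, spec: BlockSpec) -> np.ndarray:
    """Per-block means of the zero-padded image.

    Returns a ``p x q`` float matrix with ``p = ceil(A/a)``,
    ``q = ceil(B/b)``.  Padding zeros participate in boundary-block means,
    which biases those means low; this is the canonical behaviour (pad
    first, then average).
    """
    padded = pad_to_multiple(img, spec)
    p = padded.shape[0] // spec.a
    q = padded.shape[1] // spec.b
    return padded.reshape(p, spec.a, q, spec.b).mean(axis=(1, 3))


def _pad_to_tiles(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("block-mean matrix must be a non-empty 2-D array")
    pad_r = (-M.shape[0]) % 3
    pad_c = (-M.shape[1]) % 3
    if pad_r or pad_c:
        M = np.pad(M, ((0, pad_r), (0, pad_c)), mode="constant", constant_values=0)
    return M


def tile_partition(M: np.ndarray) -> np.ndarray:
    """Partition a matrix into non-overlapping 3x3 tiles, row-major.

    Ragged boundaries are zero-padded.  Returns an ``(m, 3, 3)`` array with
    ``m = ceil(p/3) * ceil(q/3)``.
    """
    Mp = _pad_to_tiles(M)
    P, Q = Mp.shape[0] // 3, Mp.shape[1] // 3
    return Mp.reshape(P, 3, Q, 3).transpose(0, 2, 1, 3).reshape(P * Q, 3, 3)


def neighbor_ring(tile: np.ndarray) -> np.ndarray:
    """The eight border entries ``n1..n8`` of a 3x3 tile.

    Fixed convention (tag ``cw-tl-v1``): clockwise from the top-left entry,
    so the center-symmetric opposite of ``n_j`` is ``n_{j+4}``.  The tile
    center is excluded.
    """
    t = np.asarray(tile, dtype=np.float64)
    if t.shape != (3, 3):
        raise ValueError(f"tile must be 3x3, got shape {t.shape}")
    return t[_RING_INDEX[:, 0], _RING_INDEX[:, 1]]


def cs_lbp_tile(ring: np.ndarray) -> np.ndarray:
    """4-bit center-symmetric code of a neighbour ring.

    Bit ``j`` (j = 1..4, emitted in order) is 1 iff ``n_j >= n_{j+4}``;
    ties therefore encode 1.
    """
    r = np.asarray(ring, dtype=np.float64)
    if r.shape != (8,):
        raise ValueError(f"neighbour ring must have 8 entries, got shape {r.shape}")
    return (r[:4] >= r[4:]).astype(np.uint8)


def encode_image(img, spec: BlockSpec) -> VeinCode:
    """BACS-LBP codeword of a grayscale image under a block spec.

    Equivalent to ``cs_lbp_tile(neighbor_ring(t))`` concatenated over
    ``tile_partition(block_mean_matrix(img, spec))`` in row-major order,
    but computed with vectorized comparisons.
    """
    M = _pad_to_tiles(block_mean_matrix(img, spec))
    P, Q = M.shape[0] // 3, M.shape[1] // 3
    tiles = M.reshape(P, 3, Q, 3).transpose(0, 2, 1, 3)  # (P, Q, 3, 3)
    bits = np.empty((P, Q, 4), dtype=np.uint8)
    for j, ((r1, c1), (r2, c2)) in enumerate(zip(_RING_INDEX[:4], _RING_INDEX[4:])):
        bits[:, :, j] = tiles[:, :, r1, c1] >= tiles[:, :, r2, c2]
    return VeinCode(bits.reshape(-1))


def code_length(shape: tuple[int, int], spec: BlockSpec) -> int:
    """Codeword length L for an ``A x B`` image: ``4*ceil(p/3)*ceil(q/3)``."""
    A, B = shape
    p = -(-A // spec.a)
    q = -(-B // spec.b)
    return 4 * -(-p // 3) * -(-q // 3)
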