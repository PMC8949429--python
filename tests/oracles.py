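"""Independent reference implementations used to cross-check the package.

These deliberately use explicit Python loops and per-step padding so they
share no code path with the vectorized implementations they validate.
"""

import math

import numpy as np

# clockwise border walk from the top-left corner of a 3x3 tile
RING = [(0, 0), (0, 1), (0, 2), (1, 2), (2, 2), (2, 1), (2, 0), (1, 0)]


def naive_encode(img, a, b):
    """Triple-loop reference coder: pad, per-block mean, per-tile compare."""
    img = np.asarray(img, dtype=float)
    A, B = img.shape
    Ap, Bp = math.ceil(A / a) * a, math.ceil(B / b) * b
    padded = np.zeros((Ap, Bp))
    padded[:A, :B] = img

    p, q = Ap // a, Bp // b
    means = np.zeros((p, q))
    for i in range(p):
        for j in range(q):
            means[i, j] = padded[i * a:(i + 1) * a, j * b:(j + 1) * b].mean()

    pt, qt = math.ceil(p / 3), math.ceil(q / 3)
    tiled = np.zeros((pt * 3, qt * 3))
    tiled[:p, :q] = means

    bits = []
    for ti in range(pt):
        for tj in range(qt):
            tile = tiled[ti * 3:ti * 3 + 3, tj * 3:tj * 3 + 3]
            ring = [tile[r, c] for r, c in RING]
            for j in range(4):
                bits.append(1 if ring[j] >= ring[j + 4] else 0)
    return np.array(bits, dtype=np.uint8)


def naive_hamming(x_bits, y_bits):
    """Per-bit loop popcount of the XOR of two bit sequences."""
    assert len(x_bits) == len(y_bits)
    count = 0
    for xb, yb in zip(x_bits, y_bits):
        if int(xb) != int(yb):
            count += 1
    return count
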