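"""3x3 local binary pattern (LBP) codes.

Each pixel receives an 8-bit code by thresholding its eight 3x3
neighbours against the centre value: bit k is set iff neighbour k is
greater than or equal to the centre.  Ties count as 1, so a flat region
codes to 255.  Bits are ordered clockwise starting at the top-left
neighbour:

    k:        0   1   2   3   4   5   6   7
    position: NW  N   NE  E   SE  S   SW  W

The codes serve two roles downstream: their per-edge Hamming distance is
the texture term of the improved random-walker weights, and the code map
itself is a texture descriptor.  Because only differences between codes
are consumed, the choice of bit order is immaterial as long as it is
fixed; the order above is the documented convention.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

#: (row, col) offsets of the 8 neighbours, in bit order k = 0..7.
NEIGHBOR_OFFSETS: tuple[tuple[int, int], ...] = (
    (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1),
)


def lbp_code(window: np.ndarray) -> int:
    """8-bit LBP code of a single 3x3 patch (centre at [1, 1])."""
    w = np.asarray(window, dtype=np.float64)
    if w.shape != (3, 3):
        raise FormatError(f"LBP window must be 3x3, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise FormatError("LBP window contains non-finite values")
    center = w[1, 1]
    code = 0
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        if w[1 + dr, 1 + dc] >= center:
            code |= 1 << k
    return code


def lbp_map(image: np.ndarray) -> np.ndarray:
    """Per-pixel LBP codes with replicate padding (output shape = input shape).

    Returns a uint8 array; codes depend only on intensity *differences*,
    so the map is invariant to constant shifts and to any strictly
    increasing intensity transform.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] < 3 or img.shape[1] < 3:
        raise FormatError(f"expected a 2-D image of at least 3x3, got {img.shape}")
    padded = np.pad(img, 1, mode="edge")
    codes = np.zeros(img.shape, dtype=np.uint8)
    for k, (dr, dc) in enumerate(NEIGHBOR_OFFSETS):
        neighbor = padded[1 + dr:1 + dr + img.shape[0], 1 + dc:1 + dc + img.shape[1]]
        codes |= ((neighbor >= img).astype(np.uint8) << k)
    return codes


def normalized_hamming(codes_a: np.ndarray, codes_b: np.ndarray) -> np.ndarray:
    """Bitwise Hamming distance between 8-bit codes, divided by 8 (in [0, 1])."""
    a = np.asarray(codes_a, dtype=np.uint8)
    b = np.asarray(codes_b, dtype=np.uint8)
    return np.bitwise_count(a ^ b).astype(np.float64) / 8.0
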