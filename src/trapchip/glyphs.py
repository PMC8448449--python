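"""Etched-digit glyph bitmaps shared by the renderer and the decoder.

The apartment addresses on the chip are etched as small seven-segment-style
digits.  Renderer and decoder both read the same 7x5 bitmaps, so changing a
glyph invalidates both sides symmetrically.
"""

from __future__ import annotations

import numpy as np

_GLYPH_ROWS = {
    0: ("01110", "10001", "10001", "10001", "10001", "10001", "01110"),
    1: ("00100", "01100", "00100", "00100", "00100", "00100", "01110"),
    2: ("01110", "10001", "00001", "00010", "00100", "01000", "11111"),
    3: ("11111", "00010", "00100", "00010", "00001", "10001", "01110"),
    4: ("00010", "00110", "01010", "10010", "11111", "00010", "00010"),
    5: ("11111", "10000", "11110", "00001", "00001", "10001", "01110"),
    6: ("00110", "01000", "10000", "11110", "10001", "10001", "01110"),
    7: ("11111", "00001", "00010", "00100", "01000", "01000", "01000"),
    8: ("01110", "10001", "10001", "01110", "10001", "10001", "01110"),
    9: ("01110", "10001", "10001", "01111", "00001", "00010", "01100"),
}

GLYPH_SHAPE = (7, 5)


def digit_glyph(digit: int, scale: int = 2) -> np.ndarray:
    """Binary bitmap of one digit, nearest-neighbour upscaled by ``scale``."""
    rows = _GLYPH_ROWS[int(digit)]
    base = np.array([[c == "1" for c in r] for r in rows], dtype=float)
    return np.kron(base, np.ones((scale, scale)))


def glyph_bank(scale: int = 2) -> list[np.ndarray]:
    """All ten digit bitmaps at the given scale."""
    return [digit_glyph(d, scale) for d in range(10)]
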