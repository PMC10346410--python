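"""Independent reference implementation of the two-subiteration thinning
rules, used only as a test oracle.

Written deliberately in a different style from the package kernel: the
image is held as a set of foreground coordinates, neighborhoods are
assembled as bit strings, and the deletion conditions are transcribed
directly from their textbook statement.
"""

from __future__ import annotations

import numpy as np

# P2..P9: clockwise ring starting straight up, (drow, dcol)
RING = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def ring_bits(fg: set, r: int, c: int) -> str:
    return "".join("1" if (r + dr, c + dc) in fg else "0" for dr, dc in RING)


def n_count(bits: str) -> int:
    return bits.count("1")


def s_count(bits: str) -> int:
    cyc = bits + bits[0]
    return sum(1 for i in range(8) if cyc[i] == "0" and cyc[i + 1] == "1")


def removable(bits: str, subiteration: int) -> bool:
    p2, p4, p6, p8 = (int(bits[i]) for i in (0, 2, 4, 6))
    if not (2 <= n_count(bits) <= 6 and s_count(bits) == 1):
        return False
    if subiteration == 1:
        return p2 * p4 * p6 == 0 and p4 * p6 * p8 == 0
    return p2 * p4 * p8 == 0 and p2 * p6 * p8 == 0


def thin(mask: np.ndarray) -> np.ndarray:
    fg = {(int(r), int(c)) for r, c in zip(*np.nonzero(np.asarray(mask)))}
    while True:
        removed_any = False
        for sub in (1, 2):
            batch = [p for p in fg if removable(ring_bits(fg, *p), sub)]
            fg -= set(batch)
            removed_any = removed_any or bool(batch)
        if not removed_any:
            break
    out = np.zeros_like(np.asarray(mask), dtype=np.uint8)
    for r, c in fg:
        out[r, c] = 1
    return out
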