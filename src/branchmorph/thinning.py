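"""Zhang–Suen two-subiteration skeleton thinning.

The thinning operator reduces a thick binary region to a one-pixel-wide
curve (an approximation of the medial axis) by repeatedly peeling border
pixels whose 3x3 neighborhood satisfies a set of local conditions.  The
neighbors of a center pixel P1 are labelled clockwise starting from the
pixel directly above:

    P9 P2 P3
    P8 P1 P4
    P7 P6 P5

A foreground pixel is deleted when

  * 2 <= N(P1) <= 6, where N(P1) is the number of foreground neighbors,
  * S(P1) == 1, where S(P1) is the number of 0->1 transitions in the
    cyclic sequence P2, P3, ..., P9, P2,
  * sub-iteration 1: P2*P4*P6 == 0 and P4*P6*P8 == 0,
  * sub-iteration 2: P2*P4*P8 == 0 and P2*P6*P8 == 0.

Deletions within a sub-iteration are simultaneous (mark-then-delete);
the two sub-iterations alternate until a full round removes nothing.
The image is implicitly zero-padded, so border windows are well defined.

The module exposes the per-window predicates (`neighbor_count`,
`transition_count`, `step1_delete`, `step2_delete`), a vectorized
`zhang_suen_thin` used by the morphometry pipeline, and a literal
per-pixel `zhang_suen_thin_literal` retained as a slow, independent
cross-check of the vectorized code path.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "neighbor_count",
    "transition_count",
    "step1_delete",
    "step2_delete",
    "zhang_suen_thin",
    "zhang_suen_thin_literal",
]

# Clockwise neighbor offsets (row, col) for P2..P9 with row increasing down.
_NEIGHBOR_OFFSETS = (
    (-1, 0),   # P2 north
    (-1, 1),   # P3 north-east
    (0, 1),    # P4 east
    (1, 1),    # P5 south-east
    (1, 0),    # P6 south
    (1, -1),   # P7 south-west
    (0, -1),   # P8 west
    (-1, -1),  # P9 north-west
)


def _validate_window(window) -> tuple[int, ...]:
    w = tuple(int(v) for v in window)
    if len(w) != 8:
        raise ValueError(f"neighbor window needs 8 values P2..P9, got {len(w)}")
    if any(v not in (0, 1) for v in w):
        raise ValueError("neighbor window values must be binary")
    return w


def neighbor_count(window) -> int:
    """Number of foreground pixels among the 8 neighbors P2..P9."""
    return sum(_validate_window(window))


def transition_count(window) -> int:
    """Number of 0->1 transitions in the cyclic sequence P2,...,P9,P2."""
    w = _validate_window(window)
    return sum(1 for a, b in zip(w, w[1:] + w[:1]) if a == 0 and b == 1)


def step1_delete(window) -> bool:
    """Sub-iteration-1 deletion predicate for a foreground center pixel."""
    w = _validate_window(window)
    p2, _, p4, _, p6, _, p8, _ = w
    return (
        2 <= neighbor_count(w) <= 6
        and transition_count(w) == 1
        and p2 * p4 * p6 == 0
        and p4 * p6 * p8 == 0
    )


def step2_delete(window) -> bool:
    """Sub-iteration-2 deletion predicate for a foreground center pixel."""
    w = _validate_window(window)
    p2, _, p4, _, p6, _, p8, _ = w
    return (
        2 <= neighbor_count(w) <= 6
        and transition_count(w) == 1
        and p2 * p4 * p8 == 0
        and p2 * p6 * p8 == 0
    )


def _as_binary(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be strictly binary (values in {0, 1})")
    return arr.astype(np.uint8)


def _neighbor_stack(padded: np.ndarray) -> np.ndarray:
    """Stack of the 8 neighbor planes P2..P9 for every interior pixel."""
    h, w = padded.shape[0] - 2, padded.shape[1] - 2
    planes = np.empty((8, h, w), dtype=np.uint8)
    for k, (dr, dc) in enumerate(_NEIGHBOR_OFFSETS):
        planes[k] = padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
    return planes


def _deletion_mask(mask: np.ndarray, step: int) -> np.ndarray:
    padded = np.pad(mask, 1)
    nb = _neighbor_stack(padded)
    n = nb.sum(axis=0, dtype=np.int16)
    rolled = np.roll(nb, -1, axis=0)
    s = ((nb == 0) & (rolled == 1)).sum(axis=0, dtype=np.int16)
    p2, p4, p6, p8 = nb[0], nb[2], nb[4], nb[6]
    if step == 1:
        direction = (p2 * p4 * p6 == 0) & (p4 * p6 * p8 == 0)
    else:
        direction = (p2 * p4 * p8 == 0) & (p2 * p6 * p8 == 0)
    return (mask == 1) & (n >= 2) & (n <= 6) & (s == 1) & direction


def zhang_suen_thin(mask: np.ndarray) -> np.ndarray:
    """Thin a binary mask to its skeleton.

    Parameters
    ----------
    mask
        2-D array with values in {0, 1}; 1 is foreground.

    Returns
    -------
    numpy.ndarray
        uint8 skeleton mask of the same shape.  The skeleton is a subset
        of the input foreground and is a fixed point of the operator.
    """
    out = _as_binary(mask).copy()
    while True:
        d1 = _deletion_mask(out, step=1)
        out[d1] = 0
        d2 = _deletion_mask(out, step=2)
        out[d2] = 0
        if not d1.any() and not d2.any():
            return out


def zhang_suen_thin_literal(mask: np.ndarray) -> np.ndarray:
    """Per-pixel transcription of the thinning rules (slow reference).

    Functionally identical to :func:`zhang_suen_thin`; kept as an
    independent code path for cross-checking the vectorized kernel.
    """
    out = _as_binary(mask).copy()
    h, w = out.shape
    predicates = (step1_delete, step2_delete)
    while True:
        changed = False
        for predicate in predicates:
            marked = []
            rows, cols = np.nonzero(out)
            for r, c in zip(rows.tolist(), cols.tolist()):
                window = [
                    out[r + dr, c + dc]
                    if 0 <= r + dr < h and 0 <= c + dc < w
                    else 0
                    for dr, dc in _NEIGHBOR_OFFSETS
                ]
                if predicate(window):
                    marked.append((r, c))
            for r, c in marked:
                out[r, c] = 0
            changed = changed or bool(marked)
        if not changed:
            return out
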