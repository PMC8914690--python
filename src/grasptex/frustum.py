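"""Frustum-graph local ternary pattern features for 1-D signals.

The operator slides a stride-1 window of 49 samples along the signal,
reshapes each window row-major into a 7x7 matrix, and compares matrix
entries along three fixed 6-edge graphs drawn on the grid: the bottom
hexagon of a frustum, the top hexagon, and the six connecting edges.
Each directed edge (a -> s) is binarised twice against a global ternary
threshold d = std(signal)/2: an "upper" bit (a - s > d) and a "lower"
bit (a - s < -d). Per window this yields six 6-bit codes; their 64-bin
histograms over all windows, concatenated, are the 384 texture features.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "BOTTOM_EDGES",
    "TOP_EDGES",
    "CONNECTION_EDGES",
    "BLOCK_LEN",
    "compute_threshold",
    "ternary_bits",
    "extract_blocks",
    "block_to_matrix",
    "encode_matrix",
    "map_signals",
    "frustum_features",
    "feature_names",
]

BLOCK_LEN = 49  # 7x7 window

# Directed edges ((row, col) -> (row, col)), 1-based on the 7x7 grid.
BOTTOM_EDGES = (
    ((1, 2), (1, 6)),
    ((1, 6), (4, 7)),
    ((4, 7), (7, 6)),
    ((7, 6), (7, 2)),
    ((7, 2), (4, 1)),
    ((4, 1), (1, 2)),
)
TOP_EDGES = (
    ((2, 3), (2, 5)),
    ((2, 5), (4, 6)),
    ((4, 6), (6, 5)),
    ((6, 5), (6, 3)),
    ((6, 3), (4, 2)),
    ((4, 2), (2, 3)),
)
CONNECTION_EDGES = (
    ((1, 2), (2, 3)),
    ((1, 6), (2, 5)),
    ((4, 7), (4, 6)),
    ((7, 6), (6, 5)),
    ((7, 2), (6, 3)),
    ((4, 1), (4, 2)),
)

_GRAPHS = (BOTTOM_EDGES, TOP_EDGES, CONNECTION_EDGES)
_GRAPH_TAGS = ("b", "t", "c")

# Histogram concatenation order: bottom-k1, bottom-k2, top-k1, top-k2,
# connection-k1, connection-k2.
MAP_ORDER = ("b1", "b2", "t1", "t2", "c1", "c2")


def _flat(rc: tuple[int, int]) -> int:
    """Row-major flat index of a 1-based (row, col) grid coordinate."""
    r, c = rc
    return (r - 1) * 7 + (c - 1)


def _edge_indices(edges) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([_flat(e[0]) for e in edges])
    s = np.array([_flat(e[1]) for e in edges])
    return a, s


_EDGE_IDX = [_edge_indices(g) for g in _GRAPHS]
_BIT_WEIGHTS = 2 ** np.arange(6)  # bit 1 is least-significant


def compute_threshold(signal, ddof: int = 1) -> float:
    """Ternary threshold d = std(signal)/2 (sample convention by default)."""
    signal = np.asarray(signal, dtype=float)
    if signal.size < 2:
        raise ValueError("need at least two samples to compute a threshold")
    return float(np.std(signal, ddof=ddof)) / 2.0


def ternary_bits(a: float, s: float, d: float) -> tuple[int, int]:
    """Upper/lower ternary comparison of a against s at threshold d.

    Boundary cases a - s = +/- d map to (0, 0).
    """
    diff = a - s
    return int(diff > d), int(diff < -d)


def extract_blocks(signal) -> np.ndarray:
    """All stride-1 overlapping 49-sample blocks, shape (len-48, 49)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be one-dimensional")
    if signal.size < BLOCK_LEN:
        raise ValueError(f"signal length {signal.size} < block length {BLOCK_LEN}")
    return np.lib.stride_tricks.sliding_window_view(signal, BLOCK_LEN)


def block_to_matrix(block) -> np.ndarray:
    """Reshape one 49-sample block row-major into a 7x7 matrix."""
    block = np.asarray(block, dtype=float)
    if block.size != BLOCK_LEN:
        raise ValueError(f"block must have exactly {BLOCK_LEN} samples")
    return block.reshape(7, 7)


def encode_matrix(mat, d: float) -> tuple[int, int, int, int, int, int]:
    """Six 6-bit codes (b1, b2, t1, t2, c1, c2) for one 7x7 matrix."""
    mat = np.asarray(mat, dtype=float)
    if mat.shape != (7, 7):
        raise ValueError("matrix must be 7x7")
    flat = mat.ravel()
    codes = []
    for a_idx, s_idx in _EDGE_IDX:
        diff = flat[a_idx] - flat[s_idx]
        codes.append(int(((diff > d) * _BIT_WEIGHTS).sum()))
        codes.append(int(((diff < -d) * _BIT_WEIGHTS).sum()))
    return tuple(codes)


def map_signals(signal, d: float | None = None) -> dict[str, np.ndarray]:
    """Per-window code sequences for all six graph/kernel combinations.

    Returns a dict keyed ``b1, b2, t1, t2, c1, c2``; each value is an
    integer array of length len(signal) - 48 with values in [0, 63].
    The threshold defaults to half the standard deviation of the whole
    signal.
    """
    signal = np.asarray(signal, dtype=float)
    if d is None:
        d = compute_threshold(signal)
    blocks = extract_blocks(signal)  # (n_blocks, 49)
    out: dict[str, np.ndarray] = {}
    for (a_idx, s_idx), tag in zip(_EDGE_IDX, _GRAPH_TAGS):
        diff = blocks[:, a_idx] - blocks[:, s_idx]  # (n_blocks, 6)
        out[f"{tag}1"] = (diff > d) @ _BIT_WEIGHTS
        out[f"{tag}2"] = (diff < -d) @ _BIT_WEIGHTS
    return out


def frustum_features(signal, d: float | None = None) -> np.ndarray:
    """The 384 texture features: six 64-bin code histograms, concatenated.

    Each histogram sums to len(signal) - 48. Invariant under positive
    affine rescaling of the input (differences and the threshold scale
    together).
    """
    maps = map_signals(signal, d=d)
    hists = [np.bincount(maps[key], minlength=64) for key in MAP_ORDER]
    return np.concatenate(hists)


def feature_names() -> list[str]:
    """Stable column names for the 384 features (b1_000 .. c2_063)."""
    return [f"{key}_{b:03d}" for key in MAP_ORDER for b in range(64)]
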