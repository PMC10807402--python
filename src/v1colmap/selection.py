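"""Orientation-chip selection: nearest-prototype inference over a column.

Each receptive field's binarized GC vector is compared against the 19 chip
weight vectors of its own orientation column, by Euclidean distance or
cosine similarity (default cosine: the normalization mirrors the explicit
division stage of the selection datapath).  A bit-packed fast path stores
the binarized weights transposed by GC position -- one word per position,
bit b holding chip b's weight -- so all chips' contributions at one
position are accumulated simultaneously with population counts; it selects
exactly the same winner as the reference path run on the binarized weights.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Winner id reported for a blank field (all scores identically zero).
NO_ACTIVATION = -1

METRICS = ("euclidean", "cosine")


@dataclass(frozen=True)
class SelectionResult:
    rf_index: int
    winner_chip: int
    score: float
    metric: str
    activated: bool = True


def chip_distance(V: np.ndarray, W: np.ndarray, metric: str = "cosine") -> float:
    """Distance (euclidean) or similarity (cosine) between an input vector
    and one chip's weights.  Cosine with a zero vector is 0 by convention."""
    v = np.asarray(V, dtype=float).ravel()
    w = np.asarray(W, dtype=float).ravel()
    if v.shape != w.shape:
        raise ValueError(f"length mismatch: {v.size} vs {w.size}")
    if metric == "euclidean":
        return float(np.sqrt(np.sum((v - w) ** 2)))
    if metric == "cosine":
        nv, nw = np.linalg.norm(v), np.linalg.norm(w)
        if nv == 0.0 or nw == 0.0:
            return 0.0
        return float(np.dot(v, w) / (nv * nw))
    raise ValueError(f"metric must be one of {METRICS}")


def _scores(V: np.ndarray, weights: np.ndarray, metric: str) -> np.ndarray:
    """Per-chip scores; euclidean scores are squared distances (monotone
    equivalent, compared as such)."""
    v = np.asarray(V, dtype=float).ravel()
    W = np.asarray(weights, dtype=float)
    if W.ndim != 2 or W.shape[1] != v.size:
        raise ValueError(f"weights shape {W.shape} incompatible with input length {v.size}")
    if metric == "euclidean":
        d = W - v[None, :]
        return np.einsum("cd,cd->c", d, d)
    if metric == "cosine":
        nv = np.linalg.norm(v)
        nw = np.linalg.norm(W, axis=1)
        dots = W @ v
        out = np.zeros(W.shape[0])
        ok = (nw > 0) & (nv > 0)
        out[ok] = dots[ok] / (nv * nw[ok])
        return out
    raise ValueError(f"metric must be one of {METRICS}")


def select_chip(V: np.ndarray, weights: np.ndarray, metric: str = "cosine",
                rf_index: int = -1) -> SelectionResult:
    """Winner over a column's chips: argmin distance / argmax similarity,
    ties resolved to the lowest chip id.  A blank field under the cosine
    metric (all scores 0) reports the :data:`NO_ACTIVATION` sentinel."""
    W = np.asarray(weights, dtype=float)
    if W.size == 0:
        raise ValueError("empty (untrained) column")
    scores = _scores(V, W, metric)
    if metric == "euclidean":
        winner = int(np.argmin(scores))
        return SelectionResult(rf_index, winner, float(np.sqrt(scores[winner])),
                               metric, activated=bool(np.asarray(V).any()))
    winner = int(np.argmax(scores))
    if scores[winner] == 0.0:
        return SelectionResult(rf_index, NO_ACTIVATION, 0.0, metric, activated=False)
    return SelectionResult(rf_index, winner, float(scores[winner]), metric)


@dataclass
class BitPackedColumn:
    """Binarized column weights stored transposed by GC position.

    ``words[i]`` holds, in bit b, chip b's binarized weight at position i.
    """

    words: np.ndarray  # (input_dim,) uint64
    n_chips: int
    cut: float = 0.5

    def __post_init__(self) -> None:
        if self.n_chips > 64:
            raise ValueError("bit-packed storage supports at most 64 chips")


def binarize_weights(weights: np.ndarray, cut: float = 0.5) -> BitPackedColumn:
    """Threshold weights at ``cut`` (bit = 1 iff weight >= cut) and pack."""
    W = np.asarray(weights, dtype=float)
    n_chips, dim = W.shape
    bits = (W >= cut).astype(np.uint64)
    shifts = np.arange(n_chips, dtype=np.uint64)
    words = (bits << shifts[:, None]).sum(axis=0, dtype=np.uint64)
    return BitPackedColumn(words, n_chips, cut)


def unpack_weights(packed: BitPackedColumn) -> np.ndarray:
    """Recover the (n_chips, input_dim) binary weight matrix exactly."""
    shifts = np.arange(packed.n_chips, dtype=np.uint64)
    return ((packed.words[None, :] >> shifts[:, None]) & np.uint64(1)).astype(np.uint8)


def bitwise_select(V_binary: np.ndarray, packed: BitPackedColumn,
                   metric: str = "cosine", rf_index: int = -1) -> SelectionResult:
    """Winner via population counts on the packed words.

    For binary vectors, per-chip dot products are popcounts of the words at
    the input's active positions; then squared Euclidean distance is
    ``|V| + |W| - 2 dot`` and cosine is ``dot / sqrt(|V| |W|)`` (L1 norms).
    The winner is identical to :func:`select_chip` on the unpacked weights.
    """
    v = np.asarray(V_binary).ravel()
    if v.shape[0] != packed.words.shape[0]:
        raise ValueError("input length does not match packed column")
    if not np.isin(v, (0, 1)).all():
        raise ValueError("bitwise selection requires a binary input vector")
    shifts = np.arange(packed.n_chips, dtype=np.uint64)
    one = np.uint64(1)
    active = packed.words[v.astype(bool)]
    # popcount of masked words, one bit-plane per chip
    dots = ((active[None, :] >> shifts[:, None]) & one).sum(axis=1).astype(np.int64)
    w_norm1 = ((packed.words[None, :] >> shifts[:, None]) & one).sum(axis=1).astype(np.int64)
    v_norm1 = int(v.sum())
    if metric == "euclidean":
        sq = v_norm1 + w_norm1 - 2 * dots
        winner = int(np.argmin(sq))
        return SelectionResult(rf_index, winner, float(np.sqrt(sq[winner])),
                               metric, activated=bool(v_norm1))
    if metric == "cosine":
        sims = np.zeros(packed.n_chips)
        ok = (w_norm1 > 0) & (v_norm1 > 0)
        sims[ok] = dots[ok] / np.sqrt(float(v_norm1) * w_norm1[ok])
        winner = int(np.argmax(sims))
        if sims[winner] == 0.0:
            return SelectionResult(rf_index, NO_ACTIVATION, 0.0, metric, activated=False)
        return SelectionResult(rf_index, winner, float(sims[winner]), metric)
    raise ValueError(f"metric must be one of {METRICS}")


def comparator_tree_depth(n_candidates: int) -> int:
    """Rounds of pairwise comparison reducing n candidates to one:
    ceil(log2 n); 0 for a single candidate (19 chips -> 5 rounds)."""
    if n_candidates < 1:
        raise ValueError("need at least one candidate")
    if n_candidates == 1:
        return 0
    return math.ceil(math.log2(n_candidates))
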