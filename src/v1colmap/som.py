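"""Orientation columns trained as restricted-connectivity SOMs.

Every receptive field owns one orientation column of 19 chips.  A chip is a
prototype vector over the field's 81 binarized GC outputs.  Training is
competitive: the chip closest to the input wins and all chips move toward
the input,

    W_{t+1}(r) = W_t(r) + alpha * sigma(r, x) * (V_{t+1} - W_t(r))

with neighborhood  sigma(r, x) = exp(-||r - x||^2)  over the chip layout
(the layout distance is divided by a width parameter before squaring;
width 1 recovers the bare form) and learning rate  alpha = 1 / (1 + t/T).

Connectivity is restricted: a column sees only its own receptive field's GC
vector, never the rest of the image, and the 600 columns of a frame are
trained independently.  The iteration counter t advances once per presented
image and is shared by all columns.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import selection
from .ganglion import DOGParams, image_to_gc
from .tiling import TilingSpec, build_tiling, generate_index_matrices

DEFAULT_N_CHIPS = 19


@dataclass(frozen=True)
class ChipTopology:
    """Layout of the chips inside one column (shared by all columns)."""

    coords: np.ndarray       # (n_chips, 2) layout positions
    pairwise_dist: np.ndarray  # (n_chips, n_chips) Euclidean layout distances
    kind: str = "hex"

    @property
    def n_chips(self) -> int:
        return self.coords.shape[0]


def _topology_from_coords(coords: np.ndarray, kind: str) -> ChipTopology:
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    return ChipTopology(coords, dist, kind)


def hex_topology(n_rings: int = 2) -> ChipTopology:
    """Centred hexagonal chip layout: 1 + 3 r (r+1) chips for r rings
    (r = 2 gives the default 19), nearest-neighbour spacing 1."""
    pts = []
    for q in range(-n_rings, n_rings + 1):
        for r in range(-n_rings, n_rings + 1):
            if abs(q + r) <= n_rings:
                # axial -> cartesian
                pts.append((q + r / 2.0, r * np.sqrt(3.0) / 2.0))
    coords = np.array(sorted(pts, key=lambda p: (round(p[1], 6), round(p[0], 6))))
    return _topology_from_coords(coords, "hex")


def grid_topology(rows: int, cols: int) -> ChipTopology:
    rr, cc = np.mgrid[0:rows, 0:cols]
    coords = np.stack([cc.ravel().astype(float), rr.ravel().astype(float)], axis=1)
    return _topology_from_coords(coords, "grid")


def neighborhood(topology: ChipTopology, r: int, x: int, width: float = 1.0) -> float:
    """Learning-gain factor exp(-(d(r, x)/width)^2); 1 at the winner."""
    n = topology.n_chips
    if not (0 <= r < n and 0 <= x < n):
        raise ValueError(f"chip id out of range [0, {n})")
    d = topology.pairwise_dist[r, x] / width
    return float(np.exp(-d * d))


def neighborhood_matrix(topology: ChipTopology, width: float = 1.0) -> np.ndarray:
    d = topology.pairwise_dist / width
    return np.exp(-d * d)


def learning_rate(t: float, T: float) -> float:
    """alpha = 1 / (1 + t/T), decaying from 1 at t=0 to 1/2 at t=T."""
    if T <= 0:
        raise ValueError("total iteration count T must be > 0")
    if not 0 <= t <= T:
        raise ValueError("iteration counter t must lie in [0, T]")
    return 1.0 / (1.0 + t / T)


@dataclass(frozen=True)
class SOMConfig:
    T: int = 240
    neighborhood_width: float = 1.0
    init: str = "uniform_random"
    seed: int = 0
    input_form: str = "binary"   # "binary" | "graded"
    metric: str = "cosine"       # winner selection during training

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.init not in ("uniform_random", "data_sample"):
            raise ValueError("init must be 'uniform_random' or 'data_sample'")
        if self.input_form not in ("binary", "graded"):
            raise ValueError("input_form must be 'binary' or 'graded'")
        if self.metric not in selection.METRICS:
            raise ValueError(f"metric must be one of {selection.METRICS}")


@dataclass
class OrientationColumnSet:
    """One orientation column per receptive field.

    ``weights`` has shape (n_fields, n_chips, input_dim) with values in
    [0, 1]; ``t`` counts presented inputs so far.
    """

    weights: np.ndarray
    topology: ChipTopology
    config: SOMConfig
    tiling: TilingSpec | None = None
    t: int = 0

    @property
    def n_fields(self) -> int:
        return self.weights.shape[0]

    @property
    def n_chips(self) -> int:
        return self.weights.shape[1]

    @property
    def input_dim(self) -> int:
        return self.weights.shape[2]

    def column(self, rf_index: int) -> np.ndarray:
        return self.weights[rf_index]


def init_columns(tiling: TilingSpec, config: SOMConfig,
                 topology: ChipTopology | None = None,
                 input_dim: int | None = None) -> OrientationColumnSet:
    """Fresh columns with uniform-random weights in [0, 1)."""
    if topology is None:
        topology = hex_topology()
    if input_dim is None:
        input_dim = tiling.gcs_per_field
    rng = np.random.default_rng(config.seed)
    W = rng.uniform(0.0, 1.0, size=(tiling.n_fields, topology.n_chips, input_dim))
    return OrientationColumnSet(W, topology, config, tiling)


def som_step(column_weights: np.ndarray, V: np.ndarray, t: int, config: SOMConfig,
             topology: ChipTopology) -> tuple[np.ndarray, int]:
    """One competitive update of a single column; returns (weights, winner)."""
    v = np.asarray(V, dtype=float).ravel()
    W = np.asarray(column_weights, dtype=float)
    if W.shape[1] != v.size:
        raise ValueError(f"input length {v.size} does not match weights {W.shape}")
    res = selection.select_chip(v, W, metric=config.metric)
    if not res.activated:
        return W.copy(), selection.NO_ACTIVATION
    winner = res.winner_chip
    alpha = learning_rate(t, config.T)
    sig = neighborhood_matrix(topology, config.neighborhood_width)[winner]
    return W + alpha * sig[:, None] * (v[None, :] - W), winner


def som_step_batch(columns: OrientationColumnSet, V: np.ndarray) -> np.ndarray:
    """One update of every column from its own field's input (in place).

    ``V`` is (n_fields, input_dim).  Blank inputs (all-zero vectors) skip the
    update for their column and report winner -1.  Returns per-field winners.
    """
    W = columns.weights
    cfg = columns.config
    v = np.asarray(V, dtype=float)
    if v.shape != (W.shape[0], W.shape[2]):
        raise ValueError(f"input batch shape {v.shape} does not match columns "
                         f"{(W.shape[0], W.shape[2])}")
    active = v.any(axis=1)
    if cfg.metric == "cosine":
        dots = np.einsum("fcd,fd->fc", W, v)
        nw = np.linalg.norm(W, axis=2)
        nv = np.linalg.norm(v, axis=1)
        denom = nw * nv[:, None]
        scores = np.divide(dots, denom, out=np.zeros_like(dots), where=denom > 0)
        winners = np.argmax(scores, axis=1)
        active &= scores.max(axis=1) > 0
    else:
        d = W - v[:, None, :]
        sq = np.einsum("fcd,fcd->fc", d, d)
        winners = np.argmin(sq, axis=1)
    alpha = learning_rate(columns.t, cfg.T)
    nb = neighborhood_matrix(columns.topology, cfg.neighborhood_width)
    sig = nb[winners]                       # (n_fields, n_chips)
    sig = sig * active[:, None]             # blank fields: no update
    W += alpha * sig[:, :, None] * (v[:, None, :] - W)
    winners = np.where(active, winners, selection.NO_ACTIVATION)
    columns.t += 1
    return winners


def train(columns: OrientationColumnSet, corpus: Sequence[np.ndarray],
          dog_params: DOGParams | None = None, epochs: int = 1,
          tiling: TilingSpec | None = None) -> OrientationColumnSet:
    """Offline training pass: for each image, tile -> DOG -> binarize -> one
    SOM step per column on its own field's GC vector.

    ``columns.config.T`` should equal (or exceed) the number of presentations
    ``epochs * len(corpus)``; t advances once per presented image.
    """
    if len(corpus) == 0:
        raise ValueError("training corpus is empty")
    if dog_params is None:
        dog_params = DOGParams()
    tiling = tiling or columns.tiling
    if tiling is None:
        img0 = np.asarray(corpus[0])
        tiling = build_tiling(img0.shape[0], img0.shape[1])
        columns.tiling = tiling
    idx = generate_index_matrices(tiling)
    total = epochs * len(corpus)
    if columns.config.T < total:
        columns.config = replace(columns.config, T=total)
    for _ in range(epochs):
        for img in corpus:
            gc = image_to_gc(np.asarray(img), tiling, dog_params, idx)
            V = gc.fired if columns.config.input_form == "binary" else gc.graded
            som_step_batch(columns, V)
    return columns
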