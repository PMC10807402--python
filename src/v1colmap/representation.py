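"""End-to-end oriented-segment representation of images.

For every receptive field of an input image the pipeline runs
tile -> DOG -> binarize -> chip selection, attaches the winning chip's
preferred orientation, and renders the result as one short line segment per
active field (coloured by the same cyclic hue as the cortical map).  Blank
fields -- those whose GC vector never fires -- are omitted.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line

from . import selection
from .cortex import ChipTuning, axial_diff, orientation_rgb
from .ganglion import DOGParams, image_to_gc
from .som import OrientationColumnSet
from .stimuli import rotate90
from .tiling import TilingSpec, generate_index_matrices

RECORD_COLUMNS = ["rf_index", "rf_row", "rf_col", "winner_chip",
                  "orientation_deg", "score"]


@dataclass
class RepresentationResult:
    """Per-active-field winners and orientations for one image."""

    records: pd.DataFrame  # columns RECORD_COLUMNS
    tiling: TilingSpec
    metric: str

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    def orientation_grid(self) -> np.ndarray:
        """(n_rows, n_cols) grid of orientations, NaN for inactive fields."""
        grid = np.full((self.tiling.n_rows, self.tiling.n_cols), np.nan)
        rows = self.records["rf_row"].to_numpy(dtype=int)
        cols = self.records["rf_col"].to_numpy(dtype=int)
        grid[rows, cols] = self.records["orientation_deg"].to_numpy()
        return grid


def represent(img: np.ndarray, columns: OrientationColumnSet, tuning: ChipTuning,
              dog_params: DOGParams | None = None, metric: str = "cosine",
              bitwise: bool = False, score_floor: float = 0.0,
              binarize_cut: float = 0.5) -> RepresentationResult:
    """Represent one image by its per-field winning chips.

    ``bitwise`` routes selection through the bit-packed binarized-weight
    path.  Fields are dropped when blank, when the winner's score falls
    below ``score_floor``, or when the winning chip has no defined
    preferred orientation.
    """
    if columns.weights.size == 0:
        raise ValueError("columns are untrained/empty")
    if dog_params is None:
        dog_params = DOGParams()
    img = np.asarray(img)
    tiling = columns.tiling
    if tiling is None:
        raise ValueError("columns carry no tiling")
    if img.shape != (tiling.image_height, tiling.image_width):
        raise ValueError(f"image shape {img.shape} does not match the "
                         f"columns' tiling {(tiling.image_height, tiling.image_width)}")
    idx = generate_index_matrices(tiling)
    gc = image_to_gc(img, tiling, dog_params, idx)
    rows = []
    for f in range(tiling.n_fields):
        v = gc.fired[f]
        if not v.any():
            continue
        if bitwise:
            packed = selection.binarize_weights(columns.weights[f], binarize_cut)
            res = selection.bitwise_select(v, packed, metric=metric, rf_index=f)
        else:
            res = selection.select_chip(v, columns.weights[f], metric=metric,
                                        rf_index=f)
        if not res.activated or res.score < score_floor:
            continue
        theta = tuning.preferred[f, res.winner_chip]
        if np.isnan(theta):
            continue
        i, j = divmod(f, tiling.n_cols)
        rows.append((f, i, j, res.winner_chip, float(theta) % 180.0,
                     float(res.score)))
    records = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    return RepresentationResult(records, tiling, metric)


def render_segments(rep: RepresentationResult, background: int = 0) -> np.ndarray:
    """Draw one oriented segment per active field on an RGB canvas.

    Each segment is centred on its field's centre pixel, has length
    ``rf_side``, and is coloured by the cyclic orientation hue.
    """
    t = rep.tiling
    canvas = np.full((t.image_height, t.image_width, 3), background, dtype=np.uint8)
    half = t.rf_side / 2.0
    for rec in rep.records.itertuples(index=False):
        cy, cx = t.field_center(int(rec.rf_index))
        th = np.radians(rec.orientation_deg)
        dr, dc = -np.sin(th) * half, np.cos(th) * half
        r0, c0 = int(round(cy - dr)), int(round(cx - dc))
        r1, c1 = int(round(cy + dr)), int(round(cx + dc))
        rr, cc = _draw_line(r0, c0, r1, c1)
        ok = (rr >= 0) & (rr < t.image_height) & (cc >= 0) & (cc < t.image_width)
        color = orientation_rgb(np.array([[rec.orientation_deg]]))[0, 0]
        canvas[rr[ok], cc[ok]] = color
    return canvas


def orientation_histogram(rep: RepresentationResult,
                          n_bins: int = 12) -> tuple[np.ndarray, np.ndarray]:
    """Proportions of active fields per orientation bin over [0, 180).

    Returns (proportions summing to 1, bin edges); an empty representation
    yields all zeros with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    if len(rep) == 0:
        warnings.warn("empty representation: returning an all-zero histogram")
        return np.zeros(n_bins), edges
    counts, _ = np.histogram(rep.records["orientation_deg"], bins=edges)
    return counts / counts.sum(), edges


@dataclass
class RotationReport:
    k: int
    match_fraction: float
    n_matched: int
    n_union: int
    tol_deg: float


def rotation_check(img: np.ndarray, columns: OrientationColumnSet,
                   tuning: ChipTuning, dog_params: DOGParams | None = None,
                   k: int = 1, tol_deg: float = 15.0,
                   metric: str = "cosine") -> RotationReport:
    """Quarter-turn equivariance of the representation.

    Rotating a square image by 90k degrees should rotate the active-field
    grid and shift every orientation by 90k (mod 180).  A field matches when
    it is active in both representations and the axial orientation
    difference is within ``tol_deg``; the match fraction is over the union
    of active fields.
    """
    img = np.asarray(img)
    t = columns.tiling
    if img.shape[0] != img.shape[1]:
        raise ValueError("rotation check requires a square image")
    if t is None or (t.image_height - t.rf_side) % t.stride != 0:
        raise ValueError("tiling is not 90-degree symmetric "
                         "((M - rf_side) must be divisible by stride)")
    rep_a = represent(img, columns, tuning, dog_params, metric=metric)
    rep_b = represent(rotate90(img, k), columns, tuning, dog_params, metric=metric)
    grid_a = rep_a.orientation_grid()
    grid_b = rep_b.orientation_grid()
    expected = (np.rot90(grid_a, k) + 90.0 * k) % 180.0
    act_e, act_b = ~np.isnan(expected), ~np.isnan(grid_b)
    union = act_e | act_b
    both = act_e & act_b
    matched = both & (axial_diff(expected, np.nan_to_num(grid_b)) <= tol_deg)
    n_union = int(union.sum())
    n_matched = int(matched.sum())
    frac = 1.0 if n_union == 0 else n_matched / n_union
    return RotationReport(k, frac, n_matched, n_union, tol_deg)
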