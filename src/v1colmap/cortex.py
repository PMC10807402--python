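"""Chip characterization and cortical orientation maps.

A trained chip's preferred orientation is measured by probing: an oriented
bar patch the size of one receptive field is pushed through the DOG +
binarization stage, and the chip's response is the cosine similarity of its
weights to the resulting GC vector.  Preferred orientation is the axial
(180-degree-periodic) circular mean of the top responses; selectivity is
1 minus the circular variance of the baseline-subtracted tuning curve on
doubled angles (0 for a flat curve).

The map places every column's 19 chips into a small block on the column
grid, colors each cell by a cyclic hue over [0, 180), and detects pinwheel
singularities as 2x2 plaquettes whose wrapped orientation differences wind
by +-180 degrees.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage as _ndi

from .ganglion import DOGParams, binarize, compute_threshold, gc_response
from .som import ChipTopology, OrientationColumnSet
from .stimuli import StimulusSpec, make_bar


@dataclass
class ChipTuning:
    """Per-chip tuning over a set of probe orientations.

    ``preferred`` is NaN where the tuning curve is flat (undefined).
    Shapes: curves (n_fields, n_chips, n_probes), preferred / selectivity
    (n_fields, n_chips).
    """

    probe_orientations: np.ndarray
    curves: np.ndarray
    preferred: np.ndarray
    selectivity: np.ndarray


def axial_mean(angles_deg: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Weighted circular mean of axial (period-180) angles, in [0, 180)."""
    a = np.radians(np.asarray(angles_deg, dtype=float) * 2.0)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    s, c = np.sum(w * np.sin(a)), np.sum(w * np.cos(a))
    return float(np.degrees(np.arctan2(s, c)) / 2.0 % 180.0)


def axial_diff(a_deg, b_deg):
    """Smallest absolute axial difference, in [0, 90]."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    return np.minimum(d, 180.0 - d)


def probe_gc_vector(orientation_deg: float, rf_side: int, dog_params: DOGParams,
                    bar_width: float = 3.0, contrast: float = 1.0,
                    offset: float = 0.0) -> np.ndarray:
    """Binarized GC vector of an oriented bar patch of one field's size.

    ``offset`` displaces the bar along its own normal (perpendicular to the
    bar axis), so a sweep over offsets covers every position at which a bar
    of that orientation can cross the field.  The threshold is the
    (max - min) * alpha rule over the patch itself.
    """
    th = np.radians(orientation_deg)
    spec = StimulusSpec(kind="bar", height=rf_side, width=rf_side,
                        orientation_deg=orientation_deg, bar_width=bar_width,
                        contrast=contrast,
                        center_offset=(-offset * np.cos(th), -offset * np.sin(th)))
    patch = make_bar(spec)
    graded = gc_response(patch.ravel(), dog_params, rf_side)
    thr = compute_threshold(graded, dog_params.alpha_threshold)
    return binarize(graded, thr, dog_params.pathway)


def probe_tuning(columns: OrientationColumnSet,
                 probe_orientations: np.ndarray | list,
                 dog_params: DOGParams | None = None,
                 bar_width: float = 3.0,
                 top_fraction: float = 0.9,
                 offsets: np.ndarray | list | None = None) -> ChipTuning:
    """Measure every chip's tuning curve, preferred orientation, selectivity.

    Chips learn position as well as orientation (inputs of one orientation
    at well-separated positions are nearly orthogonal binary patterns), so
    each orientation is probed at a sweep of perpendicular ``offsets``
    spanning the field -- the analogue of sweeping a grating's phase -- and
    a chip's response is its best cosine match over the sweep.  The default
    sweep is integer offsets covering the whole field including its
    corners.  ``top_fraction`` sets which probes count as "top responses"
    for the preferred-orientation mean (those within that fraction of the
    peak).
    """
    probes = np.asarray(probe_orientations, dtype=float)
    if probes.size < 4:
        raise ValueError("need at least 4 probe orientations")
    if columns.weights.size == 0:
        raise ValueError("columns are untrained/empty")
    if dog_params is None:
        dog_params = DOGParams()
    rf_side = int(round(np.sqrt(columns.input_dim)))
    if offsets is None:
        reach = rf_side // 2 + 2  # past the corners of the field
        offsets = np.arange(-reach, reach + 1, dtype=float)
    W = columns.weights                                   # (F, C, D)
    norms_w = np.linalg.norm(W, axis=2)                   # (F, C)
    curves = np.zeros((W.shape[0], W.shape[1], probes.size))
    for pi, th in enumerate(probes):
        best = np.zeros_like(norms_w)
        for off in offsets:
            v = probe_gc_vector(th, rf_side, dog_params, bar_width,
                                offset=float(off)).astype(float)
            nv = np.linalg.norm(v)
            if nv == 0:
                continue
            dots = np.einsum("fcd,d->fc", W, v)
            sim = np.divide(dots, norms_w * nv, out=np.zeros_like(dots),
                            where=norms_w > 0)
            np.maximum(best, sim, out=best)
        curves[:, :, pi] = best

    F, C, P = curves.shape
    preferred = np.full((F, C), np.nan)
    selectivity = np.zeros((F, C))
    a2 = np.radians(probes * 2.0)
    for f in range(F):
        for c in range(C):
            curve = curves[f, c]
            mx, mn = curve.max(), curve.min()
            if mx <= 0 or mx == mn:
                continue  # flat or silent: undefined preference
            shifted = curve - mn
            top = curve >= top_fraction * mx
            preferred[f, c] = axial_mean(probes[top], curve[top])
            R = np.abs(np.sum(shifted * np.exp(1j * a2))) / shifted.sum()
            selectivity[f, c] = float(R)
    return ChipTuning(probes, curves, preferred, selectivity)


# ---------------------------------------------------------------------------
# Map layout: one 5x5 block per column, hexagon rows padded at the corners.


def _hex_block_slots(topology: ChipTopology) -> tuple[np.ndarray, int]:
    """Assign each chip a cell in a square block covering the hex layout.

    Rows of the hexagon (grouped by layout y) are centred in a block whose
    side is the longest row; returns (n_chips, 2) block coordinates and the
    block side length.
    """
    ys = np.round(topology.coords[:, 1], 6)
    xs = topology.coords[:, 0]
    row_vals = np.unique(ys)
    side = max(len(row_vals),
               max(int((ys == y).sum()) for y in row_vals))
    slots = np.zeros((topology.n_chips, 2), dtype=int)
    for bi, y in enumerate(row_vals):
        ids = np.where(ys == y)[0]
        ids = ids[np.argsort(xs[ids])]
        start = (side - len(ids)) // 2
        for k, cid in enumerate(ids):
            slots[cid] = (bi, start + k)
    return slots, side


def orientation_field(columns: OrientationColumnSet, tuning: ChipTuning,
                      fill_undefined: bool = True) -> np.ndarray:
    """Global orientation field: per-column blocks of chip preferences.

    The result is (block * n_rows, block * n_cols) degrees in [0, 180);
    cells without a chip, or whose chip has no defined preference, are NaN
    unless ``fill_undefined`` (nearest defined cell wins, deterministically).
    """
    if columns.tiling is None:
        raise ValueError("columns carry no tiling; train or set tiling first")
    slots, side = _hex_block_slots(columns.topology)
    m, n = columns.tiling.n_rows, columns.tiling.n_cols
    field = np.full((side * m, side * n), np.nan)
    for f in range(columns.n_fields):
        bi, bj = divmod(f, n)
        for c in range(columns.n_chips):
            r, s = slots[c]
            field[bi * side + r, bj * side + s] = tuning.preferred[f, c]
    if fill_undefined and np.isnan(field).any():
        defined = ~np.isnan(field)
        if not defined.any():
            raise ValueError("no chip has a defined preferred orientation")
        _, (ir, ic) = _ndi.distance_transform_edt(~defined, return_indices=True)
        field = field[ir, ic]
    return field


def orientation_rgb(field_deg: np.ndarray) -> np.ndarray:
    """Color an orientation field with a cyclic hue over [0, 180).

    hue(0) == hue(180) exactly; NaN cells render mid-gray.
    """
    cmap = colormaps["hsv"]
    frac = (np.asarray(field_deg, dtype=float) % 180.0) / 180.0
    rgba = cmap(np.nan_to_num(frac))
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    rgb[np.isnan(field_deg)] = 128
    return rgb


def render_map(columns: OrientationColumnSet, tuning: ChipTuning,
               scale: int = 8) -> tuple[np.ndarray, np.ndarray]:
    """Render the cortical orientation map; returns (RGB image, raw field)."""
    field = orientation_field(columns, tuning, fill_undefined=True)
    rgb = orientation_rgb(field)
    if scale > 1:
        rgb = np.repeat(np.repeat(rgb, scale, axis=0), scale, axis=1)
    return rgb, field


def _wrap_half(d: np.ndarray) -> np.ndarray:
    """Wrap an orientation difference into [-90, 90)."""
    return (d + 90.0) % 180.0 - 90.0


def count_pinwheels(field_deg: np.ndarray) -> list[tuple[float, float, int]]:
    """Pinwheel singularities of an orientation field.

    For every 2x2 plaquette the four consecutive orientation differences
    (each wrapped to [-90, 90)) are summed; a net winding of +-180 degrees
    marks a singularity.  Returns (row, col, sign) at plaquette centres,
    sign +-1 (the +-half-rotation winding, reported as its sign).
    """
    f = np.asarray(field_deg, dtype=float)
    if np.isnan(f).any():
        raise ValueError("orientation field contains undefined cells")
    a, b = f[:-1, :-1], f[:-1, 1:]
    c, d = f[1:, 1:], f[1:, :-1]
    total = (_wrap_half(b - a) + _wrap_half(c - b)
             + _wrap_half(d - c) + _wrap_half(a - d))
    winding = np.rint(total / 180.0).astype(int)
    out = []
    for i, j in zip(*np.nonzero(winding)):
        out.append((i + 0.5, j + 0.5, int(winding[i, j])))
    return out


def ideal_pinwheel_field(size: int, center: tuple[float, float] | None = None,
                         sign: int = 1) -> np.ndarray:
    """Construct a single-singularity field theta = sign/2 * atan2(y-y0, x-x0)."""
    if center is None:
        center = ((size - 1) / 2.0 + 0.5, (size - 1) / 2.0 + 0.5)
    y0, x0 = center
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    theta = np.degrees(np.arctan2(yy - y0, xx - x0)) / 2.0 * sign
    return theta % 180.0
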