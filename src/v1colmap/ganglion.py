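"""Retina/LGN layer: difference-of-Gaussians ganglion cells with thresholding.

Each ganglion cell (GC) sits at one pixel of a receptive field and computes
a centre-surround response: a narrow Gaussian-weighted sum of photoreceptor
inputs minus a broader one (DOG).  Each discrete Gaussian is renormalized to
unit sum before subtraction, so the DOG kernel sums to zero and a uniform
field elicits exactly zero response.  Graded responses are then converted to
binary firing by a global threshold

    threshold = (GC_max - GC_min) * alpha        (alpha = 0.2 by default)

with strict inequality (a response exactly at threshold does not fire).
At field borders each Gaussian is renormalized over its in-field support
(normalized convolution), so the centre-surround sum runs over the cells
that exist rather than phantom zeros, and a uniform field elicits exactly
zero response everywhere including the border.
The on-centre pathway fires on positive DOG responses; the off-centre
pathway is the sign-flipped (surround-minus-centre) operator and fires on
negative ones.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .tiling import IndexMatrixSet, TilingSpec, generate_index_matrices, split_image_array

PATHWAYS = ("on", "off")


@dataclass(frozen=True)
class DOGParams:
    """DOG kernel scales (pixels), support, firing threshold fraction.

    ``threshold_scope`` chooses whether GC_max/GC_min are taken over all
    fields of a frame ("image", default) or per receptive field ("field").
    """

    sigma_cen_on: float = 0.5
    sigma_sur_on: float = 1.0
    sigma_cen_off: float = 0.5
    sigma_sur_off: float = 1.0
    kernel_side: int = 3
    alpha_threshold: float = 0.2
    pathway: str = "on"
    border: str = "renormalize"  # in-field support renormalization; or "reflect"
    threshold_scope: str = "image"

    def __post_init__(self) -> None:
        if self.sigma_cen_on >= self.sigma_sur_on:
            raise ValueError("on-pathway centre sigma must be < surround sigma")
        if self.sigma_cen_off >= self.sigma_sur_off:
            raise ValueError("off-pathway centre sigma must be < surround sigma")
        if self.kernel_side % 2 != 1:
            raise ValueError("kernel_side must be odd")
        if not 0.0 < self.alpha_threshold < 1.0:
            raise ValueError("alpha_threshold must lie in (0, 1)")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway must be one of {PATHWAYS}")
        if self.border not in ("renormalize", "reflect"):
            raise ValueError("border must be 'renormalize' or 'reflect'")
        if self.threshold_scope not in ("image", "field"):
            raise ValueError("threshold_scope must be 'image' or 'field'")


@dataclass
class GCArray:
    """Graded and binarized GC responses of one receptive field."""

    rf_index: int
    graded: np.ndarray
    fired: np.ndarray
    threshold_used: float


def make_dog_kernel(sigma_cen: float, sigma_sur: float, kernel_side: int = 3) -> np.ndarray:
    """Discrete DOG kernel: unit-sum Gaussian(sigma_cen) minus unit-sum
    Gaussian(sigma_sur); entries sum to zero by construction."""
    if sigma_cen >= sigma_sur:
        raise ValueError("sigma_cen must be < sigma_sur")
    if kernel_side % 2 != 1:
        raise ValueError("kernel_side must be odd")
    half = kernel_side // 2
    x = np.arange(-half, half + 1, dtype=float)
    r2 = x[:, None] ** 2 + x[None, :] ** 2

    def gauss(sigma: float) -> np.ndarray:
        g = np.exp(-r2 / (2.0 * sigma * sigma))
        return g / g.sum()

    return gauss(sigma_cen) - gauss(sigma_sur)


def pathway_kernel(params: DOGParams, pathway: str | None = None) -> np.ndarray:
    """Centre-minus-surround kernel built from the requested pathway's sigma
    pair.  The off pathway's sign convention (firing on negative responses)
    lives in :func:`binarize`, not in the kernel."""
    p = pathway or params.pathway
    if p == "on":
        return make_dog_kernel(params.sigma_cen_on, params.sigma_sur_on, params.kernel_side)
    if p == "off":
        return make_dog_kernel(params.sigma_cen_off, params.sigma_sur_off, params.kernel_side)
    raise ValueError(f"pathway must be one of {PATHWAYS}")


def _unit_gaussian(sigma: float, side: int) -> np.ndarray:
    half = side // 2
    x = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(x[:, None] ** 2 + x[None, :] ** 2) / (2.0 * sigma * sigma))
    return g / g.sum()


def _centre_surround(fields: np.ndarray, sigma_cen: float, sigma_sur: float,
                     params: DOGParams) -> np.ndarray:
    """Centre-surround response of stacked square fields (..., side, side).

    With the default border handling each Gaussian average runs over the
    cells that exist inside the field (its weights renormalized over the
    in-field support), so constant input gives exactly zero response
    everywhere.  "reflect" mirrors the field at its borders instead.
    """
    gc_k = _unit_gaussian(sigma_cen, params.kernel_side)
    gs_k = _unit_gaussian(sigma_sur, params.kernel_side)
    kshape = (1,) * (fields.ndim - 2) + gc_k.shape
    gc_k, gs_k = gc_k.reshape(kshape), gs_k.reshape(kshape)
    if params.border == "reflect":
        return (ndimage.correlate(fields, gc_k, mode="reflect")
                - ndimage.correlate(fields, gs_k, mode="reflect"))
    ones = np.ones(fields.shape[-2:])
    mass_c = ndimage.correlate(ones, gc_k.reshape(gc_k.shape[-2:]),
                               mode="constant", cval=0.0)
    mass_s = ndimage.correlate(ones, gs_k.reshape(gs_k.shape[-2:]),
                               mode="constant", cval=0.0)
    num_c = ndimage.correlate(fields, gc_k, mode="constant", cval=0.0)
    num_s = ndimage.correlate(fields, gs_k, mode="constant", cval=0.0)
    out = num_c / mass_c - num_s / mass_s
    # snap float residue of the two averages to an exact zero response
    out[np.abs(out) < 1e-12] = 0.0
    return out


def gc_response(rf_values: np.ndarray, params: DOGParams,
                rf_side: int | None = None) -> np.ndarray:
    """Graded GC responses of one receptive field.

    ``rf_values`` is the flattened field (length rf_side**2, 8-bit levels).
    Pixels are scaled to [0, 1] before the centre-surround computation; the
    output is flattened row-major.
    """
    v = np.asarray(rf_values, dtype=float).ravel()
    if rf_side is None:
        rf_side = int(round(np.sqrt(v.size)))
    if rf_side * rf_side != v.size:
        raise ValueError(f"receptive field length {v.size} is not a square")
    patch = v.reshape(rf_side, rf_side) / 255.0
    if params.pathway == "off":
        out = _centre_surround(patch, params.sigma_cen_off,
                               params.sigma_sur_off, params)
    else:
        out = _centre_surround(patch, params.sigma_cen_on,
                               params.sigma_sur_on, params)
    return out.ravel()


def compute_threshold(responses: np.ndarray, alpha: float) -> float:
    """Firing threshold (max - min) * alpha over the given responses."""
    r = np.asarray(responses, dtype=float)
    if r.size == 0:
        raise ValueError("cannot compute a threshold over an empty collection")
    return float((r.max() - r.min()) * alpha)


def binarize(graded: np.ndarray, threshold: float, pathway: str = "on") -> np.ndarray:
    """Binary firing: strict ``graded > threshold`` (off pathway: on the
    negated graded response)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = np.asarray(graded, dtype=float)
    if pathway == "off":
        g = -g
    return (g > threshold).astype(np.uint8)


@dataclass
class GCField:
    """GC responses of every receptive field of one image."""

    tiling: TilingSpec
    graded: np.ndarray  # (n_fields, rf_side**2)
    fired: np.ndarray   # (n_fields, rf_side**2) uint8
    threshold: float | np.ndarray  # scalar (image scope) or per-field vector
    params: DOGParams = field(repr=False, default=None)

    def as_arrays(self) -> list[GCArray]:
        thr = np.broadcast_to(np.asarray(self.threshold, float).ravel(),
                              (self.graded.shape[0],)) \
            if np.ndim(self.threshold) else np.full(self.graded.shape[0], self.threshold)
        return [GCArray(f, self.graded[f], self.fired[f], float(thr[f]))
                for f in range(self.graded.shape[0])]


def image_to_gc(img: np.ndarray, tspec: TilingSpec, params: DOGParams,
                idx: IndexMatrixSet | None = None) -> GCField:
    """Full retina/LGN pass: tile the image, run the centre-surround
    operator over every field (each field treated as an isolated patch),
    threshold, binarize."""
    if idx is None:
        idx = generate_index_matrices(tspec)
    vectors = split_image_array(img, idx)
    side = tspec.rf_side
    fields = vectors.reshape(-1, side, side).astype(float) / 255.0
    if params.pathway == "off":
        sig = (params.sigma_cen_off, params.sigma_sur_off)
    else:
        sig = (params.sigma_cen_on, params.sigma_sur_on)
    # The leading singleton kernel axis keeps fields independent.
    graded = _centre_surround(fields, sig[0], sig[1], params)
    graded = graded.reshape(-1, side * side)
    g_for_fire = -graded if params.pathway == "off" else graded
    if params.threshold_scope == "image":
        threshold = compute_threshold(graded, params.alpha_threshold)
        fired = (g_for_fire > threshold).astype(np.uint8)
    else:
        span = graded.max(axis=1) - graded.min(axis=1)
        threshold = span * params.alpha_threshold
        fired = (g_for_fire > threshold[:, None]).astype(np.uint8)
    return GCField(tspec, graded, fired, threshold, params)
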