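"""Seeded synthetic stimuli: oriented bars, edges, gratings, shapes and strokes.

The model is trained and probed on orientation-rich imagery.  This module
generates such imagery deterministically so no external dataset is needed.

Orientation convention (used everywhere in the package): degrees measured
counter-clockwise from the horizontal axis *as displayed* (origin top-left,
rows growing downward), restricted to the axial range [0, 180).  A 0-degree
bar is a horizontal band, a 90-degree bar is vertical.  ``numpy.rot90``
rotates a displayed raster counter-clockwise, so a bar at theta rotated by
one quarter turn is a bar at theta + 90 (mod 180).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Iterator, Sequence

import numpy as np

#: Smallest raster dimension that still admits one full receptive field.
MIN_SIZE = 9

KINDS = ("bar", "edge", "grating", "square", "circle", "triangle", "stroke_digit")


@dataclass(frozen=True)
class StimulusSpec:
    """Parameters of one synthetic stimulus.

    ``contrast`` is the fraction of the remaining dynamic range above
    ``background`` used for the foreground: foreground level =
    ``background + contrast * (255 - background)``.  ``noise_sd`` is the
    standard deviation of additive Gaussian noise in 8-bit levels (0 = none).
    """

    kind: str = "bar"
    height: int = 27
    width: int = 27
    orientation_deg: float = 0.0
    bar_width: float = 3.0
    contrast: float = 1.0
    background: int = 0
    noise_sd: float = 0.0
    seed: int = 0
    center_offset: tuple[float, float] = (0.0, 0.0)  # (rows down, cols right)
    digit: int = 1  # only for kind="stroke_digit"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}; choose from {KINDS}")
        if min(self.height, self.width) < MIN_SIZE:
            raise ValueError(
                f"raster {self.height}x{self.width} too small: each dimension must be "
                f">= {MIN_SIZE} (one full receptive field)"
            )
        if not 0.0 <= self.orientation_deg < 180.0:
            raise ValueError("orientation_deg must lie in [0, 180)")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")
        if not 0 <= self.background <= 255:
            raise ValueError("background must be an 8-bit level")


def _signed_distance(spec: StimulusSpec) -> np.ndarray:
    """Signed perpendicular distance of every pixel to the stimulus axis.

    The axis is the line through the (possibly offset) raster centre with
    direction (cos theta, -sin theta) in (col, row) coordinates, which is a
    counter-clockwise angle of theta in display coordinates.
    """
    th = np.radians(spec.orientation_deg)
    rows = np.arange(spec.height, dtype=float)[:, None]
    cols = np.arange(spec.width, dtype=float)[None, :]
    cy = (spec.height - 1) / 2.0 + spec.center_offset[0]
    cx = (spec.width - 1) / 2.0 + spec.center_offset[1]
    return (cols - cx) * (-np.sin(th)) - (rows - cy) * np.cos(th)


def _segment_distance(spec: StimulusSpec, segments: Sequence[tuple]) -> np.ndarray:
    """Min distance of every pixel to a set of line segments.

    Segments are given in unit coordinates (x right, y up, centred, roughly
    [-1, 1]); they are rotated by ``orientation_deg - 90`` (so the default
    90-degree orientation leaves them upright), scaled to the raster, and
    offset by ``center_offset``.
    """
    a = np.radians(spec.orientation_deg - 90.0)
    scale = 0.4 * min(spec.height, spec.width)
    cy = (spec.height - 1) / 2.0 + spec.center_offset[0]
    cx = (spec.width - 1) / 2.0 + spec.center_offset[1]

    def to_rc(x: float, y: float) -> tuple[float, float]:
        xr = x * np.cos(a) - y * np.sin(a)
        yr = x * np.sin(a) + y * np.cos(a)
        return cy - yr * scale, cx + xr * scale

    rows = np.arange(spec.height, dtype=float)[:, None]
    cols = np.arange(spec.width, dtype=float)[None, :]
    dist = np.full((spec.height, spec.width), np.inf)
    for (x0, y0), (x1, y1) in segments:
        r0, c0 = to_rc(x0, y0)
        r1, c1 = to_rc(x1, y1)
        dr, dc = r1 - r0, c1 - c0
        L2 = dr * dr + dc * dc
        if L2 == 0:
            d = np.hypot(rows - r0, cols - c0)
        else:
            t = ((rows - r0) * dr + (cols - c0) * dc) / L2
            t = np.clip(t, 0.0, 1.0)
            d = np.hypot(rows - (r0 + t * dr), cols - (c0 + t * dc))
        dist = np.minimum(dist, d)
    return dist


_DIGIT_STROKES: dict[int, list[tuple]] = {
    0: [((-0.6, 0.9), (0.6, 0.9)), ((0.6, 0.9), (0.6, -0.9)),
        ((0.6, -0.9), (-0.6, -0.9)), ((-0.6, -0.9), (-0.6, 0.9))],
    1: [((0.0, -1.0), (0.0, 1.0)), ((-0.45, 0.55), (0.0, 1.0))],
    2: [((-0.6, 0.9), (0.6, 0.9)), ((0.6, 0.9), (0.6, 0.0)),
        ((0.6, 0.0), (-0.6, -0.9)), ((-0.6, -0.9), (0.6, -0.9))],
    3: [((-0.6, 0.9), (0.6, 0.9)), ((0.6, 0.9), (-0.1, 0.1)),
        ((-0.1, 0.1), (0.6, -0.3)), ((0.6, -0.3), (0.3, -0.9)),
        ((0.3, -0.9), (-0.6, -0.9))],
}


def _foreground_fraction(spec: StimulusSpec) -> np.ndarray:
    """Per-pixel foreground mask/weight in [0, 1] for the noiseless stimulus."""
    half = spec.bar_width / 2.0
    if spec.kind == "bar":
        return (np.abs(_signed_distance(spec)) <= half).astype(float)
    if spec.kind == "edge":
        return (_signed_distance(spec) >= 0.0).astype(float)
    if spec.kind == "grating":
        period = max(2.0, 4.0 * spec.bar_width)
        return 0.5 * (1.0 + np.cos(2.0 * np.pi * _signed_distance(spec) / period))
    if spec.kind == "circle":
        rows = np.arange(spec.height, dtype=float)[:, None]
        cols = np.arange(spec.width, dtype=float)[None, :]
        cy = (spec.height - 1) / 2.0 + spec.center_offset[0]
        cx = (spec.width - 1) / 2.0 + spec.center_offset[1]
        radius = 0.3 * min(spec.height, spec.width)
        ring = np.abs(np.hypot(rows - cy, cols - cx) - radius)
        return (ring <= half).astype(float)
    if spec.kind == "square":
        s = 0.8
        corners = [(-s, s), (s, s), (s, -s), (-s, -s)]
        segs = [(corners[i], corners[(i + 1) % 4]) for i in range(4)]
        return (_segment_distance(spec, segs) <= half).astype(float)
    if spec.kind == "triangle":
        pts = [(0.0, 1.0), (0.9, -0.8), (-0.9, -0.8)]
        segs = [(pts[i], pts[(i + 1) % 3]) for i in range(3)]
        return (_segment_distance(spec, segs) <= half).astype(float)
    if spec.kind == "stroke_digit":
        strokes = _DIGIT_STROKES.get(spec.digit)
        if strokes is None:
            raise ValueError(f"no stroke template for digit {spec.digit}")
        return (_segment_distance(spec, strokes) <= half).astype(float)
    raise AssertionError("unreachable")


def make_stimulus(spec: StimulusSpec) -> np.ndarray:
    """Render a stimulus to an 8-bit grayscale raster (uint8, row-major)."""
    frac = _foreground_fraction(spec)
    img = spec.background + frac * spec.contrast * (255.0 - spec.background)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def make_bar(spec: StimulusSpec) -> np.ndarray:
    """Render an oriented bar (``spec.kind`` is forced to ``"bar"``)."""
    if spec.kind != "bar":
        spec = replace(spec, kind="bar")
    return make_stimulus(spec)


def bar_image(height: int, width: int, orientation_deg: float,
              bar_width: float = 3.0, **kw) -> np.ndarray:
    """Convenience wrapper: oriented bar through the raster centre."""
    return make_bar(StimulusSpec(kind="bar", height=height, width=width,
                                 orientation_deg=orientation_deg,
                                 bar_width=bar_width, **kw))


def rotate90(img: np.ndarray, k: int = 1) -> np.ndarray:
    """Lossless counter-clockwise rotation by k quarter turns."""
    return np.ascontiguousarray(np.rot90(img, k % 4))


class Corpus(Sequence):
    """An ordered, reproducible list of stimuli with their generating specs.

    Behaves as a sequence of images; ``specs`` carries the per-image
    :class:`StimulusSpec` for provenance and stratification checks.
    """

    def __init__(self, images: list[np.ndarray], specs: list[StimulusSpec], seed: int):
        self.images = images
        self.specs = specs
        self.seed = seed

    def __len__(self) -> int:
        return len(self.images)

    def __getitem__(self, i):
        return self.images[i]

    def __iter__(self) -> Iterator[np.ndarray]:
        return iter(self.images)

    @property
    def orientations(self) -> np.ndarray:
        return np.array([s.orientation_deg for s in self.specs])

    def manifest(self) -> dict:
        return {"seed": self.seed, "n": len(self),
                "specs": [asdict(s) for s in self.specs]}

    def save_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1)


def make_training_corpus(
    n: int,
    size: tuple[int, int] = (27, 27),
    orientations: Sequence[float] = (0.0, 45.0, 90.0, 135.0),
    seed: int = 0,
    stratified: bool = True,
    kind: str = "bar",
    bar_width: float = 3.0,
    contrast_range: tuple[float, float] = (0.6, 1.0),
    offset_frac: float = 0.45,
    noise_sd: float = 0.0,
) -> Corpus:
    """Generate ``n`` stimuli covering the requested orientations.

    Positions (via ``center_offset``, uniform within ``offset_frac`` of each
    dimension) and contrasts are randomized so that, over a corpus, every
    receptive field is exposed to every orientation.  In stratified mode
    orientation ``orientations[i % k]`` is assigned to image ``i`` (so counts
    differ by at most one); otherwise orientations are drawn uniformly.
    Identical arguments yield a bitwise-identical corpus.
    """
    if n < 1:
        raise ValueError("corpus size n must be >= 1")
    if len(orientations) == 0:
        raise ValueError("orientation list must be non-empty")
    h, w = size
    rng = np.random.default_rng(seed)
    images, specs = [], []
    for i in range(n):
        if stratified:
            theta = float(orientations[i % len(orientations)])
        else:
            theta = float(orientations[rng.integers(len(orientations))])
        off = (float(rng.uniform(-offset_frac, offset_frac) * h),
               float(rng.uniform(-offset_frac, offset_frac) * w))
        contrast = float(rng.uniform(*contrast_range))
        spec = StimulusSpec(kind=kind, height=h, width=w, orientation_deg=theta,
                            bar_width=bar_width, contrast=contrast,
                            noise_sd=noise_sd, seed=int(rng.integers(2**31)),
                            center_offset=off)
        images.append(make_stimulus(spec))
        specs.append(spec)
    return Corpus(images, specs, seed)
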