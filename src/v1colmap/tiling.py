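"""Overlapping receptive-field tiling and single-scan index matrices.

An M x N image is covered by rf_side x rf_side receptive fields whose
origins step by ``stride`` pixels (default 9x9 fields, stride 6, so adjacent
fields overlap by 3 pixels).  Because the overlap is less than half a field
on each side, a pixel belongs to at most four fields.  Membership is
precomputed into four index matrices: slot k of pixel (r, c) stores a packed
word identifying the k-th field claiming that pixel and the pixel's offset
inside that field's flattened 81-vector.  Splitting an image into field
vectors is then a single pass over the pixels, mirroring the way a hardware
scanline writer would fan pixels out to per-field memories.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

#: Sentinel for an unused index-matrix slot.
EMPTY_SLOT = -1

#: Max fields sharing one pixel when stride > rf_side/2.
MAX_SHARING = 4


def min_bits(n: int) -> int:
    """Minimal number of bits addressing ``n`` distinct values (floor of 1)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, math.ceil(math.log2(n))) if n > 1 else 1


@dataclass(frozen=True)
class TilingSpec:
    """Geometry of the receptive-field tiling over one image."""

    image_height: int
    image_width: int
    rf_side: int = 9
    stride: int = 6

    def __post_init__(self) -> None:
        if self.rf_side < 1:
            raise ValueError("rf_side must be >= 1")
        if not 1 <= self.stride <= self.rf_side:
            raise ValueError("stride must satisfy 1 <= stride <= rf_side")
        if self.image_height < self.rf_side or self.image_width < self.rf_side:
            raise ValueError(
                f"image {self.image_height}x{self.image_width} smaller than one "
                f"{self.rf_side}x{self.rf_side} receptive field"
            )

    @property
    def n_rows(self) -> int:
        return (self.image_height - self.rf_side) // self.stride + 1

    @property
    def n_cols(self) -> int:
        return (self.image_width - self.rf_side) // self.stride + 1

    @property
    def n_fields(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def gcs_per_field(self) -> int:
        return self.rf_side * self.rf_side

    @property
    def field_bits(self) -> int:
        return min_bits(self.n_fields)

    @property
    def offset_bits(self) -> int:
        return min_bits(self.gcs_per_field)

    def field_origin(self, rf_index: int) -> tuple[int, int]:
        """Top-left pixel (row, col) of a field, fields numbered row-major."""
        if not 0 <= rf_index < self.n_fields:
            raise ValueError(f"rf_index {rf_index} out of range [0, {self.n_fields})")
        i, j = divmod(rf_index, self.n_cols)
        return i * self.stride, j * self.stride

    def field_center(self, rf_index: int) -> tuple[int, int]:
        r0, c0 = self.field_origin(rf_index)
        return r0 + self.rf_side // 2, c0 + self.rf_side // 2


def build_tiling(M: int, N: int, rf_side: int = 9, stride: int = 6) -> TilingSpec:
    """Validate parameters and return the tiling.

    Fields are placed only at origins where a full ``rf_side`` square fits;
    trailing pixels not covered by a full field are excluded.
    """
    return TilingSpec(M, N, rf_side, stride)


class IndexWord(NamedTuple):
    rf_index: int
    offset: int


class ReceptiveFieldVector(NamedTuple):
    rf_index: int
    values: np.ndarray  # flattened rf_side**2 samples, row-major in the field


def pack_index(rf_index: int, offset: int, spec: TilingSpec) -> int:
    """Pack (field index, in-field offset) into one word: high bits are the
    field index, low ``offset_bits`` bits the offset."""
    if not 0 <= rf_index < spec.n_fields:
        raise ValueError(f"rf_index {rf_index} out of range [0, {spec.n_fields})")
    if not 0 <= offset < spec.gcs_per_field:
        raise ValueError(f"offset {offset} out of range [0, {spec.gcs_per_field})")
    return (rf_index << spec.offset_bits) | offset


def unpack_index(word: int, spec: TilingSpec) -> IndexWord:
    """Inverse of :func:`pack_index`."""
    if word < 0 or word >= spec.n_fields << spec.offset_bits:
        raise ValueError(f"packed word {word} out of range")
    rf_index = word >> spec.offset_bits
    offset = word & ((1 << spec.offset_bits) - 1)
    if offset >= spec.gcs_per_field:
        raise ValueError(f"packed word {word} decodes to invalid offset {offset}")
    return IndexWord(rf_index, offset)


@dataclass
class IndexMatrixSet:
    """Per-pixel field membership: ``slots[k, r, c]`` is the packed word of
    the k-th field claiming pixel (r, c) (ascending field index), or
    :data:`EMPTY_SLOT`."""

    spec: TilingSpec
    slots: np.ndarray  # (MAX_SHARING, M, N) int64

    def coverage_counts(self) -> np.ndarray:
        """Number of fields sharing each pixel."""
        return (self.slots != EMPTY_SLOT).sum(axis=0)

    def n_filled(self) -> int:
        return int((self.slots != EMPTY_SLOT).sum())

    def save(self, path) -> None:
        np.savez(path, slots=self.slots,
                 geometry=np.array([self.spec.image_height, self.spec.image_width,
                                    self.spec.rf_side, self.spec.stride]))

    @classmethod
    def load(cls, path) -> "IndexMatrixSet":
        data = np.load(path)
        M, N, side, stride = (int(v) for v in data["geometry"])
        return cls(TilingSpec(M, N, side, stride), data["slots"])


def generate_index_matrices(spec: TilingSpec) -> IndexMatrixSet:
    """Build the four index matrices in one scan over the fields.

    For every field and every in-field position exactly one slot at the
    corresponding pixel receives that (field, offset) pair; slots fill in
    ascending field index, so slot order is deterministic.
    """
    M, N = spec.image_height, spec.image_width
    slots = np.full((MAX_SHARING, M, N), EMPTY_SLOT, dtype=np.int64)
    depth = np.zeros((M, N), dtype=np.int8)
    offsets = np.arange(spec.gcs_per_field, dtype=np.int64)
    side = spec.rf_side
    for rf in range(spec.n_fields):
        r0, c0 = spec.field_origin(rf)
        rr = np.repeat(np.arange(r0, r0 + side), side)
        cc = np.tile(np.arange(c0, c0 + side), side)
        d = depth[rr, cc]
        if np.any(d >= MAX_SHARING):
            raise ValueError("a pixel is claimed by more than "
                             f"{MAX_SHARING} fields; reduce overlap")
        slots[d, rr, cc] = (rf << spec.offset_bits) | offsets
        depth[rr, cc] = d + 1
    return IndexMatrixSet(spec, slots)


def split_image_array(img: np.ndarray, idx: IndexMatrixSet) -> np.ndarray:
    """Split an image into per-field vectors in one pass over the pixels.

    Returns an (n_fields, rf_side**2) array whose row ``f`` equals the
    row-major flattening of field ``f``'s crop.
    """
    spec = idx.spec
    if img.shape != (spec.image_height, spec.image_width):
        raise ValueError(
            f"image shape {img.shape} does not match tiling "
            f"{(spec.image_height, spec.image_width)}"
        )
    out = np.zeros((spec.n_fields, spec.gcs_per_field), dtype=img.dtype)
    mask_off = (1 << spec.offset_bits) - 1
    for k in range(MAX_SHARING):
        plane = idx.slots[k]
        filled = plane != EMPTY_SLOT
        words = plane[filled]
        out[words >> spec.offset_bits, words & mask_off] = img[filled]
    return out


def split_image(img: np.ndarray, idx: IndexMatrixSet) -> list[ReceptiveFieldVector]:
    """Like :func:`split_image_array` but as labelled per-field records."""
    arr = split_image_array(img, idx)
    return [ReceptiveFieldVector(f, arr[f]) for f in range(arr.shape[0])]
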