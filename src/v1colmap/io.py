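"""Image reading/writing, weight persistence, and run configuration."""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

from .ganglion import DOGParams
from .som import (ChipTopology, OrientationColumnSet, SOMConfig, grid_topology,
                  hex_topology)
from .tiling import TilingSpec

WEIGHTS_FORMAT = "v1colmap-weights"
WEIGHTS_VERSION = 1


def read_image(path) -> np.ndarray:
    """Read a PGM (P2/P5) or PNG image as an 8-bit grayscale raster.

    Color inputs are converted to luminance with the ITU-R BT.601 weights
    (L = 0.299 R + 0.587 G + 0.114 B); 16-bit inputs are rejected.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
                raise ValueError(
                    f"{path}: {im.mode}-mode (16-bit/float) input not supported; "
                    "supply 8-bit PGM (P2/P5) or PNG"
                )
            if im.mode != "L":
                im = im.convert("L")  # Pillow uses the BT.601 weights
            return np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError, SyntaxError) as exc:
        raise ValueError(f"cannot parse {path} as PGM (P2/P5) or PNG: {exc}") from exc


def write_image(img: np.ndarray, path) -> None:
    """Write an 8-bit raster as PGM (binary P5) or PNG, chosen by suffix."""
    arr = np.asarray(img)
    mode = "L" if arr.ndim == 2 else "RGB"
    Image.fromarray(arr.astype(np.uint8), mode=mode).save(path)


def _weights_paths(path_prefix) -> tuple[Path, Path]:
    p = Path(path_prefix)
    if p.suffix == ".npy":
        p = p.with_suffix("")
    return p.with_suffix(".npy"), p.with_suffix(".json")


def save_weights(columns: OrientationColumnSet, path_prefix) -> None:
    """Persist trained columns: weight array (.npy) + JSON sidecar
    (topology, config, tiling, iteration counter)."""
    npy, sidecar = _weights_paths(path_prefix)
    np.save(npy, columns.weights)
    meta = {
        "format": WEIGHTS_FORMAT,
        "version": WEIGHTS_VERSION,
        "shape": list(columns.weights.shape),
        "t": columns.t,
        "topology": {"kind": columns.topology.kind,
                     "coords": columns.topology.coords.tolist()},
        "config": dataclasses.asdict(columns.config),
        "tiling": dataclasses.asdict(columns.tiling) if columns.tiling else None,
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def load_weights(path_prefix) -> OrientationColumnSet:
    """Inverse of :func:`save_weights`; validates format, version and shape."""
    npy, sidecar = _weights_paths(path_prefix)
    meta = json.loads(Path(sidecar).read_text())
    if meta.get("format") != WEIGHTS_FORMAT:
        raise ValueError(f"{sidecar}: not a {WEIGHTS_FORMAT} sidecar")
    if meta.get("version") != WEIGHTS_VERSION:
        raise ValueError(f"{sidecar}: unsupported weights version "
                         f"{meta.get('version')} (expected {WEIGHTS_VERSION})")
    weights = np.load(npy)
    if list(weights.shape) != meta["shape"]:
        raise ValueError(f"{npy}: weight shape {weights.shape} does not match "
                         f"sidecar {meta['shape']}")
    coords = np.asarray(meta["topology"]["coords"], dtype=float)
    if coords.shape[0] != weights.shape[1]:
        raise ValueError("sidecar topology chip count does not match weights")
    diff = coords[:, None, :] - coords[None, :, :]
    topology = ChipTopology(coords, np.sqrt((diff ** 2).sum(axis=2)),
                            meta["topology"]["kind"])
    config = SOMConfig(**meta["config"])
    tiling = TilingSpec(**meta["tiling"]) if meta.get("tiling") else None
    return OrientationColumnSet(weights, topology, config, tiling, t=meta["t"])


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration shared by the CLI subcommands."""

    rf_side: int = 9
    stride: int = 6
    n_chips: int = 19
    topology: str = "hex"
    dog: DOGParams = field(default_factory=DOGParams)
    som: SOMConfig = field(default_factory=SOMConfig)
    metric: str = "cosine"
    bitwise: bool = False
    probe_step_deg: float = 15.0
    seed: int = 0

    def probe_orientations(self) -> np.ndarray:
        return np.arange(0.0, 180.0, self.probe_step_deg)

    def make_topology(self) -> ChipTopology:
        if self.topology == "hex":
            top = hex_topology()
        elif self.topology == "grid":
            side = int(np.ceil(np.sqrt(self.n_chips)))
            top = grid_topology(side, side)
        else:
            raise ValueError("topology must be 'hex' or 'grid'")
        if top.n_chips < self.n_chips:
            raise ValueError(f"{self.topology} topology holds {top.n_chips} "
                             f"chips < requested {self.n_chips}")
        return top

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        try:
            if "dog" in d:
                d["dog"] = DOGParams(**d["dog"])
            if "som" in d:
                d["som"] = SOMConfig(**d["som"])
        except TypeError as exc:
            raise ValueError(f"invalid config section: {exc}") from exc
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
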