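"""Deployment-structure arithmetic for a given geometry.

Pure integer bookkeeping: how many receptive fields a frame yields, how many
GCs feed each column, how many chip-to-GC connections one column carries,
how wide the packed index words must be, and how many rounds a comparator
tree needs to pick the winning chip.  For the reference 123x183 frame with
9x9 fields at stride 6 and 19-chip columns this gives 600 fields, 81 GCs
per field, 1539 connections, a 10+7 bit index word, and a 5-round
comparator tree.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .selection import comparator_tree_depth
from .tiling import TilingSpec, build_tiling, min_bits


@dataclass(frozen=True)
class DeployPlan:
    image_height: int
    image_width: int
    rf_side: int
    stride: int
    n_rows: int
    n_cols: int
    n_fields: int
    gcs_per_field: int
    chips_per_column: int
    connections_per_column: int
    field_index_bits: int
    offset_bits: int
    comparator_rounds: int

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    def format_table(self) -> str:
        rows = [
            ("image", f"{self.image_height} x {self.image_width}"),
            ("receptive field", f"{self.rf_side} x {self.rf_side}, stride {self.stride}"),
            ("field grid", f"{self.n_rows} x {self.n_cols} = {self.n_fields}"),
            ("GCs per field", str(self.gcs_per_field)),
            ("chips per column", str(self.chips_per_column)),
            ("connections per column", str(self.connections_per_column)),
            ("index word", f"{self.field_index_bits} field bits + "
                           f"{self.offset_bits} offset bits"),
            ("comparator rounds", str(self.comparator_rounds)),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k.ljust(width)}  {v}" for k, v in rows)


def plan(M: int, N: int, rf_side: int = 9, stride: int = 6,
         n_chips: int = 19) -> DeployPlan:
    """Compute the deployment plan for an M x N frame."""
    t: TilingSpec = build_tiling(M, N, rf_side, stride)
    if n_chips < 1:
        raise ValueError("n_chips must be >= 1")
    return DeployPlan(
        image_height=M,
        image_width=N,
        rf_side=rf_side,
        stride=stride,
        n_rows=t.n_rows,
        n_cols=t.n_cols,
        n_fields=t.n_fields,
        gcs_per_field=t.gcs_per_field,
        chips_per_column=n_chips,
        connections_per_column=n_chips * t.gcs_per_field,
        field_index_bits=min_bits(t.n_fields),
        offset_bits=min_bits(t.gcs_per_field),
        comparator_rounds=comparator_tree_depth(n_chips),
    )
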