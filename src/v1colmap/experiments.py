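"""Seeded end-to-end experiments on synthetic stimuli.

These are the package's standard evaluation protocols: orientation recovery
by a trained column set, cortical-map pinwheel formation, and quarter-turn
equivariance of the representation.  All randomness flows from an explicit
seed; problem sizes default to a 33x33 frame (a 5x5 grid of receptive
fields), which keeps each experiment to seconds while giving every column
ample training exposure to every orientation.

Scoring note: a bar that merely grazes a field's corner induces an in-field
pattern whose local orientation can differ from the bar's global one (the
clipped segment hugs the field border).  Recovery is therefore scored only
on *core crossings* -- observations where the bar's axis passes within a
small radius of the field centre -- mirroring the physiologist's rule of
placing the stimulus in the receptive field.  Grazing contacts still occur
during training and inference; they are only excluded from scoring.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import selection
from .cortex import (ChipTuning, axial_diff, axial_mean, count_pinwheels,
                     orientation_field, probe_tuning, render_map)
from .deploy import plan
from .ganglion import DOGParams, image_to_gc
from .representation import (orientation_histogram, render_segments, represent,
                             rotation_check)
from .som import OrientationColumnSet, SOMConfig, hex_topology, init_columns, train
from .stimuli import StimulusSpec, bar_image, make_training_corpus
from .tiling import build_tiling, generate_index_matrices


def train_columns_on_bars(
    seed: int,
    image_size: int = 33,
    orientations=(0.0, 45.0, 90.0, 135.0),
    n_train: int = 240,
    dog_params: DOGParams | None = None,
    neighborhood_width: float = 1.0,
) -> tuple[OrientationColumnSet, DOGParams]:
    """Train a fresh column set on a stratified oriented-bar corpus."""
    dog_params = dog_params or DOGParams()
    tiling = build_tiling(image_size, image_size)
    corpus = make_training_corpus(n_train, size=(image_size, image_size),
                                  orientations=orientations, seed=seed)
    cfg = SOMConfig(T=n_train, neighborhood_width=neighborhood_width, seed=seed)
    columns = init_columns(tiling, cfg, hex_topology())
    train(columns, corpus, dog_params)
    return columns, dog_params


def bar_axis_distance(spec: StimulusSpec, point_rc: tuple[float, float]) -> float:
    """Perpendicular distance from an image point to a bar stimulus's axis."""
    th = np.radians(spec.orientation_deg)
    cy = (spec.height - 1) / 2.0 + spec.center_offset[0]
    cx = (spec.width - 1) / 2.0 + spec.center_offset[1]
    r, c = point_rc
    return float(abs((c - cx) * (-np.sin(th)) - (r - cy) * np.cos(th)))


@dataclass
class RecoveryReport:
    """Outcome of the four-orientation parameter-recovery experiment.

    ``class_errors_deg`` maps each trained orientation to the axial error of
    its population-vector readout: the win-count-weighted circular mean of
    the preferred orientations of all chips recruited by that class.
    """

    purity: float
    n_observations: int
    n_distinct_winner_chips: int
    per_column_distinct_min: int
    per_column_distinct_mean: float
    class_errors_deg: dict[float, float] = dc_field(default_factory=dict)
    max_class_error_deg: float = float("nan")
    n_columns: int = 0


def four_orientation_recovery(
    seed: int = 1,
    image_size: int = 33,
    orientations=(0.0, 45.0, 90.0, 135.0),
    n_train: int = 240,
    n_test: int = 120,
    probe_step_deg: float = 15.0,
    core_radius: float = 2.5,
) -> tuple[RecoveryReport, OrientationColumnSet, "ChipTuning"]:
    """Train on a 4-orientation bar corpus and measure what was learned.

    Readouts (all on a held-out randomized bar corpus, core crossings only):

    * clustering purity of (column, winner chip) clusters against the true
      stimulus orientation;
    * the number of distinct chips serving as a class's modal winner in
      some column (plus per-column distinct-winner statistics);
    * per class, the axial error of the population-vector orientation: the
      win-weighted circular mean of recruited chips' probed preferences.
    """
    columns, dogp = train_columns_on_bars(seed, image_size, orientations, n_train)
    tuning = probe_tuning(columns, np.arange(0.0, 180.0, probe_step_deg), dogp)

    test = make_training_corpus(n_test, size=(image_size, image_size),
                                orientations=orientations, seed=seed + 10_000)
    idx = generate_index_matrices(columns.tiling)
    wins: dict[tuple[int, int], dict[float, int]] = {}
    n_obs = 0
    for img, spec in zip(test.images, test.specs):
        gc = image_to_gc(img, columns.tiling, dogp, idx)
        for f in range(columns.n_fields):
            v = gc.fired[f]
            if not v.any():
                continue
            if bar_axis_distance(spec, columns.tiling.field_center(f)) > core_radius:
                continue
            res = selection.select_chip(v, columns.weights[f], metric="cosine")
            if not res.activated:
                continue
            d = wins.setdefault((f, res.winner_chip), {})
            d[spec.orientation_deg] = d.get(spec.orientation_deg, 0) + 1
            n_obs += 1

    purity = (sum(max(d.values()) for d in wins.values()) / n_obs) if n_obs else 0.0

    # modal winner chip per (column, class); distinct-winner statistics
    by_column: dict[int, dict[float, dict[int, int]]] = {}
    for (f, c), d in wins.items():
        for lab, n in d.items():
            by_column.setdefault(f, {}).setdefault(lab, {})
            by_column[f][lab][c] = by_column[f][lab].get(c, 0) + n
    pooled_modal: set[tuple[int, int]] = set()
    per_col_distinct = []
    for f, per_class in by_column.items():
        modal = {lab: max(cd, key=cd.get) for lab, cd in per_class.items()}
        for lab, c in modal.items():
            pooled_modal.add((f, c))
        if len(modal) == len(orientations):
            per_col_distinct.append(len(set(modal.values())))

    # population-vector orientation per class over all recruited chips
    class_errors = {}
    for th in orientations:
        angs, wts = [], []
        for (f, c), d in wins.items():
            n = d.get(th, 0)
            pref = tuning.preferred[f, c]
            if n and not np.isnan(pref):
                angs.append(pref)
                wts.append(n)
        if angs:
            class_errors[float(th)] = float(
                axial_diff(axial_mean(np.array(angs), np.array(wts)), th))
        else:
            class_errors[float(th)] = float("nan")

    report = RecoveryReport(
        purity=purity,
        n_observations=n_obs,
        n_distinct_winner_chips=len({fc for fc in pooled_modal}),
        per_column_distinct_min=min(per_col_distinct) if per_col_distinct else 0,
        per_column_distinct_mean=(float(np.mean(per_col_distinct))
                                  if per_col_distinct else 0.0),
        class_errors_deg=class_errors,
        max_class_error_deg=float(np.nanmax(list(class_errors.values()))),
        n_columns=columns.n_fields,
    )
    return report, columns, tuning


def broad_orientation_map(
    seed: int = 1,
    image_size: int = 33,
    n_orientations: int = 12,
    n_train: int = 360,
    probe_step_deg: float = 7.5,
) -> tuple[int, OrientationColumnSet, ChipTuning]:
    """Train on a broad-orientation corpus and count map pinwheels."""
    orientations = tuple(np.arange(n_orientations) * 180.0 / n_orientations)
    columns, dogp = train_columns_on_bars(seed, image_size, orientations, n_train)
    tuning = probe_tuning(columns, np.arange(0.0, 180.0, probe_step_deg), dogp)
    field = orientation_field(columns, tuning, fill_undefined=True)
    pinwheels = count_pinwheels(field)
    return len(pinwheels), columns, tuning


def demo(seed: int, outdir) -> dict:
    """End-to-end demonstration: corpus -> training -> tuning -> map ->
    representation of a held-out bar; writes artifacts and a summary JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report, columns, tuning = four_orientation_recovery(seed)
    n_pin, map_cols, map_tuning = broad_orientation_map(seed)
    rgb, _field = render_map(map_cols, map_tuning)
    dogp = DOGParams()
    size = columns.tiling.image_height
    held_out = bar_image(size, size, 45.0)
    rep = represent(held_out, columns, tuning, dogp)
    hist, edges = orientation_histogram(rep, n_bins=12)
    rot = rotation_check(held_out, columns, tuning, dogp, k=1)
    dplan = plan(size, size, columns.tiling.rf_side, columns.tiling.stride,
                 columns.n_chips)

    from .io import save_weights, write_image
    write_image(rgb, out / "orientation_map.png")
    write_image(render_segments(rep), out / "held_out_segments.png")
    rep.to_csv(out / "held_out_representation.csv")
    save_weights(columns, out / "columns")
    summary = {
        "seed": seed,
        "plan": dplan.to_dict(),
        "recovery": {
            "purity": report.purity,
            "n_distinct_winner_chips": report.n_distinct_winner_chips,
            "max_class_error_deg": report.max_class_error_deg,
        },
        "pinwheels_trained_map": n_pin,
        "held_out_bar_orientation_deg": 45.0,
        "held_out_histogram": hist.tolist(),
        "held_out_histogram_edges": edges.tolist(),
        "rotation_match_fraction": rot.match_fraction,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary
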