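# Methods

## Model

The package implements a three-stage feed-forward model of early vision.
An 8-bit grayscale frame is tiled into overlapping square receptive fields
(side 9, stride 6 by default, so neighbouring fields share a 3-pixel
band and a pixel belongs to at most four fields). Fields exist only where
a full square fits; trailing pixels are not covered. Field membership is
precomputed into four index matrices holding packed words
(`rf_index · 2^offset_bits + offset`, minimal bit widths with a floor of
one bit), which turns image→field splitting into a single pass over the
pixels and mirrors a scanline hardware writer.

Each field position hosts one ganglion cell. Its graded response is a
difference of two discrete Gaussian averages of the luminance (scaled to
[0, 1]): a narrow centre (σ_cen = 0.5 px) minus a broader surround
(σ_sur = 1.0 px), both over a 3×3 support. Each Gaussian is renormalized
to unit sum, so the operator has exactly zero response to uniform input —
the defining property of centre–surround antagonism. At field borders the
averages are renormalized over the cells that actually fall inside the
field ("normalized convolution"); the alternative of treating the outside
as zeros would manufacture phantom edges at every field border and make
uniform frames fire, which contradicts the physiology the operator is
meant to capture. Mirrored borders are available via `border="reflect"`.
Responses with magnitude below 1e-12 are snapped to exact zero so that the
strict-inequality firing rule is not at the mercy of float residue.

Firing is binary: a cell fires iff its graded response strictly exceeds
`(GC_max − GC_min)·α`, with α = 0.2 and the max/min taken over all fields
of the frame (per-field scope is available). The off-centre pathway uses
its own σ pair and fires on sign-flipped responses; the default pipeline
runs the on pathway only, giving the 81-element binary vector per field
that all later stages consume.

Every field owns an orientation column of 19 chips — prototype vectors in
[0, 1]^81 — arranged on a two-ring hexagonal lattice (1 + 6 + 12 chips,
unit nearest-neighbour spacing). Training is competitive and *restricted*:
a column sees only its own field's binary GC vector. Per presented image,
each active column selects its most similar chip (cosine; ties to the
lowest chip id) and updates every chip by

    W ← W + α(t) · exp(−(d/w)²) · (V − W)

where d is the layout distance to the winner, w = 1 the neighborhood
width, and α(t) = 1/(1+t/T) the learning rate (t counts presented images,
shared by all columns; T is the planned total). Updates are convex, so
weights remain in [0, 1]. Blank fields (no firing) skip their update but
the clock still advances. Note two untraditional features, kept as the
model defines them: the neighborhood never shrinks and α never falls below
1/2. Their consequences are discussed under Limitations.

Inference selects the winner chip per field by cosine similarity (default;
the normalization matches a selection datapath with an explicit division
stage) or Euclidean distance (compared as squared distances internally).
A blank field, or an all-zero score vector under cosine, yields a
"no-activation" sentinel. The bit-packed fast path stores the binarized
weights (cut 0.5) transposed by GC position — word i carries chip b's bit
in position b — and computes all 19 dot products per position via masked
population counts; for binary vectors `‖V−W‖² = ‖V‖₁+‖W‖₁−2·V·W` and
`cos = V·W/√(‖V‖₁‖W‖₁)`, so the fast winner provably equals the dense
winner on the binarized weights (asserted over seeded trials). Reducing 19
candidates takes ⌈log₂ 19⌉ = 5 comparator rounds.

## Chip characterization and maps

A chip's preferred orientation is measured by probing, not by reading its
weights. Probes are field-sized bars (width 3, contrast 1) at a grid of
orientations; because chips learn orientation *and position* (two
same-orientation bars three pixels apart produce nearly orthogonal binary
patterns), each orientation is additionally swept across perpendicular
offsets spanning the field, and the chip's response at that orientation is
its best cosine match over the sweep — the analogue of sweeping a
grating's phase in a physiology experiment. The preferred orientation is
the axial (period-180°) circular mean of the probes within 90% of the peak
response; selectivity is the resultant length of the baseline-subtracted
curve on doubled angles (0 for flat curves, whose preference is undefined).

The cortical map places each column's 19 chips into a 5×5 block (hexagon
rows centred, corner cells filled from the nearest assigned cell) on the
field grid, coloured by a cyclic hue over [0, 180) (hue(0) ≡ hue(180);
undefined cells gray, or filled from the nearest defined cell for
analysis). Pinwheels are detected by discrete winding: around every 2×2
plaquette the four consecutive orientation differences, each wrapped to
[−90°, 90°), are summed; a net ±180° marks a singularity of sign ±1. A
constructed field θ = ½·atan2(y−y₀, x−x₀) yields exactly one positive
singularity, and winding is conserved over composite fields.

## Synthetic stimuli

`stimuli` renders bars, edges, gratings, outlined shapes and digit-like
strokes with exact (non-anti-aliased) masks, so tests can assert against
brute-force rasterization oracles. Orientations are axial degrees,
counter-clockwise from the horizontal as displayed, in [0, 180); a quarter
turn of the raster adds 90° (mod 180). Training corpora place bars
through uniformly random interior points (±45% of each dimension) with
contrasts in [0.6, 1], stratified round-robin over the requested
orientations; identical spec + seed is bitwise reproducible. The generator
emulates the orientation statistics the columns are meant to learn; it
does not emulate natural-image second-order statistics, sensor noise, or
occlusion, so passing results show orientation recovery on clean oriented
structure, not natural-scene performance.

## Evaluation protocols

All experiments run on a 33×33 frame (a 5×5 field grid) — small enough
for seconds-scale runs, large enough that every column is exposed to every
orientation — with every random draw derived from one seed.

**Four-orientation recovery.** Columns are trained on 240 bars at
{0, 45, 90, 135}°, T = 240. A held-out randomized corpus (120 bars) is
represented, and observations are scored only for *core crossings*: fields
whose centre lies within 2.5 px of the bar axis. A bar that merely grazes
a field's corner leaves an in-field pattern whose local orientation
genuinely differs from the bar's global orientation (the clipped segment
hugs the border), so grazing contacts — while still part of training and
inference — are excluded from scoring, as a physiologist centres the
stimulus on the receptive field before scoring a neuron. Reported:
clustering purity of (column, winner chip) clusters against true
orientations; the number of distinct chips serving as a class's modal
winner in some column; and per class the *population-vector* error — the
win-count-weighted axial mean of recruited chips' preferred orientations
against the true class orientation. Per-column statistics (minimum and
mean distinct winners over the four classes) are reported alongside.

**Pinwheel formation.** Columns trained on a 12-orientation corpus
(360 bars) are probed at 7.5° steps; the filled orientation field is
scanned for singularities.

**Rotation equivariance.** A square frame with 90°-symmetric tiling is
represented before and after `rot90`; the rotated field grid with
orientations shifted by 90° is compared cell-wise (axial tolerance 15°),
and the match fraction is taken over the union of active fields.

## Numerical and design notes

- Winner ties resolve to the lowest chip id everywhere (training,
  inference, bitwise path). Note this deterministic rule is itself not
  rotation-equivariant: a pattern exactly tied between a 0° and a 90° chip
  resolves to the same lower id in both frames.
- Euclidean selection compares squared distances; reported scores are
  square-rooted.
- Cosine with any zero vector is defined as 0.
- Axial statistics double the angles, average, and halve.
- The weight container is a `.npy` array plus a versioned JSON sidecar
  (topology, config, tiling, iteration counter); loading validates format,
  version, and shape.

## Limitations

- Because α(t) ≥ ½ and the neighborhood never shrinks, prototypes never
  anneal: each chip remains a running mixture of its own and its
  neighbours' recent wins. The population-level readouts above are stable
  (purity ≈ 0.85–0.92, class orientation errors ≤ ~10° across seeds), but
  per-chip attribution is noisy: an individual winner's preferred
  orientation can be far from its stimulus's orientation. In particular,
  rotation-equivariance of *trained* columns measured per field is weak
  (match fractions well below the ≈1.0 of hand-constructed isotropic
  columns), and the held-out histogram of a single bar can peak off its
  true orientation through grazing fields. An annealed schedule would
  sharpen chips, but is not what this model specifies.
- Chips encode orientation×position jointly; any readout that assumes
  pure orientation tuning must sweep position (as `probe_tuning` does).
- The map's spatial arrangement (5×5 blocks on the field grid) is a
  rendering convention; pinwheel counts depend on it.
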