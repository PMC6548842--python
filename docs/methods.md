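# Methods

## Model

A trial grid is a P × Q lattice of rectangular cells of fixed pixel size
W × H; cell (p, q) sits at center (u_pq, v_pq) and may translate by
θ_pq = (δᵘ_pq, δᵛ_pq) within the box |δᵘ| ≤ Δᵘ, |δᵛ| ≤ Δᵛ. Cells never
change size, shape or orientation: traits such as emergence and yield are
quoted per sown plot area, so the sown rectangle — not the canopy outline —
is the unit of analysis.

The image enters only through a scalar field S on the pixel lattice, by
default the green–red difference index (G − R)/(G + R). Any single-band
field with higher values over plants than background can be substituted.
Pixels with G + R = 0 (and nodata pixels) are assigned S = 0, a neutral
value that neither attracts nor repels cells.

Energies per cell at a candidate displacement:

- intra-cell: d_pq = Σ S over the displaced cell rectangle;
- inter-cell: g_pq = Σ over overlapping von Neumann neighbors of
  [d_p'q' / (d_pq + d_p'q')] · (Σ S over the overlap rectangle). A pair
  with d_pq + d_p'q' = 0 contributes 0 — there is no vegetation energy to
  attribute. The two shares of an overlapping pair sum exactly to the
  overlap energy, so vegetation is never double-counted and never lost;
- net: f_pq = (d_pq − g_pq)/(W·H); grid cost f = exp(−mean f_pq).

The exponential keeps the objective positive and numerically stable; the
mean makes the cost scale-free in the number of plots. A hard-overlap
variant (infinite penalty for any overlap) is included only as a reference
for tests: it creates a barrier that traps the optimizer, whereas the
proportional ("soft") penalty lets cells pass through mild overlap on
their way to the right placement.

## Discretization

The displaced cell rectangle is snapped to the nearest integer pixel
position: the sample set is [round(c − W/2), round(c − W/2) + round(W))
per axis, always exactly round(W)·round(H) pixels. This makes every
rectangle sum an exact four-lookup query on a summed-area table (one cost
evaluation is O(P·Q) independent of image size) at the price of a
half-pixel quantization floor in the recovered displacements — 0.4 cm at
the default 0.8 cm/px, negligible against the centimeter-scale errors of
interest. The swarm still searches continuous displacements. Overlap
rectangles are intersections of the snapped cell rectangles; cells may
extend past the image border, where outside pixels contribute zero energy
(border plots near mosaic edges are legal).

Rotated trials are handled before optimization: the scalar field is
resampled once into the grid frame by inverse rotation with bilinear
interpolation, so all energies work on axis-aligned rectangles; exported
polygons are mapped back to the image/world frame.

## Optimization

Bound-constrained adaptive particle swarm over the N = 2·P·Q flattened
displacement coordinates:

| parameter | default | meaning |
|---|---|---|
| swarm_density K/N | 8 | particles per coordinate; densities 6–12 give the lowest errors, 8 sits mid-band |
| tolerance | 1e-4 | relative drop of best cost over the stall window that counts as progress |
| stall_iterations | 20 | window for the tolerance stop |
| max_iterations | 200·N | hard cap (the tolerance stop fires long before) |
| inertia_range | [0.1, 1.1] | adaptive inertia bounds |
| c1 = c2 | 1.49 | cognitive / social acceleration |
| min_neighborhood_fraction | 0.25 | initial size of the random best-neighbor subsets |
| velocity_clamp_fraction | 0.1 | per-coordinate velocity limit as a fraction of the box span |
| bounds Δᵘ, Δᵛ | half the grid pitch | a cell may not jump past a neighboring plot |

One particle is initialized at zero displacement (the uniform grid), so
the returned solution can never be worse than the starting layout; the
rest are uniform in the box. Each iteration every particle is attracted to
its personal best and to the best personal best in a freshly drawn random
neighborhood; inertia doubles (capped) while the global best improves and
halves (floored) during sustained stagnation, while stagnation also grows
the neighborhoods — a collapse-and-re-expand cycle that converts
exploration into refinement. Positions are clamped to the box with the
velocity zeroed on clamped coordinates.

Two numerical choices matter and were set by measurement on synthetic
validation trials:

- **Velocity clamp.** Clamping at the full box span lets particles
  repeatedly overshoot entire plots (the box spans the whole pitch);
  median error on validation-style trials improved from ~6 cm to ~3.6 cm
  when the clamp was tightened to 0.1 of the span, with no loss of basin
  coverage (initial positions, not velocities, provide the exploration).
- **Inertia decay on stagnation.** Adjusting inertia only on improving
  iterations leaves the swarm divergent at high inertia until the stall
  stop kills the run; decaying inertia during stalls instead converts
  stagnation into refinement and is what makes the tolerance stop
  meaningful.

The stopping rule is the relative change of the best cost over the last
`stall_iterations` iterations falling below `tolerance`. Tolerances below
1e-4 do not measurably improve alignment errors and only lengthen runs.
Runs are bit-reproducible from the seed.

## Synthetic trials

No trial orthomosaic is bundled; validation runs on generated look-alikes.
The generator renders low-frequency brown soil noise plus per-plot sown
rows of overlapping green-dominant ellipses, each plot drawn at a known
displaced position; only the statistics of the resulting index field
matter to the algorithm, not photorealism. Two geometries are bundled:

- **validation style**: 5 × 12 plots of 1.2 × 4 m, six sown rows at 0.2 m
  spacing, 0.8 cm/px. Inter-plot pitch is not part of the trial
  description and was fixed once at 1.6 × 4.8 m — 0.4 m between plot
  columns and 0.8 m alleyways, typical machinery clearances for plots of
  this size.
- **test (breeding) style**: 48 × 12 single-row plots of 0.3 × 5 m, pitch
  0.5 × 5.5 m. Single-row stands establish unevenly, so emergence
  probability and plant size taper over the outer 15% of each row
  (`end_taper = 0.15`); this center-weighted canopy is what makes
  length-trimmed grids overestimate coverage in real trials and is absent
  from the sharply delimited validation-style plots (`end_taper = 0`).

Misalignment for validation studies is i.i.d. uniform within the full
half-pitch search box — deliberately extreme, plots can nearly touch.
Breeding-style studies use longitudinal-dominant displacements (5% of the
across-row bound, 40% of the along-row bound), matching the sowing-track
variability such trials actually show. The per-run success criterion,
where one is needed, is median per-cell error ≤ ¼ of the smaller pitch.

A second misalignment tool perturbs an *existing* mosaic: each plot's
region, grown by a margin, is translated to the displaced position and the
exposed band is filled with the region's mirror reflection about its
trailing edge. The result has no voids and its seams fall in low-texture
soil; a naive cut-and-paste variant (which does leave voids) is kept for
contrast. The exact reflection construction is this package's own; it is
one of several geometries with the same no-void property.

What the generator does **not** emulate: weeds, shadows, flowering heads,
lodging, radiometric vignetting, stitching artifacts, and perspective
residues. Passing the synthetic suites therefore demonstrates the
optimizer and energy model under controlled index statistics, not
robustness to every real-world nuisance; on real mosaics the practical
failure modes are partially emerged plots (ambiguous along-row position)
and vegetation between plots.

## Evaluation

Per-cell alignment error is the Euclidean distance between true and
computed displacement vectors, converted to cm via the resolution.
Distributions are summarized boxplot-style (quartiles, 1.5 IQR whiskers,
individually flagged outliers, 1.57·IQR/√n median notches — non-overlapping
notches between two runs are the significance criterion used for the
refined-vs-uniform comparison).

Canopy coverage per cell is the fraction of its pixels above a
segmentation threshold on S; the threshold defaults to Otsu's criterion on
the index histogram (a reproducible stand-in for manual tuning) and can be
overridden. The trimmed-grid variant deliberately divides by the trimmed
cell's own area — that is how trimmed grids are used in practice and is
what produces their overestimation. Coverage across grid variants
(regular / trimmed / refined / ground truth) is compared with a one-way
ANOVA plus Tukey HSD at α = 0.05.

## Problem sizes in the bundled studies

The scripted studies and the acceptance script run at desk scale: five
validation-style trials (60 plots each, N = 120) for the pooled error
estimate, 50 swarm initializations on a reduced 3 × 8 trial (N = 48) for
the robustness count, a 4 × 6 paired-vigor zero-gap trial for the cost
ablation, and a 12 × 12 breeding-style trial (N = 288) for the
error-distribution and coverage comparisons. Full-scale replication
(50 runs / 48 × 12 grids) is a config flag away (`--full-scale`), with
runtimes growing linearly in the number of runs.

## Known limitations

- Cell dimensions are fixed; trials with variable plot sizes need a grid
  per size class.
- The energy rewards any vegetation, so heavy inter-plot weeds can anchor
  cells between plots.
- The cost optimum and the true alignment are related but not identical:
  on sparse or partially emerged plots the cost surface is flat along the
  row and a minority of cells settle tens of cm off. These show up as
  boxplot outliers; rerunning with a different seed usually resolves them.
- The shapefile I/O implements the polygon subset of the format (one outer
  ring per record, numeric/character attributes) — sufficient for plot
  grids, not a general GIS reader.
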