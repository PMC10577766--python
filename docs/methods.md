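# Methods

## The problem

The solvent-excluded surface (SES) of a molecule is the boundary of the region
a spherical solvent probe (radius 1.4 Å for water) cannot reach while rolling
over the van der Waals spheres of the atoms. It consists of contact patches
(pieces of atom spheres the probe touches directly) and reentrant patches
(inward-curving pieces traced by the probe bridging nearby atoms). Implicit
solvent models use the SES as the dielectric boundary, so surface construction
sits on the critical path of Poisson–Boltzmann energy calculations and
docking-scale screening.

`sesnet` represents the SES implicitly through a level-set field: a scalar
y(g) on a regular lattice that is positive outside the solute, negative
inside, with the surface at the zero crossing. The package provides

1. a classical grid labeler that computes y from geometry (the oracle),
2. a small neural network that *predicts* y from local atom neighborhoods,
3. surface extraction at the zero level by linear interpolation, and
4. point-cloud and field metrics (Chamfer Distance, F-score, R², MAE).

## Oracle labeling

The labeler classifies grid points in two passes:

- **Pass 1 (solvent-accessible region).** A point is SAS-interior iff its
  distance to some atom center is below `r_atom + r_probe`; equivalently, a
  probe centered there would overlap an atom.
- **Pass 2 (probe re-entry).** A SAS-interior point is re-classified exterior
  iff it lies within `r_probe` of some SAS-exterior grid point: a probe
  centered at an accessible position covers it. The remaining SAS-interior
  points are the SES interior.

The magnitude of y is the Euclidean distance to the opposite region (computed
with exact Euclidean distance transforms on the lattice), clamped to
±`clamp` (default 1.0 Å). Clamping bounds the regression targets: far-field
points all read exactly +clamp, deep interior points −clamp, and all the
geometric information concentrates in the band around the surface. With the
conventional `probe_radius = 1.4 ≥ clamp` the clamp never truncates a
distance that the probe-ball geometry could not justify.

Using grid points as the pass-2 probe-center candidates is the classic lattice
approximation; its error is O(spacing) and confined to roughly one voxel
around the surface. Two documented consequences:

- **Probe monotonicity.** Enlarging the probe can only grow the true SES
  interior. On the lattice this holds for every point deeper than one voxel;
  points in the single boundary-adjacent layer can flip either way. The tests
  assert the property at exactly that level.
- **Lattice-phase noise.** A field labeled *directly* at a coarse spacing
  carries half-voxel quantization tied to where the lattice happens to fall
  relative to the atoms. Zero-crossing surfaces extracted from two different
  lattices of the same molecule then disagree by up to half a spacing even
  though both are "correct".

### Internal fine resolution

The phase noise matters as soon as surfaces from different grids are compared,
which is the whole point of a grid-robustness analysis. `label_level_set`
therefore accepts a `resolution` parameter: the two-pass classification and
distance transform run once on an internal lattice of that spacing (pipeline
default 0.3 Å), and the fine field is trilinearly resampled onto whatever grid
is requested. Every coarse grid then samples one fixed continuous function,
and zero crossings at any spacing approximate the same surface, with only
O(s²) interpolation error. The direct per-grid path (`resolution=None`)
remains the default for single-grid use and is what the oracle's unit tests
exercise.

## Features

Each queried point g is described by its k = 24 nearest atoms: per neighbor
the displacement vector `a_j − g` (Å) and the atom radius, giving a 96-vector.
Slots are sorted by distance (ties broken by atom index) and zero-padded when
fewer than k atoms exist. Relative displacements make the representation
exactly translation invariant and — crucially — independent of the grid
spacing, which is what lets one trained model evaluate on any lattice. The
representation is rotation-*covariant* (the vectors rotate with the
molecule); rotational robustness is left to the training distribution, which
contains randomly oriented local geometry. An optional distance `cutoff`
supports a cutoff-then-pad scheme instead of pure k-NN; pure k-NN is the
default because it is parameter-free.

## Model and training

The regressor is a plain MLP, 96 → h2 → h3 → 1 with ReLU hidden activations
and a linear output; the default h2 = 64, h3 = 32 (8,321 parameters) sits in
the middle of the supported search grids h2 ∈ {8, 16, 32, 64, 96, 100},
h3 ∈ {8, 16, 32, 40} explored by `grid_search`. The loss is mean squared
error; gradients are hand-derived and verified against central finite
differences. Optimizers: plain SGD (the baseline the update rule
θ ← θ − η∇L describes), heavy-ball momentum (the default for `train`), and
Adam (used by the pipeline protocol — selectable via `optimizer=`). A
per-epoch exponential learning-rate decay (`lr_decay`) and a float32 training
mode (about 1.8× faster on one core, no measurable accuracy cost at this
model size) are available. Training carves off a seeded validation split and
returns the parameters of the best-validation epoch.

Feature values are a few Å in magnitude and are not normalized by default;
z-scoring was not needed for convergence at these scales.

## Training-set construction

Grid points are extremely imbalanced: in a typical labeled box over 80 % of
points sit at the clamp ceiling (+1) and most of the rest at the floor (−1).
Uniform sampling would drown the thin near-surface band that determines where
the zero crossing lands. Two samplers address this:

- `feature_dataset(..., balanced=True)` draws equal thirds from
  {clamped interior, |y| < clamp band, clamped exterior}.
- The pipeline's `build_training_set` keeps up to `band_per_grid` band points
  per labeling plus `far_per_grid` random clamped points, and re-labels each
  molecule on `n_grids` origin-jittered lattices (shifts up to half a
  spacing), harvesting fresh off-lattice samples of the same underlying field.

## The synthetic molecules

`generate_synthetic` provides four presets. The workhorse is `cluster`: a
bonded random walk that places each new atom 1.2–2.0 Å from a randomly chosen
existing atom (rejecting overlaps below 1.2 Å) with radii drawn from
1.2–2.0 Å. Adjacent-atom separations near bonding distances guarantee
probe-inaccessible crevices, i.e. reentrant SES patches — the geometrically
hard part of the problem. `single`, `diatomic` (parameterized separation) and
`helix` cover analytic and extended-backbone geometries. What the generator
does *not* emulate: element-specific radius patterns, secondary-structure
regularity, interior cavities of protein scale, and sizes beyond a few
hundred atoms. Passing tests therefore demonstrate that the method learns SES
geometry of compact bonded clusters, not that it matches production labelers
on real proteins.

## Evaluation protocol

The standard protocol trains on 20 cluster molecules of 40 atoms and holds
out 5 more (an 80/20 split), labels at s = 0.55 Å through the 0.3 Å internal
resolution, uses 5 jittered labelings per molecule (12,000 band + 2,500 far
samples each, ≈1.4 M rows), and trains the default network with Adam
(lr 3 × 10⁻³, decay 0.98/epoch, batch 2048, 200 epochs, float32). Molecule
size and counts were chosen as a desk-scale stand-in for a protein benchmark:
40 atoms is the smallest size with substantial reentrant area, and 25
molecules keep the full pipeline within minutes on one core.

Held-out evaluation predicts the field on each test molecule's full grid and
compares to the oracle on the same grid: R² and MAE on raw values, Chamfer
Distance and F-score (hit radius 0.15 Å) on the extracted surfaces.

The grid-spacing sweep evaluates the single model trained at 0.55 Å on grids
of 0.35, 0.55, 0.75 and 0.95 Å. Each spacing is compared against the oracle
reference *on the same grid* — both clouds then have matching point density,
so the comparison isolates the model's spacing sensitivity; comparing a
coarse predicted cloud against a dense fixed reference at a 0.15 Å hit radius
instead measures sampling density (recall collapses for any model, see
`examples/03_surface_metrics.py`).

## Numerical choices

- Exactly-zero level-set values are treated as exterior and emitted once as
  surface points; adjacent edges are not double-counted.
- Surface extraction uses linear interpolation along grid edges (the
  restriction of trilinear interpolation to edges); duplicate crossings are
  merged at 1e-9 Å.
- Chamfer Distance is the symmetric *mean* of nearest-neighbor distances, so
  values are in Å and comparable across cloud sizes.
- F-score precision/recall use closed hits (distance ≤ r) and the 0/0 → 0
  convention.
- Nearest-neighbor queries go through a k-d tree; a brute-force path
  (`method="brute"`) exists solely as an independent cross-check in tests.
- k-NN ties in feature extraction are broken by atom index for determinism.
- Grid spacing is restricted to (0, 1] Å by convention; larger spacings warn
  rather than fail so robustness sweeps can explore beyond.
- All randomness flows through explicit integer seeds; training is bitwise
  reproducible on a fixed BLAS.

## Known limitations

- Interior cavities are labeled like any other probe-inaccessible region; no
  cavity detection or special treatment is attempted.
- The oracle's pass-2 grid approximation can misclassify within one voxel of
  the surface; the internal fine resolution reduces but does not eliminate
  this (it is O(resolution), not zero).
- No analytic SES triangulation, normals, or curvature — the output is a
  surface point cloud.
- The model card is a point-cloud regressor: transfer to molecules much
  larger than, or chemically unlike, the training distribution is untested
  here by design.
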