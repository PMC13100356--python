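# Methods

## Model and assumptions

`voidscan` treats a molecular configuration as a set of mass points in a
periodic cell. A *void* is an operational, not thermodynamic, notion: a
voxel whose locally averaged mass density falls below a cutoff; a *bubble*
is a periodic-connected set of void voxels exceeding a minimum volume. The
method makes no assumptions about chemistry — only coordinates, masses, and
box vectors enter — so it applies equally to all-atom and coarse-grained
systems.

The cell is stored in lower-triangular lattice-vector form
(`a = (a_x,0,0)`, `b = (b_x,b_y,0)`, `c = (c_x,c_y,c_z)`); PDB CRYST1
lengths+angles and GRO 3- or 9-component box lines are converted to this one
convention on input, so no downstream code branches on file format. Wrapping
targets the rectangular brick `[0,a_x)×[0,b_y)×[0,c_z)`, which tiles space
under lattice translations for any such cell. The wrap proceeds bottom-up
(shift by multiples of `c` to fix z, then `b` for y, then `a` for x), each
step leaving previously fixed axes untouched. Shear components are assumed
at most about half the diagonal, as produced by standard MD engines; no
lattice reduction of extreme cells is attempted.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `resolution` | 1 | Å | voxel edge; per-axis counts are `round_half_up(L_i/h)` (≥ 1) and actual edges `L_i/n_i`, so voxels tile the brick exactly |
| `neighbor_cells` | 4 | cells | stencil radius; membership is by integer offset norm `i²+j²+k² ≤ n²` (257 offsets at n = 4), equal to 4 Å at default resolution |
| `density_cutoff` | 0.25 | g/L | voids are voxels with density strictly below this; 1/4000 of liquid water, i.e. effectively "no mass anywhere in the stencil" |
| `min_bubble_volume` | 0.1 | nm³ | components must strictly exceed this to be reported |
| `connectivity` | 26 | — | face+edge+corner adjacency; 6 available. Discretized spherical voids connect diagonally, hence 26 |
| `periodic_labeling` | on | — | adjacency wraps across all three boundaries, merging fragments of one bubble split by wrapping |

The stencil radius is counted in **cells**, not Å: with coarser grids the
averaging sphere grows with the voxel (e.g. 2 Å voxels with n = 2 average
over ±4 Å). For anisotropic voxels the integer-offset norm is a documented
approximation to a physical sphere.

Unit conversion is the single constant `G_PER_L_PER_DA_PER_A3 = 1660.539`
(1 Da/Å³ in g/L); masses stay in Da and coordinates in Å everywhere else.

## Numerical choices

- **Strict inequalities.** `density < cutoff` classifies a void;
  `volume > min_volume` reports a bubble. A component of exactly 100 voxels
  at 1 Å resolution (0.100 nm³) is suppressed; the threshold comparison uses
  a 1e-9 relative guard so that binary representation of 0.1 cannot flip
  the boundary case either way.
- **Averaging volume** is stencil size × cell volume. Under periodicity
  every stencil cell exists, so no partial-neighborhood normalization is
  needed, and total mass is conserved exactly:
  `Σ ρ(c)·V_cell = 1660.539 · Σ m`.
- **Point binning.** An atom contributes its whole mass to the single voxel
  containing its coordinate (`floor(x/h)`, clamped to `n−1` against
  floating-point spill at the upper face); no smearing kernel.
- **Wrap edge cases.** After the per-axis integer shift, one single-step
  correction handles coordinates that rounding leaves at exactly `L`; a
  coordinate within one ulp of the boundary that survives both corrections
  (possible with denormal shear components) is snapped to 0, a perturbation
  below float precision.
- **Labels** are renumbered 1..K in first-encounter raster order after the
  periodic union-find stitch, making label assignment deterministic and
  identical to the brute-force reference ordering.
- **Centroids** use the circular mean per axis (voxel centers mapped to
  angles on the periodic circle), so bubbles straddling a boundary get
  interior centroids. Second moments (radius of gyration, principal extents
  from the covariance eigendecomposition) are computed on coordinates
  unwrapped to the image nearest the centroid — valid while a bubble's
  extent stays below half the box per axis. Each principal extent is
  reported as `2·sqrt(3λ)`, the edge length of the uniform block with
  variance λ.
- **Degenerate inputs.** An empty frame is legal (the whole box is one
  bubble); an all-dense frame reports zero bubbles; an empty frame
  selection yields an empty report list, not an error.
- **Tracking tie-breaks.** Cross-frame matching is greedy on voxel overlap;
  equal overlaps are broken by lower (previous, current) label pair.
  Tracking is reporting-only and never feeds back into detection.

## Synthetic systems

The fixture generator emulates the situations the detector is meant for,
with every expected value exactly computable:

- **Solvent** is a jitter-free simple-cubic lattice of single 18.015 Da
  beads (one per water). Spacing follows `s³ = m·1660.539/ρ` (3.104 Å at
  1000 g/L); per-axis counts are chosen so the achieved mean density is
  within ~2% of target for boxes ≥ 30 Å, at the cost of mildly anisotropic
  spacing. With point beads and the default cutoff, a voxel is void exactly
  when its whole stencil contains no bead, so the expected void set is an
  independent morphological erosion computed by brute force.
- **Carved spheres** remove beads within a minimum-image radius; centering
  the sphere at a box corner produces the wrapped-fragments case.
- **Triclinic solvent** fills a skewed cell by lattice construction in
  fractional coordinates, then wraps.
- **Membrane-like profiles** stack three independent sub-lattices
  (bulk / reduced / bulk along z) so each slab hits its own density target;
  the mid-plane is constrained to ≥ 600 g/L — far above cutoff — making the
  fixture a guaranteed true negative that still exercises the
  false-positive risk of low-density bilayer cores.
- **Shrinking-bubble trajectories** carve radius
  `r_t = R₀(1 − t/(T−1))` per frame. Atom count is held constant (as
  trajectory formats require) by relocating carved beads to seeded-random
  positions outside the sphere, mimicking solvent compressed out of a
  cavity at constant volume. Frames are written as PDB plus a multi-model
  PDB trajectory with a CRYST1 record inside each MODEL block (per-frame
  boxes are how constant-pressure trajectories behave, and multi-model
  readers take dimensions from within the block).

What these fixtures do **not** emulate: thermal disorder, multi-site waters,
real force-field structure, partial densities at bubble interfaces, or
droplet-in-vacuum geometries. Passing tests therefore demonstrate the
geometry and bookkeeping of the pipeline (wrapping, stencils, periodic
labeling, thresholds, units) — not detection performance on noisy real
densities, where the interface between bubble and solvent is gradual. On
lattice fixtures the detected cavity is systematically wider than the
continuum-erosion estimate `(4/3)π(R−n·h)³` because the nearest beads sit up
to one lattice spacing outside the carved radius.

## Problem sizes

The shipped tests and the acceptance script run on 30–50 Å boxes
(≈ 0.9–2×10³ beads, 27–125×10³ voxels), 100 randomized grids up to 16³ per
brute-force cross-check, and a 10-frame trajectory — sizes chosen so every
check has an exactly computable reference while exercising all code paths;
the pipeline itself is streaming and handles arbitrarily long trajectories
at constant memory per frame.

## Known limitations

- Second moments assume a bubble spans less than half the box per axis;
  larger bubbles get correct volumes but distorted shape statistics.
- The stencil is a voxel-offset sphere; for strongly anisotropic voxels it
  is an ellipsoid in physical space.
- Droplet-in-vacuum systems report the surrounding vacuum as one large
  void; no automatic internal/external classification is attempted — the
  minimum-volume filter and the report layer give the user control.
- GRO coordinates carry 0.001 nm precision; round-trips through GRO are
  exact only to 0.01 Å. PDB and GRO store no masses, so re-read frames get
  masses inferred from element symbols.
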