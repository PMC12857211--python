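# Methods

## Coordinate and unit conventions

Volumes are 3D integer label grids indexed `(z, y, x)` with voxel
spacing `(dz, dy, dx)` in micrometers; TIFF pages are z-slices. Label 0
is background and never identifies a cell or pore. Voxel `(z, y, x)` has
its physical center at `((z+0.5)·dz, (y+0.5)·dy, (x+0.5)·dx)`; a shared
voxel face lies half a voxel further along its normal axis. All lengths
are micrometers throughout — PD diameters are hundredths of a
micrometer, OP diameters are micrometers, and a single unit avoids
silent scale errors between the two.

## Interfaces

An interface is the set of voxel faces shared by two distinct
non-background labels under 6-connectivity; diagonal contacts do not
create interfaces, and background (the volume border) never does. Face
areas honor anisotropy (`dy·dx` for z-faces, etc.), so the interface
area is exact for the discrete surface. A cell pair sharing several
disconnected wall patches is one interface: downstream statistics group
by interface class, not by patch. Interfaces below a minimum area
(default: four voxel-faces' worth, configurable and echoed in every run
manifest) are dropped as segmentation noise. Note that the discrete
(staircase) area of an oblique wall exceeds its geometric area; the
synthetic generator defines pore intensities per unit of *discrete* wall
area, so simulated densities and estimated densities share one measure.

## Pores

Pore volumes may be instance-labeled (one label per pore) or binary;
binary volumes are split under 26-connectivity because small blobs
fragment under 6-connectivity. Each pore gets the equivalent diameter of
the sphere matching its voxel volume; annotation tables supply the
diameter directly. Classification is a pure threshold on equivalent
diameter — OP iff *d* ≥ 0.2 µm by default. Plasmodesmata are tens of
nanometers wide and open pores are micrometer-scale, so any threshold in
the gap separates them; the value is configurable and always logged.
Each pore is assigned to the interface whose nearest boundary-face
center (3D Euclidean, physical units) is closest to the pore centroid;
ties go to the lexicographically smallest cell pair, and pores farther
than 2 µm (default) from every wall stay unassigned and are reported —
pores belong on walls, so distance signals segmentation error.
Densities are counts divided by the class's total wall area.

## Nearest-neighbor spacing and directional tests

NN distances are computed *within* one interface (spacing across
unrelated walls is biologically meaningless) and pooled by interface
class afterwards; an interface contributes only if it has ≥ 2 pores of
the analyzed kind set (OP alone, or PD+OP combined). Distances are 3D
Euclidean between centroids — walls are thin and near-planar at pore
spacing scales, so geodesic distance is not computed. Box summaries use
linear-interpolation quartiles (quantile *q* at position `(n−1)·q`) and
the 1.5·IQR outlier rule with whiskers at the extreme non-outlier
values.

The directional contrast tests whether PC–PC spacing exceeds TT and TP
spacing, with a pooled-variance Student's *t* (df = n₁+n₂−2), one-tailed;
Welch's form is available behind a flag. Significance codes are
* (p < 0.05) and ** (p < 0.01). Degenerate input with zero pooled
variance and equal means yields p = 0.5 by convention.

Two units of observation are supported. The display default is the
individual NN distance (`per-pore`), matching how such distances are
plotted. For inference the package prefers `per-interface-mean`: NN
distances on one wall are not independent — mutual nearest neighbors
contribute duplicated values — so a per-pore *t* test understates the
variance and rejects a true null far too often (measured at ≈ 0.10–0.37
depending on pore counts), while interface means are independent across
walls and calibrate close to the nominal level. The simulation studies
and the acceptance script therefore run the contrasts on interface
means; both units are covered by tests.

## Synthetic tissue generator

The generator emulates the statistical structure of FIB-SEM mesocarp
volumes, not their appearance:

- **Mosaic** — Voronoi tessellation of uniform seed points, with
  distances in physical units so anisotropic voxels give correct walls;
  every voxel is assigned to a cell.
- **Cell types** — Bernoulli(TC fraction) per cell, then one Potts-like
  sweep that shifts each cell's TC log-odds by
  `tc_clustering × (TC-neighbor count − expected)`, producing spatial
  clustering of tannin cells while holding the overall fraction near the
  target. Default fraction 0.35 (idioblasts are a minority), clustering
  0.5 (TCs occur in groups).
- **Pores** — per interface and kind, the count is Poisson(intensity ×
  wall area). OPs are a homogeneous Poisson process on the wall
  (area-weighted face choice, uniform in-plane jitter). PD form a
  Matérn-style cluster process: Poisson cluster centers, geometric
  offspring counts (mean 4), offspring within 0.5 µm of the center.
  Diameters are uniform: PD 0.02–0.06 µm, OP 0.5–3 µm. These sizes and
  the default intensities — OP: TT 0.02, TP 0.01, PP 0.002 µm⁻²; PD
  chosen so every class totals 0.05 µm⁻² — encode the qualitative
  findings the package is built around: OPs most frequent at TC–TC
  walls, rarest at PC–PC walls, combined PD+OP density comparable across
  classes.
- **Painting** — pores become spheres (single voxels when sub-voxel) in
  an instance-labeled pore channel, painted large-to-small so a small
  pore overlapping a big one survives as its own component. A pore whose
  sphere would cover a third cell is re-positioned on its wall (up to 10
  retries, then clipped). Generation fails if the overwritten-voxel
  fraction exceeds the collision budget (default 10%); a rare pore can
  still be fully overwritten, so painted component counts may fall
  slightly below the ground-truth table. Cells touching the volume
  border keep their outer faces pore-free: pores exist only on
  cell–cell walls.

Identical seeds give bit-identical volumes and tables.

What the generator does **not** model: grayscale appearance and imaging
noise, organelles and vesicles, PD substructure, curved cell shapes
beyond convex Voronoi polyhedra, or wall thickness. Passing tests
demonstrate that the measurement pipeline recovers known generative
parameters on this idealization — not that segmentation of real volumes
is correct.

## Simulation study sizes

Chosen once as the smallest regimes where the estimates are stable:

- **Density recovery** — 60 µm cube at 0.5 µm voxels, 110 cells,
  balanced cell types so each interface class carries > 10⁴ µm² of wall;
  pores enter as ground-truth annotations (painting adds nothing to this
  question). OP densities are recovered within a few percent and the
  TT > TP > PP order is reproduced essentially always.
- **Spacing statistics** — 144 µm cube at 1 µm voxels with 64 larger
  cells, so individual walls hold several OPs and PC–PC interfaces reach
  the ≥ 2-pore eligibility threshold; PD intensity is zero here (the
  contrasts concern OPs). Power and type-I rates marginalize over a pool
  of 10 mosaics, re-drawing cell types and pore patterns per replicate —
  regenerating a full voxel mosaic per replicate changes the rates by
  less than the Monte-Carlo noise but dominates the runtime.
- **Poisson closed form** — points are simulated directly on a
  500 × 500 µm wall at λ = 0.01 µm⁻² and fed through the NN machinery;
  focal pores within 2·(1/(2√λ)) = 10 µm of the border are excluded
  (their true nearest neighbor may lie outside the wall) but remain as
  neighbors. The edge-corrected mean matches 1/(2√λ) = 5 µm within 2%.

## Group statistics

Tukey's HSD uses the one-way-ANOVA within-group mean square and the
studentized-range distribution; unequal group sizes use the
Tukey–Kramer form `q = |x̄ᵢ−x̄ⱼ| / √(MSE/2·(1/nᵢ+1/nⱼ))`, which reduces
to the balanced formula when sizes match (and is flagged in the
output). Groups with a single replicate are excluded with a warning.
The compact letter display is a minimal cover of the non-significance
graph by maximal cliques (exact search; deterministic greedy fallback
when the graph has more than 18 maximal cliques), with letters issued
in descending-mean order so reports are reproducible. Sampling dates
are treated as categorical groups (cultivar × date), not as a time
series; the caller decides the grouping factor. The correlation utility
is Pearson by default, Spearman by option, and refuses zero-variance
input.

## Determinism

Every stochastic step draws from one `numpy` Generator seeded from the
run config; pipeline outputs contain no timestamps, so re-running a
config reproduces every CSV and JSON byte-for-byte (verified by hashing
output directories in the tests).

## Known limitations

- Assignment by nearest face center can misassign a pore exactly at a
  multi-wall junction; on collision-free synthetic tissue this affects
  well under 1% of pores.
- The per-pore *t* test is reported for display parity but is
  anti-conservative (see above); inference should use interface means.
- Discrete wall areas are staircase areas; comparing densities against
  geometric (mesh) areas would need a correction factor.
- The generator's diameter ranges and intensities are package defaults
  expressing qualitative structure, not measured persimmon values.
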