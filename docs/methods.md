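# Methods

This note records the mathematical model, the parameter defaults and the
numerical choices made in `gyralfield`, together with the known limits
of the synthetic phantom used for development and testing.

## 1. Field model

The white matter of a gyral blade is modelled by a vector field
`f : R³ → R³` whose magnitude is interpreted as streamline (fibre)
density and whose direction as fibre orientation.  `f` is built to be
divergence-free away from a finite set of point charges, so that
streamlines of `f` cannot terminate in the interior of the domain.

### 1.1 Charge field

For charges `qᵢ` at positions `pᵢ`,

    f_c(x) = Σᵢ qᵢ (x − pᵢ) / (4π |x − pᵢ|³).

Negative charges are placed at the centres of the pial-surface
triangles; charge magnitudes are proportional to the cortical volume
associated with each triangle (the wedge between corresponding white
and pial triangles, decomposed into three tetrahedra).  A single
positive charge balancing the total sits at the deep-white-matter
anchor — the centroid of the deep mask, snapped to the nearest deep
voxel centre if the centroid falls outside the mask.  The total flux
defaults to the total cortical volume: one streamline unit per mm³ of
cortex.  `f_c` is exactly divergence-free except at the charges, and
Gauss's law fixes the flux through any closed surface to the enclosed
charge (verified numerically to ±1 % with a centroid-rule quadrature on
icosphere meshes).

Field evaluation within 1 µm of a charge is rejected; the streamline
tracer additionally stops trajectories entering a configurable
`charge_radius` (default `max(step, 0.05 mm)`).

### 1.2 Divergence-free dipole bases

The correction field is a weighted sum of compactly supported,
analytically divergence-free basis fields derived from the Wendland C⁴
radial basis function (support radius `s`, `r = |x − y|/s`):

    g(r) = (1 − r)⁶ (35 r² + 18 r + 3),   r ≤ 1,  else 0.

Closed-form derivatives used throughout:

    g'(r)    = −56 r (1 − r)⁵ (5r + 1)
    g''(r)   = −56 (1 − r)⁴ (1 + 4r − 35r²)
    g'''(r)  = −1680 r (1 − r)³ (7r − 3)
    g''''(r) = −1680 (1 − r)² (−35r² + 26r − 3)

with `g(0) = 3`, `g''(0) = −56`, and `g` and its first four derivatives
vanishing at `r = 1`, so the kernel joins the zero extension with C⁴
continuity.  Each control point `y` contributes three basis fields, the
columns of

    B(x; y) = [ (−g'' − g'/r) I + (g'' − g'/r) û ûᵀ ] / s²,
    û = (x − y)/|x − y|,

with the smooth limit `B = (112/s²) I` at `x = y`.  Each column has
zero divergence for all `x` (numerically ≤ 1e−6 of the local field
scale with central differences at step `1e−4·s`), is exactly zero
outside `|x − y| > s`, and `B` is symmetric in `x` and `y`.

Control points are placed on a hexagonal-close-packing lattice with
nearest-neighbour spacing `a = s/3` (so every point in the domain lies
well inside several supports):

    x = a (i + ((j + k) mod 2)/2)
    y = a (√3/2) (j + (k mod 2)/3)
    z = a (√6/3) k

anchored at the gyral-mask bounding-box corner minus `s`, and pruned to
control points within distance `s` of some mask voxel centre.  The map
from the `3N` weights to field samples at `P` points is assembled as a
`3P × 3N` sparse CSR matrix using a KD-tree support query; assembly may
be chunked over evaluation points with bit-identical results.

## 2. Cost function

With `f̂ = f/|f|`, surface normals `n̂` pointing from white into grey
matter, and per-triangle target densities `dᵢ`:

* surface density: area-weighted mean of `(f·n̂ − d)²` over triangle
  centres, with `dᵢ = F·Vᵢ/(ΣV·Aᵢ)` so that `Σ dᵢAᵢ = F` (uniform
  streamline endpoints per cortical volume, total flux `F`);
* radiality: `−⟨f̂·n̂⟩` (area-weighted; −1 when the field crosses the
  cortex exactly radially);
* DTI alignment: `−⟨(f̂·V̂₁)²⟩` over gyral voxels — invariant to the
  sign of V1 and to rescaling of `f`;
* L2 density: `⟨|f|²⟩` over gyral voxels (keeps the density small and
  smooth where nothing else constrains it).

Total: `C = C_surf + λ_radial C_radial + λ_DTI C_DTI + λ_L2 C_L2`,
defaults `λ = (1, 1, 10⁻³)`.  Surface terms are evaluated at both the
white/grey boundary and the mid-cortical surface (equal weight by
default) and summed.  All terms have analytic gradients with respect to
the field samples, pulled back to the dipole weights through the sparse
map transpose; the normalised terms exclude (and count) samples whose
magnitude falls below `1e−12 ×` the median magnitude.

## 3. Staged estimation

1. **Charges** (no free parameters beyond the construction above).
2. **Coarse dipoles**, `s = 20` mm: weights initialised at zero and
   fitted by L-BFGS-B (`ftol 1e−8`, `gtol 1e−10`, ≤ 500 iterations)
   with analytic gradients to the DTI-free cost.  The sign-degenerate
   DTI term is excluded until a credible field direction exists.
3. **Fine dipoles**, `s = 7` mm: the full cost including DTI alignment,
   starting from the stage-2 field; coarse weights stay frozen unless
   `joint_refinement` is set.

Each stage's new grid starts at zero weights, so its objective starts
exactly at the previous stage's value and can only improve.  The fit is
deterministic; randomness enters only through synthetic-data
generation.  On the default phantom (367 coarse + 1054 fine control
points, 923 gyral voxels, 3072 surface constraints) stage 2 takes ~15 s
and stage 3 ~30 s on one CPU; the iteration cap is reached before
`ftol`, which is acceptable — the quality criteria (flux uniformity CoV
0.68 → 0.18, mean angular recovery error ~11° at 10° noise) are met
well before convergence stalls.

## 4. Gyral thickness, tracing, interface

**Gyral thickness** of a voxel is the minimum over directions `u` of the
two-sided chord `t(u) = d₊(u) + d₋(u)` to the white/grey boundary,
approximated over a prefix-stable, evenly distributed hemisphere
sequence (van der Corput radical inverse for `z`, golden-angle
azimuth; 64 directions by default).  Prefix stability makes the
estimate monotonically non-increasing as directions are added.  Rays
are cast with a batched Möller–Trumbore kernel (numba); misses beyond
`max_length = 50 mm` contribute that cap.  Voxels outside the WM mask
are NaN.  Thresholding at 10 mm yields the gyral (blade) and deep
masks.

**Tracing** integrates the *normalised* field (arclength
parameterisation) with classical RK4, default step `0.25 ×` the
smallest voxel size, batched over seeds.  Termination: interpolated
gyral thickness reaching the threshold (refined by 25 bisection steps
of the final interval), leaving the WM mask (armed only after the
trajectory has clearly been inside, so boundary seeds are not flagged
spuriously; the last interior point is kept), entering the charge
radius, or the step budget.

**Interface.**  Every white/grey-boundary vertex is advected inward
(against the outward-flowing field) to the thickness threshold,
producing a deformed mesh in 1:1 vertex correspondence with the
cortical surface.  Ragged neighbouring trajectories are relaxed by
neighbour-mean smoothing, `v ← v + α(mean(neighbours) − v)` with
`α = 0.5`, 10 iterations; the median and 95th-percentile total vertex
displacements are recorded.  On the default phantom all 825 vertices
reach the interface (0 flagged) and smoothing moves vertices a median
of 0.66 mm.

## 5. Synthetic phantom

`GyrusSpec` defaults: wavelength 16 mm, amplitude 8 mm, cortical
thickness 2.5 mm, extrusion 12 mm, 6 mm of deep white matter, 1 mm
voxels, 0.5 mm mesh spacing, 3 mm grid margin.  The white/grey boundary
is `z = A cos(2πx/λ)` over one full fold, extruded along `y`; the pial
surface is the exact normal offset by the cortical thickness; white
matter is everything below the sheet.

Ground truth for recovery experiments is a charge field plus one dipole
grid (`s = 10`, 50 control points subsampled from the lattice) with
seeded standard-normal weights scaled so the median dipole contribution
is half the median charge-field magnitude.  Synthetic V1 maps rotate the
true direction per voxel by a folded-normal angle — scaled by `√(π/2)`
so its *mean* equals the nominal noise parameter — about a uniformly
random perpendicular axis, then apply a random sign (the eigenvector
sign ambiguity).

Realism limits, deliberately accepted:

* a single isolated fold with open ends — no neighbouring gyri, no
  closed cortical surface, no fanning into a centrum semiovale;
* the exact normal offset locally folds over near the sulcal fundus
  (cortical thickness exceeds the local fold radius ≈ 0.8 mm), which
  mirrors abutting pial banks in real sulci; the resulting inverted
  wedges are counted, warned about, and their volumes taken as absolute
  values;
* no partial-volume effects, susceptibility distortion, or crossing
  fibres in the V1 model — noise is purely angular and voxel-wise
  independent;
* the "deep white matter" is a slab, so the deep anchor is a single
  point rather than a distributed sink.

Problem sizes (mesh spacing, voxel size, grid extents) are this
package's own defaults chosen so the full pipeline runs in about a
minute on one CPU while keeping several voxels and mesh cells per
cortical thickness.

## 6. Numerical choices

* All geometry in float64; NIfTI volumes stored float32 (uint8 masks),
  GIFTI vertices float32; the HDF5 model container round-trips weights
  bit-exactly.
* Divergence is verified by central differences; for compactly
  supported bases the normalisation floor is the median *nonzero*
  magnitude, since exterior points have field and divergence exactly
  zero.
* Wedge volumes use a fixed three-tetrahedron decomposition of each
  white/pial triangle pair; for convex (frustum-like) wedges this
  equals the convex-hull volume exactly.
* L-BFGS-B was chosen over CG/Newton because the cost is smooth but
  mildly nonconvex in the normalised terms and the weight dimension
  (≈ 10³–10⁴) suits a limited-memory quasi-Newton method; analytic
  gradients make each iteration one sparse mat-vec pair per term.
* Every random draw flows from an explicit integer seed
  (`numpy.random.default_rng`); repeated runs are bit-identical.
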