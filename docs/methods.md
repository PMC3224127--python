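# Methods

This note documents the model implemented by `multiseg`, the parameters
that matter and their defaults, what the synthetic phantom does and does
not emulate, and the numerical choices made where the design was open.

## 1. Surface model

A 2-simplex mesh is the topological dual of a closed triangulation: one
mesh vertex per triangle, each with exactly three neighbours.  The three
neighbours of vertex *p* define its tangent plane and outward unit normal
**n**; the *simplex angle* φ measures how far *p* lifts out of the circle
circumscribing its neighbours.  With *r* the circumradius of the neighbour
triangle and *R* the radius of the sphere through *p* and its neighbours,
`sin φ = (r/R)·sign(z)` (z the elevation above the neighbour plane, sign of
cos φ distinguishing caps larger than a hemisphere), and the discrete mean
curvature is `H = sin φ / r`.

Spheres are built as duals of subdivided icosahedra, vertices projected to
the requested radius; subdivision count 0 gives the 20-vertex dodecahedral
mesh, each further subdivision quadruples the vertex count.  Construction
fixes the neighbour ordering so that `cross(p2−p1, p3−p1)` points outward,
and that orientation is preserved by the smooth deformation.

Two derived triangulations serve different jobs:

* the **dual triangulation** (points = face centroids, one triangle per
  vertex) carries refinement: it is subdivided 1:4 at edge midpoints and
  re-dualized.  The four children of each parent vertex are then shifted so
  the central child lands exactly on the parent — without this correction
  the double centroid averaging shrinks a sphere by ~12% per refinement;
  with it the refined surface interpolates the coarse one to <2%.
* the **fan triangulation** (each polygonal face fanned around its
  centroid) passes through every mesh vertex and is the surface that is
  rasterized and exported.  Face centroids are lifted along the face normal
  by the local sagitta `H·ρ²/2` (ρ the ring radius), which removes the
  systematic inward volume bias of planar centroids; the rasterized volume
  of a sphere then converges to the analytic value as the grid is refined.

Rasterization is voxel-center parity: a voxel is inside if a +z ray from
its center crosses the fan surface an odd number of times.  Crossings are
accumulated per z-column and integrated by cumulative sum; a deterministic
sub-nanovoxel jitter of the surface avoids edge-exact rays.  A
self-intersecting surface still rasterizes under the parity rule but may
contain holes — there is deliberately no repair step, only a warning
diagnostic at refinement time.

## 2. Forces and the motion equation

Vertices evolve by `p_{t+1} = p_t + (1−γ)(p_t − p_{t−1}) + w_int·F_int +
F_ext` with damping γ = 0.65 by default.  All external terms act along the
vertex normal; tangential image forces are excluded because they are the
direct cause of surface self-intersection.

**Internal force.**  The tangential part restores the vertex toward the
position its stored reference barycentric (metric) parameters assign in
the current neighbour triangle.  The normal part drives the simplex angle
toward the mean of the *current* angles over the graph ball of radius
`smoothness_scale` — continuity-style smoothing that evens curvature
without imposing shape memory (a sphere-memory target would fight boundary
recovery).  The elevation realizing the target angle is
`L(r, d, φ) = (r²−d²)·tan φ / (± √(r² + (r²−d²) tan²φ) + r)` with the sign
flipping beyond |φ| = π/2.

**Gradient force.**  The gradient-magnitude volume is computed once per
run from the Gaussian-smoothed image (σ = 1.0 voxel by default; raw
gradients of textured data are noise-dominated).  Each vertex searches the
voxel ball of radius `gradient_search_radius` (3 voxels at low resolution,
2 in the refined stages) for the maximum value; ties break by distance to
the vertex, then lowest voxel index.  Two corrections localize the edge
properly:

* *sub-voxel refinement*: the target is shifted along the normal to the
  vertex of the parabola through the interpolated gradient values one
  voxel either side — voxel-center argmaxes otherwise sit ~0.4 voxel
  inside the boundary (the inside shoulder of the ridge is texture-boosted)
  and every mask under-segments by ~10% of its volume;
* *curvature compensation*: Gaussian smoothing moves the gradient ridge of
  a curved step inward by ≈ σ²·H, so the localized target is pushed back
  out by that amount at convex vertices (clamped to half a voxel).

The projected pull saturates at one voxel so it cannot out-scale the mesh.

**Edge force.**  Highest intensity along the normal line within the search
radius, sampled at one-voxel steps, truncated at the volume boundary.  The
default schedule keeps its weight at zero throughout.

**Balloon force.**  `B(I(p))·n` scaled by one voxel, where *I* is the
classified volume sampled nearest-neighbour (labels must not be
interpolated) and B = 1 iff `T_low ≤ I ≤ T_high` with the printed
thresholds (−0.99, 1.0) matched to the ±1 label encoding.  The balloon
drives small initial spheres across featureless interior territory that
local gradient search could never escape.

**Collision force.**  Gated by the mesh's collision energy image (next
section): vertices whose voxel has energy 1 run the same localized
gradient search over the larger `collision_search_radius` (5 voxels) — the
true boundary is assumed close to where two simultaneously inflating
surfaces met.  The search domain *excludes* voxels with energy 1: the
boundary sought cannot lie inside foreign territory, so the pull is always
back toward the vertex's own side.

**Stability cap.**  The per-iteration displacement norm is capped at
`max_displacement` = 0.5 voxel.  Once mesh edge length drops below the
image-force step size an uncapped update folds the surface and the fold
amplifies through flipped normals; the cap is what keeps refined-stage
deformation stable.

## 3. Collision detection

Each of the N meshes owns a binary *collision energy image*
`C_i = ⊕_{j≠i} M_j` — the voxelwise XOR of the other meshes' rasterized
masks, computed as `(⊕_j M_j) ⊕ M_i` so the whole set costs O(N) combines.
XOR is implemented exactly as specified, including the cancellation where
two other masks overlap each other; a `union` mode exists for robustness
experiments.  Masks and energies are refreshed every
`collision_check_interval` = 5 iterations — often enough that meshes
cannot interpenetrate deeply between checks (≤ 2.5 voxels at the 0.5-voxel
displacement cap).

A mesh with any vertex inside its energy support is *colliding*: its
balloon weight is latched to zero for the rest of the stage.  The latch
resets at each stage start — a permanent latch was tried and rejected,
because an early spurious contact (e.g. from off-center seeds) would
freeze a mesh far from its boundary with no force able to recover it.

Engine-level, the energy image dilated by 2 voxels (the over-
classification scale) is also excluded from the *regular* gradient search:
an edge ridge just outside another mesh's surface belongs to that mesh's
object and must not capture this mesh's vertices across a thin gel wedge.

## 4. Classification and the tube mask

Voxels carry two features: intensity and the standard deviation over a
centered 5³ window (truncated at volume edges).  A Gaussian model
(centroid, full covariance, ridge-regularized if singular; priors from
training counts) is fitted per class from user-picked coordinates — 25 per
class in the standard setup — and each voxel takes the MAP label, encoded
+1 (object) / −1 (gel), ties to gel.  On realistic data the classifier
over-labels a shell of 2–4 voxels around each object (boundary windows
have elevated SD) — harmless, since the balloon only needs a superset and
gradient forces stop at the true edge — and mislabels a similar band along
the tube wall, which the tube constraint owns.

The tube mask thresholds the original image between `t_low` — the mean
intensity of the voxels in the first local-minimum bin after the first
highest histogram peak (256 bins; ties take the lower-intensity bin; the
minimum is the first bin ≤ both neighbours scanning upward) — and the data
maximum.  Largest-26-connected-component selection plus hole filling
(toggleable) removes stray bright voxels and closes interior dips.  Any
vertex displacement whose target voxel has tube mask 0 is cancelled: the
vertex keeps its previous position.

Because the wall is both the strongest gradient ridge in the volume and
excluded territory, the gradient field is blanked outside a 2-voxel
erosion of the tube mask and the balloon's classified map is neutralized
in the same band; the clamp, not image evidence, governs that margin.

## 5. Deformation schedule

Stage 1 runs on 80-vertex spheres (radius 5 voxels, icosahedral
subdivision 1) seeded at the user's N points: weights w_int 0.9,
w_gradient 0.3, w_edge 0, w_balloon 0.08, w_collision 0.4, smoothness 12 —
fast, smooth, self-intersection-free expansion.  Each following stage
refines every mesh (≥2× vertices) and switches to w_int 0.7, w_gradient
0.4, w_balloon 0.02, w_collision 0.3, smoothness 3 to recover finer
boundary detail.  Refinement stops once the median mesh edge drops below
one voxel — vertices finer than the image only chase per-voxel noise — so
on the 64³ phantom the progression is 80 → 320 → 1280 vertices.

A vertex is *inactive* in an iteration when its displacement is below
`displacement_threshold` = 10⁻⁴ mm; a mesh converges when the inactive
fraction over the last `activity_window` = 10 iterations strictly exceeds
`activity_threshold` = 0.5, and converged meshes are frozen until the
stage ends.  Stages are otherwise bounded at 200 (low-res) / 100 (refined)
iterations; three refined stages by default.  All force evaluations in an
iteration use positions from the iteration start, so results do not depend
on mesh ordering, and the whole pipeline is deterministic: identical
inputs give bit-identical masks.

## 6. The phantom

The generator emulates the structure that defeats simpler methods: a
bright cylindrical tube on a dark background (≈10 ± 2), gel at 70 ± 6 and
objects at 95 ± 16 so the intensity histograms overlap, a multiplicative
bias field (mean of three low-frequency cosine modes, amplitude ±20%)
standing in for coil inhomogeneity, and additive noise (SD 2).  The
standard layout packs four ellipsoids (semi-axes 8, 8, 10 voxels) per
layer in a 64³ grid, consecutive objects touching; the 2×2 pattern sits
2.5 voxels off the tube axis so exactly one object per layer is tangent to
the wall while the rest keep a few voxels of gel clearance.  Up to 32
objects stack in 8 layers (the grid grows along z).  Truth masks are exact
strict-interior ellipsoid voxelizations, pairwise disjoint; seeds are the
centers; training points are drawn from class regions eroded by the SD
window half-width, as a user clicking representative homogeneous voxels
would pick.

What the phantom does *not* emulate: internal organ structure, thin
appendages (paws/tails — the method's acknowledged failure mode, excluded
from scope; a qualitative appendage mode exists but is not part of any
accuracy claim), partial-volume PSF blur, and scanner artifacts.  Passing
tests therefore demonstrate the mechanics — simultaneous inflation,
collision separation, wall clamping, boundary recovery — on smooth convex
objects at desk scale, not fine-feature fidelity on real specimens.

## 7. Validation measures

Voxelwise Cohen's kappa `(p_o − p_e)/(1 − p_e)`, specificity
`tn/(tn+fp)`, accuracy `(tp+tn)/n`, and Dice `2|A∩B|/(|A|+|B|)`.
Engine-level evaluation restricts the confusion counts to the tube region
— the trivially agreeing exterior background would otherwise inflate
accuracy; the whole-grid mode remains available.  Kappa errors out when
both raters are constant; specificity when there are no truth negatives.

## 8. Problem sizes and degenerate inputs

The test suite and the acceptance script run the full pipeline on 64³
phantoms with 1–4 objects (≈30 s per four-object run on one CPU) and the
seed-robustness experiment with offsets up to 10 voxels constrained to the
interior operating regime (normalized radius ≤ 0.5, initial spheres
non-adjacent): the underlying method is documented to fail for near-edge
seeds, and at phantom scale (objects ~16–20 voxels across versus real
specimens' hundreds) an unconstrained 10-voxel offset leaves that regime.

Degenerate cases: collinear neighbour triples raise a geometry error in
per-vertex queries and contribute zero internal force (with a diagnostic)
in the vectorized path; vertices outside the volume feel no image forces;
a histogram with no local minimum after its peak raises an error asking
for manual thresholds; an empty tube mask is an error; meshes must be
closed for refinement and rasterization.

## 9. Known limitations

* Convex-ish objects only: nothing recovers features absent from the
  (spherical) initial model, and there is no local/adaptive refinement.
* No self-intersection repair: prevention is by schedule (high smoothness
  during inflation) and the displacement cap, matching the method's
  design; a crumpled surface degrades its own mask.
* The interface between two touching same-intensity objects is genuinely
  ambiguous at the voxel level; collision handling bounds the overlap
  (≤1% of the smaller mask) but the sliver assignment depends on which
  mesh arrived first.
* Two-class model only; a bright container wall adjacent to dark exterior
  produces feature artifacts that the tube-margin neutralization works
  around rather than models.
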