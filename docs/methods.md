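# Methods

`myotrack` estimates 3D myocardial motion and strain from a time series of
3D tagged-MRI volumes.  The method has three stages: sparse correspondence
by hierarchical template matching, a dense smooth transformation by a 3D
Local Weighted Mean (LWM), and continuum-mechanics strain analysis on a
tracked left-ventricle (LV) surface.  A synthetic tagged-LV phantom with
exact analytic ground truth stands in for clinical data and defines the
conditions under which the implementation is tested.

## Hierarchical template matching

Each cardiac frame (the *moving* image) is matched against the
end-diastolic *reference* frame.  The moving image is tiled with cubic
**templates** of edge `t = 16` voxels, each split into 8 **segments**
(`t/2`), each segment into 8 **chunks** (`t/4`), each chunk into 8
**windows** (`t/8 = 2`).  A block is matched by maximising the normalized
cross-correlation (NCC)

    λ = Σ (f − f̄)(b − b̄) / sqrt( Σ (f − f̄)² · Σ (b − b̄)² )

of the moving block `b` against reference patches `f` at every admissible
lag; λ ∈ [−1, 1] and is invariant to affine intensity changes.  Templates
search within ±`search_radius` (default 20 voxels; unbounded reproduces a
whole-image search) of their own position; each child block searches only
inside its parent's matched block (zero margin), so the search is
progressively restricted down to windows.  The minimum-index corner of each
window, paired with the corner of its matched reference window, is one
control-point correspondence.

NCC is computed with exact sliding-window summation for small searches and
FFT correlation with box-sum normalisation for large ones; both agree with
the direct triple-sum definition to better than 1e−10.  A zero-variance
patch has no defined correlation; λ is set to 0 and the block is treated as
degenerate.  Ties (λ within `cc_tolerance`, default 1e−6, of the maximum)
resolve to the smallest Euclidean displacement from the block's own
position, then lexicographic (z, y, x) order.

**Pyramid validation.**  Each segment is re-matched through three
overlapping blocks of edges `t·{5,6,7}/8` centred on it, each chunk through
one of edge `3t/8`.  A match is accepted only if every overlap's
displacement agrees with the block's within `pyramid_agreement_tol`
(Euclidean, default 2 voxels — one window edge).  Rejected subtrees are
emitted as *non-displaced* pairs (reference = moving) flagged invalid.

**Template-level safeguards.**  Validation of segments and chunks cannot
catch a template that locked onto the wrong basin: its children are
confined to the wrong block and agree with their overlaps vacuously.  Three
additional guards therefore act at (or propagate from) the template level:

1. templates are themselves pyramid-validated with overlap blocks of edges
   `t·{9,10,11}/8`; these are clipped (not skipped) at image borders so
   border templates do not escape validation;
2. a template whose correlation peak lies on a non-image-edge boundary of
   its search region is rejected — the true optimum most likely lies
   outside the searched range;
3. a match with λ below `cc_min` (default 0.5) at any level is not trusted:
   a weak peak means the content has no reliable counterpart (moved out of
   the field, heavily distorted, or insufficiently textured).

All three emit the affected windows as non-displaced invalid pairs.

## Local Weighted Mean transformation

Given N control-point pairs, one second-order polynomial with the ten
monomials {1, x, y, z, x², y², z², xy, xz, yz} is least-squares fitted per
control point and output component over that point and its n−1 nearest
source-side neighbours (default n = 100, the neighbourhood size at which
myocardial tracking error is minimal on cardiac data; n ≥ 10 determines the
coefficients, and n ≫ 10 makes the fit well-posed).  Monomials are centred
on the owning control point for conditioning; exact-duplicate source
positions are collapsed before fitting, and a rank-deficient neighbourhood
raises an error naming the control point.

A query point p maps to the weighted mean of all local polynomials whose
influence region covers p, with the C¹ kernel

    W(R) = 1 − 3R² + 2R³  (0 ≤ R ≤ 1),   W(R) = 0  (R > 1),

where R = |p − p_i| / R_i and the influence radius R_i is the distance from
control point i to its (n−1)-th nearest neighbour.  W and dW/dR vanish at
R = 1 and dW/dR at R = 0, so the map is smooth everywhere, including across
influence boundaries.  Points beyond every influence region fall back to
the nearest control point's polynomial, keeping the map total.  (An
alternative convention, recomputing the radius per evaluation point, is
selectable via `radius_mode="evaluation"`.)  Because no global system is
solved, the transformation adapts to locally varying geometry and is
insensitive to irregular control-point spacing; it reproduces any global
polynomial map of total degree ≤ 2 exactly from noiseless correspondences.

Two transforms are fitted per frame from the same correspondences:
moving → reference (for strain gradients in current coordinates) and
reference → moving (for forward tracking).

**Which pairs feed the fit.**  By default only pyramid-validated matches
are used (`fit_on="valid"`).  A window that failed validation, or carried
no texture, contributes no displacement *measurement*; feeding it in as a
zero-displacement point would assert a quantity the matcher explicitly
declined to measure, and on the phantom such assertions cluster at the
moving wall and triple the end-systolic tracking error.
`fit_on="informative"` restores the convention of keeping validation
failures as non-displaced control points, `fit_on="all"` additionally keeps
textureless windows.

## Strain analysis

The reference LV surface mesh is carried forward through the cycle:
position at frame t = forward LWM transform of the reference node position
(frame 0 is the mesh itself).  At the tracked positions x, the displacement
u(x, t) = x − X is differentiated with respect to *current* coordinates via
central differences (step h = 0.25 voxel) of the inverse map:
U = I − J, with J the moving→reference Jacobian.  Then

    F = (I − U)⁻¹,    E = ½ (FᵀF − I).

Differentiating in current coordinates is the only reading under which this
composition returns the true material deformation gradient — verified by
the invariants that F matches the forward Jacobian on affine fields and
that rigid motions give E = 0 to rounding.  With anisotropic voxels the
gradient is similarity-transformed to physical coordinates
(U_mm = S U_vox S⁻¹).

Directional strains project E onto a local cardiac frame built on the
reference mesh: longitudinal L = unit(apex → mitral centre), one global
vector; radial R = unit(M − (M·L)L) from the outward node normal M
(area-weighted incident-triangle average, oriented away from the centroid);
circumferential C = unit(L × R).  Nodes with M ∥ L have no defined radial
direction and are excluded from aggregates.  The projected strain along a
unit direction p is E_p = pᵀEp, which always lies between the extreme
eigenvalues of E.

Aggregate curves report, per frame, the median (configurable to mean) of
E_L, E_C, E_R over nodes, and the per-sorted-position medians of the three
strain eigenvalues (principal strains).  At the reference frame all curves
are identically zero.

## The phantom

The phantom is a half-ellipsoidal LV wall (outer semi-axes (22, 22, 24),
inner (12.5, 12.5, 14.5) voxels — a ~9-voxel wall, matching end-diastolic
wall thickness at the 0.96 mm voxel size) in a 64³ volume, apex pointing
down the long axis.  Its intensity is a 3D tag lattice (product of three
cosines, period 7 voxels, contrast 0.5 on background 0.25) inside the wall,
over a faint aperiodic tissue texture covering the whole volume (smoothed
seeded random field, amplitude 0.15, correlation length ~1.2 voxels).  The
texture is a material property — it deforms with the motion — and plays two
roles a real acquisition plays for free: every block sees structure (a
constant background makes NCC degenerate, with near-constant patches
reaching |λ| ≈ 1 spuriously), and the tag lattice's exact periodicity is
broken (pure cosines admit period-offset matches that tie with the true
one).

The motion composes, in shell-centred cylindrical coordinates, all
modulated by an amplitude a(t) rising from 0 to 1 at end-systole (frame 5
of 10) and relaxing to 0.1 at the final frame:

* a circumferential twist (8° at the base, linear to 0 at the apex),
* a radial contraction with transmural gradient (endocardial scale
  reduction 0.18, thickening factor 0.3 → E_C ≈ −0.16 endocardial, −0.12
  epicardial at end-systole, the level measured on 3D tagged MRI),
* longitudinal shortening (10%, base plane fixed), and
* a strain-free bulk translation (1.6, −1.6, 2.0) voxels — the rocking of
  the heart within the chest — decaying over an ellipsoidal envelope.

Outside the wall every component decays smoothly (e-folding ~10 voxels for
the cylindrical terms): an abrupt taper would concentrate artificial shear
just outside the epicardium beyond what any block matcher can represent,
while no taper at all would translate the image borders, whose content then
has no in-grid counterpart to match.  Peak wall displacement at end-systole
is ≈ 6.5 voxels (median ≈ 4.9).  The radial contraction is deliberately
physiological rather than larger: a volumetric contraction of tens of
percent shrinks a block's reference footprint beyond its matched parent
block, which a nested zero-margin hierarchical search cannot represent —
this is a property of the method, not of the implementation.

The forward map is analytic and invertible (monotone in each factor); the
inverse is solved by a damped fixed point on the forward map,
X ← X + (x − forward(X)), which contracts because the deformation-gradient
eigenvalues of every admissible parameter set stay well inside (0, 2);
round-trip error is ~1e−13.  The deformation gradient is evaluated by
central differences at step 1e−4 (error O(h²) ≈ 1e−9, far below every
tolerance it oracles for), and E = ½(FᵀF − I) from it.  Exact landmark
trajectories (12 mid-wall landmarks: anterior/septal/posterior/lateral ×
basal/mid/apical), a triangulated mid-wall surface with apex and
mitral-centre anchors, and per-point strain tensors are exported from the
same maps.

Frames are rendered by backward mapping — trilinear sampling of the
reference image through the inverse deformation — then blurred with a
Gaussian acquisition PSF (σ = 0.6 voxel) applied identically to every
frame: a scanner blurs all frames with one PSF, and leaving the reference
crisp against interpolation-smoothed moving frames would make it sharper
than any real image.  Tag fading (geometric amplitude decay, default off)
and seeded Gaussian noise (default off) come last.  Zero-amplitude motion
renders bit-identical frames, and identical spec + seed reproduce
bit-identical volumes.

### What the phantom does and does not emulate

It emulates tag geometry and fading, structured surrounding tissue,
physiological strain magnitudes and phase, bulk cardiac motion, scanner
PSF, and optional noise.  It does not simulate MRI physics (k-space, SPAMM
pulse sequences, slice profiles), through-plane tag dilution, blood-pool
signal dynamics, receive-coil shading, or motion artefacts.  Passing the
phantom tests therefore shows the pipeline is a faithful, numerically sound
implementation under realistic geometry and motion — not that clinical
accuracy on patient data would match it.

## Accuracy floors of integer-voxel matching

Window matches are integer voxel positions.  Two floors follow, measured on
the phantom and worth stating because they bound what any parameter choice
can deliver:

* **Tracking:** quantization noise (~0.3 voxel rms) averaged over n = 100
  neighbourhood fits leaves a median landmark error of ~0.4 voxel over the
  cycle (~1 voxel at end-systole, where matching is hardest).
* **Strain:** the LWM differentiates a field known only at integer levels.
  Refitting the *true* correspondences rounded to integers — a perfect
  matcher — still leaves ~0.01 (circumferential) to ~0.035 (longitudinal)
  median absolute strain error at end-systole; the longitudinal field's
  gentle gradient (~0.1) produces unit-height staircases with ~10-voxel
  treads that survive quadratic fitting over ~7-voxel neighbourhoods.  The
  realised errors (~0.06–0.08) sit above these floors by the matching
  noise.  For the same reason a rigid rotation of a few degrees, whose
  smooth displacement gradient is ~0.07, cannot be recovered to strain
  ~1e−3 from integer matches — though it is recovered to ~1e−14 from exact
  correspondences.  Sub-voxel correlation-peak interpolation would lift
  these floors but is outside this method's definition.

Aggregate strain *curves* are more robust than per-node values (medians
over hundreds of nodes), but adjacent frames around end-systole differ by
only a few percent of strain, so which of frames 5/6 carries the extreme of
the noisier curves (longitudinal, second eigenvalue) can flip; the
circumferential curve and the first principal strain peak reliably at
end-systole with negative sign during contraction.

## Numerical and design choices

* Half-open blocks `[origin, origin+size)`, 0-based voxel indices; geometry
  in mm, image operations in voxels, conversion by the voxel spacing with
  the origin at voxel (0,0,0).
* "Divided into four segments" in 2D becomes 8 children in 3D (halving each
  axis); block sizes t/2, t/4, t/8 force this reading.
* Partial boundary template blocks are skipped; windows there contribute no
  control points.
* Pyramid overlap blocks clipped by the image border are skipped at
  segment/chunk level (their cube sizes are mandated) but clipped-and-kept
  at template level (otherwise border templates would go unvalidated).
* The consensus filter for two-observer landmarks pools all three distance
  populations (two intra-observer final-vs-initial, one inter-observer
  final-vs-final) and takes the nearest-rank 75th percentile; "relatively
  close" is strict `<`.  Degenerate all-zero populations select nothing and
  warn.
* Point-to-surface distance is the exact point-to-triangle minimum
  (barycentric region clamping), not a vertex-only approximation.
* The error summary's "all frames" category excludes the reference frame,
  where the error is identically zero by construction.
* `F = (I − U)⁻¹` raises with the node index and condition number when
  I − U is near-singular; strain tensors are checked symmetric to 1e−8
  before eigenanalysis (eigenvalues ascending, medians per sorted
  position).

## Known limitations

* Radial strain is poorly constrained: the wall is thin relative to the
  control-point spacing, and transmural gradients are at the resolution
  limit — the radial curve is reported as computed, close to zero, and
  should not be over-interpreted.  The directional projections share one
  global longitudinal axis; no AHA segmentation, torsion, or
  incompressibility constraint is provided.
* Matching is integer-voxel by design (see the floors above).
* The hierarchy cannot represent volumetric strains large enough that a
  child's reference footprint leaves its parent's matched block (roughly
  |E| ≳ 0.15 at these block sizes).
* The phantom's background texture and tapers are idealised; regions whose
  true correspondence leaves the imaged volume are rejected rather than
  extrapolated.
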