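# Methods

This note documents the models, parameter choices, and numerical decisions
behind `pairmorph`, and what the synthetic validation does and does not
establish about real CT-derived data.

## Problem setting

Bilateral symmetry of paired bones is quantified by dense surface
correspondence: the left bone is mirrored and registered to the right, the
right is nonrigidly deformed onto it, and the per-vertex displacement
magnitude ("CP distance", mm) is the local asymmetry measure. Everything
operates on closed triangle meshes in millimetres; the pipeline deliberately
starts downstream of segmentation (no images, no DICOM).

## Mesh processing

* **Canonicalization.** Duplicate vertices are merged within 1e-6 mm — far
  below CT resolution, so no anatomy can collapse — and zero-area faces are
  dropped on construction.
* **Fragment filtering.** Only the largest-area connected component is kept,
  emulating the exclusion of loose ossific fragments from segmentations.
  Ties (1e-9 relative area) break to the component containing the lowest
  vertex index, so the choice is deterministic.
* **Isotropic remeshing.** Incremental split / collapse / flip / relax
  remeshing (long edges > 4/3 of the 2.0 mm target split at midpoints, short
  edges < 4/5 collapsed under a link-condition check, flips toward valence 6,
  tangential Laplacian relaxation with back-projection onto the original
  surface). Five iterations bring the median edge within ±25% of target
  while keeping the surface within 0.2 mm Hausdorff and area/volume within
  2%. Back-projection uses an exact point-to-triangle query over k-d-tree
  candidate faces.
* **Mirroring** negates one coordinate (default x, the left-right axis of
  LPS/RAS CT frames; configurable because mesh provenance varies) and flips
  face winding, so outward orientation and signed volume are preserved and
  the operation is an exact involution.

## Coherent point drift

Both registration stages are EM over a Gaussian mixture whose centroids are
the transformed moving points, with a uniform outlier component of weight
`w`. The E-step is log-sum-exp stabilized; σ² is floored at 1e-8 mm².

* **Rigid** (no scale): rotation from the SVD of the posterior-weighted
  centered cross-covariance with determinant correction; translation and σ²
  closed-form. A scale factor is deliberately omitted — a size difference
  between sides *is* asymmetry and must not be absorbed.
* **Initialization.** EM from the identity stalls in local optima for
  initial rotations beyond roughly 20°. The loop therefore starts from the
  best of a deterministic candidate set — identity, centroid shift, and the
  four proper principal-axes alignments — scored by mean squared
  nearest-neighbour residual, with strict improvement required so already
  aligned inputs keep the identity start. σ² is initialized at three times
  that residual rather than the full cloud spread: spread-based starts give
  near-uniform early posteriors that can pull the estimate back out of the
  selected basin. Each returned trace is a single EM chain, so the recorded
  objective (observed-data NLL) is non-increasing to float precision.
* **Sampling floor.** Registering two meshes that sample the *same* surface
  differently lets a fully annealed GMM lock onto individual vertices and
  pick up a spurious "sampling-interlock" pose of 0.1-0.2°. The pipeline's
  rigid stage therefore floors σ² at 0.5 mm² — the sampling scale of 2 mm
  meshes, σ ≈ 0.35 × edge length — so posteriors always average a few
  neighbouring vertices and the fit tracks the surface, not the sampling.
  This is a constrained M-step, so EM monotonicity is untouched; with
  exactly corresponding clouds the optimum is still the exact pose. The
  floor is a `CpdParams` field (default numerical-only at 1e-8 mm²),
  keeping plain point-cloud registration exact to machine precision.
* **Nonrigid**: displacement field v(y) = Σⱼ exp(−‖y−yⱼ‖²/2β²) Wⱼ over
  control points; each M-step solves (diag(P1)G + λσ²I)W = PX − diag(P1)Y;
  the recorded objective adds the coherence penalty (λ/2)tr(WᵀGW) and is
  likewise non-increasing (MAP-EM).
* **Defaults**: w = 0.1, β = 10 mm, λ = 2, tol 1e-6 relative objective
  change, 150 max iterations. β sets the coherence scale; 10 mm is smooth at
  bone scale while still resolving condyle-sized asymmetries. λ = 2 is the
  weakest regularization that suppresses tangential "sampling chasing" on
  bone-shaped surfaces (surfaces with local rotational symmetry — e.g. a
  cylindrical shaft — admit cheap tangential drift, which is why the tibia
  surrogate carries a tuberosity; real bones are similarly asymmetric).
* **Subsampling.** The nonrigid fit uses at most 2,000 seeded uniformly
  subsampled control points, then evaluates the kernel field at every vertex;
  this keeps the M-step solve (O(M³)) in the tens of seconds on one CPU at
  negligible accuracy cost for smooth fields. The exact full-kernel path is
  recovered by raising `subsample_cap`.

## Alignment and trimming

The anatomical coordinate systems of the source protocol are not fully
specified, so alignment is a documented surrogate: area-weighted principal
axes map the long axis to Z and the second axis to X (medial-lateral), with
the Z sign fixed by putting the wider (joint) end at −Z for the femur and +Z
for the tibia. When the first-to-second extent ratio is below 1.3 the axes
are ambiguous and a pre-aligned reference model is required instead (the
patella path).

Trim height = medial-lateral (X) extent of the right mesh; short bones
(available proximal-distal extent below target, beyond a 1e-6 mm guard
against float round-off on re-cut meshes) use the available extent minus
5 mm. The right, fixed mesh defines the trim spec and both meshes are cut at
the *same* global plane — the right never moves, so the cut plane is
stationary across iterations and the two trim-register iterations serve to
let the rigid registration settle on joint-only geometry; a third iteration
moves the plane by construction less than numerical noise. Cutting clips
crossing triangles at the plane (no whole-face deletion), keeping cuts
straight. Residual cut differences are absorbed by excluding CPs within
2.0 mm (inclusive comparison: exactly 2.0 mm is kept) of any cut plane.

## CP distance definition

The CP distance at each right-mesh vertex is the displacement magnitude
‖T(y) − y‖ under the nonrigid deformation. "Distance between corresponding
nodes" could also be read as a post-hoc nearest-neighbour distance, but the
deformed nodes *are* the correspondences, the definition keeps one value per
right-mesh vertex (matching heatmaps drawn on the right bone), and it retains
tangential mismatch, which a nearest-surface distance would hide.

Percentiles use linear interpolation between order statistics (numpy's
default), fixed once; summaries report n, median, IQR bounds, 1st/99th
percentiles, and mean over *included* CPs only. Group pooling concatenates
included CP distances per bone; no hypothesis testing is performed.

## Synthetic data

Surrogates are smooth unions of implicit primitives: capsule shaft plus two
condylar spheres and a trochlear sphere (femur); shaft, anterior tuberosity
ridge and flattened plateau ellipsoid (tibia); ridged ellipsoid (patella).
They are surfaced by marching cubes at 1.5 mm pitch and remeshed to 2.0 mm.
Default long-axis scales (femur 70 mm, patella 38 mm, tibia 75 mm) put the
joint regions at the small end of the adult range, keeping a full pair
analysis in tens of seconds; the fixture cohort jitters scale by ±5%.

Pairs: the right mesh carries Gaussian bumps (amplitude a ≤ 5 mm, radius
r > 2 mm, falloff exp(−d²/2r²) along vertex normals, truth recorded before
noise); the left is the mirrored base under a random rigid misalignment.
Noise is N(0, σ²) along vertex normals with σ = 0.3 mm by default,
modelling segmentation/voxel uncertainty at ~0.7 mm CT voxels. The fixture
cohort's three groups inject no bumps, 1-2 mm bumps, and 2-4 mm bumps (the
latter with a loose patellar fragment); bump anchors are restricted to the
joint half of long bones, because group-level asymmetry is a joint
phenomenon and the shaft is trimmed away.

What the surrogates do **not** emulate: real trochlear morphology and its
dysplastic variants, cortical ridges and fossae, segmentation artifacts that
correlate across neighbouring vertices, and intensity-dependent boundary
errors. Passing the synthetic acceptance suite therefore establishes that
the *pipeline* is unbiased and precise on bone-scale geometry, not that any
particular clinical effect size is detectable.

## Numerical choices and degenerate inputs

* σ² floored (see above); E-step log-sum-exp stabilized.
* Degenerate point sets (coincident/collinear) are rejected before EM.
* Non-convergence returns the current estimate flagged `converged=False`
  with a warning, mirroring common EM practice.
* Exclusion masks must retain ≥ 50% of vertices; trims removing > 75% of a
  mesh abort — both indicate misalignment upstream.
* All subsampling and synthetic randomness flows from explicit integer
  seeds; reruns are bit-identical.

## Known limitations

* Principal-axes alignment is a surrogate for anatomically defined
  coordinate systems; on pathological shafts the medial-lateral axis may
  rotate, changing trim heights slightly (the shared-plane cut and 2 mm
  exclusion margin limit the effect on statistics).
* CPD correspondence is soft and unconstrained by landmarks; in regions of
  local surface symmetry the tangential component of correspondence is
  weakly determined. The null-symmetry and noise-floor tests bound the
  resulting bias on surrogate geometry only.
* Problem sizes in the validation suite (surrogates of 1,500-2,500 vertices
  after trimming, one pair per group in the cohort check) are chosen for
  single-CPU turnaround; the pipeline itself has no size assumptions beyond
  memory for the M×M nonrigid kernel.
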