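# Methods

This note documents the model implemented by `paretodose`, the synthetic
cohort it is exercised on, and every numerical choice that was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dose prediction model

### Conventions

Grids are `(slice, row, col)` arrays; slices increase superior→inferior,
rows anterior→posterior. Doses are fractions of the prescription (1.0 = 70
Gy); all RMSE-style errors are quoted as 100× these fractions ("% of
prescription"). Structure masks are 0/1 float grids so priority scaling is a
multiplication. Clinical-resolution grids are 128×128 in-plane; the data
model accepts any in-plane size so that the whole pipeline can be exercised
on small phantoms.

### Initialization

The initialization assumes dose decays isotropically with distance from the
planning target volume — appropriate for arcs wrapping (nearly) 360° around
the patient, and deliberately crude everywhere else:

    D_init = 1 / (1 + a1·s1^a2 + c·s2^a3)

`s1` is the in-plane distance (per slice) to the nearest PTV voxel and `s2`
the along-axis distance to the nearest slice whose PTV covers the voxel's
(row, col). Numerical choices:

* Distances are divided by 10 mm before exponentiation so that powers of
  typical distances stay near unity; the exponents then fit on a tame scale.
* Where a distance is undefined (slice without PTV; a (row, col) column the
  PTV never meets) it is capped at the grid-diagonal length, driving
  `D_init` toward 0 far from the target.
* All four constants (`c` included) are fitted jointly, by full-batch Adam
  on log-parameters (positivity by construction), minimizing the masked
  RMSE against the reference doses. Default: 800 iterations at learning
  rate 0.05 from the guess (1, 2, 1, 1). The fit always precedes network
  training.
* In-plane distances use an exact Euclidean distance transform; along-axis
  distances use an exact two-pass 1-D scan.

### Features

Per voxel: 9×9 transverse patches of 4 channels (PTV, bladder, rectum masks
scaled by their priorities, plus the current dose) at atrous rates 1, 3, 10
→ 4×3×81 = 972 values, then the raw priority triplet → 975 features.
Choices the architecture leaves open:

* Zero padding outside the slice for both smoothing and patch sampling; the
  exterior of the body is near-zero dose anyway.
* The even 10×10 smoothing kernel is anchored at the top-left of its central
  2×2 (window offsets −4..+5).
* The dose channel is smoothed before rate-3/10 sampling exactly like the
  structure channels, keeping the receptive-field semantics uniform across
  channels.
* Patches are strictly 2-D (transverse); no 3-D sampling.

### Residual network

Six independent blocks (no weight sharing), each: 975 → 100 (leaky ReLU,
slope 0.2) → 100 (leaky ReLU) → 1 with scaled-softsign output
0.3·x/(1+|x|), so each block shifts the dose by at most ±0.3 of
prescription and six blocks by at most ±1.8. After each block the dose
patches are re-extracted from the updated dose map; structure patches are
computed once per slice and cached (structures do not change). The priority
triplet is part of every block's input. Dose values are not clipped between
blocks; the final map is clipped to [0, 1.5] for reporting only.

The network, Glorot-uniform initialization (±√(6/(fan_in+fan_out)), zero
biases) and Adam (α=0.001, β₁=0.9, β₂=0.999, ε=1e−8) are implemented
directly in NumPy. The reverse pass mirrors the forward pass operator by
operator — patch gather ↔ scatter-add, uniform smoothing ↔ its adjoint
(mirrored window), softsign/leaky-ReLU derivatives — and is verified against
central finite differences to <1e−4 relative error in the test suite.
Training arithmetic is float32 by default (float64 in the gradient tests).

### Training

* Loss: RMSE (not MSE, with an ε-guard at exactly zero loss) over voxels
  inside the body on slices containing at least one critical structure.
* Batches: whole slices, sampled "diagonally". With batch size B, P
  patients in a seeded order, slot j of iteration t visits patient
  perm[(j + tB) mod P] at slice (⌊j·S/B⌋ + t) mod S — concurrent slices sit
  at staggered depths, every patient's slices are swept cyclically, and the
  plan of a multi-plan patient rotates per iteration. Default B = median
  slice count of the cohort. Slices contributing no masked voxel are
  skipped.
* Defaults: 2 000 iterations; the desk-scale experiments in the tests and
  the acceptance script use 300 iterations on 16×32×32 grids, which is the
  problem size at which a full run completes in minutes on one CPU core.
* Cross-validation: (a) k-fold over patients repeated R times with fresh
  seeded shuffles, each patient tested exactly once per repetition; (b) a
  rotating-subset scheme over 10 fixed subsets, validation j training on
  the cyclic window j..j+T−1 and testing on the rest, so every subset
  appears in exactly T training and 10−T test sets. Both protocols re-fit
  the initialization on each training set before training the network.

## Objectives and surface metrics

Objective space is (HI = D2%−D98% of the PTV, bladder D25%, rectum D25%).
Dx% uses an exactly testable integer convention: sort the structure's doses
descending and take element ⌈x/100·N⌉ (1-based), no interpolation; D95%
normalization divides by that element, making the post-condition
(D95% = 100%) exact in floating point.

A patient's Pareto surface is sampled by 25 plans on a 5×5 grid over two
convex-combination parameters (α, β) ∈ {0, ¼, ½, ¾, 1}² of three bounding
priority vectors: p = α·P1 + (1−α)(β·P2 + (1−β)·P3). Duplicates at α=1 are
retained so vertices stay matched to the parameter grid. The surface is
triangulated in the (α, β) plane (two triangles per cell → 32 triangles for
5×5; objective-space triangulation of a curved surface could flip
simplices) and the triangles are carried to objective space.

* **Matched RMSE**: √mean of squared 3-D distances between matched
  vertices — errors accumulate across objectives rather than averaging.
* **Hausdorff**: over the vertex sets only (its outlier sensitivity is the
  motivation for ANPD).
* **APD**: displacements of matched pairs projected on the mean-displacement
  direction, then averaged (algebraically the norm of the mean
  displacement). Undefined when the mean displacement vanishes while
  individual displacements do not (an error); a self-comparison (all
  displacements zero) returns 0 by convention.
* **ANPD**: each surface supersampled on a barycentric grid (default ≥105
  points per triangle, subdivision level 13); each sample's distance to the
  other surface is the *exact* point-to-triangle distance minimized over
  that surface's triangles (plane projection / edge / vertex cases, with an
  edge fallback for degenerate triangles, which occur when duplicated α=1
  plans collapse). Directed means are averaged. The brute-force
  point-to-dense-sample version exists only as the test oracle.

## Synthetic cohort

The generator stands in for a clinical cohort (contours + planning-system
doses) and reproduces the statistical structure the model assumes, not
pelvic anatomy in detail:

* **Anatomy**: per-slice elliptical body; ellipsoidal PTV near the grid
  centre; ellipsoidal bladder anterior-superior; rectal tube posterior.
  Radii are fractions of the grid extent with ±10 % per-patient jitter and
  ±4 mm centre jitter (clamped so the target always fits); radii are floored
  at ~1 voxel pitch so coarse test grids stay valid. Femoral heads are not
  modelled (their fixed clinical constraint is outside this scope).
* **Surrogate dose**: `base · sparing · heterogeneity + anisotropy + noise`,
  then D95% normalization.
  - *base* is the initialization formula with known constants
    (1.5, 2.0, 0.8, 0.6), so the network's learning target is a small,
    structured residual.
  - *sparing* (outside the PTV only): 1 − Σ_o s_o·(w_o/(1+w_o))·exp(−d_o/τ)
    for o ∈ {bladder, rectum}, with d_o the in-plane organ distance,
    defaults s_o = 0.25, τ = 15 mm. The saturating response w/(1+w) makes
    each organ's dose depend only on its *own* priority, so organ D25% is
    provably non-increasing in that organ's priority — a share-based
    response w_o/Σw would couple the organs and break the monotone
    trade-off.
  - *heterogeneity* (inside the PTV): 1 + h·g/(1+w_HI) with g a smooth,
    zero-mean unit-variance field shared by all plans of a patient;
    h = 0.05. Its amplitude shrinks with the homogeneity priority, giving a
    monotone HI trade-off.
  - *anisotropy* (outside the PTV): an additive anterior/posterior lobe
    κ·cosθ·exp(−d_PTV/40 mm), κ = 0.20 of prescription, priority-independent.
    Real arc doses are not radially symmetric about the target; this is the
    component the isotropic initialization *cannot* fit, and κ is chosen
    once so that the initialization-only RMSE of the synthetic cohort sits
    in the ~5 %-of-prescription regime reported for clinical arc doses,
    leaving the residual network a realistic amount of structure to learn.
  - *noise*: σ·(uniform-kernel-smoothed white noise, renormalized to unit
    variance), σ = 0.02, kernel 5 — spatially correlated, as planning-system
    dose noise is, and shared across a patient's plans so that trade-offs
    remain exactly monotone.
  Because sparing and anisotropy vanish inside the PTV, target coverage and
  hence the D95% normalization factor are independent of the organ
  priorities; normalization cannot undo the monotone trade-offs.
* **Plans**: 25 per patient on the deterministic 5×5 convex-combination grid
  with default bounding vectors (10,1,1), (1,10,1), (1,1,10) — one
  objective-dominant corner each. Clinical bounding points were manually
  tuned and are not public; these are stand-ins, not claims about clinical
  values.

What the phantom does **not** emulate: CT intensities, beam transport,
collimation or deliverability, inter-patient anatomical variety beyond
jittered ellipsoids, and dose-grid artefacts. Passing tests therefore show
that the pipeline learns and evaluates the *kind* of structure the model
targets (priority-conditioned, geometry-driven dose shifts), not that it
reaches clinical accuracy on real patients.

## Degenerate inputs and tie-breaks

* Empty PTV, empty loss mask, empty point sets, zero D95%: validation
  errors.
* `Dx%` ties: resolved by the descending-sort order statistic itself.
* Leaky-ReLU derivative at exactly 0 is taken as the negative-side slope
  0.2.
* Five identical α=1 plans make some objective-space triangles degenerate;
  the point-to-triangle routine falls back to edge/vertex distances there.
* Batches whose slices contain no masked voxel produce no update and a NaN
  loss-trace entry.

## Known limitations

* The initialization is isotropic; it is expected to fail for static-field
  IMRT or short arcs (the anisotropic surrogate component makes this
  visible in the initialization-only RMSE).
* Prediction is voxel-wise; nothing enforces spatial smoothness of the
  output, so predicted maps can look jagged between neighbouring voxels.
* Surfaces are triangulated in parameter space; if the priority grid is not
  the square convex-combination scheme, simplices must be supplied
  explicitly.
* Training cost scales with (voxels per slice) × (batch slices) ×
  iterations; the 2 000-iteration default at 128×128 resolution is a
  multi-hour CPU run and is intended for offline use.
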