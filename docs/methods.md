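# Methods

`kneessm` models the shape of the tibio-femoral joint — the distal femur and
proximal tibia as one two-bone complex — with a point-distribution statistical
shape model (SSM), and asks whether the model's modes of variation (MoVs)
carry the information a clinician reads off five alignment angles.  This note
records the model, the conventions, the parameters that matter, and the
choices made where the design was genuinely open.

## Coordinate and angle conventions

All geometry is in millimetres.  Package-wide axes: x = medio-lateral
(+lateral for a right knee), y = antero-posterior (+anterior), z =
proximo-distal (+proximal).  Frontal plane = (x, z), sagittal = (y, z),
axial = (x, y).  Left knees are mirrored (x negated, face winding flipped) to
a common right-side convention before any statistics.

Five signed angles (degrees) describe tibio-femoral alignment:

| angle | symbol | plane    | definition                                              | normal range |
|-------|--------|----------|---------------------------------------------------------|--------------|
| HKA   | α      | frontal  | femoral vs tibial mechanical axis                        | 0 ± 3        |
| FVV   | β      | frontal  | femoral mechanical axis vs femoral joint-line normal     | −6 ± 2       |
| TVV   | γ      | frontal  | tibial joint line vs tibial-axis normal                  | 0 ± 5        |
| IER   | θ      | axial    | epicondylar axis vs plateau medio-lateral axis           | 0 ± 5        |
| TS    | ω      | sagittal | plateau antero-posterior line vs tibial-axis normal      | 7 ± 4        |

Signs: varus positive, valgus negative (hence the physiological FVV of −6°),
external rotation positive, posterior slope positive.  When the two joint
lines are parallel in the frontal plane, β + γ = α exactly.  A knee is
*unstable* with respect to an angle when the angle leaves its normal range;
the boundary counts as stable (the ranges are closed intervals).  All angles
are computed in a frame rebuilt from the landmarks themselves (z along the
tibial mechanical axis, x along the orthogonalized plateau medio-lateral
axis), which makes them exactly invariant to rigid motion of the input.

## Synthetic cohort generator

No patient data ship with the package; every downstream stage is validated on
a parametric generator.  The canonical template is primitive-based — a bent
elliptic-cylinder femoral shaft ending in two condylar lobes separated by an
intercondylar groove, and a flattened elliptic tibial plateau tapering into a
shaft — deliberately *not* an anatomical scan: the validation targets are
statistical and geometric structure (correspondence, variance recovery,
classification), not surface realism.  What the generator emulates: variable
shaft crop lengths (femur 20–40 mm, tibia 20–30 mm past the joint region),
left/right sides, smooth per-bone shape variation (scale, shaft
length/diameter/frontal bend, condyle and plateau sizes), relative
femur–tibia rotations with known ground-truth angles, tracked landmarks, and
isotropic vertex noise.  What it does not emulate: cartilage, osteophytes,
segmentation artefacts, and manual-landmarking error — so green tests say the
*pipeline* recovers structure it is fed, not that it is robust to every
artefact of real CT surfaces.

Deformations are applied in a fixed order — region scalings → shaft
elongation → frontal bend → global scale → pose rotations → vertex noise →
mirroring — and landmarks ride through every map except the noise, so the
recorded ground-truth angles are exact.  Because plane-projection angles do
not compose exactly under fixed-order 3D rotations (the cross-talk is
~0.03° at 5–10° poses), the generator does not apply the five pose/tilt
parameters as literal rotations; it solves a five-unknown calibration
(femur global frontal + axial rotation, condylar intrinsic tilt, plateau
frontal + sagittal tilt) against the package's own angle computation with a
Newton root find, to a residual below 1e-9°.  The five pose parameters are
therefore *exactly* the measured HKA/FVV/TVV/IER/TS of the noise-free sample.

Cohort draws use truncated normals (±3 SD by default, which keeps the meshes
free of self-intersections).  The default distributions were chosen once so
that the five stable/unstable class fractions land near the imbalance typical
of a pathological pre-surgical cohort (roughly 60/40 unstable for HKA and
FVV, 15–30% unstable for IER, TVV and TS) and are fully config-exposed; they
are conventions of the synthetic study, not estimates fitted to any dataset.
Noise defaults to 0.2 mm SD per vertex, the order of sub-millimetre CT
segmentation uncertainty.

## Correspondence pipeline

1. **Preprocessing.** Taubin λ/µ smoothing (λ = 0.5, µ = −0.53;
   shrinkage-free) and quadric edge-collapse decimation to a configurable
   vertex budget.  Scale and shaft lengths are never normalized: the relative
   femur/tibia size and the crop variability are part of the signal.
2. **Reference selection.** The sample minimizing the summed absolute
   deviation of its five angles from the physiological centers — a
   deterministic analogue of picking a low-deformity sample at random.  The
   reference can optionally be remeshed to a uniform edge length.
3. **Rigid pair alignment.** One rotation + translation per sample fitted to
   the concatenated femur+tibia cloud (landmark-Procrustes initialization
   when landmarks exist, else centroid + principal axes; ICP refinement).
   Never scale, and never per-bone: the intra-sample joint space is
   preserved exactly.
4. **Coherent point drift.** Non-rigid CPD per bone deforms the reference
   vertices toward the sample: a Gaussian-kernel motion field estimated by
   EM over a Gaussian mixture with a uniform outlier component.  Points are
   normalized internally to a shared zero-mean, unit-RMS frame so the classic
   defaults (β = 2, λ = 3, w = 0.1) keep their usual meaning; β is the kernel
   width in units of the cloud radius (smoothness of the motion field), λ
   trades data fit against coherence, w is the expected outlier mass.  For
   point sets above 500 the kernel is replaced by its top-60
   eigenmodes; the truncation is used consistently in the E-step, M-step and
   penalty, so the EM objective stays monotone for the approximated model
   (the trace is checked to 1e-8 per step).
5. **Projection.** Each deformed reference vertex is projected to its closest
   point on the sample surface (exact, all-triangles).  Projections beyond a
   5 mm gate are flagged as outliers and keep the deformed position.
   Correspondences are therefore reference-indexed: every sample contributes
   the same P points in the same order.

## Shape model

The P corresponding points per sample are flattened to 3P-vectors; PCA of the
sample covariance (divisor M−1, computed through the M×M Gram matrix) yields
the mean shape m̄, orthonormal modes v_i and mode SDs σ_i, with at most M−1
non-zero modes.  Explained variance EV_j = σ_j²/Σσ_i²; reconstruction
("morphing") Š = m̄ + Σ λ_i σ_i v_i; projection λ_i = v_i·(s − m̄)/σ_i, so
weights are unitless SD multiples and λ = 0 is the mean shape.  Retention
keeps the smallest k with cumulative EV ≥ 0.95 (configurable).  Mode signs
are fixed (largest-magnitude component positive) for determinism.  There is
no iterative mean/pose re-estimation: alignment is a single pass.

Reconstruction error is reported per sample as the maximum, mean and rms of
per-point deviations between the reconstruction and the sample's
correspondence points (point-to-point on the shared indexing, an upper bound
on true surface distance).  Only the rms — the L2 norm the projection
actually minimizes — is guaranteed non-increasing as modes are added; the
maximum and mean usually decrease too but carry no such guarantee.

## Statistical layer

Per angle, samples split into stable/unstable; "unstable" is the positive
class everywhere.  The SSM is fitted once on the full cohort and
leave-one-out cross-validation applies to the classifiers only — weights of
the held-out sample are computed in a shape space that saw its surface.  This
mirrors the intended use (the model is a fixed descriptor) but is a mild
optimism leak; it is deliberate and documented rather than hidden.

* **LDA/QDA**: Gaussian discriminants with shrinkage
  Σ ← (1−ρ)Σ + ρ·diag(Σ), ρ = 0.1 by default.  With tens of modes and
  classes as small as a dozen samples the raw class covariances are singular;
  the shrinkage form keeps per-feature scale while damping off-diagonal
  noise.
* **Logistic regression**: maximum-likelihood IRLS (tol 1e-8) with Wald
  z/p per mode.  Under complete separation the MLE diverges; the fit is
  redone with a small ridge (1e-4) and flagged.
* **Subset selection**: greedy forward selection maximizing LOO accuracy,
  ties to the lower mode index — deterministic, and verified against
  exhaustive search at small k.  Other selection schemes (exhaustive,
  coefficient-ranked) would be equally defensible; greedy is the declared
  choice, not a claim about any external procedure.
* **Rank-sum test**: unpaired two-sided Mann–Whitney comparing a mode's
  weights across the two conditions; exact enumeration of all C(n, nA)
  splits for n ≤ 12 (valid under ties), tie-corrected continuity-corrected
  normal approximation above.  An unpaired test is the correct choice here —
  the stable and unstable groups are different knees, not paired
  measurements.
* **Spearman correlation** of each mode weight against the corrected
  variables X̂ = |X − X̄| (deviation from the physiological mean), since
  drift in either direction means instability.
* No multiple-testing correction is applied by default (each test at
  p < 0.05); the analysis is exploratory screening, not confirmatory.

## Reference validation study

The standing study conditions (used by the acceptance tests and
`scripts/acceptance.py`) are: n = 20 knees at ~1000 vertices per bone, five
latent parameters (global scale, femoral shaft length, frontal rotation,
axial rotation, tibial slope), vertex noise 0.2 mm.  Two draws of the frontal
rotation serve two questions: its default continuous distribution
(N(0, 6°) truncated at ±15°) for latent *recovery* — cumulative EV must reach
0.95 within G+3 = 8 modes and the dominant mode's Spearman correlation with
the latent must exceed 0.8 — and a two-class draw (stable near 0°, unstable
near 6° = twice the normality half-width) for *classification*, where QDA
leave-one-out accuracy must reach 0.9.  The desk-scale problem sizes are the
package's standing test conditions; the same pipeline runs unchanged at
larger cohort sizes and finer meshes through the configuration file.

Known limitation: at n = 20 the dominant mode mixes latents to a degree that
varies with the draw (chance sample correlations between latents), so the
latent-vs-mode Spearman fluctuates by roughly ±0.1 across seeds.  The
reported numbers are measurements at the stated seed, not population
constants.

## Numerical choices

* Decimation: quadric edge collapse with link-condition and normal-flip
  guards, so watertight manifolds stay watertight; non-manifold input is an
  error, never silently repaired.
* Remeshing: edge subdivision to below 1.33× the target, then decimation to
  the area-implied vertex budget (V ≈ 2A/(√3 L²)) with up to three
  recalibrations and a light Taubin relax; mean edge within 10% of target.
* Point-to-surface distance: exact (every triangle), vectorized in chunks;
  Hausdorff distances are vertex samples against the full opposing triangle
  set, symmetric by taking the max of the two directed maxima.
* PCA rank cut: eigenvalues below max(σ₁²·1e-10, 1e-16) are treated as zero,
  so byte-identical shapes yield a zero-mode model instead of noise modes.
* Degenerate inputs: coincident landmark pairs raise errors naming the pair;
  an all-identical cohort short-circuits to a "degenerate" pipeline status;
  LOO folds that lose a class are flagged and excluded from the counts.
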