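# Methods

This note documents the models behind `qmap`, the parameters that matter,
the numerical choices, and what the synthetic testbed does and does not
show. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and relaxometry

The acquisition is a multi-slice saturation-recovery, multi-echo spin-echo
sequence: after a saturation pulse the longitudinal magnetization regrows
for a delay TD, then a multi-echo readout samples the transverse decay at
echo times TE. Under ideal saturation, complete spoiling and
mono-exponential decay the signal is

    S(TD, TE) = M0 · (1 − exp(−TD·R1)) · exp(−TE·R2)

with TD, TE in seconds, R1 and R2 in s⁻¹, and M0 the fully recovered signal
in arbitrary units. The default protocol is 4 saturation delays
(100, 400, 1380, 2860 ms; TR 2950 ms) × 5 echoes (14–70 ms in 14 ms steps),
i.e. 20 images per slice. No B1 or saturation-efficiency correction is
modelled: the phantom and the fitter share the same ideal physics, so the
round trip is exact by construction, and the model makes no claim of
reproducing any vendor reconstruction.

**Fitting.** For fixed (R1, R2) the model is linear in M0, so M0 is
eliminated analytically (variable projection) and the optimizer works on a
two-parameter objective. The solver is a Levenberg–Marquardt iteration
vectorized over all voxels at once:

* initialization is deterministic — R2 from the log-linear echo decay at
  the longest delay, R1 from the first/last-delay recovery-amplitude ratio
  solved by bisection (the ratio is strictly increasing in R1);
* the Jacobian is projected onto the orthogonal complement of the M0 model
  direction (Kaufman's approximation). This matters: because M0 re-optimizes
  at every step, the unprojected normal equations overestimate curvature and
  the iteration crawls along a flat valley on low-SNR voxels;
* convergence at 1e-8 relative parameter change or SSE stationarity
  (relative drop ≤ 1e-12), capped at 200 iterations; rates are clipped to
  [1e-4, 50] s⁻¹ (R1) and [1e-4, 500] s⁻¹ (R2);
* unusable voxels (all-zero, non-finite, non-positive projected M0) are
  flagged with NaN maps, a False validity bit and a per-voxel flag code —
  never silently zeroed.

PD is carried in raw M0 units; `calibrate_pd` rescales so the median M0 in
a user-supplied free-water reference region (ventricular CSF) reads 100%.
Cohort simulations emit M0 numerically equal to PD percent, i.e. a
scanner-calibrated convention, and do not re-calibrate per subject: scaling
every subject by its own drawn ventricular PD (94.3 ± 8.8%) would inject
~9% multiplicative variance into every other tissue, which is neither what
a calibrated quantitative sequence does nor a property of the statistics
under study.

## Contrast synthesis and smoothing

Any spin-echo contrast follows from the maps:
`S = PD · (1 − e^{−TR·R1}) · e^{−TE·R2}`, with an inversion-recovery
variant `|1 − 2e^{−TI·R1} + e^{−TR·R1}|` available. The registration source
is the T2-weighted image at TE = 100 ms / TR = 4500 ms, at which CSF is the
brightest class.

Gaussian smoothing takes its FWHM in millimetres and converts per axis, so
anisotropic grids are handled. Boundaries use edge replication (zero padding
would darken the brain rim and bias the SSD registration toward shrinking
the head). Invalid voxels are excluded by normalized masked convolution; a
voxel with no valid support returns NaN rather than bleeding zeros.

## Spatial normalization

A 12-parameter affine — translation (mm), rotation (Euler z·y·x, radians),
shear (unit upper-triangular), zoom — maps template-space world coordinates
(mm, RAS) to subject-space world coordinates; the matrix convention
`T·Rz·Ry·Rx·Shear·Zoom` is recorded in every transform file, and the
params↔matrix round trip (QR-based decomposition) is exact to ~1e-12.

The estimate minimizes the mean squared difference between the
intensity-standardized source and template. Choices that proved load-bearing:

* **Background-anchored standardization.** Images are scaled by the
  Otsu-foreground SD and shifted so the air median is 0. Out-of-field
  samples are filled with 0, so with air at 0 they blend into background
  instead of penalizing any transform that moves tissue across the field
  edge (with conventional zero-mean standardization, air sits several SDs
  below zero and the optimizer refuses to translate at all).
* **Masked cost.** SSD is evaluated on the template head dilated by ~14 mm,
  enough to see a misaligned brain edge without wasting samples on air.
* **Multi-resolution with progressive parameter opening.** Levels at
  8/4/2 mm (anti-alias smoothing + grid subsampling); L-BFGS with the
  analytic image gradient chained through the parameter-to-matrix
  derivative. At the coarsest level the parameters open progressively —
  translation+rotation, then +zoom, then the full 12 — which removes the
  classic local minima in which shear and zoom imitate a rotation.
  Initialization is identity plus the intensity-centroid translation; there
  are no random restarts, so registration is bit-deterministic.
* Each level's result is accepted only if its SSD did not increase; a
  budget-capped derivative-free polish pass exists (`polish=True`) for the
  stall cases trilinear interpolation can cause, but is off by default.

Quantitative maps are resampled trilinearly, validity masks and labels by
nearest neighbour; target-grid voxels that map outside the source are NaN
(floats) or background (labels). The shipped template is the noise-free
synthetic T2-weighted image of the canonical phantom on the 2 mm grid,
generated by code at call time (`default_template()` / `qmap template`);
any user-supplied template volume is accepted.

## Reference atlas and deviation statistics

The atlas stores, per parameter and voxel, the sample mean, the sample SD
with the n−1 denominator, and CoV = σ/mean where the mean exceeds 1% of its
in-brain median (background guard; CoV is never clipped in data, only at
render time). Per-voxel coverage counts contributing subjects; SD requires
coverage ≥ 2.

A subject is compared voxelwise as z = (subject − mean)/σ, signed, positive
meaning above the reference mean. The two-sided significance threshold is
Student's t at (group − 1) degrees of freedom — 2.04 for a group of 31 at
α = 0.05, 1.96 in the Gaussian limit — applied with per-voxel degrees of
freedom (coverage − 1) so partially covered edge voxels get honestly wider
thresholds. The combined map is the vector-sum magnitude
S = √(z_R1² + z_R2² + z_PD²), displayed above S > 5. Under an
independent-Gaussian null S follows the 3-df chi distribution;
`vector_sum_tail` gives that tail and `expected_false_positives` the
per-image expected count under a Gaussian or t null (at α = 0.05 a 256×256
image is expected to show ≈3277 spurious voxels; a Gaussian threshold of 5
leaves ≈0.04). No multiple-comparison correction is applied — the
false-positive accounting above is the stated alternative.

Numerical guard: a cohort SD at or below 1e-9·|mean| is treated as zero
variation (nanstd of bit-identical values returns ~3e-16 of summation dust,
which would otherwise produce |z| ≈ 0.8 from nothing); z is 0 there when
the subject matches the mean to the same precision, sentinel otherwise.

## ROI analysis and volume fractions

ROI means are computed per subject over valid voxels of each label, then
aggregated across the cohort — so reported SDs are between-subject SDs, and
the age regression (statsmodels OLS, two-sided slope p, significance at
p < 0.05, 95% CI) operates on per-subject ROI means, not pooled voxels.
Empty ROIs yield flagged rows.

Tissue classification is rule-based on calibrated maps: intracranial = the
largest connected component of PD > 30% after morphological closing;
CSF = PD > 85% and R1 < 0.6 s⁻¹ within it; parenchyma is the rest. Both
thresholds are configuration-exposed; they separate the generating class
values exactly, and on real data they would approximate what a
partial-volume segmentation does better. BPF = 100·|parenchyma|/|ICV| and
LVF = 100·|ventricles|/|ICV| with the ventricle mask taken from the label
atlas.

## The digital phantom

Anatomy is parametric-geometric so every volume has an analytic oracle: a
triaxial head ellipsoid (52/66/46 mm semi-axes), an outer CSF shell sized
so the parenchymal fraction is 90%, a ~4 mm cortical ribbon riding on a
sinusoidal folding (relief ≈ 3 mm, 6 cycles), two lateral-ventricle
ellipsoids solved analytically to 1.1% of intracranial volume, bilateral
caudate/putamen/thalamus ellipsoids, and optional spherical white-matter
lesions with R1/R2 decreased and PD increased (the demyelination
direction). Overlaps resolve by fixed priority (lesion > ventricle > deep
nucleus > cortex > white matter > CSF). The head was made clearly triaxial
deliberately: for a near-rotationally-symmetric head, rotation about the
symmetry axis is unidentifiable to *any* affine registration — an ellipsoid
is invariant under a family of affine maps — which is a degeneracy of the
object, not of the optimizer.

Tissue values are typical of healthy brain at 1.5 T (white matter
R1 = 1.38 ± 0.05 s⁻¹, R2 = 11.79 ± 0.26 s⁻¹, PD = 70.0 ± 1.0%; cortical GM
1.04/9.87/75.1; ventricular CSF 0.38/3.89/94.3 with the large in-vivo SDs
0.32/2.35/8.8 that partial-volume contamination produces; and so on). Per
subject, each class draws one (R1, R2, PD) triple from these Gaussians
(clipped at physiological floors), optional per-class age slopes shift the
means linearly around the cohort mean age, and a random small affine
(rotation σ 2°, translation σ 3 mm, log-zoom σ 0.03, shear σ 0.01) warps
the anatomy by evaluating the primitives at transformed world coordinates —
no resampling, so the jitter inverse is the exact normalization truth.
Acquisitions add Gaussian (default) or Rician noise; the cohort default
σ = 1.4 M0-units ≈ 2% of white-matter signal (SNR ≈ 50, typical of 1.5 T).
Ages are uniform on 26–67 years (mean 46.5, SD ≈ 12). All randomness flows
from named seeds through `numpy.random.SeedSequence`; a fixed master seed
reproduces a cohort directory byte-for-byte.

### What the phantom does not emulate

Partial-volume mixing (each voxel is a pure class), B1/saturation
imperfections, slice profiles, motion/ghosting/bias fields, realistic
cortical folding, and within-class spatial texture. Two consequences are
worth stating plainly:

* Passing recovery tests shows the estimator inverts its own generating
  model at realistic SNR — not that it reproduces vendor maps on real
  scanners.
* Because between-subject variation is a single draw per tissue class, all
  voxels of a class share it. The pooled |z| exceedance rate of a held-out
  cohort therefore has a genuine cohort-to-cohort spread (roughly ±0.02
  around the expected 0.053 for a 31-subject reference; four independent
  cohort seeds gave 0.034–0.072 during development). This is the finite
  reference group showing through, and a real 31-subject study behaves the
  same way; the fixed-seed acceptance test evaluates the calibrated
  operating point, and the null rate is computed over the eroded parenchyma
  (GM, WM, deep nuclei) where the draws are unclipped Gaussians.

## Problem sizes

The default phantom grid is 64×80×64 at 2 mm (≈83k brain voxels); tests
that iterate many replicates use a 40×50×40 grid at 2.6 mm with
proportionally scaled anatomy. The test suite runs 31-subject reference
cohorts plus 30 held-out subjects for null calibration, 20 random affine
perturbations for registration recovery, 1000 replicate voxels for noisy
parameter recovery, and 100 cohort replicates for slope-CI coverage.
`scripts/acceptance.py` recomputes the same quantities at 10 perturbations,
20 held-out subjects and 30 slope replicates — sizes chosen to keep a
single-core run around two minutes while leaving Monte-Carlo error well
inside the decision margins.

## Known limitations

Affine-only normalization (no nonlinear refinement), no group-vs-group
inference, no covariate-adjusted (age/sex) normative modelling, no FDR or
cluster-level correction, single-compartment relaxometry, and the
rule-based tissue classifier is a threshold model, not a partial-volume
segmentation.
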