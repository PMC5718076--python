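# Methods

`petmrvol` implements a tumour-volume concordance analysis for cervical
cancer imaging: it derives the same three families of tumour volume a
multimodal staging work-up produces — anatomical (ATV), functional (FTV) and
metabolic (MTV) — and quantifies how well each functional/metabolic estimate
agrees with the anatomical reference across a cohort.  Because the clinical
cohort itself is not distributable, the package ships a synthetic phantom
generator that reproduces the *structure* of the data (geometry, signal
models, noise), so every stage can be validated against analytic or planted
ground truth.

## Volume primitives

All grids are voxel-centred, axis order (slice, row, column), spacing in mm.
Masks must live on the grid of the image they annotate; mismatched grids are
rejected rather than resampled, since silent resampling would hide
registration errors none of the downstream statistics could detect.  Volumes
are voxel counts × voxel volume, reported in cm³; planimetric volumes are
Σ(slice area) × slice thickness, and the two agree exactly when slice areas
are derived from a mask (a property test enforces this).  The two-reader ATV
is a plain mean of two volume estimates.

## ADC mapping

The DWI signal is modelled as mono-exponential decay,

    S_b = S0 · exp(−b · ADC),

with ADC in mm²/s and b in s/mm².  The default acquisition schedule has 13
b-values over 0–1000 s/mm² (0, 25, 50, 75, 100, 150, 200, 300, 400, 500,
600, 800, 1000), densely sampled at low b where the decay carries most
information; the schedule is fully configurable and nothing downstream
depends on it.

Per voxel, a log-linear least-squares fit of ln S_b against b (positive
samples only) initialises (S0, ADC); a damped Gauss–Newton
(Levenberg–Marquardt) refinement then minimises the untransformed
sum-of-squares.  The refinement is batched: the 2×2 normal equations are
solved in closed form for all voxels simultaneously, with per-voxel damping
factors adapted by the usual accept/reject rule.  Convergence is a relative
parameter step below 1e-8 or 200 iterations.  Trial steps are boxed to
S0 ≥ 0 and ADC ≥ −0.01 mm²/s to keep the exponential bounded; final negative
ADC estimates are clamped to 0 and flagged (`fit_ok = False`), since ADC is
physically non-negative and the clustering stage needs well-defined
features.  Voxels whose measured b=0 signal falls below 5% of the robust
(99.5th percentile) maximum are treated as background and left unfitted;
voxels with fewer than two positive samples are flagged rather than fatal.

On noiseless model data the log-linear step is already exact, so round-trip
recovery is at machine precision.  On magnitude (Rician) data the noise
floor biases low signals upward; at SNR 30 (b=0) the median ADC bias of the
refined fit measures ≈ 0.3% in the shipped simulations, well inside the 2%
budget used in the tests.

## Metabolic tumour volume

SUVmax is the single hottest voxel inside the operator VOI (no
peak-averaging).  MTV_t is the volume of VOI voxels with
SUV ≥ (t/100)·SUVmax, inclusive at ties, with no connected-component
filtering: the VOI is the spatial gate that keeps physiological uptake such
as the bladder out of the measurement.  The default sweep is t = 20…80% in
5% steps (13 thresholds).  Two structural properties follow directly and are
tested: superlevel sets nest, so MTV is non-increasing in t; and thresholds
are relative, so MTV is invariant to positive rescaling of the SUV field.

## Functional tumour volume

Manual FTV is voxel counting of a reader-drawn mask.  Semi-automated FTV
clusters every VOI voxel's (S0, ADC) pair into k = 3 classes with K-means
(k-means++ seeding, best of 10 restarts, fixed seed) and keeps only the
solid-tumour cluster.  Both features are z-scored over the VOI first: S0 and
ADC differ by ~5 orders of magnitude and Euclidean K-means is
scale-sensitive, so standardisation is what makes the two features
commensurate (and makes the labels invariant to positive affine rescaling of
either feature).  Clusters are mapped to tissue classes by their raw ADC
centroid order — fat/fibrotic (low), tumour (intermediate), normal/cystic
(high) — with exact ADC ties broken by the S0 centroid.  Whole-VOI
("volumetric") clustering is the default; a slice-by-slice option exists for
comparison with 2D protocols.

## Concordance statistics

For each modality, over patients with complete pairs: the paired difference
of means `mean(ATV) − mean(modality)` (positive ⇔ the modality
under-estimates anatomy), the percent difference with mean(ATV) as the
denominator (this denominator is what reproduces the published table
arithmetic), a two-tailed paired-samples t test on per-patient differences
(Wilcoxon signed-rank behind a flag; with constant differences the p-value
is reported as 1 or 0 rather than NaN), and Pearson's r with the t-transform
p-value on n−2 degrees of freedom.  No multiple-testing correction is
applied across the 15 modality rows.  Display rounding: volumes/differences
and percents to 1 decimal, r to 3 decimals.

## Synthetic phantoms

**PET.** SUV(r) = B + (P−B)·exp(−r²/2σ²) about the grid centre on a 64³,
2 mm grid; defaults P = 9.2 (the reported cohort mean SUVmax), B = 0.6, σ =
15 mm, spherical VOI of radius 40 mm, plus a confounder sphere at 52 mm
offset set to 3× peak, which must clear the VOI (validated).  The percent-t
superlevel set of this profile is the ball of radius σ·sqrt(−2 ln u) with
u = (tP/100 − B)/(P − B), so the whole MTV sweep has a closed form; the
voxelised sweep is required to agree within one surface-voxel layer
(4πr²·Δ), and in practice agrees within ~0.1 of one.

**DWI.** A (20, 96, 96) grid at (4, 1.5, 1.5) mm — 20 axial slices of 4 mm,
matching a typical pelvic DWI acquisition.  The tumour is a central
ellipsoid; the VOI is the same ellipsoid scaled by 1.3.  Planted classes:
solid tumour = ellipsoid minus a small central cystic core (radius 0.35 ×
smallest semi-axis); normal/cystic = core plus the superior half of the
VOI-minus-tumour shell; fat/fibrotic = inferior half of the shell.
Class-conditional (ADC, S0) draws use means (0.30, 0.934, 2.00)×10⁻³ mm²/s —
the tumour value is the reported cervical-tumour mean — and (150, 450, 900)
signal units, with narrow spreads (0.03–0.10 ×10⁻³; 10–45 units) so the
classes form the distinctly separated clusters the three-tissue model
assumes.  Signals follow the mono-exponential model at the 13 scheduled
b-values; Rician corruption is √((S+g₁σ)²+(g₂σ)²).  PET noise, when
enabled, is additive Gaussian (post-reconstruction PET noise is
approximately Gaussian after smoothing).

**Cohort.** Per patient, drawn from one master seed via hierarchical
`SeedSequence` spawning: peak SUV ~ U(3.3, 16.7) (the reported range),
background 5–10% of peak, anatomical equivalent radius ~ U(15, 30) mm
(cohort mean ATV ≈ 53 cm³, matching the reported ~55 cm³ scale), and mild
volume-preserving axis anisotropy (ratios 0.85–1.18, smallest axis along the
slice direction).  The PET σ is calibrated per patient so the analytic MTV
equals the anatomical volume at the 32.5% threshold — the midpoint of the
30–35% bracket where intermediate-threshold concordance is expected — which
makes the cohort's mean MTV curve cross the mean ATV between adjacent
thresholds and reproduces the mechanism behind the concordance result
without claiming the clinical numbers.  Truth tables carry analytic values
for ATV and MTV and planted voxel volumes for the FTVs.

What the phantoms deliberately do **not** emulate: anatomical realism
(organs, bladder filling, partial-volume mixtures at tissue boundaries),
PET reconstruction physics (OSEM noise correlations, resolution blur),
MR artefacts (eddy currents, motion, fat-suppression failure), inter-reader
delineation variability (the "manual" masks are the planted truth), and
overlap between tissue classes in feature space.  Passing tests therefore
show the pipeline is correct and stable under the stated models, not that
the clinical effect sizes would be reproduced on patient data.

## Problem sizes and determinism

Default sizes keep every stage desk-scale: 64³ PET grids, ~12–27k fitted
DWI voxels per patient, 29-patient cohorts; the full test suite runs in
seconds and the end-to-end cohort in a few seconds on one core.  All
randomness flows from explicit seeds (cohort → patient → voxel via
`SeedSequence`); a fixed configuration reproduces its output CSVs byte for
byte, which a test asserts.

## Known limitations

* The mono-exponential model ignores perfusion (IVIM) and kurtosis effects;
  at b ≤ 1000 s/mm² this is the standard clinical simplification.
* Magnitude fitting has a noise-floor bias at low SNR; the package bounds it
  empirically at SNR 30 but does not implement Rician-likelihood fitting.
* K-means assumes roughly isotropic clusters in z-scored feature space;
  heavily overlapping or skewed tissue distributions would need a mixture
  model.
* The published per-patient correlations (r ≈ 0.78–0.97) cannot be
  recomputed without the clinical cohort; the package reproduces the
  published *table arithmetic* exactly and validates the statistics against
  closed-form oracles instead.
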