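# Methods

`tbiqmri` implements a multiparametric quantitative MRI analysis for
focal traumatic brain injury in the rat, together with a digital-phantom
cohort generator that stands in for scanner data. This note records the
models, the defaults and why they were chosen, the numerical machinery,
and the limits of what the synthetic validation can show.

## Map models

All reconstructions operate voxel-wise on single-slice magnitude images.

* **T1 (inversion recovery).** Three-parameter model
  `I(TI) = A + B exp(-TI/T1)`. Magnitude acquisition discards the sign
  of pre-null points, so the fit runs on polarity-restored data: for
  each candidate null index *k* the first *k* samples are sign-flipped
  and the candidate with the lowest residual wins (exhaustive search,
  at most nTI+1 candidates per voxel, implemented as a short
  exploratory fit per candidate followed by a full-precision refit of
  the winner). The phantom generates ideal inversion, `A = M0`,
  `B = -2 M0`.
* **T2 and ADC.** Mono-exponential decays `I = I0 exp(-TE/T2)` and
  `I = I0 exp(-b ADC)`, fitted by bounded nonlinear least squares seeded
  from a weighted log-linear fit (weights `y^2`, nonpositive samples
  excluded). Voxels with fewer than three positive samples are invalid.
* **CBF (ASL).** Single-compartment continuous-labeling estimate
  `CBF = 6000 (lambda/T1_app) (S_ctrl - S_lbl) / (2 alpha S_ctrl)` in
  mL/100 g/min, with blood-brain partition coefficient
  `lambda = 0.9 mL/g`, labeling efficiency `alpha = 0.8`, and `T1_app`
  from the fitted T1 map (constant 1.5 s fallback where the T1 fit is
  invalid). The same constants drive the phantom's forward model, so the
  pair is exactly invertible. Negative differences are kept and flagged.
* **APTw.** Asymmetry of the saturated signal at +/-3.5 ppm:
  `100% x [S(-3.5)/S0 - S(+3.5)/S0]`. No clamping; healthy tissue is
  assigned small negative values, the expected sign under this
  convention (upfield macromolecular transfer outweighs the amide pool
  at baseline).
* **MTR.** `100% x [1 - S_sat(2 kHz)/S0]` (2 kHz ~ 10 ppm at 4.7 T).

Maps can be upsampled 2x to a 384x384 display grid by bilinear
interpolation in the align-corners convention (exact on affine fields);
validity masks travel by nearest neighbor. ROI statistics taken before
and after upsampling agree to well under 0.5% on smooth maps.

## Acquisition protocol defaults

Echo times 30-90 ms in 10-ms steps (NA 4); inversion times 0.05, 0.3,
0.6, 1.2, 1.8, 2.5, 3.5 s (NA 4) — the first value is read as 50 ms,
the plausible correction of an inconsistent printed list, and is
configurable; b-values 0, 166.7, 333.3, 500, 666.7, 833.3, 1000 s/mm2
(NA 8); saturation offsets +/-3.5 ppm and 2 kHz at 1.3 uT for 4 s
(NA 16, applied per acquired image); 192x192 matrix over a 32-mm field
of view, 1.5-mm slice.

## Phantom geometry and injury model

A single coronal slice: an elliptical brain (semi-axes 13 x 10 mm) on
the square grid, with seven regions — circular injury core in the
dorsal-left (ipsilateral) parietal cortex, an annular perilesion band
around it, the mirrored contralateral band, and paired hippocampal and
thalamic disks. Region placement guarantees pairwise disjointness for
every severity (checked at build time; overlap is an error, as is a
core poking outside the brain). Ipsilateral = left = columns below the
grid midline; the convention is recorded in each sidecar.

Severity grades (sham/mild/moderate/severe, mirroring graded impactor
depths) set the core radius (0 / 1.2 / 2.4 / 3.0 mm) and select a table
of additive truth shifts per (severity, timepoint, region). The default
table encodes the qualitative injury course: core CBF and APTw
depressed acutely with early ADC decline; day-3 core T2 elevation;
perilesion APTw (moderate/severe) and CBF (severe) overshoot at day 3;
severe injury adds T1 increases and MTR decreases across ipsilateral
regions; hippocampal APTw starts slightly low and rises through day 3.
Tissue baselines are typical rat-brain values at 4.7 T (cortex T1 1.5 s,
T2 60 ms, ADC 0.75e-9 m2/s, CBF 100 mL/100 g/min, APTw -2%, MTR 30%).
Every shifted value must still satisfy the physical ranges declared on
the tissue table (T1 > T2, ADC in [0, 4e-9], APTw inside the (-6, 6)%
display window, and so on); violations abort phantom construction.

## Noise model

Magnitude-MRI (Rician) noise: independent complex Gaussian noise of
standard deviation sigma is added per signal average, the magnitude
taken, and the `NA` averages averaged. `sigma = S_ref / SNR`, where
`S_ref` is the mean over nonzero voxels of the stack's brightest
condition plane — the acquired S0-equivalent (the b = 0 image, the
unsaturated image, the longest-TI or shortest-TE frame). Referencing
noise to an acquired plane is the only definition an experimenter can
realize; it also keeps the per-sequence information content consistent
across sequences with different dynamic ranges. Default SNR 40,
a typical preclinical 4.7-T surface-coil value; configurable.

Under this model a 1000-voxel Monte Carlo at SNR 40 with the default
condition lists yields median relative errors of about 2% for T1 and
about 1-1.5% for T2 and ADC, a factor ~1.1-1.3 above the Cramer-Rao
bound for these designs — the estimator is close to efficient.

## Cohort and outcome model

Default group sizes 7/16/17/16 (sham/mild/moderate/severe, n = 56);
sexes assigned half/half at random. A configurable early-sacrifice
subset per group (default 0/7/6/6) receives day-3 histology (Iba1
counts) and no 28-day behavior; survivors receive behavior and no
histology.

Each subject carries a latent effect multiplier
`m = clip(1 + 0.2 eps, 0.5, 1.5)` scaling its severity shifts, so
regional truth varies within groups. Outcomes (mNSS 0-18 integer,
sucrose preference 0-1, Barnes escape time and forced-swim immobility
0-240 s, Iba1 counts >= 0 integer) are linear in a designated regional
APTw predictor plus Gaussian noise, then clamped and rounded. The
linear link is anchored at the sham and severe group expectations (for
example mNSS 0.5 -> 11, so a sham's pre-noise expectation is near 0).

The noise SD of each outcome is **calibrated, not closed-form**: a
deterministic internal large-sample draw (200 000 subjects, fixed
internal seed, common random numbers) bisects sigma until the
correlation between predictor and *finished* outcome — after clamping
and rounding — equals the configured r. A Gaussian formula would be
biased as soon as clamping is active (the mNSS floor at 0 binds for
shams); calibration makes "configured r is realized" a structural
property of the model. Configured targets that exceed the zero-noise
ceiling, or predictors with no severity contrast, are rejected with an
error. Degenerate sub-cohorts (for instance sham-only) have no
correlation to realize and fall back to anchor-scale noise (10% of the
sham-severe span).

Default configured links: day-1 core APTw vs mNSS (r = -0.60), sucrose
preference (+0.50), Barnes escape (-0.55), Iba1 in the core region
(-0.45); day-1 hippocampal APTw vs forced-swim immobility (-0.45);
day-3 perilesion and thalamic APTw vs local Iba1 (+0.60, +0.50).
Because all predictors share the severity axis, further relations
emerge without being calibrated (day-3 perilesion APTw correlates
positively with mNSS and negatively with sucrose preference); these are
declared as induced sign expectations and tested as such.

## ROI statistics and volumetry

ROI means/SDs are taken over valid voxels only; a fit that failed
excludes its voxel rather than imputing. ROIs transfer unchanged
between coregistered maps; the only permitted grid change is the
integer 2x display upsampling (nearest-neighbor label scaling). Any
other mismatch is an error — cross-grid registration is out of scope.

Contusion volume is segmented on a T2w-like image as voxels above
`mean + k SD` of the contralateral-cortex reference region (k = 2 by
default; the choice follows common lesion-segmentation practice, and k
is a config knob). 8-connected in-plane components are retained only if
they touch the ipsilateral half-grid, which discards mirror-side
artifacts. Volume = voxel count x in-plane voxel area x slice
thickness, summed over however many slices are supplied.

## Statistics

Exploratory sex comparisons use uncorrected independent-sample t-tests
(pooled-variance Student form — the conventional default reading of an
unqualified "independent-sample t-test"; Welch is available via a
flag). Severity comparisons use one-way ANOVA followed by Tukey's HSD
(Tukey-Kramer for unequal n), all pairs reported with versus-sham rows
starred at 0.05/0.01/0.001. Brain-behavior relationships use Pearson
correlation with listwise deletion (early-sacrifice subjects lack
behavior). No multiplicity correction is applied beyond Tukey's.

Degenerate inputs follow explicit conventions: zero pooled variance
with equal means gives t = 0, p = 1; with unequal means p = 0, flagged;
zero within-group variance flags the ANOVA/Tukey result as degenerate.
Ties in the T1 polarity search resolve to the lowest residual.

## Numerical choices

Nonlinear fits run as a damped (Levenberg-Marquardt) least-squares
iteration vectorized across voxels: bounds by projection, damping
adapted per voxel (x0.3 on success, x4 on failure), convergence when
the relative step falls below 1e-12 or the cost improvement stays below
1e-13 for two consecutive accepted steps; voxels whose damping
saturates are abandoned and marked invalid. Bounds: T1 in [0.05, 10] s,
T2 in [1, 500] ms, ADC in [1e-11, 4e-9] m2/s. On noiseless data the
round trip through every forward model recovers truth to better than
1e-6 relative error per voxel (in practice ~1e-15).

Brain masking thresholds at 0.2x the mean nonzero intensity of the
reference plane and keeps the largest 8-connected component.

## Problem sizes

Full-protocol phantoms use the 192x192 acquisition matrix. The test
suite and the end-to-end demo run on 48-96 grids with 2-4 subjects per
group and recover the same structure; these sizes were chosen so a
complete simulate-fit-analyze cycle stays in the minutes range on a
single CPU while every ROI still spans dozens to hundreds of voxels.
Calibration checks use 2000 null replicates; correlation-recovery
checks use 200 replicate cohorts of 40 subjects.

## Limitations

The phantom is a single slice with piecewise-constant tissue classes:
no partial-volume gradients, no B0/B1 inhomogeneity, no motion, no
hemorrhage/susceptibility modelling, no multi-exponential relaxation,
and the saturation images are generated from a symmetric-baseline
asymmetry construction rather than Bloch-McConnell two-pool physics —
by design, so the map formulas have exact algebraic inverses and
reconstruction correctness is testable in isolation. Passing tests
therefore demonstrate correctness of the estimators and statistics
under the stated models, not robustness to physics the phantom does not
contain. Outcome distributions are linear-Gaussian with clamping, a
deliberately minimal generative model: it realizes the configured
correlation structure but not floor/ceiling shapes or ordinal response
artifacts of real behavioral instruments.
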