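# Methods

This note documents the models, estimators, numerical choices and
limitations behind `aortaflow`.  It states no empirical result that the
test suite does not itself compute.

## Data model and conventions

A 4D flow dataset is a three-component velocity field on a regular
axis-aligned grid, `[nx, ny, nz, nt]`, in m/s, with a magnitude image,
voxel spacing (mm) and temporal resolution (ms).  World coordinates are
`index * spacing`; no orientation matrix is carried (phantoms are
generated on this grid; scanner-frame orientation handling is out of
scope).  Spacing converts to metres exactly where spatial derivatives or
world coordinates are formed, so WSS is produced directly in Pa and PWV
in m/s.  Background phase-offset correction is a scanner/reconstruction
step and is not reimplemented; the generator can inject a constant
offset to probe downstream sensitivity.

The PC-MRA (segmentation substrate) is the time-averaged product of
magnitude and speed; peak systole is the frame maximizing the spatially
averaged speed inside the lumen, ties to the earliest frame.

## Synthetic phantom world

The generator emulates the conditions the analysis is designed for:
tubes of radius ~10 mm at 2.5 mm isotropic resolution and 30 frames of
~32 ms, straight or U-bend (two straight limbs joined by a half-circle,
default bend radius 35 mm, giving an arch-like geometry with an
unambiguous inner/outer side).

* **Velocity model.** Axial Poiseuille flow,
  `v(r, s, t) = vmax * w(t - s/PWV) * (1 - r^2/R^2)`, with `w` a
  periodic waveform (max 1, linear interpolation between samples) and
  `s` the centerline arc length.  The default waveform is a raised-cosine
  systolic pulse over 45% of the cycle on a 5% diastolic baseline, peaking
  near frame 7 of 30.  Poiseuille (not Womersley) is deliberate: it has
  closed-form wall shear rate `2*vmax/R` and flow `pi*R^2*vmax/2`, which
  are the oracles every estimator is tested against.
* **Wave propagation.** The waveform phase is shifted by exactly `s/PWV`
  per cross-section, so the pulse propagates with zero dispersion and the
  PWV estimator's error is isolated from any modelling error.
* **Noise.** Independent Gaussian noise per velocity component, inside
  and outside the lumen (default SD 0.05 m/s = SNR 20 at vmax 1 m/s,
  matching a reasonable clinical 4D-flow operating point).  The magnitude
  image is identically 1; magnitude weighting is not exercised by any
  downstream quantity.
* **Cohorts.** Subject i draws `vmax_i = vmax * exp(sigma_v z)` and
  `R_i = R * exp(sigma_R z')` (defaults sigma_v = 0.10, sigma_R = 0.05 —
  ~10% velocity and ~5% caliber spread, a plausible healthy-cohort
  range).  All subjects share the template grid, so voxelwise atlas
  statistics are defined without registration error.
* **Determinism.** All randomness descends from a single integer seed
  via spawned `SeedSequence`s; identical specs give bit-identical
  datasets.

What the phantoms do **not** emulate: secondary/helical flow, turbulence,
non-Newtonian rheology, valve jets, wall motion, curvature-induced
profile skewing, intensity-dependent noise, or registration error between
subjects.  A green test therefore establishes estimator correctness in
laminar, dispersion-free conditions — not robustness to flow features the
generator does not produce.

## Wall geometry

* **Wall points and normals.** One wall point per exposed boundary-voxel
  face centroid.  Inward normals are the gradient of the signed distance
  transform (positive inside), Gaussian-smoothed at sigma = 1 voxel:
  the raw voxel-center EDT has staircase plateaus that corrupt gradient
  directions on curved surfaces (the sphere check degrades from <5° to
  ~12° mean error without smoothing).
* **Local lumen diameter.** Ray-marching from each wall point along its
  inward normal at 0.25 × min-spacing steps until the (smoothed) signed
  distance re-crosses zero, refined by linear interpolation.  Rays that
  leave the grid or never enter the lumen mark the point invalid (NaN,
  never 0); invalid points are excluded downstream.
* **Centerline.** The ridge of the interior distance transform, traced
  as the minimum-cost path between the two geodesically farthest mask
  voxels with edge cost = step length × inverse-squared wall distance
  (26-connectivity, Dijkstra).  3D thinning was rejected: it collapses
  the limbs of thicker capped tubes.  The cap regions — where the ridge
  path dives toward mask corners — are trimmed and re-grown as straight
  extensions along the end tangents; this keeps the centerline both
  full-length and curvature-clean at the ends.  A coverage check rejects
  masks that are not a single unbranched tube.  The path is smoothed
  (window 3) and resampled every 2 mm.
* **Regions.** Longitudinal classes (ascending / arch / descending) come
  from configured arc-length landmarks — they are located manually in
  practice and provided as ground truth by the phantoms.  The
  inner/outer side of a point is the sign of its offset along the local
  curvature normal (pointing at the center of curvature = inner).  The
  clinical literature does not define inner/outer operationally; this
  curvature convention is this package's definition.  Curvature is
  measured at a ~22 mm smoothing scale: the spec-level floor of 1/(1 m)
  is far below voxel-noise curvature at finer scales (a 0.1 mm ripple
  over 1 cm already exceeds it).  Where curvature is below the floor the
  side falls back to the tangent-perpendicular direction toward the
  centerline chord midpoint (for an arch: toward the inside), and for
  fully straight vessels to an explicit `apex_normal` configuration.
* **Rigid registration.** Follow-up segmentations are registered to
  baseline by maximizing mask overlap, not image intensity: soft Dice of
  Gaussian-smoothed masks, Nelder–Mead over 3 rotations + 3 translations,
  initialized from centroids and principal-axes candidates with
  near-ties broken toward the smaller rotation (so symmetric shapes
  resolve to the near-identity optimum).  Results carry the final hard
  Dice; below 0.5 they are flagged, not silently used.

## Wall shear stress

At each valid wall point, velocity is sampled by trilinear interpolation
at D/4 and D/2 along the inward normal (D = local lumen diameter), each
sample is projected onto the wall-tangent plane, and each tangential
component is fitted with the unique quadratic through (0, 0), (D/4, v1),
(D/2, v2) — no-slip enforced at the wall.  WSS = mu × slope at the wall.
The quadratic interpolant is exact for linear and parabolic profiles, so
the estimator is unbiased on the Poiseuille phantom up to interpolation
and wall-localization error; the acceptance suite asserts the error
bounds and its monotone decrease with voxel size (averaged over
sub-voxel lattice phases — a single alignment of the tube axis with the
voxel lattice is a degenerate configuration that confounds convergence
measurement).

Viscosity defaults to mu = 3.2e-3 Pa·s, the conventional blood value in
this estimator family; it is configurable and enters only as a scale.

Regional means: WSS is averaged over the valid wall points per region;
velocity over lumen voxels, each voxel taking the longitudinal class of
its nearest wall point and its side from the curvature rule applied to
the voxel itself.  Both are evaluated at the peak-systole frame only —
the source description is ambiguous on whether regional velocity uses
all frames; peak systole is this package's reading (flagged here).

## Atlases and abnormality maps

Healthy subjects are projected onto the shared geometry (trilinear
velocity sampling at shared lumen voxel centers; WSS matched to the
nearest subject wall point within 2 voxels; an optional rigid transform
maps geometries first).  At each location the atlas stores the mean
vector, mean magnitude and sample SD (n−1) of the magnitude, defined
only where ≥ 80% of the cohort (and ≥ 2 subjects) contribute.

* *Elevated*: patient magnitude strictly above `mean + 1.96 * SD`
  (one-sided — only elevated maps are reported clinically; decreased
  values are not flagged).
* *Abnormally directed*: angle between patient vector and atlas mean
  vector > 120°; locations where either vector is below 0.01 m/s
  (velocity) or 0.01 Pa (WSS) are not evaluated, since the angle is
  numerically meaningless near zero vectors.
* Per-region patient flags are the OR over the region's locations; the
  incidence map is the percentage of flagged patients per location among
  those covering it.

Null calibration: a healthy subject from the same generative
distribution should exceed the one-sided 95% bound at roughly 2.5% of
voxels.  Within one subject the exceedances are strongly correlated —
the cohort-level vmax multiplier shifts all voxels together — so the
acceptance check averages the elevated fraction over five held-out
subjects (decided before measurement) and asserts the < 10% bound.

## Pulse wave velocity

1. **Temporal resampling** to a uniform ~20 ms grid by evaluating the
   trigonometric (rFFT) interpolant of the periodic cycle; the output
   frame count is `round(period/20 ms)` with dt the exact divisor, the
   cycle mean is preserved to machine precision, and a field already on
   the target grid passes through unchanged.
2. **Flow waveforms** through planes orthogonal to the centerline every
   10 mm: tangential velocity summed over lumen voxels in a one-voxel
   slab × voxel area, in ml/s; sections with < 4 voxels are dropped;
   slab membership is restricted to voxels whose nearest-centerline arc
   length is local, so U-bend limbs cannot contaminate each other.
3. **Wavelet delays** relative to the most proximal section: complex
   Morlet CWT (omega0 = 6, 32 log-spaced scales spanning periods from
   2·dt to half the cycle, computed via the FFT of the mean-subtracted
   periodic signal); cross-spectrum `C = W_ref * conj(W_i)`; delay =
   cross-power-weighted mean of `phase(C)/omega` over the region with
   `|C| >= 50%` of its maximum, weight = total cross-power there.  The
   phase-weighted average (rather than a cross-correlation peak) tracks
   the transit time even as the waveform changes shape; omega0 = 6 and
   the 50% mask are this package's dialect, exposed as parameters.  The
   estimator is exactly antisymmetric under argument exchange.  Flat
   waveforms return an undefined delay with zero weight.
4. **Regression**: weighted OLS of delay on arc length (weights = section
   cross-power); PWV = 1/slope, marked invalid for non-positive slope or
   R² < 0.5; fewer than 3 usable sections is an error.

## Statistics

Paired and unpaired comparisons are classical Student t tests with 95%
CIs (pooled variance for the unpaired test — Welch is deliberately not
the default, matching the named reference test; scipy provides both).
Zero-variance paired differences are reported *undefined* rather than
given a conventional p.  Fisher's exact two-sided p sums hypergeometric
probabilities no larger than the observed table's (verified in tests by
full enumeration over all 2×2 tables with n ≤ 40).  McNemar's exact test
is the capped doubled binomial tail on the discordant pairs,
`min(1, 2·P(X ≤ min(b,c)))`, reported NA when b + c = 0.  ICC(2,1)
(two-way random effects, absolute agreement, single measurement) is
computed from the ANOVA mean squares with the F-based
(Satterthwaite-df) confidence interval; pingouin serves as an
independent cross-check in the test suite, never as the implementation.
No multiple-testing correction is applied anywhere (none is applied in
the reference battery).  Report formatting rounds percentages half away
from zero and prints p to three decimals ("<0.001" below).

## Pipeline and reproducibility

`run_pipeline` executes simulate → geometry → WSS → atlas → patients →
PWV → registration → incidence → reports.  Patients share the template
geometry with elevated peak velocities (default ×1.35, i.e. a clearly
abnormal cohort), per-patient wave speeds drawn from N(8.5, 1.5²) m/s
clipped to [4, 13] — spanning the healthy-to-stiff clinical range — and
small (3%) session-to-session jitter.  Blood pressures and heart rates
are drawn once per patient around typical adult values (SBP 115 ± 13,
DBP 66 ± 9 mmHg, HR 61 ± 9 bpm) with small per-visit variation, purely
to exercise the clinical-table machinery.  All stages derive their
randomness from the single configured seed; CSV/JSON outputs are
bit-identical across reruns, and every run writes provenance (config
hash, seed, version).

## Known limitations

* Voxel-native wall representation: no sub-voxel surface reconstruction;
  WSS carries a small negative bias from wall-localization error that
  shrinks with resolution.
* Rigid-only registration; the source methodology family uses deformable
  co-registration for atlas mapping.  Nearest-neighbour / trilinear
  lookup is the mapping dialect, recorded in output metadata.
* Regional velocity means at peak systole only (see above).
* The inner/outer split is the curvature convention defined here; other
  operationalizations would shift region boundaries for near-straight
  segments.
* PWV assumes a periodic, dispersion-free pulse; foot-to-foot and
  transit-time variants are out of scope.
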