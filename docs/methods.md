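# Methods

This note documents the models, conventions and numerical choices behind
`girdlekin`, and what the synthetic test bed does and does not establish.

## Measurement model

Each bony segment *s* ∈ {thorax, clavicle, scapula, humerus} carries a
rigid cluster of four reflective markers. At every frame the cluster pose
(R_s, t_s) is the orthogonal-Procrustes minimiser of
Σᵢ ‖R mᵢ + t − oᵢ‖² over proper rotations, solved by SVD with the standard
reflection guard (flip the smallest singular direction when det < 0). With
three or more visible markers the fit proceeds (a warning-level situation
monitored through the residual RMS); fewer is an error. The estimator is
equivariant: transforming all observations by a rigid map transforms the
estimated pose by the same map, a property several pipeline guarantees rely
on.

Anatomy is digitised once in the CT frame of each bone: the ISB landmarks
(thorax IJ, C7, PX, T8; clavicle SC, AC; scapula AA, TS, AI; humerus GH,
EL, EM), the scapular reference point `P_dorsal` (most dorsal point of the
acromion at the AC joint), and the cluster markers as segmented in CT.
Because the same physical markers appear in CT and in the cluster model,
a Procrustes fit of the CT marker set onto the technical-frame model gives
the CT→technical registration (default rejection threshold: 1.0 mm RMS);
any CT-frame point can then be replayed through the pose series.

### Anatomical frames and joint angles

Frames follow the ISB shoulder conventions (lab axes: X anterior,
Y superior, Z to the right; right shoulder). The clavicle's axial rotation
is unobservable from SC and AC alone, so its anatomical frame is completed
with the thorax Y direction; since the cluster provides a full 6-DOF pose,
the frame defined at the reference posture is effectively carried by the
tracked pose.

AC joint rotations are the mobile Y-X-Z Euler angles of the scapula frame
relative to the clavicle frame: R_rel = R_Y(α)·R_X(β)·R_Z(γ) with
α = retraction(−)/protraction(+), β = lateral(−)/medial(+) rotation,
γ = anterior(−)/posterior(+) tilt. AC displacements are the components of
`P_dorsal` expressed along the clavicle (joint) axes, reported as
superior(+Y), anterior(+X), lateral(+Z) in millimetres; they are raw in the
kinematics layer and zero-referenced only in the outcome reduction.
Thoracohumeral orientation uses the Y-X-Y sequence (plane of elevation,
elevation, axial rotation).

Both sequences are degenerate at a gimbal configuration (|β| = 90° for
Y-X-Z; elevation 0°/180° for Y-X-Y). Frames whose trigonometric pivot is
within 1e-6 of the degeneracy are flagged and linearly interpolated from
their neighbours; at the Y-X-Y degeneracy the continuity convention
attributes the whole Y rotation to the axial angle so the identity maps to
(0, 0, 0). Rotational traces are 360°-unwrapped.

### Left shoulders

The study design ties the surgical-sequence group to the side (left =
AC-first, right = CC-first). To pool both sides under one sign convention,
a left shoulder's marker data *and* CT anatomy are reflected across the
laboratory sagittal plane (Z → −Z in this package's lab convention); the
reflected data set is a geometrically valid right shoulder, so every
downstream formula applies unchanged, and applying the reflection twice is
the identity. The raw point map has determinant −1; all derived rotations
remain proper because model and observations are reflected together.

## Preprocessing

Occlusion gaps must be interior and at most `gaps.max_gap_s` (default
0.5 s); they are filled per coordinate with a cubic spline through the
visible samples. Filtering is a second-order Butterworth low-pass at
6 Hz applied forward–backward (zero phase) per coordinate, mean-removed
before padding so DC passes exactly. Zero-phase application squares the
single-pass magnitude, so the analytic amplitude gain used in verification
is 1/(1 + r⁴) with r the bilinear-prewarped frequency ratio
tan(πf/fs)/tan(πfc/fs). The package filters marker coordinates (not
angles); this is a package decision where the acquisition description is
silent.

## Outcome reduction

**Alignment.** Within the abduction trial, the thoracohumeral elevation
trace is split into the trial's three cycles; in each, the resting sample
is the centre of the longest near-minimal elevation plateau (tolerance
0.5°, absorbing noise and the low-pass undershoot at motion onset), and
the six AC DOFs at the three resting samples are averaged. Per shoulder,
each condition is referenced to the intact joint as **intact − condition**
— the likeliest sign-convention pitfall in reproduction: a joint sitting
8.7 mm *inferior* to intact reports **+8.7 mm**. Intact rows are
identically zero by construction.

**Stability.** Per DOF, each motion's three cycles are averaged after
time-normalisation (native per-cycle resolution, so no extrema are lost),
the peak-to-peak range taken, and ranges summed over the six motions
(cumulative range of motion; lower = stiffer joint). Missing motions are
excluded with a warning.

**Summaries.** Group cells are summarised as median, bootstrap percentile
95% CI (2000 resamples, seeded) and IQR. Two comparison conventions are
deliberately distinct, each calibrated once to the reporting style being
emulated and then fixed: condition-vs-reference uses
`median(reference) − median(condition)` for both median and IQR; the
between-sequence comparison uses `median(second) − median(first)` for
medians but `iqr(first) − iqr(second)` for dispersions (so with AC-first
listed first, a negative median difference means AC-first has the larger
median and a negative IQR difference means it has the smaller dispersion).

## Statistics

* **Mann-Whitney U** (sequence effect on alignment, unpaired): exact
  distribution for tie-free groups of ≤ 10 (the emulated study has 5
  shoulders per group, 20 pooled construct observations), tie-corrected
  normal approximation otherwise.
* **Friedman** (construct effect on stability, paired across conditions):
  mid-ranks with tie correction. For tie-free matrices with ≤ 12 blocks the
  p-value comes from the permutation null of the statistic — a cached,
  derandomised 200 000-draw simulation per (n, k), with the add-one rule so
  p > 0 — because the chi-square reference is measurably conservative at
  n = 5 (true level ≈ 0.034 at α = .05); chi-square with k−1 df is used
  otherwise. The statistic itself is unchanged.
* **Fisher LSD post hoc**: Conover-style t comparisons on within-block rank
  sums with (n−1)(k−1) df, unadjusted for multiplicity (that is the LSD
  procedure), evaluated only when the omnibus is significant at α = .05.
* Box-plot statistics support two whisker conventions behind a flag:
  `minmax` (whiskers to the extremes, no outliers) and `tukey` (1.5·IQR
  fences with outliers) — source figures mix the two descriptions, so
  neither is asserted as canonical.

α = .05 two-sided throughout; no additional multiplicity correction is
applied, matching the emulated analysis plan.

## Synthetic generator

The generator is the pipeline's ground-truth instrument, emulating the
study conditions:

* **Design**: 5 shoulders per group (left/AC-first, right/CC-first), 7
  conditions (intact, Rockwood 5 lesion, CC-only, 4 bracing constructs),
  6 motions × 3 cycles at 100 Hz.
* **Waveforms**: each DOF follows raised-cosine humps
  `rest + A·(1−cos)/2` per cycle (default 3 s cycles), separated and
  flanked by 1.5 s rest holds — robot-driven passive motion is smooth, and
  holding the resting posture between repetitions both mirrors robotic
  practice and gives the resting-alignment stage a quiescent plateau whose
  filtered value is transient-free. The protocol's motion amplitudes were
  specimen-specific and are not published; defaults (a few degrees of AC
  rotation, a few mm of displacement per motion, humeral elevation sweeping
  15–105°) are package choices fixed in `default_waveforms`. In the
  abduction waveform the AC *displacement* amplitudes are zero:
  translational excursions are exercised by the traction and compression
  motions, which keeps the resting-alignment evaluation of displacement
  DOFs exact and mirrors the small translational excursion of a guided
  abduction.
* **Conditions**: a static alignment offset (condition − intact, 6 DOF) and
  a per-DOF stability scale multiplying the AC motion amplitudes. Offset
  medians default to the negated emulated-table median differences
  (Rockwood: (3.3, 1.8, 3.0, −8.7, 3.0, 6.3); AC-first reconstructions:
  (−1.9, 0.2, −10.1, −2.2, 0.8, 1.0); CC-first: (−1.1, 2.1, −0.7, −3.7,
  2.4, 2.3)). Rotational offsets are injected as a rest-anchored
  premultiplier on the commanded AC orientation, so the commanded Euler
  offsets are exact at the resting posture; translational offsets shift the
  commanded `P_dorsal` position in the (static) clavicle frame exactly.
* **Dispersion**: between-shoulder variability is an additive draw per
  shoulder × condition from a logistic distribution with scale
  IQR/(2·ln 3) (a logistic's IQR is 2s·ln 3) — medians and IQRs are the
  natural summaries of the emulated analysis and the underlying shape is
  unknown. The published dispersion information constrains only IQR
  *differences*; absolute levels (AC-first (2.0, 3.0, 3.0, 2.0, 2.5,
  1.6), CC-first (3.8, 2.1, 7.8, 3.5, 2.2, 5.0), Rockwood (3.0, 3.0, 3.0,
  4.0, 3.0, 4.5)) are package choices consistent with those differences.
* **Stability scales**: intact 1.0, Rockwood 2.5, CC-only 1.3, constructs
  1–4 (double vertical, single vertical, single horizontal,
  horizontal+box): 0.5, 0.8, 0.9, 0.7 — the double-vertical design is the
  stiffest, all constructs stiffer than intact, the lesion loosest.
* **Noise and occlusion**: isotropic Gaussian marker noise (σ in mm;
  0.2 mm is a realistic optical-capture figure) and NaN occlusion runs per
  marker. Left shoulders are generated as exact sagittal mirrors.

**What the generator does not emulate**: soft-tissue artifact (pins are
intracortical, so none is expected), robot dynamics and force control,
inter-marker cluster deformation, CT segmentation error, and any
specimen-specific anatomy beyond the single canonical skeleton. Passing
tests therefore establish the correctness of the *computation chain* under
the stated measurement model, not the biological variability of real
shoulders; real-data conclusions still depend on the acquisition quality of
the actual experiment.

## Numerical choices

* Degenerate cluster/landmark configurations (collinear points, coincident
  landmarks) are errors, detected via singular values or vanishing norms
  (tolerance 1e-10 relative).
* The filter requires trials several filter lengths long and a cutoff below
  Nyquist; gaps must be filled first.
* Euler extraction clamps trigonometric pivots to [−1, 1]; the gimbal guard
  band is 1e-6 on the pivot.
* The resting-plateau tolerance (0.5°) and the per-cycle equal-duration
  split are the cycle-handling choices; how cycles were pooled in the
  emulated analysis is unspecified, and cycle-averaging before ranges is
  this package's choice.
* Problem sizes used by the verification battery: 200 random pose
  instances against a brute-force rotation-space minimiser; 10³ Euler grid
  points per sequence; a 70-trial zero-noise study for end-to-end recovery;
  1000-replicate null calibrations. `scripts/acceptance.py` uses a
  420-trial full study (all six motions) for the Table-style quantities.

## Known limitations

* The C3D codec covers the Intel/float point-data subset of the standard
  (plus integer-scaled reading); analog channels and other processor types
  are out of scope. Positions round-trip at float32 precision; the TSV
  path is the full-precision interchange.
* Cumulative ROM depends on the equal-duration cycle split; strongly
  asymmetric real recordings would need explicit cycle events.
* The Fisher-LSD comparison degenerates (zero rank-sum variance) when all
  blocks rank identically — possible in noise-free synthetic data, where
  a two-point p (0 or 1) is reported.
* Statistical power and type-I calibrations are properties of the
  generator-plus-test pairing at the emulated effect sizes, not claims
  about any real data set.
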