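# Methods

This note records the models, numerical choices and limitations behind
`afsource`, in the spirit of a model-documentation page.

## Signal model and preprocessing

A recording is a T×L matrix of surface potentials at sampling rate fs
(clinically 1 kHz), with lead labels and optional 3-D electrode
positions. Clinical preprocessing follows the f-wave analysis pipeline:

* **Band-pass 2–30 Hz, Butterworth order 2**, applied zero-phase
  (forward–backward), which doubles the effective order but leaves the
  autocorrelation lags undistorted — important because cycle lengths are
  read directly off ACF peak positions.
* **Channel-wise z-scoring.** The normalization method is a design
  choice: the CL/MaxAC features and the separation are scale-invariant,
  and z-scoring stabilizes the covariance whitening. Constant channels
  are zeroed with a warning rather than an error.
* **QRS exclusion** by Pan–Tompkins (5–15 Hz band-pass, derivative,
  squaring, 150 ms integration, adaptive threshold trained on the first
  2 s, 200 ms refractory). Two stages reject non-ventricular envelopes:
  peaks must reach 15% of the global envelope maximum and 3× the
  envelope mean — a pure f-wave trace fails the latter because its
  integrated energy is nearly uniform. QRS intervals default to
  −60/+100 ms around the refined R peak; both windows are configurable
  since no canonical values exist for this step.
* **T-wave exclusion**: in each inter-QRS gap, the 200 ms sliding window
  with maximal cross-channel variance is excised (ties break to the
  earliest window). The window length is a configurable default.
* **f-wave segments** are the surviving gaps of ≥ 800 ms; intervals are
  half-open [start, end) in ms with 0-based sample indexing.
* **12-lead derivation** uses Einthoven/Goldberger limb leads and
  precordial leads referenced to the Wilson Central Terminal
  (RA+LA+LL)/3. Which vest electrodes stand in for the 9 ECG roles is a
  required configuration input; the bundled cylinder vest assigns them
  to the electrodes nearest canonical torso landmarks.

## Second-order blind source separation

Pipeline: center → whiten to K dimensions (eigendecomposition of the
zero-lag covariance; requesting K beyond the effective rank, at relative
eigenvalue tolerance 1e-10, is an error) → symmetrized lagged
covariances at lags 10, 20, …, 300 ms → orthogonal joint
diagonalization by Jacobi sweeps with the closed-form per-pair Givens
angle, rotation-angle tolerance 1e-10, at most 100 sweeps → sources =
rotationᵀ · whitened. The diagonalization lags span the full
cycle-length band so that sources with any clinically plausible period
produce distinct lagged-covariance signatures.

The algorithm is deterministic given its input; the arbitrary source
sign is left free here and canonicalized only in the s1-to-leads
feature. Sources are returned with exactly unit variance; the mixing
matrix (pseudo-inverse of the unmixing chain) absorbs the rescaling.

**Ranking.** Sources are ordered by MaxAC (periodicity) by default;
`rank_by="eigen"` preserves the variance-explained order instead. MaxAC
is the default because the downstream dominant-CL rule scans sources in
periodicity order.

**Unbiased ACF.** ACF(τ) = (T−1)/(T−τ−1)·Σ(s_t−s̄)(s_{t+τ}−s̄)/Σ(s_t−s̄)²,
computed via FFT and verified in the tests against a direct double-loop
oracle to 1e-10. ACF(0) = 1 exactly. A consequence of the small-sample
correction worth knowing: for a strongly periodic source whose period
and double both lie inside the search window, the correction grows with
τ and the argmax can land on the harmonic lag (e.g. 316 instead of
158 ms). Downstream logic therefore always matches cycle lengths
*through harmonics* (factor m ≤ 3, tolerance 5 ms), which is also how
focal-CL agreement is scored.

**Confidence band.** The 95% half-width uses the Bartlett large-lag
approximation 1.96·√[(1 + 2Σ_{j<τ}ACF(j)²)/T]. The dominant CL is the
first ranked CL whose peak exceeds its half-width; episodes where no
source qualifies return "none" rather than a number.

**Lag window.** T_FS defaults to the contiguous band 100–330 ms,
covering the clinical focal-CL range 120–270 ms with margin on both
sides; it is configurable.

## Features and baselines

* **CL/MaxAC vector**: interleaved (CL₁, MaxAC₁, …, CL_K, MaxAC_K) in
  rank order; duplicate CLs are kept (no deduplication).
* **s1-to-leads**: mixing column of s₁; sign flipped iff strictly more
  coefficients are negative than positive (an exact tie keeps the
  original sign — deterministic and order-free), then min-max rescaled
  to [0, 1]; a constant column maps to 0.5 everywhere with a warning.
* **AFFTr2DF**: squared-magnitude FFT of the mean-removed V1 lead, no
  taper (matching the 1 Hz resolution of 1 s / 1 kHz clinical segments),
  normalized over positive frequencies; DF is searched in 3–10 Hz (the
  atrial band — a choice, since no canonical band exists) and the ratio
  sums bins in (0, 2·DF], closed at the top.
* **NDI**: 1 − (variance of the top 3 lead-space principal components)/
  (total variance), computed by SVD on the centered segment.

On the synthetic corpus the two baseline metrics carry little contrast
between categories (driver vs reentrant AFFTr2DF means differ by ~0.03
with overlapping distributions). This mirrors their weak discriminative
performance as classifier features and is a property of the generator's
wavelet morphology: the 40 ms activation wavelet concentrates spectral
energy in comb harmonics above 2·DF for every category.

## Classifiers and validation

* **Tasks.** FS presence (positive = driver- or initiator-type FS, all
  segments eligible); AF sustainability (positive = initiator-type FS,
  FS-induced AF, reentrant AF; negative = driver-type FS); FS location
  (FS-driven segments only; positive = right atrium).
* **SMOTE** is implemented in-package: each minority class is topped up
  to the majority count with uniform convex combinations of a random
  class member and one of its k = 5 nearest within-class neighbors
  (k reduced with a warning for classes smaller than 6). Original rows
  are preserved verbatim.
* **Random forest**: 200 trees (fixed), otherwise library defaults,
  seeded.
* **Nested leave-one-patient-out CV**: the outer loop holds out each
  patient once; the inner loop cycles one further patient out as a
  validation set and picks the K with the highest mean inner accuracy
  (ties → smallest K, the cheaper extraction). The model is retrained on
  the full pool with the chosen K. Inner folds whose training split
  lacks two trainable classes are skipped; precision/recall are
  positive-class metrics, reported NaN with a warning when undefined.
  Metrics are summarized as mean ± s.d. across outer folds.
* **Mechanism mapping**: the three binary outputs map to six signal-level
  mechanisms (location ignored when FS presence is negative); a patient
  is Group 1 iff initiator-type FS calls occur and all originate from
  one atrium.

## Tissue analysis

Phase movies: per-node 15 Hz low-pass (4th-order Butterworth,
zero-phase), DC removal by mean subtraction (the "0 Hz notch"), analytic
signal angle. Constant traces are masked.

Phase singularities: the elementary closed loop is a grid plaquette on
regular grids and a triangle on meshes; the wrapped phase differences
around the loop are summed and |Σ ∓ 2π| < π/4 marks a PS at the loop
centroid. The triangle (rather than the one-ring fan) was chosen as the
mesh primitive because it is the elementary closed loop of a
triangulation, needs no manifold edge-ordering, and a one-ring's winding
equals the sum of its member triangles' windings. The π/4 tolerance is a
choice; the analytic-spiral tests bound the localization error by one
grid cell.

Tracking is greedy nearest-neighbor between consecutive frames with
equal-chirality matching under the 2 mm/ms gate (scaled by the frame
interval); unmatched detections open tracks, unmatched tracks close. No
gap bridging is performed. Rotor duration drops tracks shorter than
100 ms and returns the measure of the union of the survivors' lifetime
intervals, so it is monotone non-increasing in the threshold.

Activation maps: first upward −30 mV crossing after the stimulus (local
activation), first downward −70 mV crossing after it (repolarization),
both linearly interpolated between samples; APD is their difference.
ERP brackets: largest blocked CL to smallest conducted CL above it, with
±∞ sentinels at the grid edges and a warning on non-monotone outcomes.

## Synthetic corpus

The generator stands in for a biophysically simulated training corpus;
it reproduces the *statistical structure* the classifiers exploit, not
tissue biophysics.

* **Waveforms**: Gaussian-derivative wavelets (width 40 ms) at the
  effective CL spacing, unit RMS; 2:1 conduction block drops alternate
  beats (doubling the beat spacing); fibrillatory sources get ±3 ms
  cycle-to-cycle CL drift, focal drivers none.
* **Forward model**: infinite-homogeneous-medium dipole sum
  φ(r) = (1/4πσ)Σ pᵢ·(r−rᵢ)/|r−rᵢ|³ with σ = 0.2 S/m, each source a
  fixed-orientation (seeded) dipole at an anatomically laid-out site:
  RA centered at +x, LA at −x, PVs posterior-left, with (α, β) grid
  coordinates mapped to within-chamber offsets. The dipole simplification
  (not a full transmembrane-gradient volume integral) suffices because
  the separation stage only assumes an instantaneous linear mixture.
* **Vest**: 252 electrodes quasi-uniform on a 15 cm × 40 cm cylinder
  (the real vest geometry is not redistributable); ECG roles assigned to
  nearest-landmark electrodes. Perturbations are rigid z-rotations about
  the centroid plus translations.
* **Categories**: driver-type FS = jitter-free focal dipole + two
  CL-synchronized satellites; initiator-type FS adds a drifting
  reentrant source with CL differing by > 10 ms; FS-induced AF = the
  parent initiator's reentrant sources alone (focal ablation); reentrant
  AF = 2–3 drifting sources. Episodes are 1000 ms at 1 kHz with white
  noise at SNR 20 dB — one-second segments being the clinical analysis
  unit.
* **Inducibility policy**: the probability that an FS configuration
  becomes an initiator peaks at CL 180 ms for LA/PV foci (0.88/0.95) and
  at 210 ms for RA foci (0.24), with an ACh bonus for LA 150–210 ms and
  PV 150 ms, scaled by a per-patient factor in [0.8, 1.2]. These numbers
  shape the category mix only; they are explicitly not a biophysical
  claim.
* **Default corpus size**: 5 virtual patients × (48 sampled focal
  configurations + paired induced-AF segments + 24 reentry
  configurations) ≈ 410 episodes — chosen as a desk-scale corpus that
  still exercises patient-wise generalization.

**What passing tests do and do not show.** The generator produces
episodes whose category differences live exactly in the features the
method uses (CL structure, periodicity, spatial origin). Success on it
demonstrates that the pipeline recovers those structures through an
unknown linear forward mixture with noise — not that real fibrillatory
electrograms are this well-behaved. Real BSPMs add ventricular activity,
non-stationary source morphology, correlated noise and torso
inhomogeneity that the generator does not model; the QRS/T machinery is
exercised on constructed waveforms only.

## Numerical conventions

Half-open [start, end) intervals in ms throughout; 0-based sample
indexing; argmax ties break to the smallest lag; K-selection ties break
to the smallest K; whitening rank tolerance 1e-10; Jacobi tolerance
1e-10 / 100 sweeps; PS winding tolerance π/4; all randomness flows
through explicit seeds or `numpy.random.Generator` arguments.

## Known limitations

* The separation assumes an instantaneous, stationary linear mixture;
  moving or morphologically evolving sources violate it.
* Harmonic ambiguity of the unbiased ACF is inherent when period
  multiples share the search window; consumers must compare CLs through
  harmonics.
* The FS-location feature (s1-to-leads) is by construction sensitive to
  electrode placement; only FS presence and AF sustainability are
  placement-robust.
* No ECGi-style inverse reconstruction, no PDE tissue simulation, no
  survival analysis: those are outside the package's scope.
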