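# Methods

`opmbeta` couples a synthetic wearable-MEG cohort generator to the analysis
chain used in developmental studies of sensorimotor beta dynamics:
homogeneous field correction, LCMV beamforming, Hilbert-envelope spectral
measures, leakage-corrected amplitude envelope connectivity, and a
time-delay-embedded hidden Markov model (TDE-HMM) for pan-spectral burst
detection. Because every recording is simulated with known structure, each
analysis stage can be validated against a planted ground truth. This note
records the model assumptions, the parameter choices that matter, and the
places where the design was genuinely open.

## Synthetic cohort

### Geometry and forward model

Heads are spherically symmetric conductors; head radius grows linearly with
age (0.07 m at 2 y to 0.09 m at 34 y), exercising the adaptable-array
property of optically pumped magnetometer (OPM) systems: every participant
gets a triaxial sensor array packed on a Fibonacci spiral over the upper
65 % of a sphere offset 10 mm from their own scalp. Each sensor measures
along one radial and two tangential orthonormal axes, so 64 sensors yield
192 channels (desk-scale runs use 14 sensors / 42 channels).

Fields are computed with the closed-form current-dipole-in-a-conducting-
sphere solution. This is deliberately simpler than a realistic single-shell
boundary-element conductor — it is exact, fast, and testable (radial and
central dipoles are silent; the radial field component equals the primary
dipole term), but it is a fidelity limit: absolute localization accuracy on
real anatomy will differ.

### Task and sources

The task is passive tactile stimulation: 0.5 s stimulus trains every 3.5 s,
alternating between two finger conditions, 42 trials each (84 trials,
294 s). Simulated source content:

* **Sensorimotor pan-spectral bursts.** A two-state Markov chain whose
  stationary ON-occupancy is `p_base` (default 0.5) at rest and `p_stim`
  (default 0.2) during the 0–0.8 s window after each stimulus onset; the
  exit rate is set by the mean burst duration (0.25 s) and the entry rate
  derived so the stationary occupancy equals the requested probability
  exactly. The burst waveform is a Tukey-gated (taper fraction 0.4) sum of
  narrowband stochastic carriers (2.5 Hz bandwidth) centred at 3, 9, 21 and
  37 Hz. Stochastic carriers, rather than fixed sinusoids, keep the burst
  class a single Gaussian process in the lag-embedded space; with
  deterministic carriers the random per-burst phase of the slow components
  splits the class into mirror-image clusters that a Gaussian mixture model
  resolves as two separate states.
* **Mu rhythm.** The same source carries a task-independent bursting
  mu/alpha rhythm (7.5–10.5 Hz, occupancy 0.4, mean duration 0.3 s, 0.47 of
  the burst amplitude) plus a small stochastic floor (0.13). This is
  physiologically motivated — sensorimotor cortex expresses a prominent,
  task-stable mu rhythm — and it matters methodologically: a three-state
  HMM needs three genuinely distinct signal classes (quiet, mu, burst). If
  the background is a single homogeneous Gaussian process, maximum
  likelihood spends the spare state splitting the burst class instead.
* **Evoked component.** A biphasic, Gaussian-windowed (20 ms) 20 Hz wave
  peaking 50 ms after each onset — an M50 analogue — oriented orthogonally
  to the burst dipole at the same location.
* **Network sources.** One beta-band source per parcel of a 78-region
  template. Each signal is `(1 + 0.35 z(t)) * carrier(t)` where `z` is a
  unit-variance Gaussian modulator low-passed at 1 Hz and the carrier is a
  phase-continuous sinusoid whose instantaneous frequency drifts slowly
  around 21 Hz (so its envelope is identically one and survives beta-band
  filtering unperturbed). Within the frontal and occipital parcel groups
  the modulators share a common factor, making every pairwise envelope
  correlation equal the planted coupling.
* **Noise.** Six deep 1/f dipolar background sources, white sensor noise
  at 15 fT/√Hz, and (optionally) a spatially homogeneous interference
  field with 1/f spectrum for exercising homogeneous field correction.

### Planted age effects

Linear trends anchored at age 2: burst suppression deepens with age
(`p_stim` falls 0.009/y from 0.45 while `p_base` stays 0.5), the 3 Hz
carrier weight falls (−0.02/y from 1.2) while the 21 Hz (+0.015/y) and
37 Hz (+0.008/y) weights rise, the 9 Hz weight is constant (alpha-band
stability), frontal envelope coupling rises (+0.009/y from 0.15) while
occipital coupling is flat at 0.25, and the evoked amplitude grows weakly.
Ages are drawn uniformly: children 2–13 y, adults 21–34 y (27 + 26 by
default). `AgeEffectSlopes.null()` freezes all trends at their mid-cohort
values for null-calibration runs.

## Preprocessing

Bad channels are flagged from log10 broadband power: dead channels, and
channels more than 3 scaled MADs *and* 0.5 decades from the cross-channel
median (the absolute floor prevents the MAD rule from flagging healthy
channels in homogeneous arrays, where the MAD reflects estimator noise
only). Filtering is a zero-phase 4th-order Butterworth band-pass plus IIR
notches (Q = 30) at the powerline frequency and its harmonics (harmonics at
or above Nyquist are skipped). Trials whose pooled good-channel variance
exceeds mean + 3 sample SDs are removed, with one re-iteration of the rule
on the survivors; the comparison is strict, so a variance exactly at the
threshold is retained. Homogeneous field correction projects the data onto
the orthogonal complement of the rank-3 subspace spanned by the channel
orientation vectors (symmetric idempotent projector of rank
`n_channels − 3`).

## Beamforming

Covariance matrices are sample covariances of band-filtered data over good
channels and trials, Tikhonov-regularized by 5 % of the largest eigenvalue,
and inverted by eigendecomposition (condition number retained). The scalar
LCMV filter chooses, per voxel, the tangential orientation minimising
`lᵀC⁻¹l` (equivalently maximising projected power) via the closed-form 2×2
eigenproblem, then `w = C⁻¹l / (lᵀC⁻¹l)`, which enforces unit gain
`wᵀl = 1`. Task contrast images use beta-band (13–30 Hz) covariance and
the normalisation `(P_active − P_control)/(P_active + P_control)` over the
0.3–0.8 s and 2.5–3.0 s windows — chosen for scale invariance since the
exact pseudo-T normalisation is a free choice; a noise-normalised variant
(`(Pa − Pc)/2Pn`) is available via `normalization="noise"`. The virtual
electrode is extracted at the most negative pseudo-T voxel (strongest beta
desynchronisation; ties break to the lowest linear index) with broadband
(1–48 Hz) weights. Grids default to 8 mm (16 mm at desk scale).

## Spectral measures

Envelopes are magnitudes of the analytic signal of zero-phase band-filtered
data. The time-frequency spectrogram uses 4 Hz-wide bands stepped by 2 Hz
from 1 Hz, per band: envelope → trial average → fractional change from the
2.5–3 s baseline. The beta modulation index is
`(β_post − β_stim)/β_baseline` with windows 1–1.5 s, 0.3–0.8 s and
2.5–3 s, computed on the trial-averaged beta envelope (trials are averaged
before baseline correction). The evoked response is the plain trial
average of the 4–40 Hz virtual electrode; the M50 is the signed extremum
in 40–70 ms after subtracting the −0.1–0 s pre-stimulus mean. Note the
beamformer orientation sign is arbitrary, so the *sign* of the M50 is not
comparable across participants; the cohort-level M50 trend is therefore
expected to be weak in this pipeline.

## Connectivity

Beta-band virtual electrodes are computed at the 78 template parcel
centroids. For each ordered pair, the zero-lag (leakage) component of one
signal is regressed out of the other before envelopes are correlated; the
two directions are averaged, giving a symmetric amplitude-envelope
correlation (AEC) matrix with zero diagonal. Orthogonalization exactly
nulls dominantly-leaked pairs; note that for *intermediate* mixtures
(comparable leaked and intrinsic components) symmetric orthogonalization
produces a known negative bias through mirrored interference terms — this
is a property of the estimator, not a bug, and negative values are retained
unclipped. Global connectivity is the off-diagonal mean; node degree the
column sum. The analytic null threshold for an AEC value is
`3/√(B_env · T)` where `B_env` is the *envelope* bandwidth — the filter
width for band-limited noise, but the (much smaller) modulator bandwidth
for processes with slow envelopes like the synthetic network sources.
The batched connectome path does its O(n² T) envelope arithmetic in single
precision (double-precision accumulation), agreeing with the pairwise
reference to ~1e-6.

## Burst detection (TDE-HMM)

The 1–48 Hz virtual electrode is decimated to 100 Hz and lag-embedded with
lags −7…+7 samples (15 dimensions, 150 ms window), each column
standardized. A K = 3 Gaussian HMM with full covariances is fitted by
maximum-likelihood EM (Baum–Welch): k-means++ initialisation, several
restarts (5 by default, 2–3 at desk scale), convergence at relative
log-likelihood change < 1e-6 or 500 iterations, a variance floor of 1e-6
on collapsing covariances, and exact scaled forward–backward smoothing
(the inner loops are numba-compiled). Maximum-likelihood EM was chosen
over variational schemes because it is exactly testable: the
forward–backward output is verified against brute-force path enumeration,
and the smoother is cross-checked against an independent HMM library given
identical parameters.

Posteriors are binarized at 2/3 (a posterior exactly at threshold counts
as active; with K = 3 at most one state can exceed 2/3 per sample).
Occupancies are folded into trials and trial-averaged. **Burst-state
selection** takes the state with the largest *signed* post-minus-stimulus
occupancy difference (1–1.5 s minus 0.3–0.8 s) — the state most suppressed
during stimulation, which is the defining signature of sensorimotor bursts
in this task. Selecting by absolute modulation instead (available as
`direction="absolute"`) is structurally degenerate: whenever a single
quiescent state carries the complement of burst occupancy, that complement
modulates at least as strongly as the burst state itself, so the magnitude
rule systematically returns the background state. Burst-probability
modulation is the same signed difference for the selected state; burst
amplitude is the mean broadband envelope over burst-on samples.

State-resolved spectra concatenate the samples where the binarized state
indicator is on, split them into 256-sample segments, and average
multitaper (DPSS, time-bandwidth 4, 7 tapers) periodograms over segments,
reported on 1–48 Hz. Because multitaper smoothing turns narrowband peaks
into ~3 Hz plateaus whose raw argmax wanders, peak frequencies are read
out as the power-weighted centroid of the contiguous region within 3 dB of
the local maximum (`spectral_peak`).

## Cohort statistics

Pearson correlations use the exact two-sided p from the t-distribution
with n − 2 df; pairs with missing metrics are excluded pairwise and the
effective n reported. Z-transforms within age groups use the sample SD
(ddof = 1). The child tertile split sorts by age with participant-id
tie-breaks; remainders join the oldest group. No multiple-comparison
correction is applied across the correlation family. The full pipeline is
a pure function of (configuration, seed): per-participant seeds derive
from the master seed via `numpy` seed sequences, and the cohort CSV is
written with a fixed float format so reruns are byte-identical.

## Problem sizes

The full-scale configuration (1200 Hz, 64 sensors, 8 mm grid, 5 EM
restarts) reflects the study conditions; the `desk_scale` configuration —
200 Hz sampling, 14 sensors, 1–90 Hz band (the 100 Hz notch harmonic is
then above Nyquist and skipped), 16 mm localisation grid, 2 EM restarts
with at most 100 iterations, and 2× decimated AEC envelopes — is the
package's own choice of routine problem size for interactive runs, the
test-suite and the acceptance script; the task structure (84 × 3.5 s
trials) is identical in both. Localization calibrations always use the
8 mm grid.

## What the synthetic data do and do not show

The generator plants the qualitative structure the analysis is meant to
recover — task-suppressed pan-spectral bursts, age-graded burst and
coupling parameters, envelope-coupled networks, homogeneous interference —
so passing tests demonstrate that each stage recovers its own plant under
the stated noise and geometry. They do not demonstrate performance on real
OPM-MEG: the conductor is a sphere rather than anatomy, sources are point
dipoles with stationary statistics, there are no movement, ocular or
cardiac artifacts (hence no ICA stage), helmet geometry is idealised, and
amplitudes/durations of real bursts are not calibrated to measurements —
burst process defaults are plausible placeholders exposed in the
configuration. Recovered effect sizes (e.g. cohort R² values) are
properties of the planted effect strengths, not predictions of the real
developmental effect sizes.

## Known limitations

* Spherical conductor and template (ellipsoidal) parcellation; real AAL
  centroids can be supplied but no anatomical registration is performed.
* Binarized occupancy underestimates true burst occupancy near state
  boundaries, attenuating recovered burst-probability modulation by
  roughly 10 % relative; window-occupancy estimates also inherit the
  Markov chain's relaxation lag after regime switches.
* The M50 sign ambiguity described above.
* EM is maximum-likelihood, not Bayesian: no model-order or embedding
  uncertainty is propagated.
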