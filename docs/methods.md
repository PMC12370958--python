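# Methods

## Data model

A session is a frames × 9 nodes × 3 axes array of coordinates in cm at a
fixed sampling rate (default 30 Hz; a 20-min open-field session is 36000
frames and 27 coordinate columns). z is vertical, frames are 0-based, all
frame intervals are half-open `[start, end)`. Eight body segments connect
anatomically adjacent nodes (head = nose→neck, f_body = neck→chest,
h_body = chest→anus, tail = anus→tip, arms = chest→hands, legs =
anus→feet); segment vectors are coordinate differences and therefore
translation-invariant. Pose CSVs with NaN gaps of ≤ 5 frames per
coordinate are repaired by linear interpolation; longer gaps reject the
session — tracking dropouts beyond a sixth of a second cannot be
reconstructed credibly at 30 Hz.

## Motion segmentation

Chest 3D speed (forward difference × fs, first sample duplicated) above
1.5 cm/s marks a frame as moving; a trailing 100-frame window with
strictly more than 80% moving frames is a Moving window; episodes are
maximal unions of overlapping Moving windows. This "union of qualifying
windows" reading is deterministic and parameter-faithful; trailing (not
centred) windows are used. Clips are consecutive non-overlapping
fixed-length windows from the episode start; remainder frames are dropped.
The first episode's interval is measured from session start so the
motion-interval feature is defined for every episode. Episode detection is
property-tested against an exhaustive window-scan oracle.

## Kinematic features (340 per clip)

83 per-frame signals: 27 node speeds (9 nodes × 1D(z)/2D(xy)/3D), 7
angles, 14 pair distances with space tags, 8 absolute angle differences,
27 raw coordinates. Four statistics per signal (min, max, mean, std with
denominator n−1) give 332 columns; the 8 per-episode temporal parameters
(duration, interval, clip count, onset time, chest 2D path length, mean
chest 2D speed, rest ratio interval/(interval+duration), episode ordinal)
broadcast to each clip complete 340. Degenerate angle frames (coincident
nodes) are NaN-masked and excluded from the statistics; a clip whose
signal has fewer than two unmasked frames is dropped with a log entry.
The signal registry is configurable, so an exact published inventory can
be reconciled if one becomes available.

Quantile trimming masks cells outside the per-group [0.01, 0.99] feature
quantiles. The trim levels refer to the full sample — already-masked cells
count toward the trimmed tail mass (half per tail) — which makes the
operation idempotent instead of repeatedly shaving 1% off the remainder.

## Classifiers, APS and attribution

Feature selection: drop near-zero-variance columns, drop the later member
of any pair with |r| > 0.95, rank survivors by mean |TreeSHAP attribution|
of a preliminary gradient-boosted fit, keep the top k. The clip classifier
is XGBoost (library defaults, pinned seed, hist tree method) on k = 30
features with class balancing by seeded downsampling and a stratified 7:3
split; the gait classifier is Extra Trees on k = 20 per-stride features at
6:4. An unseen-animal evaluation mode splits by whole mouse instead of by
clip. Validation metrics stored: accuracy, precision, recall, F1, Cohen's
kappa, MCC.

APS = 100 × (PD-classified clips)/(total clips) per animal; status bins
are half-open: [0,25) NP, [25,75) mild, [75,100] severe. The PD gait score
uses the same proportion over steps.

Attributions are path-dependent TreeSHAP, computed in float64 over the
parsed booster JSON (split decisions replicate the booster's float32
comparisons). Margins are recomputed by direct tree descent — an
independent code path — so the additivity identity base + Σφ = margin is a
genuine check; it holds to ~1e-14 and is asserted below 1e-6. The
library's native float32 contributions serve as an independent
cross-check (agreement to ~1e-5, its output precision) but cannot
themselves meet a 1e-6 additivity contract on strongly-fit models.

## Spectro-temporal operators

Long (120-frame) clips over a pinned registry of core signals (chest/neck
3D velocity and acceleration, tail angle, tip 3D velocity, hands 3D and
feet 2D distance; acceleration = forward difference of speed × fs).

* Ricker CWT at widths 1..9 by direct convolution (`same` length,
  kernel support 10 × width capped at the signal length).
* Wavelet entropy: per-scale energy Eᵢ = Σₜ|W(aᵢ,t)| (the time aggregation
  is the sum of absolute coefficients, matching the common feature-library
  convention), entropy −Σ dᵢ ln dᵢ ≤ ln 9; zero-energy signals score 0.
* Fundamental frequency: mean-removed DFT; peaks are frequencies with
  magnitude > 0.3 × max; return the lowest strictly positive peak; flagged
  NaN when none qualifies.
* Wavelet std at scale 5: sample std (T−1) of the width-5 coefficients.
* PSD bandwidth: Welch with nperseg = signal length (Hann window ⇒ a
  modified periodogram), signal pre-normalised by its std; the lower bound
  is where the bottom-up cumulative power reaches 95% of the total, the
  upper where the top-down cumulative reaches 95%; bandwidth is the
  absolute difference, so a narrowband tone scores ≈ 0 and white noise
  near the Nyquist range. A constant signal scores 0.
* Autocorrelation at zero lag: Σₜxₜ² (unnormalised by design).
* Zero crossings: count of |sgn(xₜ)−sgn(xₜ₋₁)| = 2 with sgn(0) = 0 — a
  count, not a rate.

All operators are verified against brute-force oracles (explicit O(n²)
convolution, explicit DFT sums, direct sums) at 1e-9 on short signals.

## Event analyses

**Turning.** Heading = direction angle of the anus→chest xy vector.
Heading change at lag 2, wrapped to (−180°,180°]; |Δ| ≥ 90° zeroed as
noise; 5-frame trailing rolling mean; frames with smoothed rate
> 0.5°/frame are categorised by sign (+1 left); runs of ≥ 5 frames become
events carrying the maximum cumulative heading change (turning angle), the
time to that peak, and angle/duration. The rate threshold and minimum run
length are package choices tuned to suppress tracking jitter while keeping
slow turns; direction is a label, so the turning feature count is 3.

**Rearing** is annotation-driven (events supply start/peak/end); 11
descriptors: up/down displacement, up/down/total duration, and mean/max/std
of the signed chest vertical velocity in each phase.

**Gait.** A foot strike is a swing end; strides span consecutive strikes
of the same foot; strides overlapping a rearing annotation are excluded.
The 28-descriptor registry covers timing (stride/swing/stance durations,
duty factor, cadence), geometry (stride length, step height, stance width,
feet distances, body length/angle), dynamics (swing speeds, toe-off and
strike speeds, vertical-speed std, drag duration below 0.2 cm), and
coordination (contralateral leg-angle correlation, left–right phase lag,
behind-anus fraction, straightness, stride regularity). The registry is
configurable; stride regularity is the lag-1 autocorrelation of a foot's
stride-duration series, broadcast to its strides.

**Axial bending.** θ = cos⁻¹ of the normalised dot product of the
hindlimb-midpoint→nose and →anus xy vectors; frames with θ < 75° are
flagged; a 60-frame trailing rolling mean ≥ 0.7 marks a bending period,
extended 60 frames backward and segmented into 60-frame clips with mean θ.

**Foot placement.** Hind-foot xy positions mapped into the anus-origin
body frame (+x toward the chest); a 2D histogram plus the percentage of
positions with x < 0 (feet behind the anus — the foot-trailing signature).

## Group statistics and TRE

KDE: Gaussian kernel, Scott bandwidth, 200-point grid spanning the sample
range ± 3 bandwidths. KL divergence D(p‖q) interpolates q onto p's grid
and integrates p ln(p/q) trapezoidally over grid points where both
densities exceed 1e-12 (the floor realises "computed only when both
density estimates are available"). Longitudinal trajectories use six
seeded 150-clip subsamples per week (without replacement when possible)
against the baseline-week KDE.

Task scores: best-two-trial means (shortest latencies for beam walking,
longest for rotarod) as percent of baseline; BWS > 600% is excluded
(failure type II). TSS: a clasping class scores 1 iff ≥ 2 incidences each
> 2 s; TSS = c₁ + 2c₂ + 3c₃ ∈ {0..6}.

TRE: with S(x,y) the Holm–Šidák-corrected Welch significance (family =
all features within one pairwise batch, α = 0.05): unaffected =
¬S(dis,CT) ∧ ¬S(tr,CT); completely treated = S(dis,CT) ∧ ¬S(tr,CT);
untreated = S(dis,CT) ∧ S(tr,CT) ∧ ¬S(tr,dis); partially treated adds
S(tr,dis) and a treated mean strictly between the disease and CT means;
every remaining case (including a treated-only shift without a disease
effect) is treat-associated. The assignment is exhaustive and mutually
exclusive by construction. Zero-variance comparisons yield p = 1.

## Synthetic data generator

The generator is a harmonic-plus-noise model: a body frame on a smoothed
random-walk locomotion path, with limb oscillators attached. Its defaults
are the study conditions every test runs under.

* **Bouts**: alternating rest/move periods; durations ~N(10, 3) s control
  vs N(28, 8) s severe PD (clamped ≥ 6 s); rest intervals N(45, 15) vs
  N(25, 8) s (clamped ≥ 8 s). PD animals move in longer episodes with
  shorter intervals, matching the direction in which motion duration and
  motion interval discriminate PD from control.
* **Locomotion**: per-bout speed N(8, 2) control vs N(4.5, 1.5) cm/s PD;
  heading meanders smoothly with injected 0.8–1.6 s turn segments
  (2–3.5°/frame, ~2/min of movement) so turning events exist everywhere.
* **Stride oscillators**: trot pattern (diagonal limbs in phase,
  left–right anti-phase) at frequency clip(speed/4, 1.5, 3.5) Hz, phase
  jitter 0.2 rad control vs 0.8 rad PD; swing = the foot-forward
  half-cycle of the oscillator phase, recorded as ground-truth swing
  annotations so stride detection has an exact oracle. With probability
  0.3 per stride a severe-PD hind foot trails: no lift, no forward
  oscillation, attachment shifted 0.8 cm backward, and no swing annotation
  (no toe-off).
* **Tremor band**: chest oscillation at 2.8 Hz / 0.15 cm (control) vs
  6.0 Hz / 0.05 cm (severe PD), half propagated to the neck, with a
  fore-aft component of half amplitude so the band appears at its true
  frequency in 3D speed/acceleration (a purely vertical oscillation would
  rectify to 2f there). Residual rest amplitude 0.01 cm keeps resting
  chest speed below the 1.5 cm/s movement threshold.
* **Posture**: body length N(4.2, 0.3) vs N(5.0, 0.3) cm; body angle
  N(150, 8)° vs N(165, 6)°; hand separation N(2.5, 0.4) vs N(1.1, 0.3) cm;
  stance width N(2.8, 0.4) vs N(4.2, 0.5) cm; slow AR-like fluctuations
  (Gaussian-filtered noise, σ = 12–30 frames).
* **Rearing**: Poisson events (1.5/min control, 0.6/min PD) inside bouts,
  3 cm chest excursion with raised-cosine ascent whose peak vertical speed
  is the phenotype parameter (8 vs 3.5 cm/s).
* **Tail**: AR(1) lateral wiggle with lag-1 coefficient 0.6 vs 0.9.
* Coordinate jitter: 0.015 cm Gaussian-filtered noise on every channel.
* All randomness flows from one seeded generator; cohorts derive
  per-session seeds from (seed, group, mouse, week); week effects drift
  PD parameters linearly toward the severe preset (frac = week/10).

What the generator does **not** emulate: arena walls and thigmotaxis,
grooming and other non-locomotor behaviours, tracking outliers and
identity swaps, inter-mouse morphological variation beyond the drawn
parameters, and any correlation structure between features beyond what
the shared body frame induces. Passing tests therefore demonstrate that
the pipeline recovers effects of the planted kind and magnitude, not that
the classifier would reach the same accuracy on in-vivo recordings — the
synthetic phenotypes are deliberately well separated, so held-out
accuracy saturates near 1.0 and APS at 0/100%.

## Problem sizes

Tests and the acceptance script run desk-scale cohorts chosen as the
package's own simulation sizes: 10 mice/group with 6-min sessions for
classifier and direction-recovery checks (~1300 clips), 500-seed
simulations for TRE category recovery (20 features, n = 20/group, 3-sd
effects), 1000 random series for the episode-detection oracle, and one
full 20-min session for the structural dimension checks.

## Numerical choices and edge cases

* Speeds are unsigned; signed vertical velocity appears only in rearing.
* std denominators are n−1 throughout.
* Degenerate body frames (anus ≈ chest in xy within 1e-6 cm) raise in the
  scalar API and map to NaN in the vectorised API; downstream consumers
  skip those frames.
* KL is floored at −1e-9 in invariants to absorb trapezoidal round-off.
* Min-max normalisation maps a constant vector to zeros; log mode applies
  ln(x + 1e-6) before normalising.
* Status-bin ties are half-open as stated (75 → severe).
* xgboost split comparisons are replicated in float32 during attribution
  so leaf assignments match the booster exactly.

## Known limitations

* The published 340-feature inventory and 28-gait-feature table live in
  supplementary material not reproduced here; the pinned registries are
  reconstructions that match every feature named in the main text, and
  both are configurable for exact reconciliation.
* The spectro-temporal table implements the six published operators plus
  the shared statistics over eight core signals (88 columns), not a
  full external feature-library surface (thousands of columns).
* Rearing detection is annotation-driven by design; no automatic detector
  is provided.
* One classifier family per task is implemented (gradient-boosted trees
  for clips, randomised trees for gait) rather than a multi-model AutoML
  sweep; these are the families the analysis ultimately relies on.
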