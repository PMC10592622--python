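# Methods

`spikegait` analyses the relationship between striatal single-unit spiking
and single-limb gait in freely walking mice: it segments strides from
tracked keypoints, quantifies spike coupling to the limb gait cycle with a
resultant-vector statistic against a spike-time jitter null, classifies
whole-body start/stop and speed coding, identifies D1/D2 medium spiny
neurons by optogenetic tagging, and compares groups with a circular
permutation test. Everything is exercised on a synthetic-data generator
with known ground truth.

## Gait model and stride segmentation

The behavioral input is a 2-D pose track of six body parts (four limbs,
nose, tail base) at 80 frames/s, calibrated at 0.3 mm/pixel; the public
contract uses mm, s and degrees throughout.

Pipeline, in order:

1. **Missing data**: NaN keypoints are linearly interpolated across gaps of
   at most 5 frames; longer gaps stay undefined and exclude those frames
   from bouts.
2. **Smoothing**: 3rd-order Savitzky–Golay filter. The window is 7 frames
   (~87 ms) by default: short enough to pass 8 Hz limb oscillations
   essentially unattenuated, long enough to suppress single-frame tracking
   jitter. The order is fixed at 3 (a cubic is reproduced exactly).
3. **Projection**: each limb is projected onto the per-frame nose–tail
   axis, `(limb − tail)·unit(nose − tail)`, so the scalar grows toward the
   nose. The projection is invariant to rigid rotation/translation of the
   scene, which the tests verify.
4. **Band-pass**: 0.5–8 Hz 3rd-order Butterworth applied forward–backward
   (`sosfiltfilt`). Zero-phase filtering matters because stance/swing
   onsets are read off extrema times; a causal filter would bias them.
5. **Walking bouts**: candidate intervals where whole-body speed (centered
   finite difference of the 6-keypoint centroid) exceeds 50 mm/s for at
   least 0.5 s, with sub-0.25 s dips merged. Candidates are auto-accepted
   when a rhythmicity score — the fraction of projected-limb variance
   inside the 0.5–8 Hz band, averaged over the four limbs — reaches 0.5.
   This score replaces frame-by-frame manual curation; a manual override
   map ({bout id: accept/reject}) is still honored and wins over the score.
6. **Strides**: within accepted bouts, stance onsets are troughs and swing
   onsets peaks of the filtered projection. Extrema need a minimum
   separation of half the 8 Hz period and a prominence of 10% of the
   segment SD; consecutive same-type extrema keep the more extreme one.
   Extrema within 0.125 s of a bout edge are discarded: the walking/rest
   transition is a genuine signal discontinuity and distorts zero-phase
   filter output locally (without this margin, a limb whose trough falls
   exactly on the bout edge acquires a spurious 3-frame-short stride).
   Strides are assembled trough→peak→trough; stride length is the
   Euclidean displacement of the (smoothed, unfiltered) limb position
   between the two stance onsets.
7. **Phase**: limb phase runs linearly from 0° at stance onset to 360° at
   the next stance onset and is undefined outside strides. A spike takes
   the phase of the video frame containing it (frame *f* covers
   `[f/80, (f+1)/80)` s), matching the frame-count occupancy
   normalization below.

One labelling caveat: troughs of the nose-ward projection are the limb's
rearmost excursion. We keep the operational convention "trough = stance
onset, phase 0" because every downstream statistic (durations, phases,
coupling) is invariant to which extremum is called stance; only the
semantic stance/swing labels would swap.

## Phase coding

Firing rate vs phase uses 24 bins of 15°: rate(bin) = spikes in frames of
that bin / frames in that bin × 80. Bin centers (7.5°, 22.5°, …) represent
bins in the resultant so that flat tuning gives length 0 without bias. The
mean vector length (0–1) and angle are the normalized resultant of the
binned rates. For a von Mises rate profile with concentration κ under
uniform occupancy the population value is I₁(κ)/I₀(κ) (≈ 0.446 at κ = 1),
which the recovery tests verify by comparison with numerical integration.

Significance uses the spike-time jitter test: 100 iterations, each adding
an independent uniform draw on ±0.5 s to every spike and recomputing the
vector length against the same phase series; jittered spikes that land on
frames without defined phase drop out, exactly as real spikes outside
walking do. A unit is phase coding when its real length strictly exceeds
more than 95% of jittered lengths for at least one limb; per-limb tests
are deliberately not corrected for four limbs, mirroring the
"at least one limb" rule, and this choice is part of the contract. With
100 iterations the exceedance rule has an exact null level of 5/101 ≈ 5%,
which the calibration test confirms empirically.

Units with any vector length above 0.9 are treated as outliers and dropped
from all downstream group analyses. Multi-limb profiles are classified as
none/single/pair-diagonal/pair-other/multi, with LF–RR and LR–RF the
diagonal pairs.

## Start/stop and speed coding

Whole-body motion bouts are runs of speed > 50 mm/s lasting ≥ 0.3 s,
extended backward/forward to the 20 mm/s crossings (ties at threshold
count as above; edge-truncated bouts are flagged and excluded from
event-aligned analyses that need the full baseline). Start/stop coding
compares the mean rate in a −5 to −1 s baseline window against the ±0.5 s
event window with a paired t-test across events (p < 0.05, ≥ 2 usable
events). The modulation index normalizes rates by the baseline mean, bins
the event window at 20 ms, takes the maximum bin of the event-aligned
average (FRevent), and reports |FRevent − 1|; it is invariant to uniform
rescaling of the unit's rate and captures uniform suppression as well as
excitation.

Speed coding bins the whole-session speed (up to the first laser pulse) at
10 mm/s, computes the occupancy-normalized rate per bin, and scores
|Pearson r| between bin rate and bin-center speed. Bins occupied for less
than 1 s are excluded as unstable. Significance shuffles the rate values
across bins (100 iterations; the shuffle permutes bin labels, not frames,
so the bin-level rate distribution is preserved) with the same > 95%
exceedance rule.

## Optogenetic tagging

Three conjunctive criteria on the post-session laser protocol (200 pulses,
10 ms, one per 3 s):

1. a significant excitatory response within 6 ms of pulse onset, after
   removing spikes within 0.6 ms of onset (photoelectric artifacts). The
   test compares per-pulse counts in (0.6 ms, 6 ms] against duration-
   matched pre-pulse windows, one-sided paired t-test at p < 0.05 (a
   Wilcoxon alternative is selectable); the underlying test is not pinned
   down by the criteria themselves, so the choice is configurable.
2. Pearson r > 0.95 between mean evoked and mean baseline waveforms
   (undefined, hence untagged, below 10 evoked spikes);
3. voltage-minimum amplitude ratio < 2, computed symmetrically
   (max(mₑ/m_b, m_b/mₑ) ≥ 1) so the cutoff is direction independent.

Tagged units are labelled D1 or D2 from the session genotype (D1-Cre vs
A2a-Cre).

## Group comparisons

The angular permutation test compares two angle samples by the Euclidean
distance between their mean resultant vectors (unit weight per sample),
against 1000 random reassignments with fixed group sizes; significance
follows the ≥ 95% exceedance rule with Bonferroni adjustment over the
number of comparisons (the four limbs, in the group reports). The reported
p-value uses the (1 + k)/(1 + N) small-sample form so it is never zero;
the significance decision itself uses the exceedance rule. Angular spread
is the angular deviation √(2(1 − R)) in degrees. Vector lengths are
compared both with a group × limb two-way ANOVA on per-limb values
(treating unit × limb entries as observations, the layout used in the
factor-style captions) and with a two-sample t-test on per-unit mean
lengths, which is robust to the within-unit correlation across limbs.

## Synthetic data generator

The generator is the test bed: it emulates a lateral-sequence quadruped
walk with known ground truth, not a rendering of real mouse posture.

* **Gait**: the body translates at a scheduled speed during walking bouts
  (optionally turning at constant curvature) and is stationary between
  them. Each limb's projected position is `anchor − (A/2)·cos(φ)` with φ
  advancing at the stride frequency (default 2.5 strides/s, amplitude
  30 mm peak-to-peak). A sinusoid stands in for the stance-drift/swing-
  return waveform because downstream detection only uses band-passed
  extrema. Default phase offsets LR 0°, LF 185°, RR 175°, RF 10° encode
  left–right alternation within each girdle and near-synchronous diagonals
  (within 10°), reproducing the footfall order LR→LF→RR→RF and the ~180°
  same-side front–rear offset. Per-stride timing jitter (SD 10 ms) and
  per-frame Gaussian position noise (0.3 mm, one pixel) are on by default;
  stride length ground truth is speed/frequency (150 mm/s / 2.5 Hz =
  60 mm).
* **Spikes**: inhomogeneous Poisson with rate
  `max(0, (base + gain·v(t)) · g_phase · g_start)`. The speed term is an
  additive slope — so exact linear speed tuning is representable — while
  phase (von Mises kernel, normalized to mean 1 over the cycle so κ does
  not change the mean rate) and start/stop transients (Gaussian bumps at
  bout boundaries) multiply it; the product is rectified at zero. Rates
  are piecewise constant per video frame, so per-frame Poisson counts with
  uniform placement are an exact simulation.
* **Tagging**: background Poisson spiking continues through a 200-pulse
  protocol appended 5 s after the session; each pulse evokes a spike at
  the set latency with the set probability. Waveform snippets are a
  biphasic template (scaled by `evoked_scale` for evoked spikes) plus
  white noise.

What the generator does **not** emulate: postural variability and body
shape change, turning-specific limb kinematics (the constant-curvature
option makes no fidelity claim for lesioned-animal turning), tracking
outliers/identity swaps, bursting or refractory spike statistics, and
spike-sorting contamination. Passing tests therefore demonstrate that the
estimators recover known parameters under the stated model, not that they
are robust to every pathology of real pose tracking.

## Numerical choices and degenerate inputs

* Zero-occupancy phase bins are NaN and excluded from the resultant; all-
  zero rates give length 0 with undefined angle.
* Zero spikes: jitter test returns not significant; modulation index is
  undefined (NaN) at zero baseline rate; speed coding is undefined below
  3 occupied bins.
* All RNG flows through `numpy.random.Generator` seeds surfaced in every
  API; identical seeds give bit-identical outputs, which the determinism
  tests assert file-for-file.
* Problem sizes in tests and drivers: one ~5-minute session (≈ 24 000
  frames, ≈ 600 strides/limb) for recovery and calibration runs, 200 units
  for null-calibration rates, 500 repetitions for permutation-test
  calibration, 20 units/group for the power check — sizes at which the
  binomial error bars are tight enough for the stated tolerances.

## Known limitations

* The bout rhythmicity score can slightly exceed 1 (filtfilt edge effects
  inflate band variance on short segments); it is used only as a
  threshold.
* The two-way ANOVA layout treats unit × limb entries as independent;
  the per-unit t-test is reported alongside as the conservative view.
* Stride-length ground truth assumes straight walking; under constant-
  curvature turning the chord displacement slightly underestimates arc
  length.
* The start/stop baseline window (−5 to −1 s) overlaps preceding bouts in
  densely scheduled sessions, which dilutes baseline estimates — as it
  does in real open-field data.
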