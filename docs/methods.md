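# Methods

This note documents the models behind `tmteeg`, the parameters that matter,
what the synthetic generator does and does not emulate, and the numerical
choices made where the design was open. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Task and session model

A session follows a block design: each run repeats, four times, the sequence
fixation (10 s) → control (19 s) → fixation → TMT-A (40 s) → fixation →
TMT-B (60 s), closed by a final fixation; two runs give 8 trials per part.
Trigger events mark every phase onset; EEG epochs span −10…42 s (part A) and
−10…62 s (part B) around the TMT onset, the extra 2 s on each side existing
only to absorb wavelet edge artifacts. The first trial of each part is
excluded by default (habituation/learning — the pattern the Kruskal-Wallis /
Dunn-Šidák trial screen in `behav_stats` is designed to detect), leaving 7
analysis trials per part.

## Stimulus layouts

25 circles (radius 28 px, ≥12 px clearance) are placed sequentially on a
1280×1024 px canvas, each item a uniform 90–340 px step from its sequence
predecessor. Sequential bounded steps — rather than a uniform scatter with
arbitrary ordering — reproduce the leg lengths of the standard test sheet
(~200–250 px on this canvas); a uniform scatter would give display-scale legs
and implausibly long links. Trial variants rotate the geometry by 180° and/or
swap number-only against number-letter labels. Both operations preserve all
inter-item distances, so parts A and B built from one base geometry have
identical motor demands; this is what makes the perfect-responder null test
exact (constant-speed metric distributions are *identical* across parts, so
two-sample KS p-values equal 1).

## Behavioral generator

A trial alternates:

- **non-linking pauses**: stylus resting on the current item with Gaussian
  positional jitter (SD 0.15 px per sample — digitizer-scale noise); duration
  log-normal, default median 400 ms, log-SD 0.6 (right-skewed, matching real
  period distributions);
- **links**: straight-line travel under a raised-cosine (Hann) speed bell —
  smooth acceleration to peak at the midpoint, symmetric deceleration. Peak
  speed is log-normal (median 550 px/s, log-SD 0.25), so the link duration is
  2·distance/peak; a 150 ms floor keeps every link scorable.

Part B multiplies link and non-link durations by 1.25 (part-B slowing).
Errors (default rate 0.02/link) link to the skip-ahead item and are corrected
immediately (… 2 → 4 → 3 …), exercising the sequence-based error scoring.
Timestamps are ~40 Hz with ±10 % uniform jitter. Trials truncate at the block
duration; if the cutoff lands inside a link fragment shorter than the 150 ms
scorable minimum, the analyzed trial ends just before that fragment so the
ground-truth link count and the scorable sequence stay consistent.

With these defaults a part-A cohort completes in ~27–30 s with SPL ≈ 1.2 s
and sub-second linking periods — the scale real young-adult data shows.

**What the generator does not emulate:** pen lifts (supported by the
analysis, not generated by default), pressure dynamics, curvature of real
link paths, inter-trial learning trends, and EEG nonstationarities beyond the
condition-locked amplitude model below. Passing recovery tests therefore
demonstrate correctness of the analysis chain under the stated generative
assumptions, not performance on real recordings.

## Kinematic analysis

Speed is the finite difference of position divided by the sample interval,
assigned to midpoint times; pairs spanning a pen lift are set to zero so gap
interiors count as non-linking time. Processing order follows the acquisition
chain: **sigma filter → 5 Hz low-pass → cubic spline → 1000 Hz grid.**

- *Sigma filter*: centered 151 ms window; samples beyond 2 SD of the window
  mean are replaced by the mean of the window's non-outliers (window median
  if none). It targets finite-difference spikes and is idempotent on
  spike-free series.
- *Low-pass*: 4th-order Butterworth at 5 Hz applied forward-backward
  (zero-phase, so interval boundaries are not shifted), treating the jittered
  grid as uniform at the median rate (±10 % jitter changes the effective
  cutoff negligibly).
- *Resampling*: cubic spline onto a 1 ms grid; negative overshoot clipped at
  zero.

**Threshold segmentation** raises a candidate threshold from 0 in 1 px/s
steps; at each step, supra-threshold excursions are counted after merging
gaps < 20 ms and dropping excursions < 50 ms. The accepted threshold is the
smallest whose count equals the known link count **and is stable for 5
consecutive steps** — the automated counterpart of requiring that linking
periods be "readily identifiable": inside the pause-noise band the count
fluctuates step to step and can match the target by coincidence; a stable
plateau only exists above the fastest non-linking excursion. If no stable
plateau exists (rare, truncation-heavy trials) the smallest exact match is
accepted and logged. Link targets are the nearest stimulus within 1.5× the
stimulus radius at each interval end; items crossed mid-link without a
segmentation boundary are ignored; an error does not advance sequence
progress, so the corrective link is scored correct.

**Known bias.** A threshold crossing on a Hann flank trims
`(D/π)·asin(√(threshold/peak))` from each side of a link. Pause *speed* noise
has an irreducible positive mean (it is the magnitude of position jitter per
sample — no linear filter removes its DC), so thresholds land near 20–30 px/s
and recovered linking masks are systematically ~10 % narrower than truth:
link counts are recovered essentially always, while the temporal Jaccard
overlap of the linking mask plateaus near 0.88 under default conditions (the
segmentation-recovery study reports both). At a burst-to-pause ratio of 5 the
same geometry caps the overlap near 0.71 — a property of threshold
segmentation itself, not of this implementation.

## Behavioral statistics

All tests are non-parametric, mirroring heavy-tailed SPL distributions:
one-sample KS against a normal with plug-in mean/SD for normality; Kruskal-
Wallis across trials with Dunn's rank-based pairwise z-tests at a
Šidák-corrected α for the trial screen (a leading trial significantly slower
than ≥4 later trials is flagged for exclusion, and the screen re-runs to
confirm no residual effect); Wilcoxon signed rank on participant means and on
per-participant skewness plus two-sample KS on pooled observations for part
comparisons. Histogram-bin CIs bootstrap **participants** (not trials or
observations, respecting within-participant dependence; 1000 resamples by
default, percentile intervals).

## EEG preprocessing

Recordings (EDF+ or BrainVision; the package writes both formats and reads
them back through MNE) are downsampled to 1000 Hz (polyphase FIR
anti-aliasing), band-passed 0.1–100 Hz with a zero-phase windowed-sinc FIR
(transition widths 0.1 Hz at the low edge, 25 Hz at the high edge — the
narrow low transition implies a ~33 s kernel, hence the long epochs), ICA-
decomposed for artifact removal, re-referenced to the mean of TP9/TP10
(which are then dropped, leaving 30 analysis channels), and epoched.

The artifact step exposes a pluggable scorer interface: any callable mapping
(mixing matrix, source time-courses, channel names) to per-component artifact
probabilities; components scoring > 0.9 are removed. The built-in scorer is a
deliberately simple statistic — the product of a logistic in source kurtosis
(transient-heavy components) and a logistic in frontal topography energy
fraction — sufficient to remove the generator's stereotyped blink transients
(frontal RMS drops > 50 % in the test); classification of real artifact
taxonomies is out of scope and would be supplied by the user through the same
interface. With no scorer the step is the identity.

## Time-frequency analysis

20 Morlet wavelets at `f_i = 0.1·500^(i/19)` Hz, i = 0…19 (geometric,
anchored exactly at 0.1 and 50 Hz; adjacent ratio 500^(1/19) ≈ 1.387), all
with 6 cycles (σ_t = 6/(2πf)). Convolution is frequency-domain multiplication
with analytically evaluated unit-energy Morlet spectra (O(n log n), scale-
comparable across frequencies); 2 s is trimmed from each epoch end. Power is
normalized as `10·log10(P / mean baseline P)` per channel and frequency, with
the baseline the −8…−1 s fixation window (avoiding its own edge artifacts).

Band assignment: delta 0.3–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–50 Hz by interval membership; for each interior boundary (4, 8, 13, 30 Hz)
the single nearest wavelet joins both adjacent bands (ties resolved toward
the lower frequency), giving exactly four dual wavelets. The four wavelets
below 0.3 Hz are computed but feed no band (their ≥6-cycle support also
exceeds the epochs, so their power is only partially valid — a logged
warning). Features are means of the dB field over (period mask × band
wavelets), then over trials, yielding one value per participant × condition
(LinkA/LinkB/NonlinkA/NonlinkB) × electrode (30) × band (5); masks are
half-open intervals at 1 ms resolution, and samples after the completion time
belong to no period.

**Wavelet leakage and the recovery study.** The power time-course is smoothed
by the squared wavelet envelope (Gaussian, SD σ_t/√2 ≈ 50–100 ms in alpha),
so mask-averaged dB differences are biased toward zero by boundary leakage:
at TMT-realistic sub-second periods a true −6 dB linking effect measures
≈ −4.5 to −5 dB. The recovery study therefore uses the documented
`steady_state_params()` preset (log-normal link durations, median 3 s;
non-link median 2.5 s), where leakage costs only ~0.2–0.3 dB and the analytic
value 20·log10(0.5) = −6.02 dB is the meaningful truth; the acceptance run
recovers ≈ −5.7 dB over 16 simulated participants. The EEG generator's
oscillators are band-limited Gaussian noise (e.g. 8–13 Hz for alpha) rather
than pure sinusoids, because a rhythm whose amplitude is halved occupies a
band: a single spectral line would drive only the nearest wavelet and dilute
the band-averaged effect.

## Task PLS

X stacks the feature table condition-major (row = participant within
condition; column = electrode-major, band-minor feature; 64 × 150 for the
full design) and is column-mean-centered, making `E = XᵀY` proportional to
condition-mean deviations — the standard task-PLS formulation. SVD of E gives
latent variables; variance explained is `sᵢ²/Σs²` (the `s` convention is a
configuration point; squared singular values are used).

- **Permutation test**: condition labels are shuffled within participant
  (respecting the repeated-measures structure); `p = (1 + #{s* ≥ s}) /
  (n_perm + 1)`, 1000 permutations by default, exhaustive enumeration when
  the design admits fewer distinct permutations than requested.
- **Bootstrap**: participants are resampled with replacement, all their
  condition rows together; each resample's X is re-centered and decomposed,
  and each LV is sign-aligned to the observed solution (sign of the combined
  dot product of spatial and task saliences) before accumulation — without
  alignment the SVD sign ambiguity inflates the SD. BSR = bootstrap mean /
  SD; a zero SD yields a signed-infinity sentinel excluded from maps. No
  Procrustes rotation is applied beyond the sign flip; with the dominant
  single LV these analyses target, axis swapping is not a practical concern.
- **Contrast saliences**: for each condition pair, the bootstrap distribution
  of paired task-salience differences (mean, SD, BSR). The paired-difference
  reading is implemented; differencing against permuted resamples would
  estimate a null-referenced contrast instead and is noted as the
  alternative.
- **Thresholded maps**: two-tailed p from the standard-normal approximation
  of the BSR, Benjamini-Hochberg across all 150 electrode × band saliences of
  the LV jointly, plus |BSR| > 2; entries failing either are zero.
- **Subtests**: any condition pair, or Link(A+B) vs Nonlink(A+B) with dB
  features summed across parts before assembly. In two-condition designs the
  LV p-value and variance explained are fixed by construction and therefore
  suppressed.

## Validation studies and problem sizes

Each study in `tmteeg.validation` is deterministic given its seed; the same
functions back `tests/test_acceptance.py` and `scripts/acceptance.py`.

| study | size | checks |
|---|---|---|
| matrix assembly | 16 participants × 4 conditions | X is 64 × 150, Y has 4 columns |
| segmentation recovery | 16 × 7 part-A trials | exact link counts (≥95 %); mask Jaccard (reported; ~0.88 under default noise, see bias note) |
| part-B direction | 50 cohort replicates, 16 × 7 × 2 parts | SPL, linking, non-linking all larger in B, signed-rank p < 0.05, in ≥90 % of replicates |
| perfect responder | 16 constant-speed participants | between-part KS non-significant for every metric (exactly p = 1 by construction) |
| alpha recovery | 16 participants, 2 trials, 4 active channels, steady-state preset | Link − Nonlink alpha feature −6.0 ± 0.7 dB |
| PLS recovery | 16 participants, −3 dB at 10 electrodes (delta+theta), 1000 perms/boots | LV1 p < 0.05; ≥8/10 electrodes in the map, consistent sign |
| null calibration | 20 replicates, 250 resamples | nonzero map fraction ≤ 0.07; LV1 p uniform |

The reduced trial/channel counts in the alpha-recovery study and the reduced
resampling in the null study keep each study a one-to-two-minute computation;
the recovered quantities are means over participants or replicates and are
insensitive to those counts.

## Known limitations

- Threshold segmentation's boundary trim (above) biases linking masks narrow;
  any mask-based EEG feature inherits a small dilution of period contrasts at
  sub-second periods.
- The default artifact scorer handles stereotyped frontal transients only.
- The generator's EEG is stationary 1/f plus condition-gated oscillators; no
  forward head model, no muscle/EMG artifacts, no electrode drift.
- Layouts are generated, not replicas of the standard published sheet, whose
  exact coordinates are not reproduced here; variants preserve distances, as
  in the real design.
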