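# Methods

This note documents the models and procedures implemented in
`mindmetrics`, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was open.

## Study design being modeled

Each subject contributes calibration recordings — breath-count
(protocol length 30 min) and 1-back/3-back recall (21 min each) — and a
novel threat-detection task with per-trial accuracy and reaction time.
Breath-count anchors the *low* state for both fatigue and stress; the
3-back anchors the *high* state.  Two readings of the same recordings
differ on purpose: for **fatigue** only the latter half of the 3-back is
labeled high (fatigue accrues with time on task), while for **stress**
the whole 3-back is high (stress follows cognitive load on a fast time
scale).  **Attention** labels come only from breath-count button presses
marking self-caught mind-wandering: 6 s windows from 8–2 s before a
press are inattentive, 2–8 s after are attentive; an attentive window
that overlaps any other event's inattentive window is relabeled
inattentive; subjects with fewer than three usable events are excluded
from the attention analysis.

## Signal processing

* **Basic filters.** 59–61 Hz band-stop, 0.1 Hz high-pass, DC removal,
  average re-reference over retained EEG channels only.  Both filters
  are applied spectrally (zero-phase by construction).  A time-domain
  IIR high-pass with a 0.1 Hz corner at 250–500 Hz sampling is
  numerically fragile — the poles sit within ~2·10⁻⁶ of the unit circle
  and filtfilt error reached 0.7 RMS on a pure tone in our checks — so
  the high-pass is a raised-cosine roll-off from 0.05 to 0.1 Hz applied
  to the rFFT, and the notch nulls the 59–61 Hz bins exactly.
* **Channel rejection.** A channel is flagged iff its total 1–250 Hz
  periodogram power (capped at Nyquist), divided by the across-channel
  median and log-transformed, exceeds mean + 3 SD across EEG channels;
  single pass.  Note the arithmetic bound: the largest achievable
  z-score among *n* channels is √(n−1), so with fewer than ~11 channels
  no outlier can be flagged — the rule presumes a dense montage.
* **ICA artifact loop.** FastICA on the retained EEG channels with one
  component per channel, capped at the numerical rank of the data
  (average re-referencing removes one dimension; whitening a
  zero-variance direction makes the unmixing blow up).  Components are
  ranked by their maximum |Pearson r| against any nuisance lead (EOG,
  ECG, accelerometer if present).  Visiting components in rank order,
  a component stays on the noise list iff removing it changes the
  quality index by ≤ −0.001 (lower = better); the loop stops when all
  components have been tried or only 25% remain unrejected.  The quality
  index is a pluggable contract; the default proxy scores the fraction
  of spectral power in 59–61 Hz plus everything above 100 Hz.
* **Interpolation and drift.** Flagged channels are rebuilt by
  spherical-spline interpolation on the standard 10–20 montage
  (inverse-distance weighting when fewer than three retained neighbors
  exist); then every channel has its centered moving average subtracted
  (1000 samples EEG, 50 samples ECG), with edge shrinkage.

## Features

**EEG band power** is the contribution of the DFT bins inside a band to
the window's mean-square signal power: a tone of amplitude A contributes
A²/2, and band powers over a partition of [0, Nyquist] sum to the window
variance exactly (rectangular taper).  The default taper is Hann with
power normalization; features are log₁₀(power + 10⁻¹²) and z-scored with
training-set statistics before fitting (raw mode available) — raw powers
are heavy-tailed and destabilize IRLS.  Bands: δ 1–3, θ 4–8, α 8–12,
β 13–30, γ 30–50, high-γ 50–100 Hz.  Training bins are 10 s
non-overlapping (6 s for attention); test windows slide at a 1 s stride
and are stamped at their centers.

**HRV features.** R-peaks are detected with a band-pass (5–30 Hz),
squared-derivative, adaptive-threshold detector; sub-physiological
intervals (< 0.3 s) are merged and long gaps (> 2 s) flagged.  The RR
tachogram is resampled to 4 Hz with a cubic spline — linear
interpolation's triangular kernel acts as a sinc² low-pass that
depresses HF power by ~30% at ~65 bpm — detrended, and its periodogram
integrated over VLF/LF/HF (or 0.1 Hz bins over 0.01–0.4 Hz).  Because
VLF is unresolvable inside a 10 s bin, each bin receives features from a
120 s context window centered on it.  The context keeps its full length
near the recording edges by sliding inside the recording rather than
shrinking: shrinking changes spectral resolution systematically along
the trace and injected a spurious time effect into held-out traces on
short recordings.

## Models

Per electrode, a binomial GLM with logit link is fitted by IRLS;
convergence at max |Δβ| < 10⁻⁸ within 100 iterations.  A ridge penalty
of 10⁻⁴ on the slopes (never the intercept) keeps separable training
sets finite while moving non-degenerate fits by far less than the fold
scatter.  Wald p-values come from the penalized information matrix.
Committees average member probabilities; ECG-only sets (Ps1, Ps2) have a
single member.  For Ps4 the three HRV band features are appended to
every electrode's six EEG band features (9 columns per member); the
alternative — HRV as an extra committee member — is available by
configuration.  Label polarity: the trace reads "probability of the high
state" (attentive = 1 for attention); a configuration flag flips it.

## Validation

* **Level 1.** Balanced k-fold CV (k = 10; k = 3 for attention, whose
  event counts are small): each fold holds an equal number of windows
  per class, surplus rows are discarded with a seeded RNG, each channel
  is scored independently at threshold 0.5 and the subject accuracy is
  the mean over channels and folds.
* **Level 2.** Leave-one-out committee scores on the training windows
  give low/high bounds; the mean trace value on the held-out 1-back is
  the intermediate score.  Two paired t-tests across subjects
  (one-tailed by default, the hypotheses being directional; two-tailed
  exposed) check low < intermediate < high at 0.025 each (two
  comparisons).  A one-way repeated-measures ANOVA over five equal time
  bins of the held-out trace probes for a time-on-task effect —
  expected for fatigue (ramping latent), absent for stress (flat
  latent).
* **Level 3.** Biometric traces are averaged over each trial's 2 s
  extent; accuracy and reaction time are smoothed with trailing moving
  averages of 1–10 trials; the Pearson correlation of the aligned series
  is referred to a null built from 3,000 shuffles of the *raw* per-trial
  performance, re-smoothed after each shuffle so the null respects the
  smoothing-induced autocorrelation.  p = (1 + #{|r₀| ≥ |r|})/3001,
  two-sided (reported effects go both ways across subjects).  A subject
  counts 1 if significant for both threat types (recorded on separate
  days), 0.5 for one, 0 for neither.  Shuffling the biometric instead of
  the performance gives the same null only when both series are
  exchangeable; with an autocorrelated biometric the roles are not
  symmetric, which is why performance is the shuffled quantity.

## Synthetic data

Each EEG channel is a sum of band-limited Gaussian-noise carriers (one
per band, fourth-order Butterworth band-pass, unit RMS) whose
instantaneous amplitude is baseline × (1 + Σ effect × latent), plus a
1/f background (exponent 1.0).  The signed effect table follows the
directions the committee models are expected to recover: fatigue —
frontal γ up, fronto-central α down; stress — θ up pre-frontally,
centrally and centro-parietally, frontal γ up, fronto-central δ, frontal
β and widespread α down; mind-wandering — θ/δ up and α/β down globally.
Two normalization details matter for honest nulls: the 1/f background is
scaled by its *expected* (not realized) RMS, and per-channel baseline
jitter (10%) is keyed by subject and channel, never by task — otherwise
every recording carries a private gain signature and "uninformative"
features classify tasks well above chance.

Latents: fatigue ramps linearly to a task-specific cap (0.15
breath-count, 0.6 1-back, 1.0 3-back); stress steps at task onset to
0.1/0.5/0.9 for breath-count/1-back/3-back (ordering strict by
construction); attention alternates attentive runs (mean 60 s) with
mind-wandering bouts (mean 20 s, minimum 4 s) only during breath-count,
with a button press at each bout's end.  No published bout statistics
exist; these values yield ≥ 3 events in most 5 min sessions while
keeping bouts long enough to label.

ECG: beat times integrate RR(t) = RR₀ + a_LF sin(2π·0.1t + φ) +
a_HF sin(2π·0.3t + ψ) + jitter, with a_LF rising and a_HF falling in the
stress latent; the waveform is a Mexican-hat QRS template train plus
noise, and true beat times are always exported.  Behavior: per-trial
correctness is Bernoulli(σ(b₀ + b·latents)) and reaction time r₀ +
r·latents + Gaussian noise truncated to (0, 2] s; a null mode zeroes the
couplings.  Default couplings put the trial-level biometric–RT
correlation near 0.5 at 200 trials.

What the generator does **not** emulate: dipolar scalp topographies
(carriers are independent across channels), realistic ECG morphology
(P/T waves), EOG beyond blink transients, learning effects in the novel
task, and non-stationarities other than the modeled latents.  Passing
recovery tests therefore demonstrates that the pipeline's inference is
correct under its own assumptions — not that real 32-channel recordings
will reach the same accuracies.

## Problem sizes and scaled defaults

Tests and the results-reproduction script run desk-scale versions of the
experiments: 5 min sessions at 250 Hz over the five frontal electrodes
(synthesis and leave-one-out fitting dominate the cost and scale
linearly in channels × duration), 10-subject regression cohorts, 200
null sessions and 50 power seeds at the full 3,000 permutation
iterations.  Full-length protocol sessions (30/21/21 min, 500 Hz, 29
channels) remain available through `PipelineConfig`; every numeric
protocol constant (band tables, window lengths, k, −0.001 SQI threshold,
25% IC floor, 1000/50-sample drift windows, 3,000 iterations) is the
config default, and any deviation is logged.

## Known limitations

* The true signal-quality index of the original preprocessing chain is
  not reproducible from public sources; the default proxy follows the
  stated sign convention (decrease = quality increase) but is a
  different quantity.  The IC loop accepts any user-supplied index.
* With a single recording per class, within-subject CV can learn
  per-recording gain offsets; the generator minimizes these by
  construction, but on real data the fatigue design (latter-half
  labeling) retains a mild optimistic bias of this kind.
* Attention models are data-starved by design (few mind-wandering
  events per subject); with scaled 5 min sessions the attention CV often
  cannot run at k = 3 and is reported as excluded, mirroring the
  exclusion rule.
* The ±0.15 slope-recovery tolerance, CV bands and permutation
  calibration bands used in the tests are Monte-Carlo tolerances at the
  stated problem sizes, not instrument specifications.
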