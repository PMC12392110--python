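# Methods

This note documents the models, conventions and numerical choices behind
`sleseg`, in the spirit of a methods appendix: what is computed, under which
assumptions, and where the genuinely open design decisions were made.

## Signal and event model

A recording is a single-channel LFP trace sampled at 2,000 Hz and low-pass
filtered at 30 Hz by the acquisition chain. Seizure-like events (SLEs) are
defined operationally: repetitive, similar-morphology spiking lasting at
least 0.2 s, separated from neighbouring events by at least 0.1 s. Events
are stored as half-open, 0-based sample intervals `[onset, offset)`, which
makes durations and concatenations exact integer arithmetic; a per-sample
binary label series at the 125-Hz analysis rate is the dual representation.

## Synthetic generator

The generator (`sleseg.synth`) emulates disinhibition-model recordings well
enough to exercise every downstream stage against known ground truth:

* **Event process.** Onsets follow a renewal process: each inter-event gap is
  `min_gap_s + Exp(θ)` and each duration is lognormal (mean 2.0 s, CV 0.5,
  resampled below the 0.2-s floor). θ is solved so that the mean cycle
  length matches the configured rate (default 12 events/min, the event rate
  typical of 4-AP-based disinhibition); infeasible combinations (rate too
  high for the mean duration plus gap) raise a configuration error. By the
  elementary renewal theorem the expected event count is
  `duration_s · rate/60`, which the tests verify by Monte Carlo.
* **Intra-event spiking.** Troughs recur near-rhythmically at 10 Hz with
  lognormal inter-spike intervals (CV 0.05) and lognormal amplitude jitter
  (CV 0.2) around a default amplitude of 8 (in units of the baseline noise
  SD), so events are "almost rhythmic" rather than metronomic and the
  strict-minimum spike detector is exercised realistically. Each spike is a
  negative-Gaussian kernel (scale 0.02 s) whose trough is the unique strict
  minimum of the snippet.
* **Baseline and band limit.** Spike content and Gaussian baseline noise are
  filtered with a zero-phase 6th-order Butterworth low-pass at 30 Hz
  (matching the acquisition filter); the noise is rescaled to unit SD after
  filtering. Optional 50-Hz mains hum is added *after* the low-pass, since
  contamination physically enters downstream of the filter. For default
  configurations less than 1 % of total power lies above 30 Hz.
* **Interictal spikes.** Isolated, slightly wider kernels (scale 0.03 s,
  amplitude 6) are stamped at 2/min outside events, providing the
  false-positive class that the 0.1-s drop rule targets.
* **Treatment effects and cohorts.** A treatment is a multiplicative triple
  on (duration, spike frequency, rate); (1, 1, 1) is the identity. Cohorts
  are groups × animals × slices (2–6 slices per animal). All randomness
  flows from one seed through `SeedSequence` spawn keys; by default matched
  (animal, slice) positions share streams across groups (common random
  numbers), so an identity treatment reproduces the control recordings bit
  for bit and effect-recovery contrasts are variance-reduced. Set
  `paired_seeds=False` for fully independent groups (e.g. null simulations
  of the statistical layer).

What the generator does **not** model: biophysical network dynamics, the two
bath-solution chemistries, electrode drift, multi-channel montages, or the
amplitude statistics of any particular rig. No published amplitude/SNR
figures exist for the recordings this emulates, so the default SNR was
chosen once to make detection non-trivial rather than to match real traces;
passing tests demonstrate correctness of the pipeline's logic and
calibration on this family of signals, not detector performance on real
tissue.

## Detector

The classifier maps a standardized 30-s, 125-Hz segment to per-sample SLE
probabilities. Architecture (`sleseg.nn`): an input 1×1 convolution to C
channels; N residual blocks of kernel-2 dilated convolutions with gated
activation (tanh × sigmoid), per-block 1×1 residual and skip projections;
summed skips pass through a relu head to one logit per sample. Class
defaults are N = 10, C = 32, dilations 1…512 (receptive field 1,024 samples
≈ 8.2 s, ~10⁵ parameters). Padding is symmetric by default — alternate
blocks look backwards and forwards, legitimate because segmentation is
offline — with a causal mode retained for fidelity to the architecture's
ancestry. The network, binary cross-entropy loss and Adam optimizer are
implemented directly on NumPy arrays in float32; backpropagation is
hand-derived and verified against numerical differentiation.

Training conventions:

* per-segment standardization (population SD; constant segments map to
  zeros with a logged warning rather than aborting),
* dataset duplication with sign inversion (field-potential polarity is
  montage-dependent),
* four-way augmentation in exactly equal quarters (largest-remainder
  rounding over a seeded permutation): unchanged / weak 50-Hz tone plus
  Gaussian noise (50 Hz is below the 62.5-Hz Nyquist of the label rate, so
  the hum is injected at 125 Hz directly) / one contiguous 5-s Gaussian
  burst per 30-s segment / pointwise Gaussian replacement of a random 10 %
  of samples. Targets are never altered.
* a greedy, deterministic recording-exclusive split stratified by treatment
  status and balanced on total SLE duration,
* plateau schedule: "improvement" means any increase of the *corrected*
  validation accuracy (per-sample agreement after the rule-based
  correction) over the best so far; after more than 2 epochs without
  improvement the learning rate is divided by 10. Best-epoch weights are
  retained.

Desk-scale problem sizes: the tests train an 8-block, 16-channel variant
(receptive field 256 samples ≈ 2 s) for 12 epochs on ~60 min of synthetic
signal with ~20 min held out, reaching corrected validation accuracy ≈ 0.99
in about a minute per run; the class defaults above remain the recommended
configuration for full-size datasets.

## Post-processing

Probability series are corrected in a fixed order: binarize (label positive
at probability ≥ 0.5; the threshold is a declared default, not a measured
constant), convert maximal runs to events, drop events strictly shorter
than 0.1 s, merge events whose gap is strictly below 0.2 s (transitively),
then snap each offset to just past the last strict interior extremum of the
event's waveform (neighbourhood 1; onsets never move; events without an
interior extremum are unchanged). Applying drop before merge is
deliberate: merging first would let sub-0.1-s fragments bridge gaps and
changes results. Corrected accuracy is computed per sample over whole
recordings at 125 Hz.

## Metrics

Per analysis unit: fraction = Σ durations / analyzed time; rate = count /
minutes; mean duration = Σ durations / count (missing, not zero, when there
are no events); spike frequency = pooled spike count / pooled event time.
Pooling (rather than averaging per-event frequencies) is robust for very
short events; this is a declared convention. Spike troughs are strict local
minima within ±0.165 s, evaluated on the 2,000-Hz trace (the window is
specified in seconds and trough timing benefits from full resolution; the
rate is configurable). Because 0.165 s exceeds the ~0.1-s intra-event
inter-spike interval, shallower alternate troughs are suppressed by the
rule itself; the implementation reproduces the stated rule rather than
"fixing" it, and between-group comparisons are unaffected. Out-of-range
window comparisons clamp to the boundary sample, so the first/last samples
of a recording are never troughs.

Pauses are maximal event-free intervals strictly longer than 120 s;
leading and trailing gaps count (edge handling is a declared convention).
Animal-level aggregation pools events, event time, spikes and analyzed time
across a given animal's slices within a group and recomputes the metrics,
which equals time-weighted averaging and is invariant to slice order.

## Spectra

Each whole (final-40-min) recording yields one periodogram (Hann window,
density scaling). Ordinates at f ≤ 0 or f > 30 Hz are removed; the rest are
divided by their in-band total, then summed into 150 right-closed 0.2-Hz
bins (0, 0.2], …, (29.8, 30] — summing, not averaging, so normalized bins
still total 1 (a per-bin scale convention; normalized totals are
unaffected). Confidence bands use the percentile bootstrap (10⁴ resamples,
95 %) of the across-recording mean per bin, each recording being one
resampling unit; BCa refinements were considered unnecessary for a band
that is read qualitatively. Peak detection reports strict local maxima over
bins (edge bins count when they exceed their single neighbour).

In simulated control recordings the binned spectrum reproduces the two
features expected of untreated disinhibition recordings: the
event-recurrence peak below 1 Hz and the intra-event spike peak within one
bin of 10 Hz.

## Statistics

Fisher's exact test (two-sided, probability method) with the sample odds
ratio ad/bc (infinite when bc = 0); the test suite checks it against exact
rational hypergeometric enumeration. Kruskal–Wallis uses the tie-corrected H
with the chi-squared approximation by default; an exact permutation method
(`method="exact"`) enumerates the null for very small samples, where the
chi-squared approximation is known to be inaccurate — the degenerate
all-equal case is defined as H = 0, p = 1. Dunn's post hoc z-statistics come
from pooled ranks with tie correction; p-values are two-sided; the
Holm–Bonferroni step-down is applied over an explicitly named family of
pairs, because which contrasts form a family is an analysis decision that
should not be implicit.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives all
stage seeds from one global seed. Rule-based stages are bit-reproducible;
training is reproducible bit-for-bit on the same BLAS build and within
float32 round-off otherwise. The results bundle is self-describing:
re-running the statistics stage on a bundle's metric CSVs reproduces its
stats CSV byte-for-byte.

## Known limitations

* EDF export quantizes to 16 bits of the physical range (inherent to the
  format); round-trips are exact only to that resolution.
* The generator's event envelope is rectangular (no waxing/waning amplitude
  within an event), which slightly flatters boundary placement relative to
  real recordings.
* The strict-window spike rule undercounts intra-event spikes at ~10-Hz
  spacing (see above); absolute spike frequencies are therefore
  convention-dependent, ratios between groups are not.
* Slice-within-animal nesting is addressed only by the pooled animal-level
  re-analysis, not by mixed-effects modelling.
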