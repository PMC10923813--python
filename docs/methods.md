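# Methods

This note documents the models and procedures implemented in `dialogtrf`,
the parameters that matter, the synthetic benchmark's assumptions, and the
numerical choices made where the design was genuinely open. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## The encoding model

EEG channel *c* at frame *t* (128 Hz) is modeled as a linear functional of
the preceding 600 ms of a stimulus feature stream:

    y_c(t) = Σ_f Σ_{l=1}^{77} w_c(f, l) x_f(t − l) + ε_c(t)

The contemporaneous sample (lag 0) is excluded — it approximates the ~3 ms
acoustic travel time from mouth to ear — so the lag axis is 1..77 samples
(7.8125–601.6 ms). One feature (envelope) gives 77 design columns; the
16-band mel spectrogram gives 77 × 16 = 1232. The weight tensor w_c,
reshaped to (feature × lag), is the multivariate temporal response function
(mTRF) and is interpreted like an evoked response to continuous speech: a
linear-systems estimate of the EEG deflection caused by a unit feature
impulse, valid only where the model has verified predictive power.

**Estimation.** Ridge regression per channel,
ŵ = argmin ‖y − Xw‖² + α‖w‖², with the intercept handled by centering X
columns and y on the training split. The solver eigendecomposes the
centered Gram matrix XᵀX once and reuses it: (a) all α values on the
selection grid are then one rescaling each, and (b) the sample-permutation
null (below) costs one matrix–vector product per surrogate, because
permuting whole rows of X leaves XᵀX and the column means invariant.
Stimulus feature streams are non-negative and strongly autocorrelated, so
the design is highly collinear; regularization is not optional here.

**Cross-validation.** Contiguous, unshuffled 5-fold CV over the valid
samples. Per fold, α is selected per channel on the training split by inner
contiguous 3-fold CV over a log-spaced grid 10⁻²…10⁶ (13 points),
maximizing the mean held-out Pearson r; ties resolve to the smallest α.
mTRFs are averaged over folds first, then (in group analyses) over
participants. Performance is the Pearson correlation between predicted and
recorded EEG on each held-out fold, fold-averaged per channel.

A property of the correlation-maximizing selector worth knowing: when the
target is pure noise, the selected α is close to uniformly distributed over
the grid (slightly favoring small values, whose held-out scores are nearly
independent draws while large-α scores are nearly identical). This is
harmless downstream — for null channels r is chance-level at every α, and
the permutation test holds α fixed anyway — but it means the selector
should not be read as a noise detector.

**No future leakage.** Design rows use only frames ≤ t; tests verify that
perturbing any frame after the last sample leaves designs, fits and
predictions bit-identical.

## Dialog conditions and training samples

An inter-pausal unit (IPU) is a maximal single-speaker speech segment
bounded by pauses longer than 100 ms; annotated bursts with gaps ≤ 100 ms
(with a 1 ns float tolerance) are merged. Intervals are half-open
[start, end) seconds; frame t covers [t/fs, (t+1)/fs) and counts as speech
when its midpoint lies inside an IPU — an unambiguous rasterization the
source annotations do not prescribe.

Each frame gets exactly one condition from one participant's perspective:
S (only self speaks), E (only the partner), B (both), Silence (neither).
Valid training samples for a condition are all frames t whose trailing
window [t − 76, t] carries that condition (overlapped sliding windows, step
one frame) — at least 600 ms of uninterrupted condition context. Frames
earlier than 77 (which cannot carry a full lag window) are excluded.
B-frames are analyzed from both perspectives: E|B drives the model with the
partner's microphone features, S|B with one's own.

## Significance of the encoding models

Per channel and fold, 3000 surrogate models (configurable; desk-scale runs
use 200) are fitted to row-permuted training designs — each row keeps its
internal 600 ms lag structure — with the originally selected α, and predict
the untouched test set. The p-value uses the add-one rule
p = (N_exceed + 1)/(N_perm + 1) with strict exceedance, so p ∈
[1/(N_perm+1), 1] and can never be 0. A channel is significant for a
subject only when p clears the threshold in **all** folds. On a full
128-channel montage the threshold is Bonferroni 0.05/128 = 3.90625 × 10⁻⁴
(note 1/3001 = 3.33 × 10⁻⁴ is just below it — 3000 permutations is the
minimum that makes the corrected decision reachable). At desk scale
(n_perm = 200, 4–16 channels) the corrected threshold sits below the
permutation floor, so the pipeline's default decision rule is the
uncorrected per-channel 0.05 in all folds; the correction is a config
switch (`significance_correction`).

## Group statistics

Paired per-channel comparisons between conditions use the exact
(enumerative) two-sided Wilcoxon signed-rank test (exact for n ≤ 25;
e.g. 12 uniformly positive differences give p = 2/2¹² ≈ 4.9 × 10⁻⁴).
Effect size is paired Cohen's d = mean(diff)/SD(diff) with the sample SD
(ddof = 1). Bayes factors are JZS paired-t with Cauchy prior scale √2/2,
reported as log₁₀ and binned: > 0 positive, > 0.5 substantial, > 2 decisive
evidence. The exact Bayes-factor recipe behind the published analyses is
not recorded anywhere accessible; the JZS paired-t default is this
package's stand-in and is labeled as such.

Hemispheric lateralization compares 12 frontal channels per hemisphere;
since montage halves have no anatomical 1:1 pairing, values are sorted
within hemisphere and paired by rank before the exact signed-rank test —
a package decision, recorded here.

TFCE cluster inference over the (feature × lag) mTRF plane uses the
one-sample sign-flip permutation test with threshold-free cluster
enhancement (start 0, step 0.2, E = 0.5, H = 2, lattice adjacency,
4096 permutations by default, capped at the 2^N exhaustive bound), scored
against the permutation distribution of the maximum enhanced statistic.
BH-FDR step-up adjustment is available as the less conservative
alternative to Bonferroni.

## Phase locking

|PLV(τ)| = |mean_t exp(i(θ_env(t−τ) − θ_eeg(t)))| with phases from the
Hilbert transform of both series band-passed 4–8 Hz with the identical
zero-phase FIR design, so PLV latencies are not filter-shifted. Positive τ
delays the envelope — the brain following the audio; negative τ would
require the EEG to precede the stimulus. The sign convention is fixed by
the delayed-copy identity: an EEG channel that is the envelope delayed by
125 ms must peak at τ = +125 ms.

The lag grid steps one sample (7.8125 ms) and additionally contains the
exact interval endpoints −200 and 400 ms. Since those are not integer
sample shifts, lags are applied as FFT phase rotations of the band-limited
analytic signal, which is exact for any real shift and reduces to `roll`
for integer shifts. All samples of a dialog condition are pooled as one
single trial; samples within 0.25 s (one period of the band's low edge) of
a segment boundary are dropped to limit filter edge transients — the
precise guard width is a package decision.

## EEG preprocessing

Band filters are window-method FIR (hamming), minimum-phase causal by
default — no output before input onset, at the price of a small group
delay that shifts apparent mTRF latencies by a few tens of ms — or
zero-phase for latency-faithful analyses (the PLV path always uses
zero-phase). Transition bandwidths are 25% of the band's lower edge,
floored at 0.1 Hz so the broad band stays realizable on minute-scale
recordings; edges are padded with edge values. Downsampling applies an
anti-alias FIR low-pass before integer sub-sampling (plain decimation would
alias; the choice is recorded as a package decision), then z-scores each
channel (population convention, exact mean 0 / SD 1). Band filtering runs
at the native rate before decimation. Average re-referencing subtracts the
instantaneous electrode mean. Component-based artifact removal is a
pass-through hook: it requires expert supervision on real recordings and
has no synthetic counterpart.

## The synthetic dialog generator

The generator is this package's own construction — the analyses it
validates were designed for recorded dialog, and no generative model of
such data exists — so every choice below is an artifact decision.

**Turn-taking.** Speakers alternate; turn and pause lengths are exponential
(memoryless) with means 1.5 s and 0.5 s plus a 0.3 s turn floor, matching
the scale of task-oriented dialog turns. With probability 0.2 a turn onset
overlaps the previous speaker's turn (overlap mean 0.4 s), producing
Both-speaking intervals; same-speaker gaps are kept above the 100 ms IPU
rule. Defaults give roughly balanced S/E time with a few percent overlap.

**Features.** 16 "mel-like" band streams at 128 Hz: a shared syllabic-rate
modulator (smoothed rectified noise, < ~6 Hz) scaled by per-band gains and
slow band-specific fluctuations — band-correlated like real speech spectra
— and exactly zero outside speech intervals. Waveform audio is not
synthesized for the benchmark; the analysis consumes features, and the
feature-extraction module is validated against constructed audio signals
(tones, AM carriers) instead.

**EEG.** y_c = gain_other · Σ_f (k_cf ⊛ x_f^other) + gain_self · Σ_f
(k_cf ⊛ x_f^self) + σ · pink noise, with strictly causal convolution
(lag ≥ 1 sample). Kernels mimic auditory evoked responses (negative
deflection near 100 ms, positive near 210 ms) with smooth channel-to-channel
amplitude variation. Background noise is 1/f (power exponent 1) via
spectral shaping. `gain_self = 0` encodes total suppression; `crosstalk`
adds an attenuated copy of the partner's features to one's own microphone
stream, emulating acoustic leak between close-talk microphones. When a
target SNR is requested, σ is set per channel as
SD(deterministic part)/√SNR.

**What it does not emulate**, hence what passing tests do not show about
real recordings: phonetics and prosody, ocular/muscle artifacts and their
removal, electrode drift or bridging, volume conduction (channels are
conditionally independent given the stimulus), inter-subject anatomical
variability, and background acoustics during silence — synthetic features
are exactly zero there, so Silence-condition models are degenerate
(constant design) and the pipeline skips them with a warning, whereas real
silence contains room noise and the published Silence baselines are
estimable.

**Identifiability.** With 16 band-correlated streams the per-band kernels
are only weakly identifiable — collinearity spreads ridge weight across
bands (measured tensor cosine ≈ 0.91 against ground truth at SNR 10), which
is the expected behavior of a regularized solution, not an estimation bug.
Ground-truth parameter recovery is therefore assessed where the model is
identifiable: a single-feature-stream session (recovery cosine ≈ 0.998 at
SNR 10) and the envelope model against the band-summed kernel (> 0.95).

## Desk-scale study conditions

Property checks run on seeded synthetic sessions sized for a single CPU:
sessions of 120–300 s, 4–24 channels, envelope designs (77 columns) for the
permutation-heavy analyses, n_perm = 200 for suppression recovery and null
calibration, 256–512 sign-flip permutations for TFCE calibration (18
subjects, d = 2 injected cluster), 200 replicates for p-value uniformity.
The full suite and the acceptance script each complete in a few minutes.

## Known limitations

- Real-data ingestion (WAV, interval CSV / TextGrid) is implemented at the
  module level; EDF/BrainVision readers, ICA cleaning and audio–EEG
  synchronization against a recorded sync channel must be orchestrated by
  the user — the pipeline's end-to-end mode is the synthetic benchmark.
- The α-selection protocol and the Bayes-factor recipe are this package's
  documented stand-ins for procedures whose original details are not
  publicly recorded.
- Noise-ceiling correction of correlations is out of scope: it requires
  repeated identical trials, which continuous unscripted dialog cannot
  provide.
- Headline correlation values from published 18-participant EEG corpora
  (e.g. Theta-band spectrogram r ≈ 0.4) are properties of real data and are
  not reproduced by the synthetic benchmark, whose SNR is a free parameter.
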