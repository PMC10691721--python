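# Methods

## Problem setting

`eggpipe` analyzes single-channel serosal electrogastrograms (EGG)
recorded from freely moving animals while electrical vagus nerve
stimulation (VNS) is switched on and off. The scientific question is a
binary one per stimulation frequency: can baseline windows be told apart
from stimulation windows, and through which signal properties? The
pipeline answers it with four stages — artifact-robust pre-processing, a
broad time/frequency feature battery, ensemble-voting feature selection,
and a permutation-tested classifier — each usable on its own.

Because freely-moving serosal recordings of this kind are not publicly
deposited, the package ships a synthetic generator that reproduces the
statistical structure the analysis assumes. All quantitative results in
the test suite and the acceptance script are computed on that generator.

## Synthetic EGG model

The slow wave is a sinusoid with a weak second harmonic whose
instantaneous frequency is `f0 + OU(t)`, an Ornstein–Uhlenbeck jitter
process (correlation time 10 s) integrated into phase. This is the
minimal model that produces a realistic spread of dominant-frequency
estimates and non-trivial entropy values; it makes no attempt at
biophysical pacemaker (ICC) modeling.

Defaults, chosen once as plausible study conditions:

| parameter | default | meaning |
|---|---|---|
| `slow_wave_freq_cpm` | 10 cpm | ferret normogastric dominant frequency |
| `slow_wave_amp_uv` | 200 µV | serosal slow-wave amplitude scale |
| `harmonic_weight` | 0.1 | second-harmonic fraction (keeps >99% of power at f0) |
| `freq_jitter_sd_cpm` | 0.5 cpm | OU jitter SD |
| `pink_noise_sd_uv` | 30 µV | 1/f background (SNR ≈ 13 dB against the slow wave) |
| `spike_rate_per_min` | 0.2 | implausible spikes, amplitude 2e8–1e9 µV |
| `motion_artifact_rate_per_min` | 0.5 | raised-cosine bumps, 3000–10000 µV, 2–5 s |
| `vns_pulse_amp_uv` | 5000 µV | biphasic pulse-train artifact amplitude |
| `amp_effect` | 1.5 | VNS-10Hz multiplicative slow-wave amplitude effect |
| `freq_shift_cpm` | −2 cpm | VNS-30Hz dominant-frequency shift |
| `complexity_effect` | 1.0 | VNS-30Hz jitter/noise inflation factor |

The two condition effects deliberately mirror the two stimulation
regimes the pipeline is meant to discriminate: a pure amplitude/energy
effect at 10 Hz and a frequency/irregularity effect at 30 Hz
(`complexity_effect` scales both the frequency-jitter SD and the
broadband-noise SD by `1 + c`). Their magnitudes are free parameters of
the simulator — no animal data exist to calibrate them — so passing
tests demonstrate that the pipeline recovers effects of this kind and
size, not that real stimulation produces them.

Stimulation pulses are 0.1 ms wide, which is sub-sample at 2 kHz; they
are rendered as adjacent +A/−A single-sample pairs at the stimulation
frequency. Spike amplitudes start at 2e8 µV so the excision stage is
exercised unambiguously; motion bumps span 3000–10000 µV so the 2000 µV
clamp is exercised after band-passing (a 2–5 s bump retains most of its
amplitude inside the 0.01–0.5 Hz band). Every component draws from its
own child stream of the recording seed, so studies are bit-reproducible
and components can be toggled independently.

What the generator does *not* emulate: non-stationary state dependence
(feeding cycles), electrode-quality drift within a session, correlated
multi-channel structure, or any coupling between artifact rate and
condition. Conclusions about real recordings must respect those gaps.

## Pre-processing

Stage order is fixed: (1) samples with |x| > 1e8 µV are deleted —
electrode-disconnection spikes carry no signal, so the array shortens
and the deletions are counted; (2) band-pass 0.01–0.5 Hz by DCT index
blocking (IB-DCTFM): orthonormal type-II DCT over the whole recording,
coefficients at indices whose frequency `k·fs/(2N)` falls outside the
band are zeroed, inverse DCT returns a zero-phase, unconditionally
stable filtered signal; (3) residual samples with |x| > 2000 µV are
replaced by the pre-substitution signal mean (single pass — the simplest
reading of mean substitution; the corner case where the mean itself
exceeds the threshold is accepted and unit-tested); (4) decimation to
4 Hz by simple stride — the signal is already band-limited at 0.5 Hz, a
factor 8 below the new Nyquist rate, and the O(N²) entropy estimators
would be intractable on 120 000-sample windows; (5) segmentation into
60 s windows stepped by 40 s (20 s overlap), partial tails discarded.

Per window, `removed_pct` = 100 × (excised + substituted samples in the
window's raw span) / (raw samples per window). Excisions are attributed
to the window covering the deleted sample's position in the shortened
array. Windows with `removed_pct ≥ 30%` are dropped (strict less-than
keeps a window). Excision happens on the raw recording before
filtering; whether to filter first is a genuine design freedom, but
excision-first prevents 1e8 µV spikes from smearing through the DCT.

## Feature battery

17 time-domain features: population moments (mean, variance, 64-bin
histogram mode, median, skewness, excess kurtosis), RMS, line length,
approximate entropy (Pincus; self-matches included; m = 2, r = 0.2·SD),
sample entropy (Richman–Moorman; self-matches excluded), permutation
entropy (order 3, delay 1, normalized by log 3!), SVD entropy (embedding
order 3, normalized by log 3), LZ76 phrase count of the median-binarized
window, Hjorth mobility and complexity (first differences), Petrosian
fractal dimension, and a Hurst exponent. `m = 2, r = 0.2·SD` and
`order 3` are the standard small-sample choices for 240-sample windows;
all are configurable.

10 frequency-domain features from a Welch PSD: dominant frequency and
power in 0.6–30 cpm, PMMP (percent of in-band bins strictly above DP/4),
spectral entropy (normalized, in-band), relative band powers over the
3–8 / 8–11 / 11–15 cpm brady/normo/tachygastric bands, PSD crest factor,
median frequency (first cumulative crossing of 50%), and mean power
frequency. The PSD uses a single Hann-tapered segment per 60 s window,
zero-padded to a 0.1 cpm grid; the native resolution of a 1-minute
window is 1 cpm, so the fine grid interpolates the spectrum rather than
adding information — peak positions gain, neighboring bins are
correlated.

Numerical choices worth knowing: DF ties resolve to the lowest
frequency; PMMP uses a strict inequality; ordinal-pattern ties break by
index order (stable argsort); PFD carries a zero difference on the
previous sign; a zero-variance window returns documented fallbacks
(entropies 0, Hjorth (0,0), Hurst 0.5) with warnings instead of failing.
The Hurst estimator uses Anis–Lloyd–Peters-corrected rescaled range
(`H = 0.5 + slope of log(R/S) − log E[R/S]` over dyadic windows 16…n/2):
the uncorrected slope is biased to ≈0.55–0.6 for white noise at these
window lengths.

The battery has 27 features; `removed_pct` travels with each row as a
bookkeeping column and is excluded from classifier inputs by default
(configurable), since it indexes recording quality rather than
physiology.

## Feature selection

Nine base selectors (ANOVA F, mutual information, |coefficients| of L1-
and L2-penalized linear SVCs, RFE over a random forest, forward and
backward sequential selection with logistic regression, permutation
importance of a random forest, variance thresholding). All but variance
thresholding run per training fold of an unshuffled stratified 5-fold
split; fold importances are averaged, clipped at zero, and normalized to
sum one. Scale-sensitive estimators (the SVCs, SFS) see z-scored
features with train-fold statistics; tree methods use raw features.
Subset-only methods need a weighting rule: SFS spreads 1/k over its k
selected features (the same rule variance thresholding uses), RFE
weights by inverse elimination rank. RFE/SFS keep ⌈p/2⌉ features.

The vote averages the nine weight vectors, re-normalizes, sorts
descending (alphabetical tie-break for determinism), and selects the
shortest prefix whose cumulative weight reaches 0.9 — a heuristic that
keeps most of the aggregated importance mass while shrinking the
feature set. The cumulative rule operates on renormalized weights;
this is the only reading under which a 0.9 cumulative threshold is
well-defined.

A Spearman correlation clustering (distance 1 − ρ, average linkage) is
provided as the redundancy diagnostic; constant columns get zero
correlation with a warning.

## Evaluation

Classifiers (random forest with 100 trees, linear and RBF SVM, Gaussian
naive Bayes, logistic regression) run at pinned defaults under
stratified unshuffled 5-fold CV. Metrics per fold: ROC-AUC as the
Mann–Whitney rank statistic with half credit for ties, accuracy, F1 and
F2 (F2 weights recall twice as heavily — missing a stimulation window is
the costlier error). Note the windows of one recording are distributed
across folds, so fold AUCs measure window-level, not session-level,
generalization — the appropriate reading of the study design, where
every subject contributes both conditions.

Significance: the five true-label fold AUCs are compared against the
pooled fold AUCs of 1000 seeded label permutations (5000 values) with a
two-sample KS test (exact p when both samples ≤ 25, asymptotic
otherwise). Pooling fold AUCs rather than per-shuffle means gives the
null sample the size needed for p < 1e-3, which a 5-vs-5 comparison
cannot reach. The feature-set comparison runs the same CV for: the
scenario's selected features, the other scenario's selection, all
features, random same-size subsets (re-drawn each repetition), and
shuffled labels.

Hyperparameter tuning is a seeded random search over a documented
random-forest grid whose first candidate is always the default
configuration, so the returned score never falls below the default's.

## Problem sizes used by the tests and the acceptance script

The acceptance script reproduces the headline regime at full scale:
7 subjects × (10-min baseline + 10-min VNS-10Hz) at 2 kHz → 196 windows,
the complete selector battery, and 1000 permutations (5005 forest fits).
Unit and property tests use smaller studies (2–4 subjects, 2–5 minute
segments, 10–50 permutations, naive-oracle inputs of n ≤ 300) chosen so
each property is still exercised at honest tolerances; the brute-force
entropy oracles run on 50 seeded inputs.

## Known limitations

* Effect sizes of the generator are assumptions, not calibrations.
* The 0.1 cpm PSD grid on 60 s windows is interpolated; band powers near
  band edges inherit Hann main-lobe leakage (≈0.4 cpm at 10 min, ≈2 cpm
  at 60 s).
* Windows overlap by 20 s and share recordings across CV folds, so fold
  metrics are optimistic relative to leave-session-out validation.
* SampEn can be +∞ (no template matches) on short pathological windows;
  the extractor maps that to 0 with a warning.
* The battery reports exactly the 27 features above; `removed_pct` is
  bookkeeping. Any count quoted elsewhere as "29 features" does not
  correspond to a set this implementation can reconstruct.
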