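# Methods

`neuroprose` implements the analysis machinery used to relate word
embeddings to word-aligned intracranial neural activity during natural
speech comprehension: lagged cross-validated linear encoding, surrogate-
based significance testing, confidence/surprise coupling, embedding-space
manipulations, and feed-forward decoding evaluated by word-classification
ROC-AUC. Because the kind of electrocorticographic and behavioral data
this machinery targets is rarely shareable, the package ships a synthetic
study generator with known ground truth; every pipeline stage is validated
against that ground truth and against independent numerical oracles.

## Preprocessing model

Raw multi-electrode signals are reduced to smoothed, z-scored high-gamma
broadband power in five stages:

1. **Despiking.** Samples beyond a robust threshold are replaced by cubic
   interpolation over retained samples. Two thresholds are selectable:
   `median ± 4·IQR` (default) and `mean ± 3·IQR`; both appear in practice
   and differ only for strongly skewed amplitude distributions.
2. **Common-average re-referencing** removes per-sample signal shared by
   all electrodes.
3. **Broadband power.** Six-cycle complex Morlet wavelets (via
   `mne.time_frequency.tfr_array_morlet`, reflection-padded at the edges)
   estimate power at 10 log-spaced center frequencies in 70–200 Hz, with
   frequencies within ±5 Hz of 60/120/180 Hz line noise removed from the
   grid. Per-frequency log power is averaged (`mean_of_log`; `log_of_mean`
   is available) and z-scored per electrode.
4. **Zero-phase smoothing.** A unit-sum 50-ms Hamming window is applied
   forward and backward (`filtfilt`), preserving peak latencies.

*Line-noise exclusion is a grid choice, not a notch filter.* A six-cycle
wavelet has a spectral bandwidth of roughly f/6 (≈20 Hz at 120 Hz), so
removing centers within ±5 Hz of a line frequency attenuates but cannot
null a carrier at that frequency — neighboring wavelets still respond to
it. The tests therefore assert attenuation relative to included-frequency
controls rather than full suppression.

*Temporal leakage.* Both the wavelet power estimate and the symmetric
smoothing kernel mix information over tens of milliseconds, so the
preprocessed signal at time t contains a bounded amount of future signal.
`impulse_leak_audit` measures this directly: a unit impulse in silence is
run through the wavelet-power stage (linear power — the log and z-score
are pointwise and cannot move energy in time, while the log of an exactly
zero baseline is degenerate) and the smoothing stage, and the backward
extent is the interval from the earliest output sample exceeding 1e-3 of
the peak to the impulse. At 512 Hz the full chain leaks ≈55 ms backward,
inside the analytic bound of 93 ms (half the 6/70-s support of the slowest
wavelet, ≈43 ms, plus the 50-ms smoothing kernel); the wavelet stage alone
at 70 Hz leaks ≈35 ms ≤ 43 ms. `scripts/acceptance.py` recomputes both.

## Encoding model

For each electrode and each lag on a grid (default 161 lags, −2000…2000 ms
in 25-ms steps), the response to a word is the signal averaged over a
200-ms window centered on onset+lag (the window alignment is a package
choice; a causal variant would shift, not reshape, the lag curve). An
ordinary least-squares model with intercept maps embedding vectors to
responses under 10-fold cross-validation: folds are a uniform random
partition of events (seeded; a contiguous-block option exists for
autocorrelation-sensitive variants), weights are fit on 90% of words and
applied to the held-out 10%, and performance is the Pearson correlation
between the concatenated held-out predictions and the actual responses.
OLS uses the pseudoinverse, which degrades gracefully to the minimum-norm
solution on rank-deficient designs (with a warning). Events whose window
leaves the recording at any lag are dropped from all lags to keep rows
aligned.

Because the per-fold prediction operator `X_test · pinv(X_train)` does not
depend on the responses, it is precomputed once (`CVLinearPredictor`) and
applied to arbitrary stacked response matrices. This makes the surrogate
procedures below cheap: thousands of permutations reduce to matrix
multiplications.

## Significance procedures

* **Electrode significance (max-statistic phase randomization).** Each
  surrogate randomizes every electrode's Fourier phases independently
  (amplitudes, and hence autocorrelation, preserved exactly; DC kept, the
  Nyquist bin kept real), re-extracts lagged responses and re-runs the full
  encoding. Per surrogate the maximum encoding value over lags is taken per
  electrode, then the maximum over electrodes; the pooled maxima form the
  null. Electrode p-values are (k+1)/(n+1) percentiles of the observed
  max-over-lags value in that null — never exactly zero — and are
  Benjamini–Hochberg corrected; electrodes at q < 0.01 are significant.
  Surrogates are processed in batches with a precomputed amplitude
  spectrum; 5,000 permutations are the reference setting, and reduced
  profiles (with proportionally coarser p-value resolution) are used for
  calibration simulations.
* **Paired model comparison.** Per lag, the electrode-mean difference
  between two encoding maps is tested against a sign-flip null (swapping
  the two models' values within an electrode flips its difference),
  two-sided by default, BH-corrected across lags.
* **Bootstrap-shift mean test.** Per lag, electrodes are resampled with
  replacement; the bootstrap distribution of the mean, shifted by the
  observed mean, forms the null; BH across lags.
* **Constrained comparison.** The paired test restricted to lags where the
  first map is significant on its own; the base test is bootstrap by
  default, sign-flip permutation optionally (both interpretations are
  defensible, so both are exposed).

## Confidence, surprise and behavior

A next-word probability model assigns each word a distribution before its
onset. Confidence is the entropy H = −Σ p log p (in nats by default —
consistent with the natural-log convention used elsewhere in the chain and
with standard cross-entropy loss; bits optional). Surprise is the
cross-entropy −log P(actual word). Words are split into correctly and
incorrectly predicted by top-k membership (k = 5 or 1; ties broken by
vocabulary index). Coupling between these measures and neural activity is
the per-lag, per-electrode partial correlation of windowed power with
entropy controlling cross-entropy (and vice versa), computed from the
three-variable closed form, averaged over electrodes, with per-lag FDR
flags from a one-sample t-test on Fisher-z coefficients.

The behavioral predictability score of a word is the fraction of raters
whose normalized guess (case-folded, punctuation-stripped; no spelling
correction) matches it. Calibration curves bin assigned probabilities and
report empirical top-1 accuracy per bin (empty bins are missing, not
zero). Count-based n-gram baselines (orders 2–5, MLE or add-k smoothing)
are built from normalized corpus tokens; unseen histories yield flagged
zero probabilities under MLE.

## Decoding model

Neural input per word is an electrodes × 10 matrix of 62.5-ms bin means
spanning 625 ms around onset+lag (32 samples per bin at 512 Hz). Data are
split into five contiguous temporal folds with rotating train (3), early-
stopping development (1) and test (1) roles. Where electrode selection is
enabled, the phase-randomization significance procedure is re-run on the
80% of events outside the test fold. The decoder is a feed-forward MLP
(default 256→128 hidden units, trained by Adam on MSE with one
`partial_fit` pass per epoch and explicit patience-based early stopping on
development MSE, best-development weights restored; identical seeds give
identical trajectories). An ensemble (default 10; reduced in calibration
runs) of independently initialized decoders is trained per fold.

Classification happens in embedding space: for each label with at least
five training-set repetitions, the cosine distance from the predicted
embedding to every training instance of the label is averaged into one
score, negated, averaged across ensemble members, and softmax-transformed
across labels (averaging before the softmax keeps ensemble combination on
the distance scale). Per-label one-vs-rest ROC-AUC is computed by the rank
statistic and averaged weighted by test-set label frequency. A
frequency-only decoder sits at AUC 0.5 by construction.

## Synthetic study generator

The generator emulates the statistical skeleton of a word-aligned
listening experiment; all defaults are the package's benchmark
conditions:

* **Vocabulary and transcript.** Rank-frequency law rank^(−a) (default
  a = 1.05, so a usable fraction of types reaches ≥5 repetitions);
  inter-onset gaps exponential with a 50-ms floor and 350-ms mean
  (natural-speech-like while keeping events separable).
* **Embeddings.** Arbitrary: one uniform[−1,1] vector per type. Static:
  unit-norm Gaussian type vectors with ~60% of variance in a shared
  low-rank subspace (distributional-semantics-like similarity structure).
  Contextual: √(1−s²)·static + s·context, where the context component is a
  unit-norm AR-weighted mixture (ρ = 0.7) of the static vectors of the 10
  preceding events plus an occurrence-specific innovation — matching the
  10-word window used by the concatenation control. The within-type
  variance of the context component scales as s², and the mean within-type
  cosine similarity is ≈1−s². An optional recurring-context term
  (`context_type_bias` b, default 0) mixes a per-type direction into the
  context component, emulating that a given word tends to recur in similar
  contexts; same-type contexts then correlate by ≈b². This term is what
  makes contextual embeddings carry word-identity information *beyond*
  their static core: without it, context is label-orthogonal and a
  contextual-target decoder cannot outperform a static-target one at word
  classification, whereas the decoding benchmark (b = 0.5) shows the
  genuine contextual advantage.
* **Neural responses.** Electrode e carries
  Σ_w kernel(t−onset_w)·⟨u_e, emb_w⟩ with Gaussian tuning vectors u_e and
  a Gaussian lag kernel (default peak +150 ms, σ = 60 ms), plus spectrally
  shaped 1/f^α Gaussian noise (α = 1, typical of field potentials) scaled
  so evoked/noise variance equals the requested SNR. The generative model
  is a benchmarking choice, not a claim about real data: it is exactly the
  linear model the encoding analysis assumes, so recovery tests probe the
  machinery, not the model class.
* **Predictions and raters.** Next-word distributions are
  temperature-controlled softmaxes over log-frequency-plus-noise logits;
  the actual word's logit is raised into the top five for a
  Bernoulli(accuracy) subset of events (rank 1 with probability 0.58,
  otherwise ranks 2–5) and pushed below otherwise, so realized top-5
  accuracy matches the target. Raters guess i.i.d. from each event's
  distribution.

**What the generator does not emulate:** acoustic/phonetic structure,
syntactic dependencies, non-stationarity, electrode covariance, shared
noise across electrodes after re-referencing, and real embedding
geometries. Passing tests therefore demonstrate that the machinery
recovers what it assumes, at the stated sizes and SNRs — not that real
cortex behaves like the generator.

### Benchmark calibration for the manipulation ordering

The context-manipulation benchmark plants the qualitative ordering
contextual > averaged ≈ static > scrambled ≈ arbitrary. With embedding
dimension d, type count T and context strength s, held-out encoding
levels scale approximately as 1 (contextual), √(1−s²) (static, and
averaged-per-type, since context averages out over ≥5 occurrences),
(1−s²) (occurrence-scrambled — an errors-in-variables attenuation: the
wrongly paired context component acts as design noise), and
κ·√(1−s²) (arbitrary, where κ ≈ 0.7 is the chance overlap between a
random d-dimensional type basis and the planted structure; Zipf weighting
makes κ nearly independent of T once T ≫ d). The identity-only and
scrambled levels coincide when √(1−s²) = κ, so the benchmark defaults are
d = 32, T = 200, s = 0.7, 2,500 words, 30 electrodes, SNR 1.

## Problem sizes

The default test-suite and benchmark sizes are deliberately desk-scale:
hundreds to a few thousand word events, 8–50 electrodes, sampling rates of
64–128 Hz for generated (already power-like) signals and 512 Hz wherever
the preprocessing chain itself is under test, 1,000-permutation null
calibrations over 100 Monte-Carlo runs, and 3-member decoder ensembles.
These sizes give comfortable statistical margins for every property tested
while keeping a full run in minutes on one CPU; all of them scale up
through function arguments.

## Numerical choices and edge cases

* Permutation/bootstrap p-values use (k+1)/(n+1); FDR is
  Benjamini–Hochberg (`statsmodels`), validated against a brute-force
  step-up oracle.
* Phase surrogates keep the DC bin and give the Nyquist bin a random sign,
  so surrogates are exactly real with exactly preserved amplitude spectra.
* Pearson correlations with a zero-variance side are defined as 0 in the
  encoding map (an electrode with constant response carries no signal).
* Zero-norm predicted embeddings get maximal cosine distance (2.0), with a
  warning.
* Start-of-sequence context is zero-padded; PCA for the concatenation
  control is fit on caller-specified rows only (training folds) to avoid
  leaking held-out events into the projection.
* Derangement-preferring scrambling redraws permutations with fixed points
  up to a retry budget; for types with very few occurrences a fixed point
  may be unavoidable.
* The entropy of a distribution with zero entries uses 0·log 0 = 0;
  cross-entropy of a zero-probability actual word raises unless clamping
  to 1e-10 is enabled.

## Known limitations

* Ridge or banded regularization is not implemented; the encoding model is
  plain OLS as analyzed.
* ICA-based re-referencing, forced alignment, anatomical localization and
  Kneser–Ney smoothing are out of scope.
* The decoder architecture is a compact MLP; results quoted for it are
  property-level (chance on null data, recovery on planted data), not
  architecture benchmarks.
* Extraction of embeddings from pretrained language models is not part of
  the package; embedding matrices are inputs.
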