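# neuroprose

Lagged encoding, significance testing and embedding-space decoding of
word-aligned neural activity — with a synthetic study generator for
ground-truth validation.

## The problem

During natural speech comprehension, cortical activity (especially
high-gamma broadband power, 70–200 Hz) carries information about each
word before and after its moment of articulation. A standard way to
quantify this is the **lagged linear encoding model**: represent each
spoken word w by an embedding vector x_w ∈ R^d, extract the neural
response y_{e,w}(τ) of electrode e averaged over a 200-ms window centered
at onset(w)+τ, and fit, per electrode and lag τ,

    y_{e,·}(τ) ≈ X β_{e,τ}

by OLS under 10-fold cross-validation, scoring the Pearson correlation
r_e(τ) between concatenated held-out predictions and actual responses
across the lag grid τ ∈ {−2000, −1975, …, 2000} ms. Inference uses
phase-randomization surrogates with a max-over-lags/max-over-electrodes
null and Benjamini–Hochberg FDR; paired sign-flip and bootstrap-shift
tests compare models and threshold mean curves. The inverse, **decoding**,
maps an electrodes × 10-bin window of activity to embedding space with an
MSE-trained feed-forward network and classifies word identity by cosine
distance, scored as frequency-weighted one-vs-rest ROC-AUC.

The package is aimed at researchers analyzing word-aligned
electrophysiology (ECoG/iEEG) against word-embedding hypotheses —
comparing contextual vs static vs arbitrary embeddings, relating
pre-onset activity to prediction confidence (entropy) and post-onset
activity to surprise (cross-entropy −log P(actual word)), and scoring
human next-word-prediction behavior. Since such datasets are rarely
shareable, a first-class `synthetic` module generates transcripts,
embeddings, prediction distributions, evoked recordings (lag-kernel
convolutions of embedding projections plus 1/f noise) and simulated
raters with known ground truth; every stage of the pipeline is tested
against it. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from neuroprose import synthetic as syn
from neuroprose.encoding import encode_all_lags
from neuroprose.stats import electrode_significance
from neuroprose.types import LagKernel

vocab = syn.gen_vocabulary(n_types=120, zipf_exponent=1.05)
events = syn.gen_word_events(vocab, n_words=800, mean_gap_s=0.35, seed=1)
emb = syn.gen_embeddings(events, dim=32, kind="contextual",
                         context_strength=0.7, seed=2)
rec, truth = syn.gen_neural_recording(
    events, emb, LagKernel.gaussian(center_ms=150.0, sigma_ms=60.0),
    n_electrodes=16, fs=128.0, snr=1.0, seed=3)

lags = np.arange(-600.0, 601.0, 25.0)
emap = encode_all_lags(rec, events, emb, lags, n_folds=10, seed=0)
peak = int(np.argmax(emap.mean_curve))
print(f"peak mean r = {emap.mean_curve[peak]:.3f} at lag {lags[peak]:+.0f} ms")

sig = electrode_significance(rec, events, emb, np.arange(-200.0, 401.0, 50.0),
                             n_perm=300, q=0.01, seed=0)
print(f"significant electrodes: {int(sig.significant.sum())}/{rec.n_electrodes}")
```

prints (in under a minute on one CPU)

```
peak mean r = 0.746 at lag +150 ms
significant electrodes: 16/16
```

The electrode-mean held-out correlation peaks at +150 ms — exactly where
the generator planted its response kernel — at r ≈ 0.75 under SNR 1, and
every tuned electrode survives the max-statistic permutation test at
q < 0.01. Replacing the contextual embeddings with their per-type averages
or with occurrence-scrambled copies lowers the curve in the order
contextual > averaged ≈ static > scrambled ≈ arbitrary (see
`neuroprose.embedding_ops` and the orchestration suites).

A command-line interface covers the same ground:

```bash
neuroprose simulate --events events.tsv --rec rec.h5 --ledger truth.json
neuroprose encode --rec rec.h5 --events events.tsv --emb contextual \
    --lags=-600:600:25 --out map.h5
neuroprose benchmark --out-dir reports/
```

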