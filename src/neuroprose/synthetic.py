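"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a word-aligned intracranial
recording experiment: a Zipfian vocabulary, a transcript of timed word
events, per-type (static/arbitrary) and per-occurrence (contextual)
embeddings, temperature-controlled next-word prediction distributions,
evoked multi-electrode responses (lag-kernel-convolved linear projections
of the embeddings plus 1/f noise), and simulated human raters guessing
each upcoming word.

Every generator takes an integer seed and is bit-reproducible; the
recording generator additionally returns a :class:`GroundTruthLedger` so
downstream recovery can be audited against the planted truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .types import (
    BehavioralTable,
    EmbeddingMatrix,
    GroundTruthLedger,
    LagKernel,
    NeuralRecording,
    PredictionSet,
    Vocabulary,
    WordEventTable,
)

__all__ = [
    "gen_vocabulary",
    "gen_word_events",
    "gen_embeddings",
    "gen_prediction_distributions",
    "gen_neural_recording",
    "gen_behavioral_responses",
    "one_over_f_noise",
]

# Minimum inter-onset gap (natural speech rarely articulates faster).
GAP_FLOOR_S = 0.05


def gen_vocabulary(n_types: int, zipf_exponent: float = 1.1, seed: int = 0) -> Vocabulary:
    """Vocabulary with rank-frequency law ``f(rank) ∝ rank**(-zipf_exponent)``.

    ``zipf_exponent=0`` gives the uniform limit. The seed is accepted for
    interface symmetry with the other generators (the construction is
    deterministic given ``n_types`` and the exponent).
    """
    if n_types < 2:
        raise ValueError("n_types must be >= 2")
    ranks = np.arange(1, n_types + 1, dtype=float)
    weights = ranks ** (-float(zipf_exponent))
    freqs = weights / weights.sum()
    types = [f"w{i:04d}" for i in range(n_types)]
    return Vocabulary(types=types, frequencies=freqs)


def gen_word_events(
    vocab: Vocabulary,
    n_words: int,
    mean_gap_s: float = 0.35,
    start_s: float = 2.5,
    seed: int = 0,
) -> WordEventTable:
    """Timed transcript: i.i.d. tokens, exponential gaps with a 50-ms floor.

    Gaps are ``GAP_FLOOR_S + Exponential(mean_gap_s - GAP_FLOOR_S)`` so the
    mean inter-onset interval equals ``mean_gap_s`` while keeping events
    separable. Word offsets are drawn inside the following gap.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    if mean_gap_s <= GAP_FLOOR_S:
        raise ValueError(f"mean_gap_s must exceed the {GAP_FLOOR_S*1000:.0f}-ms floor")
    rng = np.random.default_rng(seed)
    type_ids = rng.choice(len(vocab), size=n_words, p=vocab.frequencies)
    gaps = GAP_FLOOR_S + rng.exponential(mean_gap_s - GAP_FLOOR_S, size=n_words)
    onsets = start_s + np.cumsum(gaps) - gaps[0]  # first onset at start_s
    next_gap = np.append(gaps[1:], gaps[-1])
    durations = np.minimum(rng.uniform(0.1, 0.3, size=n_words), 0.8 * next_gap)
    offsets = onsets + durations
    counts = np.bincount(type_ids, minlength=len(vocab))
    df = pd.DataFrame(
        {
            "token": [vocab.types[t] for t in type_ids],
            "onset_s": onsets,
            "offset_s": offsets,
            "type_id": type_ids,
            "repetition_count": counts[type_ids],
        }
    )
    return WordEventTable(df)


def _static_base(n_types: int, dim: int, seed: int, latent_share: float = 0.6) -> np.ndarray:
    """Unit-norm Gaussian type vectors with a planted low-rank component.

    A fraction ``latent_share`` of each vector's variance lives in a shared
    low-dimensional subspace (rank ``max(2, dim // 8)``), mimicking the
    similarity structure of distributional semantic embeddings.
    """
    rng = np.random.default_rng([seed, 0])
    q = max(2, dim // 8)
    loadings = np.linalg.qr(rng.standard_normal((dim, q)))[0]  # orthonormal dim x q
    z = rng.standard_normal((n_types, q))
    idio = rng.standard_normal((n_types, dim))
    vecs = np.sqrt(latent_share) * z @ loadings.T / np.sqrt(q) + np.sqrt(
        1.0 - latent_share
    ) * idio / np.sqrt(dim)
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def gen_embeddings(
    events: WordEventTable,
    dim: int = 50,
    kind: str = "static",
    context_strength: float = 0.0,
    context_k: int = 10,
    context_type_bias: float = 0.0,
    seed: int = 0,
) -> EmbeddingMatrix:
    """Per-event embeddings of the requested kind.

    arbitrary
        One uniform[-1, 1] vector per type, repeated across occurrences
        (word identity, no semantic structure).
    static
        One unit-norm Gaussian vector per type with a planted low-rank
        similarity structure, repeated across occurrences.
    contextual
        ``sqrt(1 - s**2) * static_base(type) + s * context`` with
        ``s = context_strength``; the context component is a unit-norm
        AR-weighted mixture of the static vectors of the ``context_k``
        preceding events plus an occurrence-specific innovation, so all
        occurrences of a type share a vector iff ``s == 0``.

    ``context_type_bias`` in [0, 1) adds a per-type recurring-context
    direction to the contextual component (weight ``b``, so same-type
    contexts correlate by ~``b**2``), emulating that a given word tends to
    recur in similar contexts. At the default 0 the context component is
    orthogonal to word identity and the mean within-type cosine similarity
    is ~``1 - s**2``.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    if kind not in ("arbitrary", "static", "contextual"):
        raise ValueError(f"unknown embedding kind {kind!r}")
    if not 0.0 <= context_strength <= 1.0:
        raise ValueError("context_strength must lie in [0, 1]")

    type_ids = events.type_ids
    n_types = int(type_ids.max()) + 1

    if kind == "arbitrary":
        rng = np.random.default_rng([seed, 2])
        per_type = rng.uniform(-1.0, 1.0, size=(n_types, dim))
        return EmbeddingMatrix(per_type[type_ids], kind="arbitrary")

    base = _static_base(n_types, dim, seed)
    if kind == "static" or context_strength == 0.0:
        return EmbeddingMatrix(base[type_ids], kind=kind)

    # Contextual: AR(1)-weighted mixture over the static vectors of the
    # previous context_k events, plus an occurrence-specific innovation and
    # (optionally) a per-type recurring-context direction.
    if not 0.0 <= context_type_bias < 1.0:
        raise ValueError("context_type_bias must lie in [0, 1)")
    rng = np.random.default_rng([seed, 1])
    n = len(events)
    rho, mix = 0.7, 0.7
    ctx = np.zeros((n, dim))
    innov = rng.standard_normal((n, dim)) / np.sqrt(dim)
    bias_dirs = rng.standard_normal((n_types, dim))
    bias_dirs /= np.linalg.norm(bias_dirs, axis=1, keepdims=True)
    b = context_type_bias
    for i in range(n):
        acc = np.zeros(dim)
        for j in range(1, context_k + 1):
            if i - j < 0:
                break
            acc += rho**j * base[type_ids[i - j]]
        norm = np.linalg.norm(acc)
        history = acc / norm if norm > 0 else acc
        unit_innov = innov[i] / np.linalg.norm(innov[i])
        occ = mix * history + np.sqrt(1.0 - mix**2) * unit_innov
        c = np.sqrt(1.0 - b**2) * occ + b * bias_dirs[type_ids[i]]
        ctx[i] = c / np.linalg.norm(c)
    s = context_strength
    vectors = np.sqrt(1.0 - s**2) * base[type_ids] + s * ctx
    return EmbeddingMatrix(vectors, kind="contextual")


def gen_prediction_distributions(
    events: WordEventTable,
    vocab: Vocabulary,
    confidence: float = 1.0,
    accuracy: float = 0.62,
    top1_fraction: float = 0.58,
    seed: int = 0,
) -> PredictionSet:
    """Temperature-controlled next-word distributions with planted accuracy.

    Base logits are ``log frequency`` plus per-event Gaussian noise,
    sharpened by ``confidence`` (temperature ``1/confidence``). For a
    Bernoulli(``accuracy``) subset of events the actual word's logit is
    raised into the top five (rank 1 with probability ``top1_fraction``,
    otherwise uniform over ranks 2-5); for the remaining events it is pushed
    below the top five, so the realized top-5 accuracy matches the target in
    expectation.
    """
    if confidence <= 0:
        raise ValueError("confidence must be positive")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n, V = len(events), len(vocab)
    actual = events.type_ids.astype(int)
    z = np.log(vocab.frequencies)[None, :] + rng.standard_normal((n, V))
    hits = rng.random(n) < accuracy
    ranks = np.where(rng.random(n) < top1_fraction, 1, rng.integers(2, 6, size=n))
    for i in range(n):
        others = np.delete(z[i], actual[i])
        order = np.sort(others)[::-1]
        if hits[i]:
            rho = min(ranks[i], V - 1)
            if rho == 1:
                z[i, actual[i]] = order[0] + 1.0
            else:
                z[i, actual[i]] = 0.5 * (order[rho - 2] + order[rho - 1])
        else:
            floor_rank = min(5, V - 1)
            z[i, actual[i]] = order[floor_rank - 1] - 1.0  # strictly below top-5
    logits = confidence * z
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    return PredictionSet(probs=probs, actual_index=actual)


def one_over_f_noise(
    n_electrodes: int, n_samples: int, fs: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f**exponent power spectrum."""
    white = rng.standard_normal((n_electrodes, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    freqs[0] = freqs[1] if n_samples > 1 else 1.0  # keep DC finite
    spec *= freqs ** (-exponent / 2.0)
    noise = np.fft.irfft(spec, n=n_samples, axis=1)
    noise -= noise.mean(axis=1, keepdims=True)
    sd = noise.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return noise / sd


def gen_neural_recording(
    events: WordEventTable,
    embeddings: EmbeddingMatrix,
    kernel: LagKernel | None = None,
    n_electrodes: int = 50,
    fs: float = 512.0,
    snr: float = 1.0,
    noise_exponent: float = 1.0,
    seed: int = 0,
    margin_s: float = 3.0,
) -> tuple[NeuralRecording, GroundTruthLedger]:
    """Word-evoked recording: lag-kernel-convolved embedding projections + 1/f noise.

    Electrode ``e`` carries ``sum_w kernel(t - onset_w) * <u_e, emb_w>``
    where the tuning vectors ``u_e`` are Gaussian; the noise floor is scaled
    so that (evoked variance / noise variance) equals ``snr``. ``snr=0``
    yields pure noise; ``snr=inf`` yields a noiseless recording.
    """
    if embeddings.n_events < len(events):
        raise ValueError("embedding rows fewer than events")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if snr < 0:
        raise ValueError("snr must be nonnegative")
    if kernel is None:
        kernel = LagKernel.gaussian()

    rng = np.random.default_rng(seed)
    dim = embeddings.dim
    tuning = rng.standard_normal((n_electrodes, dim)) / np.sqrt(dim)

    n_samples = int(np.ceil((events.df["offset_s"].max() + margin_s) * fs))
    taps, tap_offset = kernel.sample(fs)
    amplitudes = embeddings.vectors[: len(events)] @ tuning.T  # events x electrodes

    evoked = np.zeros((n_electrodes, n_samples))
    if snr > 0:
        onset_idx = np.round(events.onsets * fs).astype(int)
        impulses = np.zeros((n_electrodes, n_samples))
        np.add.at(impulses, (slice(None), onset_idx), amplitudes.T)
        full = fftconvolve(impulses, taps[None, :], mode="full", axes=1)
        # evoked[t] = full[t - tap_offset], clipped to the recording extent
        shifted = np.zeros_like(evoked)
        t0 = max(0, tap_offset)
        t1 = min(n_samples, full.shape[1] + tap_offset)
        shifted[:, t0:t1] = full[:, t0 - tap_offset : t1 - tap_offset]
        evoked = shifted

    evoked_var = float(evoked.var()) if snr > 0 else 0.0
    if snr == 0:
        noise = one_over_f_noise(n_electrodes, n_samples, fs, noise_exponent, rng)
        noise_var = 1.0
        signal = noise
    elif np.isinf(snr):
        noise_var = 0.0
        signal = evoked
    else:
        noise = one_over_f_noise(n_electrodes, n_samples, fs, noise_exponent, rng)
        noise_sd = np.sqrt(evoked_var / snr)
        noise_var = noise_sd**2
        signal = evoked + noise_sd * noise

    rec = NeuralRecording(signal, fs=fs, stage="smoothed")
    ledger = GroundTruthLedger(
        tuning=tuning,
        kernel=kernel,
        context_strength=0.0,
        snr=float(snr),
        noise_exponent=float(noise_exponent),
        seed=int(seed),
        evoked_variance=evoked_var,
        noise_variance=noise_var,
    )
    return rec, ledger


def gen_behavioral_responses(
    events: WordEventTable,
    dists: PredictionSet,
    vocab: Vocabulary,
    n_raters: int = 50,
    seed: int = 0,
) -> BehavioralTable:
    """Simulated raters: each guess is an i.i.d. draw from the event's distribution."""
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if dists.n_events != len(events):
        raise ValueError("distributions not aligned to events")
    rng = np.random.default_rng(seed)
    types = np.asarray(vocab.types, dtype=object)
    guesses = np.empty((n_raters, len(events)), dtype=object)
    for i in range(len(events)):
        picks = rng.choice(len(vocab), size=n_raters, p=dists.probs[i])
        guesses[:, i] = types[picks]
    return BehavioralTable(guesses=guesses)
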