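"""Generator correctness: frequencies, timing, embeddings, distributions, SNR."""

import numpy as np
import pytest
from scipy.signal import welch

from neuroprose import synthetic as syn
from neuroprose.prediction_measures import accuracy_split, entropy, predictability_score
from neuroprose.types import LagKernel


class TestVocabulary:
    def test_uniform_limit(self):
        v = syn.gen_vocabulary(2, zipf_exponent=0.0)
        np.testing.assert_allclose(v.frequencies, [0.5, 0.5])

    def test_harmonic_weights(self):
        # ranks 1,2,3 at exponent 1: weights 1, 1/2, 1/3 -> 6/11, 3/11, 2/11
        v = syn.gen_vocabulary(3, zipf_exponent=1.0)
        np.testing.assert_allclose(v.frequencies, [6 / 11, 3 / 11, 2 / 11], atol=1e-15)

    def test_determinism(self):
        a = syn.gen_vocabulary(10, 1.1, seed=5)
        b = syn.gen_vocabulary(10, 1.1, seed=5)
        assert a.types == b.types
        np.testing.assert_array_equal(a.frequencies, b.frequencies)

    def test_too_few_types_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_vocabulary(1)


class TestWordEvents:
    def test_single_event(self, vocab):
        ev = syn.gen_word_events(vocab, 1, seed=0)
        assert len(ev) == 1
        assert ev.onsets[0] >= 0

    def test_onsets_strictly_increasing(self, events):
        assert np.all(np.diff(events.onsets) > 0)

    def test_most_frequent_share_matches_zipf(self):
        vocab = syn.gen_vocabulary(50, 1.1)
        ev = syn.gen_word_events(vocab, 10_000, seed=7)
        p = vocab.frequencies[0]
        share = np.mean(ev.type_ids == 0)
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(share - p) < 3 * se

    def test_mean_gap_controls_duration(self):
        vocab = syn.gen_vocabulary(10, 1.0)
        n, gap, start = 100, 0.3, 2.5
        # sum-of-gaps oracle: last onset ~ start + (n-1)*gap, sd ~ sqrt(n)*(gap-floor)
        ev = syn.gen_word_events(vocab, n, mean_gap_s=gap, start_s=start, seed=3)
        expected = start + (n - 1) * gap
        sd = np.sqrt(n) * (gap - 0.05)
        assert abs(ev.onsets[-1] - expected) < 3 * sd

    def test_repetition_counts(self, events):
        tid = events.type_ids
        counts = np.bincount(tid)
        assert np.array_equal(events.repetition_counts, counts[tid])


class TestEmbeddings:
    def test_contextual_zero_strength_equals_static(self, events):
        ctx = syn.gen_embeddings(events, 16, "contextual", context_strength=0.0, seed=2)
        sta = syn.gen_embeddings(events, 16, "static", seed=2)
        np.testing.assert_array_equal(ctx.vectors, sta.vectors)

    def test_arbitrary_bounds_and_type_sharing(self, events):
        arb = syn.gen_embeddings(events, 16, "arbitrary", seed=2)
        assert np.all((arb.vectors >= -1) & (arb.vectors <= 1))
        tid = events.type_ids
        t = tid[0]
        idx = np.flatnonzero(tid == t)
        if idx.size >= 2:
            np.testing.assert_array_equal(arb.vectors[idx[0]], arb.vectors[idx[1]])

    def test_within_type_cosine_tracks_context_strength(self):
        # mean within-type cosine ~ (1 - s^2) of the pure-static value (=1),
        # cross-checked against a direct Monte-Carlo estimate over pairs
        s = 0.8
        vocab = syn.gen_vocabulary(80, 1.0)
        ev = syn.gen_word_events(vocab, 2500, seed=9)
        ctx = syn.gen_embeddings(ev, 32, "contextual", context_strength=s, seed=4)
        rng = np.random.default_rng(0)
        cos = []
        tid = ev.type_ids
        for _ in range(1000):
            t = rng.integers(0, 80)
            idx = np.flatnonzero(tid == t)
            if idx.size < 2:
                continue
            i, j = rng.choice(idx, 2, replace=False)
            a, b = ctx.vectors[i], ctx.vectors[j]
            cos.append(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        mc = float(np.mean(cos))
        assert abs(mc - (1 - s**2)) < 0.08

    def test_context_component_variance_scales_with_s_squared(self):
        vocab = syn.gen_vocabulary(40, 1.0)
        ev = syn.gen_word_events(vocab, 1200, seed=5)
        sta = syn.gen_embeddings(ev, 16, "static", seed=6)
        strengths = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        variances = []
        for s in strengths:
            ctx = syn.gen_embeddings(ev, 16, "contextual", context_strength=s, seed=6)
            resid = ctx.vectors - np.sqrt(1 - s**2) * sta.vectors
            variances.append(resid.var())
        slope = np.polyfit(strengths**2, variances, 1)[0]
        # component variance proportional to s^2: linear fit through the grid
        fit = np.polyval(np.polyfit(strengths**2, variances, 1), strengths**2)
        assert slope > 0
        assert np.max(np.abs(fit - variances)) < 0.05 * max(variances)

    def test_recurring_context_bias_correlates_same_type_contexts(self):
        # with bias b, contexts of two occurrences of a type correlate ~b^2;
        # the contextual rows then have within-type cosine (1-s^2) + s^2 b^2
        vocab = syn.gen_vocabulary(50, 1.0)
        ev = syn.gen_word_events(vocab, 2000, seed=13)
        s, b = 0.8, 0.6
        sta = syn.gen_embeddings(ev, 32, "static", seed=14)
        tid = ev.type_ids

        def mean_within_type_cos(bias):
            ctx = syn.gen_embeddings(
                ev, 32, "contextual", context_strength=s,
                context_type_bias=bias, seed=14,
            )
            comp = (ctx.vectors - np.sqrt(1 - s**2) * sta.vectors) / s
            rng = np.random.default_rng(0)
            cos = []
            for _ in range(800):
                t = rng.integers(0, 50)
                idx = np.flatnonzero(tid == t)
                if idx.size < 2:
                    continue
                i, j = rng.choice(idx, 2, replace=False)
                u, v = comp[i], comp[j]
                cos.append(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
            return float(np.mean(cos))

        # contexts carry a small baseline same-type correlation even at b=0
        # (frequent words recur as context); the bias adds b^2 on top
        baseline = mean_within_type_cos(0.0)
        observed = mean_within_type_cos(b)
        expected = b**2 + (1 - b**2) * baseline
        assert observed > baseline + 0.2
        assert abs(observed - expected) < 0.08

    def test_unknown_kind_rejected(self, events):
        with pytest.raises(ValueError):
            syn.gen_embeddings(events, 8, "glove")

    def test_same_seed_identical(self, events):
        a = syn.gen_embeddings(events, 8, "contextual", context_strength=0.5, seed=11)
        b = syn.gen_embeddings(events, 8, "contextual", context_strength=0.5, seed=11)
        np.testing.assert_array_equal(a.vectors, b.vectors)


class TestPredictionDistributions:
    def test_low_confidence_approaches_uniform(self, events, vocab):
        d = syn.gen_prediction_distributions(events, vocab, confidence=1e-6, seed=0)
        h = entropy(d)
        assert np.all(h > 0.99 * np.log(len(vocab)))

    def test_full_accuracy_high_confidence_top1(self, events, vocab):
        d = syn.gen_prediction_distributions(
            events, vocab, confidence=5.0, accuracy=1.0, top1_fraction=1.0, seed=0
        )
        assert accuracy_split(d, k=1).all()

    def test_target_top5_accuracy_recovered(self):
        vocab = syn.gen_vocabulary(100, 1.0)
        ev = syn.gen_word_events(vocab, 5000, seed=1)
        target = 0.62
        d = syn.gen_prediction_distributions(ev, vocab, confidence=2.0, accuracy=target, seed=2)
        realized = accuracy_split(d, k=5).mean()
        se = np.sqrt(target * (1 - target) / 5000)
        assert abs(realized - target) < 3 * se

    def test_nonpositive_confidence_rejected(self, events, vocab):
        with pytest.raises(ValueError):
            syn.gen_prediction_distributions(events, vocab, confidence=0.0)


class TestNeuralRecording:
    def test_noiseless_delta_kernel_copies_kernel(self, vocab):
        ev = syn.gen_word_events(vocab, 1, seed=0)
        emb = syn.gen_embeddings(ev, 4, "static", seed=1)
        rec, ledger = syn.gen_neural_recording(
            ev, emb, LagKernel.delta(at_ms=150.0), n_electrodes=3, fs=128,
            snr=np.inf, seed=2,
        )
        onset = int(round(ev.onsets[0] * 128))
        shift = int(round(0.150 * 128))
        expected = emb.vectors[0] @ ledger.tuning.T
        np.testing.assert_allclose(rec.signal[:, onset + shift], expected, atol=1e-12)
        mask = np.ones(rec.n_samples, bool)
        mask[onset + shift] = False
        assert np.abs(rec.signal[:, mask]).max() < 1e-12

    def test_zero_snr_is_pure_noise(self, events, static_emb):
        rec, ledger = syn.gen_neural_recording(
            events, static_emb, None, n_electrodes=4, fs=128, snr=0.0, seed=3
        )
        assert ledger.evoked_variance == 0.0
        np.testing.assert_allclose(rec.signal.std(axis=1), 1.0, atol=1e-6)

    def test_noise_spectrum_slope(self):
        rng = np.random.default_rng(0)
        noise = syn.one_over_f_noise(1, 2**16, fs=128.0, exponent=1.0, rng=rng)
        f, p = welch(noise[0], fs=128.0, nperseg=4096)
        sel = (f > 1) & (f < 50)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert abs(slope - (-1.0)) < 0.2

    def test_empirical_snr_close_to_requested(self):
        vocab = syn.gen_vocabulary(50, 1.0)
        ev = syn.gen_word_events(vocab, 1000, seed=4)
        emb = syn.gen_embeddings(ev, 16, "static", seed=5)
        rec, ledger = syn.gen_neural_recording(
            ev, emb, None, n_electrodes=8, fs=128, snr=2.0, seed=6
        )
        assert abs(ledger.evoked_variance / ledger.noise_variance - 2.0) < 0.2

    def test_embedding_shape_mismatch_rejected(self, events, vocab):
        short = syn.gen_embeddings(events.subset(np.arange(10)), 4, "static", seed=0)
        with pytest.raises(ValueError):
            syn.gen_neural_recording(events, short, None, n_electrodes=2, fs=128, seed=0)

    def test_same_seed_bit_identical(self, events, static_emb):
        a, _ = syn.gen_neural_recording(events, static_emb, None, n_electrodes=3, fs=128, snr=1, seed=9)
        b, _ = syn.gen_neural_recording(events, static_emb, None, n_electrodes=3, fs=128, snr=1, seed=9)
        np.testing.assert_array_equal(a.signal, b.signal)


class TestBehavioralResponses:
    def test_one_hot_distribution_gives_full_predictability(self, vocab):
        ev = syn.gen_word_events(vocab, 50, seed=0)
        n, V = len(ev), len(vocab)
        probs = np.zeros((n, V))
        probs[np.arange(n), ev.type_ids] = 1.0
        from neuroprose.types import PredictionSet

        dists = PredictionSet(probs, ev.type_ids.astype(int))
        table = syn.gen_behavioral_responses(ev, dists, vocab, n_raters=10, seed=1)
        scores = predictability_score(table, ev)
        np.testing.assert_allclose(scores, 1.0)

    def test_mean_score_matches_p_correct(self, vocab):
        ev = syn.gen_word_events(vocab, 300, seed=2)
        n, V = len(ev), len(vocab)
        p = 0.28
        probs = np.full((n, V), (1 - p) / (V - 1))
        probs[np.arange(n), ev.type_ids] = p
        from neuroprose.types import PredictionSet

        dists = PredictionSet(probs, ev.type_ids.astype(int))
        table = syn.gen_behavioral_responses(ev, dists, vocab, n_raters=50, seed=3)
        scores = predictability_score(table, ev)
        se = np.sqrt(p * (1 - p) / (50 * n))
        assert abs(scores.mean() - p) < 3 * se
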