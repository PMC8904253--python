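"""Significance procedures: surrogates, FDR, paired/bootstrap tests, coupling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroprose import synthetic as syn
from neuroprose.encoding import make_folds
from neuroprose.stats import (
    bh_fdr,
    bootstrap_mean_threshold,
    constrained_comparison,
    electrode_significance,
    entropy_surprise_coupling,
    paired_model_comparison,
    partial_correlation,
    phase_randomize,
    trigger_average,
)
from neuroprose.types import LagEncodingMap, LagKernel, NeuralRecording, PredictionSet


def _bh_oracle(p, q):
    """Brute-force BH step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k_star = 0
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            k_star = k
    reject = np.zeros(m, bool)
    reject[order[:k_star]] = True
    return reject


class TestPhaseRandomize:
    def test_amplitude_spectrum_preserved_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1024)
        s = phase_randomize(x, seed=1)
        a_in = np.abs(np.fft.rfft(x))
        a_out = np.abs(np.fft.rfft(s))
        np.testing.assert_allclose(a_out, a_in, rtol=1e-10)

    def test_parseval_total_power(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(999)  # odd length: no Nyquist bin
        s = phase_randomize(x, seed=2)
        np.testing.assert_allclose(np.sum(s**2), np.sum(x**2), rtol=1e-10)

    def test_constant_signal_unchanged(self):
        x = np.full(512, 3.0)
        s = phase_randomize(x, seed=3)
        np.testing.assert_allclose(s, x, atol=1e-10)

    def test_autocorrelation_preserved(self):
        # Wiener-Khinchin: same amplitude spectrum -> same autocorrelation
        rng = np.random.default_rng(2)
        n = 4096
        x = np.convolve(rng.standard_normal(n), np.ones(20) / 20, mode="same")
        s = phase_randomize(x, seed=4)

        def acf(v, k=50):
            v = v - v.mean()
            full = np.correlate(v, v, "full")[v.size - 1 : v.size - 1 + k]
            return full / full[0]

        assert np.abs(acf(x) - acf(s)).max() < 5 / np.sqrt(n)

    def test_surrogate_is_real_and_seeded(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((3, 256))
        a = phase_randomize(x, seed=7)
        b = phase_randomize(x, seed=7)
        np.testing.assert_array_equal(a, b)
        assert np.isrealobj(a)


class TestBHFDR:
    @given(
        st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20),
        st.sampled_from([0.01, 0.05, 0.1]),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_step_up(self, p, q):
        p = np.asarray(p)
        _, reject = bh_fdr(p, q)
        np.testing.assert_array_equal(reject, _bh_oracle(p, q))

    def test_exhaustive_small_grid(self):
        grid = [0.004, 0.02, 0.3, 0.9]
        from itertools import product

        for m in range(1, 5):
            for combo in product(grid, repeat=m):
                p = np.asarray(combo)
                _, reject = bh_fdr(p, 0.05)
                np.testing.assert_array_equal(reject, _bh_oracle(p, 0.05))


class TestElectrodeSignificance:
    def test_boundary_p_value_convention(self, vocab):
        # observed below every null maximum -> p = (k+1)/(n+1), never 0 or > 1
        ev = syn.gen_word_events(vocab, 80, mean_gap_s=0.25, seed=0)
        emb = syn.gen_embeddings(ev, 6, "static", seed=1)
        rec, _ = syn.gen_neural_recording(
            ev, emb, None, n_electrodes=4, fs=64.0, snr=0.0, seed=2
        )
        res = electrode_significance(
            rec, ev, emb, np.array([-100.0, 0.0, 100.0]), n_perm=100, seed=3
        )
        assert np.all(res.p > 0) and np.all(res.p <= 1)

    def test_planted_coupling_detected(self, vocab):
        ev = syn.gen_word_events(vocab, 150, mean_gap_s=0.25, seed=4)
        emb = syn.gen_embeddings(ev, 8, "static", seed=5)
        rec, _ = syn.gen_neural_recording(
            ev, emb, LagKernel.gaussian(150, 60), n_electrodes=10, fs=64.0,
            snr=2.0, seed=6,
        )
        res = electrode_significance(
            rec, ev, emb, np.arange(-100.0, 251.0, 50.0), n_perm=500, seed=7
        )
        assert res.significant.sum() >= 9

    def test_low_n_perm_warns(self, vocab):
        ev = syn.gen_word_events(vocab, 60, mean_gap_s=0.25, seed=8)
        emb = syn.gen_embeddings(ev, 4, "static", seed=9)
        rec, _ = syn.gen_neural_recording(
            ev, emb, None, n_electrodes=2, fs=64.0, snr=0.0, seed=10
        )
        with pytest.warns(UserWarning, match="n_perm"):
            electrode_significance(rec, ev, emb, np.array([0.0]), n_perm=50, seed=11)


class TestPairedComparison:
    def _map(self, r, lags=None):
        lags = np.arange(r.shape[1], dtype=float) if lags is None else lags
        return LagEncodingMap(r=r, lags_ms=lags, fold_assignment=np.zeros(1))

    def test_identical_maps_nothing_significant(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 0.5, size=(20, 8))
        res = paired_model_comparison(self._map(r), self._map(r.copy()), n_perm=500, seed=1)
        assert res["significant"].sum() == 0

    def test_constant_difference_forced_significant(self):
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 0.3, size=(160, 5))
        res = paired_model_comparison(
            self._map(base + 0.1), self._map(base), n_perm=2000, seed=2
        )
        assert res["significant"].all()
        assert np.all(res["p"] <= 1 / 1000)

    def test_null_calibration_flags_few_lags(self):
        rng = np.random.default_rng(2)
        n_sig = 0
        n_lags = 0
        for i in range(30):
            a = rng.normal(0, 0.1, size=(30, 20))
            b = rng.normal(0, 0.1, size=(30, 20))
            res = paired_model_comparison(
                self._map(a), self._map(b), n_perm=300, q=0.05, seed=i
            )
            n_sig += res["significant"].sum()
            n_lags += 20
        assert n_sig / n_lags <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_lags)

    def test_mismatched_grids_rejected(self):
        a = self._map(np.zeros((4, 3)))
        b = self._map(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            paired_model_comparison(a, b)


class TestBootstrapThreshold:
    def _map(self, r):
        return LagEncodingMap(
            r=r, lags_ms=np.arange(r.shape[1], dtype=float),
            fold_assignment=np.zeros(1),
        )

    def test_degenerate_identical_electrodes_significant(self):
        r = np.full((30, 4), 0.3)
        res = bootstrap_mean_threshold(self._map(r), n_boot=500, seed=0)
        assert res["significant"].all()

    def test_null_electrodes_rarely_flagged(self):
        rng = np.random.default_rng(1)
        flagged = 0
        total = 0
        for i in range(30):
            r = rng.normal(0, 0.1, size=(40, 10))
            res = bootstrap_mean_threshold(self._map(r), n_boot=300, q=0.05, seed=i)
            flagged += res["significant"].sum()
            total += 10
        # two-sided noise: at most ~half the lags have positive means, and of
        # those only ~q survive; generous bound
        assert flagged / total <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / total)

    def test_threshold_shrinks_with_electrode_count(self):
        rng = np.random.default_rng(2)
        thresholds = []
        for n in (10, 40, 160):
            r = rng.normal(0.2, 0.1, size=(n, 6))
            res = bootstrap_mean_threshold(self._map(r), n_boot=2000, seed=3)
            thresholds.append(res["threshold"].mean())
        assert thresholds[0] > thresholds[1] > thresholds[2]

    def test_single_electrode_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_mean_threshold(self._map(np.zeros((1, 3))))


class TestConstrainedComparison:
    def test_constraint_mask_limits_significance(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 0.05, size=(40, 10))
        a = base.copy()
        a[:, :5] += 0.3  # map A significant only at the first 5 lags
        b = base.copy()
        map_a = LagEncodingMap(r=a, lags_ms=np.arange(10.0), fold_assignment=np.zeros(1))
        map_b = LagEncodingMap(r=b, lags_ms=np.arange(10.0), fold_assignment=np.zeros(1))
        res = constrained_comparison(map_a, map_b, n_perm=500, seed=4)
        assert not res["significant"][~res["constraint_mask"]].any()
        assert res["significant"][:5].any()


class TestTriggerAverage:
    def test_identical_classes_identical_curves(self, recording, events):
        rec, _ = recording
        labels = np.zeros(len(events), dtype=int)
        labels[::2] = 1
        # identical responses in expectation; here use the same label twice
        series = trigger_average(rec, events, labels, np.array([0.0, 150.0]))
        assert set(series.class_means) == {0, 1}

    def test_planted_bump_on_one_class(self, vocab):
        ev = syn.gen_word_events(vocab, 400, mean_gap_s=0.4, seed=5)
        rng = np.random.default_rng(6)
        labels = (rng.random(len(ev)) < 0.5).astype(int)
        fs = 128.0
        n_samp = int((ev.df["offset_s"].max() + 3) * fs)
        sig = rng.standard_normal((6, n_samp)) * 0.1
        bump = np.exp(-0.5 * ((np.arange(-50, 51)) / 12.0) ** 2)
        for i in np.flatnonzero(labels == 1):
            c = int(ev.onsets[i] * fs) + int(0.4 * fs)  # bump at +400 ms
            sig[:, c - 50 : c + 51] += bump
        rec = NeuralRecording(sig, fs=fs, stage="smoothed")
        lags = np.arange(-200.0, 801.0, 100.0)
        series = trigger_average(rec, ev, labels, lags)
        diff = series.class_means[1] - series.class_means[0]
        assert lags[int(np.argmax(diff))] == 400.0

    def test_se_scales_with_electrode_count(self, vocab):
        ev = syn.gen_word_events(vocab, 200, mean_gap_s=0.3, seed=7)
        rng = np.random.default_rng(8)
        fs = 64.0
        n_samp = int((ev.df["offset_s"].max() + 3) * fs)
        ses = []
        for n_el in (5, 20, 80):
            sig = rng.standard_normal((n_el, n_samp))
            rec = NeuralRecording(sig, fs=fs, stage="smoothed")
            series = trigger_average(rec, ev, np.zeros(len(ev), int), np.array([0.0]))
            ses.append(series.class_se[0][0])
        assert ses[0] > ses[1] > ses[2]

    def test_empty_class_rejected(self, recording, events):
        rec, _ = recording
        labels = np.zeros(len(events), dtype=int)
        with pytest.raises(ValueError):
            trigger_average(rec, events, labels[:10], np.array([0.0]))


class TestPartialCorrelation:
    def test_independent_control_equals_simple_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(5000)
        y = x + 0.5 * rng.standard_normal(5000)
        z = rng.standard_normal(5000)
        # orthogonalize z against x and y so the control carries nothing
        z = z - np.polyval(np.polyfit(x, z, 1), x)
        z = z - np.polyval(np.polyfit(y, z, 1), y)
        simple = np.corrcoef(x, y)[0, 1]
        partial = partial_correlation(x, y, z)
        assert abs(partial - simple) < 1e-10 or abs(partial - simple) < 0.01

    def test_closed_form_on_known_gaussian(self):
        rng = np.random.default_rng(1)
        n = 2000
        z = rng.standard_normal(n)
        x = 0.6 * z + 0.8 * rng.standard_normal(n)
        y = 0.5 * z + 0.7 * rng.standard_normal(n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expected = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        np.testing.assert_allclose(partial_correlation(x, y, z), expected, atol=1e-10)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        n = 300
        z = rng.standard_normal(n)
        x = 0.4 * z + rng.standard_normal(n)
        y = -0.3 * z + rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        expected = pingouin.partial_corr(df, x="x", y="y", covar="z")["r"].iloc[0]
        np.testing.assert_allclose(partial_correlation(x, y, z), expected, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.ones(10), np.arange(10.0), np.arange(10.0))


class TestEntropySurpriseCoupling:
    def test_preonset_entropy_coupling_recovered(self, vocab):
        # brain whose pre-onset activity is proportional to -entropy
        ev = syn.gen_word_events(vocab, 500, mean_gap_s=0.4, seed=9)
        dists = syn.gen_prediction_distributions(
            ev, vocab, confidence=1.0, accuracy=0.6, seed=10
        )
        from neuroprose.prediction_measures import entropy

        ent = entropy(dists)
        rng = np.random.default_rng(11)
        fs = 64.0
        n_samp = int((ev.df["offset_s"].max() + 3) * fs)
        sig = 0.3 * rng.standard_normal((8, n_samp))
        width = int(0.2 * fs)
        for i in range(len(ev)):
            c = int(ev.onsets[i] * fs) - int(0.3 * fs)  # pre-onset window
            sig[:, c - width // 2 : c + width // 2] += -(ent[i] - ent.mean())
        rec = NeuralRecording(sig, fs=fs, stage="smoothed")
        series = entropy_surprise_coupling(
            rec, ev, dists, np.array([-300.0, 300.0])
        )
        assert series.partial_r_entropy[0] < -0.3
        assert abs(series.partial_r_entropy[1]) < 0.15
        assert series.q_entropy[0] < 0.01
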