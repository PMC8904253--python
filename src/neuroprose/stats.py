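"""Significance procedures and neural-behavioral coupling statistics.

Four inference procedures operate on encoding results:

* ``electrode_significance`` — phase-randomization surrogates with a
  max-over-lags, max-over-electrodes null distribution, FDR-corrected per
  electrode. Phase randomization preserves each electrode's amplitude
  spectrum (hence autocorrelation) while destroying its alignment to the
  word events.
* ``paired_model_comparison`` — per-lag sign-flip permutation test of the
  electrode-mean difference between two encoding maps.
* ``bootstrap_mean_threshold`` — per-lag bootstrap-shift test of the
  electrode-mean encoding value against zero.
* ``constrained_comparison`` — the paired test restricted to lags at which
  one map's own bootstrap test is significant.

``trigger_average`` and ``entropy_surprise_coupling`` relate event-locked
activity to prediction accuracy and to the confidence (entropy) / surprise
(cross-entropy) of a next-word probability model, the latter via partial
correlations.

All permutation p-values use the (k+1)/(n+1) convention and are never
exactly zero; FDR control is Benjamini-Hochberg throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .encoding import (
    CVLinearPredictor,
    WindowExtractor,
    default_lag_grid,
    extract_lagged_responses,
    make_folds,
    pearson_columns,
)
from .types import (
    CouplingSeries,
    EmbeddingMatrix,
    LagEncodingMap,
    NeuralRecording,
    PredictionSet,
    SignificanceResult,
    WordEventTable,
)

__all__ = [
    "phase_randomize",
    "bh_fdr",
    "electrode_significance",
    "paired_model_comparison",
    "bootstrap_mean_threshold",
    "constrained_comparison",
    "trigger_average",
    "partial_correlation",
    "entropy_surprise_coupling",
]


def phase_randomize(signal: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Surrogate with the exact amplitude spectrum but i.i.d. uniform phases.

    Works on a 1-D signal or an (electrodes x samples) array; each row gets
    independent phases. The DC bin keeps its original (real) value; for
    even lengths the Nyquist bin keeps its magnitude with a random sign, so
    conjugate symmetry holds and the surrogate is exactly real.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.asarray(signal, dtype=float)
    one_d = x.ndim == 1
    x2 = x[None, :] if one_d else x
    n = x2.shape[1]
    spec = np.fft.rfft(x2, axis=1)
    amp = np.abs(spec)
    nf = spec.shape[1]
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(x2.shape[0], nf))
    surrogate_spec = amp * np.exp(1j * phases)
    surrogate_spec[:, 0] = spec[:, 0]  # DC unchanged (real)
    if n % 2 == 0:
        signs = rng.choice([-1.0, 1.0], size=x2.shape[0])
        surrogate_spec[:, -1] = amp[:, -1] * signs  # Nyquist stays real
    out = np.fft.irfft(surrogate_spec, n=n, axis=1)
    return out[0] if one_d else out


def bh_fdr(p: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted q-values and the significant mask at level q."""
    p = np.asarray(p, dtype=float)
    reject, qvals, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return qvals, reject


def electrode_significance(
    rec: NeuralRecording,
    events: WordEventTable,
    emb: EmbeddingMatrix,
    lags_ms: np.ndarray | None = None,
    n_perm: int = 5000,
    q: float = 0.01,
    seed: int = 0,
    window_ms: float = 200.0,
    n_folds: int = 10,
    return_map: bool = False,
    perm_batch: int = 25,
):
    """Electrode-level significance of the lagged encoding map.

    For each of ``n_perm`` surrogates, every electrode's signal phase is
    randomized (independently per electrode), the entire lagged encoding
    procedure is re-run, the maximum encoding value across lags is retained
    per electrode, and the maximum across electrodes forms one null sample.
    Each electrode's p-value is the (k+1)/(n+1) percentile of its observed
    max-over-lags value in that pooled null; electrodes with BH-adjusted
    q-values below ``q`` are flagged significant.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse p-value resolution")
    if lags_ms is None:
        lags_ms = default_lag_grid()
    lags_ms = np.asarray(lags_ms, dtype=float)

    extractor = WindowExtractor(rec, events, lags_ms, window_ms)
    Y = extractor.apply(rec.signal)
    kept = extractor.kept
    n, E, L = Y.shape
    Xv = emb.vectors[kept]
    fold_assignment = make_folds(n, n_folds, seed)
    predictor = CVLinearPredictor(Xv, fold_assignment)

    preds = predictor.predict(Y)
    r_obs = pearson_columns(preds.reshape(n, -1), Y.reshape(n, -1)).reshape(E, L)
    obs_max = r_obs.max(axis=1)

    # Surrogates are processed in batches: B independently phase-randomized
    # copies of all electrodes are stacked as B*E signal rows, reduced to
    # lagged responses in one gather, and pushed through the shared
    # cross-validated linear maps in one matrix multiplication.
    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm)
    exceed = np.zeros(E, dtype=int)
    S = rec.n_samples
    spec = np.fft.rfft(rec.signal, axis=1)
    amp = np.abs(spec)
    nf = amp.shape[1]
    done = 0
    while done < n_perm:
        B = min(perm_batch, n_perm - done)
        # random unit phasors via normalized complex Gaussians
        g = rng.standard_normal((B, E, nf, 2))
        z = g[..., 0] + 1j * g[..., 1]
        z /= np.abs(z)
        surr_spec = amp[None, :, :] * z
        surr_spec[:, :, 0] = spec[None, :, 0]  # DC unchanged
        if S % 2 == 0:  # Nyquist stays real
            surr_spec[:, :, -1] = amp[None, :, -1] * np.sign(g[:, :, -1, 0])
        surrogate = np.fft.irfft(surr_spec.reshape(B * E, nf), n=S, axis=1)
        Yp = extractor.apply(surrogate)  # n x (B*E) x L
        predp = predictor.predict(Yp)
        rp = pearson_columns(
            predp.reshape(n, -1), Yp.reshape(n, -1)
        ).reshape(B, E, L)
        m = rp.max(axis=(1, 2))
        null_max[done : done + B] = m
        exceed += (m[:, None] >= obs_max[None, :]).sum(axis=0)
        done += B

    p = (exceed + 1) / (n_perm + 1)
    qvals, signif = bh_fdr(p, q)
    result = SignificanceResult(
        p=p, q=qvals, null_max=null_max, significant=signif,
        q_threshold=q, observed_max_r=obs_max,
    )
    if return_map:
        emap = LagEncodingMap(
            r=r_obs, lags_ms=lags_ms, fold_assignment=fold_assignment,
            electrode_ids=list(rec.electrode_ids),
        )
        return result, emap
    return result


def paired_model_comparison(
    map_a: LagEncodingMap,
    map_b: LagEncodingMap,
    n_perm: int = 5000,
    q: float = 0.01,
    seed: int = 0,
    two_sided: bool = True,
) -> dict:
    """Sign-flip permutation test of the per-lag electrode-mean difference A-B.

    Randomly swapping the two models' encoding values within an electrode
    flips the sign of that electrode's difference; the null distribution of
    the electrode-mean difference is built from random sign assignments.
    """
    if map_a.r.shape != map_b.r.shape or not np.array_equal(map_a.lags_ms, map_b.lags_ms):
        raise ValueError("encoding maps must share electrode set and lag grid")
    diff = map_a.r - map_b.r  # E x L
    E, L = diff.shape
    obs = diff.mean(axis=0)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, E))
    null = signs @ diff / E  # n_perm x L
    if two_sided:
        k = (np.abs(null) >= np.abs(obs)[None, :]).sum(axis=0)
    else:
        k = (null >= obs[None, :]).sum(axis=0)
    p = (k + 1) / (n_perm + 1)
    qvals, signif = bh_fdr(p, q)
    return {"lags_ms": map_a.lags_ms, "mean_diff": obs, "p": p, "q": qvals,
            "significant": signif, "null": null}


def bootstrap_mean_threshold(
    emap: LagEncodingMap,
    n_boot: int = 5000,
    q: float = 0.01,
    seed: int = 0,
) -> dict:
    """Bootstrap-shift test of the per-lag electrode-mean encoding value.

    Electrodes are resampled with replacement; the bootstrap distribution
    of the mean is shifted by the observed mean to form the null, and the
    p-value is the fraction of null samples at or above the observed mean
    ((k+1)/(n+1) convention). The per-lag threshold is the (1-q) quantile
    of the null plus the observed mean's null-centering, i.e. the smallest
    observed mean that would be significant before FDR correction.
    """
    r = emap.r
    E, L = r.shape
    if E < 2:
        raise ValueError("bootstrap needs >= 2 electrodes")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, E, size=(n_boot, E))
    boot_means = r[idx].mean(axis=1)  # n_boot x L
    obs = r.mean(axis=0)
    null = boot_means - obs[None, :]
    k = (null >= obs[None, :]).sum(axis=0)
    p = (k + 1) / (n_boot + 1)
    qvals, signif = bh_fdr(p, q)
    threshold = np.quantile(null, 1.0 - q, axis=0)
    return {"lags_ms": emap.lags_ms, "mean": obs, "p": p, "q": qvals,
            "significant": signif, "threshold": threshold}


def constrained_comparison(
    map_a: LagEncodingMap,
    map_b: LagEncodingMap,
    base: str = "bootstrap",
    n_perm: int = 5000,
    q: float = 0.01,
    seed: int = 0,
) -> dict:
    """Paired comparison constrained to lags where map_a is significant alone.

    The base test establishing map_a's own significance is either the
    bootstrap-shift test (default) or the sign-flip permutation test of
    map_a against a zero map.
    """
    if base == "bootstrap":
        own = bootstrap_mean_threshold(map_a, n_boot=n_perm, q=q, seed=seed)
    elif base == "permutation":
        zero = LagEncodingMap(
            r=np.zeros_like(map_a.r), lags_ms=map_a.lags_ms,
            fold_assignment=map_a.fold_assignment,
        )
        own = paired_model_comparison(map_a, zero, n_perm=n_perm, q=q, seed=seed)
    else:
        raise ValueError("base must be 'bootstrap' or 'permutation'")
    mask = own["significant"]
    paired = paired_model_comparison(map_a, map_b, n_perm=n_perm, q=q, seed=seed)
    constrained = paired["significant"] & mask
    return {**paired, "constraint_mask": mask, "significant": constrained}


def trigger_average(
    rec: NeuralRecording,
    events: WordEventTable,
    labels: np.ndarray,
    lags_ms: np.ndarray | None = None,
    window_ms: float = 200.0,
) -> CouplingSeries:
    """Event-locked mean activity per label class, with s.e. over electrodes.

    For each lag, responses are averaged over the events of a class per
    electrode, then summarized as mean +/- s.e. across electrodes.
    """
    if lags_ms is None:
        lags_ms = default_lag_grid()
    lags_ms = np.asarray(lags_ms, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != len(events):
        raise ValueError("labels must align with events")
    Y, kept = extract_lagged_responses(rec, events, lags_ms, window_ms, return_kept=True)
    labels = labels[kept]
    class_means, class_se = {}, {}
    for lab in np.unique(labels):
        mask = labels == lab
        if not mask.any():
            raise ValueError(f"empty class {lab!r}")
        per_electrode = Y[mask].mean(axis=0)  # E x L
        class_means[lab] = per_electrode.mean(axis=0)
        class_se[lab] = per_electrode.std(axis=0, ddof=1) / np.sqrt(per_electrode.shape[0])
    return CouplingSeries(lags_ms=lags_ms, class_means=class_means, class_se=class_se)


def partial_correlation(x: np.ndarray, y: np.ndarray, control: np.ndarray) -> float:
    """Partial Pearson correlation of x and y controlling for one covariate.

    Closed form: (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, control))
    for v in (x, y, z):
        if v.std() == 0:
            raise ValueError("zero-variance variable in partial correlation")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))


def _partial_columns(power: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Partial corr of each power column with a, controlling b (vectorized)."""
    r_xa = pearson_columns(power, np.tile(a[:, None], (1, power.shape[1])))
    r_xb = pearson_columns(power, np.tile(b[:, None], (1, power.shape[1])))
    r_ab = np.corrcoef(a, b)[0, 1]
    return (r_xa - r_xb * r_ab) / np.sqrt((1 - r_xb**2) * (1 - r_ab**2))


def entropy_surprise_coupling(
    rec: NeuralRecording,
    events: WordEventTable,
    dists: PredictionSet,
    lags_ms: np.ndarray | None = None,
    window_ms: float = 200.0,
    q: float = 0.01,
) -> CouplingSeries:
    """Per-lag partial correlations of signal power with confidence and surprise.

    For every lag and electrode, the event-wise power is partially
    correlated with the prediction entropy (controlling cross-entropy) and
    with the cross-entropy (controlling entropy); electrode means are
    reported per lag, with per-lag FDR flags from a one-sample t-test on
    Fisher-z transformed electrode coefficients.
    """
    from .prediction_measures import cross_entropy, entropy

    if lags_ms is None:
        lags_ms = default_lag_grid()
    lags_ms = np.asarray(lags_ms, dtype=float)
    ent = entropy(dists)
    xent = cross_entropy(dists)
    if ent.std() == 0 or xent.std() == 0:
        raise ValueError("zero-variance regressor")
    Y, kept = extract_lagged_responses(rec, events, lags_ms, window_ms, return_kept=True)
    ent, xent = ent[kept], xent[kept]
    n, E, L = Y.shape
    pr_ent = np.empty((E, L))
    pr_xent = np.empty((E, L))
    for li in range(L):
        power = Y[:, :, li]
        pr_ent[:, li] = _partial_columns(power, ent, xent)
        pr_xent[:, li] = _partial_columns(power, xent, ent)

    def lag_p(mat: np.ndarray) -> np.ndarray:
        z = np.arctanh(np.clip(mat, -0.999999, 0.999999))
        t = z.mean(axis=0) / (z.std(axis=0, ddof=1) / np.sqrt(E))
        return 2 * sps.t.sf(np.abs(t), df=E - 1)

    q_ent, _ = bh_fdr(lag_p(pr_ent), q)
    q_xent, _ = bh_fdr(lag_p(pr_xent), q)
    return CouplingSeries(
        lags_ms=lags_ms,
        partial_r_entropy=pr_ent.mean(axis=0),
        partial_r_cross_entropy=pr_xent.mean(axis=0),
        q_entropy=q_ent,
        q_cross_entropy=q_xent,
    )
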