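"""Embedding-space decoding of word identity from spatiotemporal windows.

The decoder maps a flattened electrodes x 10-bin window of neural activity
(ten 62.5-ms bins spanning 625 ms around onset+lag) to the word-embedding
space with a small feed-forward network trained on MSE. Word
classification is then performed entirely in embedding space: for each
unique word label, the cosine distance from the predicted embedding to
every instance of the label is averaged into one score (logit), scores
are softmax-transformed, and each label's one-vs-rest ROC-AUC is computed
and averaged weighted by test-set label frequency.

Cross-validation is temporal (five contiguous folds: three train, one
development for early stopping, one test), electrode selection is nested
inside the training portion, and an ensemble of independently initialized
decoders is averaged at the score level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPRegressor

from .encoding import extract_lagged_responses
from .stats import electrode_significance
from .types import DecodingResult, EmbeddingMatrix, NeuralRecording, WordEventTable

__all__ = [
    "bin_windows",
    "temporal_folds",
    "nested_electrode_selection",
    "DecoderConfig",
    "train_decoder",
    "ensemble_label_scores",
    "roc_auc_weighted",
    "run_decoding",
]

N_BINS = 10
BIN_MS = 62.5


def bin_windows(
    rec: NeuralRecording,
    events: WordEventTable,
    center_lag_ms: float,
    n_bins: int = N_BINS,
    bin_ms: float = BIN_MS,
    return_kept: bool = False,
):
    """Per-event electrodes x n_bins matrix of bin-mean activity.

    The window spans ``n_bins * bin_ms`` ms centered on onset+lag (625 ms
    by default; at 512 Hz each 62.5-ms bin holds 32 samples). Events whose
    window leaves the recording are dropped with a warning.
    """
    span = n_bins * bin_ms
    centers = center_lag_ms - span / 2 + bin_ms * (np.arange(n_bins) + 0.5)
    vals, kept = extract_lagged_responses(
        rec, events, centers, window_ms=bin_ms, return_kept=True
    )  # events x electrodes x n_bins
    if return_kept:
        return vals, kept
    return vals


def temporal_folds(n_events: int, n_folds: int = 5) -> list[dict]:
    """Contiguous temporal folds with rotating train/dev/test roles.

    Events (assumed ordered by onset) are split into ``n_folds`` contiguous
    near-equal blocks. Rotation ``i`` uses block ``i`` as test, block
    ``i+1`` (mod n) as development, and the rest for training; every event
    is in exactly one test fold across rotations.
    """
    if n_folds < 3:
        raise ValueError("need >= 3 folds for train/dev/test roles")
    blocks = np.array_split(np.arange(n_events), n_folds)
    configs = []
    for i in range(n_folds):
        dev_i = (i + 1) % n_folds
        train = np.concatenate(
            [blocks[j] for j in range(n_folds) if j not in (i, dev_i)]
        )
        configs.append({"train": train, "dev": blocks[dev_i], "test": blocks[i]})
    return configs


def nested_electrode_selection(
    rec: NeuralRecording,
    events: WordEventTable,
    emb: EmbeddingMatrix,
    fold: dict,
    lags_ms: np.ndarray,
    n_perm: int = 200,
    q: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Significant-encoding electrodes chosen on train+dev data only.

    Runs the phase-randomization max-statistic significance procedure on
    the 80% of events not in the test fold; returns the indices of
    electrodes flagged at the FDR threshold.
    """
    keep = np.sort(np.concatenate([fold["train"], fold["dev"]]))
    sub_events = events.subset(keep)
    sub_emb = EmbeddingMatrix(emb.vectors[keep], kind="derived", note="selection")
    result = electrode_significance(
        rec, sub_events, sub_emb, lags_ms=lags_ms, n_perm=n_perm, q=q, seed=seed
    )
    selected = np.flatnonzero(result.significant)
    if selected.size == 0:
        raise ValueError(
            "no electrode passed the nested selection; lower q, increase SNR, "
            "or pass an explicit electrode subset"
        )
    return selected


@dataclass
class DecoderConfig:
    """Architecture and optimization settings for the feed-forward decoder."""

    hidden: tuple[int, ...] = (256, 128)
    max_epochs: int = 300
    patience: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    alpha: float = 1e-4  # L2 penalty


def train_decoder(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_dev: np.ndarray,
    Y_dev: np.ndarray,
    config: DecoderConfig | None = None,
    seed: int = 0,
) -> MLPRegressor:
    """MSE-trained MLP with explicit dev-set early stopping.

    One ``partial_fit`` pass per epoch; training stops when the development
    MSE has not improved for ``patience`` epochs and the best-dev weights
    are restored. Identical seeds give identical training trajectories.
    """
    if config is None:
        config = DecoderConfig()
    X_train = np.asarray(X_train, float).reshape(X_train.shape[0], -1)
    X_dev = np.asarray(X_dev, float).reshape(X_dev.shape[0], -1)
    net = MLPRegressor(
        hidden_layer_sizes=config.hidden,
        batch_size=min(config.batch_size, X_train.shape[0]),
        learning_rate_init=config.learning_rate,
        alpha=config.alpha,
        random_state=seed,
        max_iter=1,
        shuffle=True,
        warm_start=False,
    )
    best_mse = np.inf
    best_params = None
    stale = 0
    for _epoch in range(config.max_epochs):
        net.partial_fit(X_train, Y_train)
        if not np.all(np.isfinite(net.coefs_[0])):
            raise RuntimeError(f"decoder training diverged (seed={seed})")
        mse = float(np.mean((net.predict(X_dev) - Y_dev) ** 2))
        if mse < best_mse - 1e-12:
            best_mse = mse
            best_params = (
                [c.copy() for c in net.coefs_],
                [b.copy() for b in net.intercepts_],
            )
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_params is not None:
        net.coefs_, net.intercepts_ = best_params
    return net


def _cosine_distance(pred: np.ndarray, refs: np.ndarray) -> np.ndarray:
    """Cosine distances from each predicted vector to each reference vector.

    A zero-norm predicted vector is maximally distant (2.0) from everything.
    """
    pn = np.linalg.norm(pred, axis=1, keepdims=True)
    rn = np.linalg.norm(refs, axis=1, keepdims=True)
    zero_pred = pn[:, 0] == 0
    if zero_pred.any():
        warnings.warn("zero-norm predicted embedding; distance set to maximum (2.0)")
    pn[pn == 0] = 1.0
    rn[rn == 0] = 1.0
    sims = (pred / pn) @ (refs / rn).T
    dist = 1.0 - sims
    dist[zero_pred] = 2.0
    return dist


def ensemble_label_scores(
    decoders: list[MLPRegressor],
    X_test: np.ndarray,
    label_instances: dict[int, np.ndarray],
) -> tuple[np.ndarray, list[int]]:
    """Per-event softmax label probabilities from an ensemble of decoders.

    For each decoder: predict an embedding per test event, compute the
    cosine distance to every instance of each label, average over instances
    (one value per label), and negate to a score. Scores are averaged over
    ensemble members and softmax-transformed across labels.

    Returns (events x labels probabilities, label order).
    """
    if not decoders:
        raise ValueError("need at least one decoder")
    labels = sorted(label_instances)
    Xf = np.asarray(X_test, float).reshape(X_test.shape[0], -1)
    scores = np.zeros((Xf.shape[0], len(labels)))
    for net in decoders:
        pred = net.predict(Xf)
        for j, lab in enumerate(labels):
            d = _cosine_distance(pred, np.atleast_2d(label_instances[lab]))
            scores[:, j] += -d.mean(axis=1)
    scores /= len(decoders)
    shifted = scores - scores.max(axis=1, keepdims=True)
    probs = np.exp(shifted)
    probs /= probs.sum(axis=1, keepdims=True)
    return probs, labels


def roc_auc_weighted(
    scores: np.ndarray,
    score_labels: list[int],
    true_labels: np.ndarray,
) -> tuple[float, dict[int, float], dict[int, float]]:
    """Frequency-weighted mean of per-label one-vs-rest ROC-AUCs.

    Each label with at least one positive and one negative test instance
    gets a rank-based AUC from its score column; labels with no positives
    are excluded with a warning. Weights are the scored labels' test-set
    frequencies, normalized to sum to 1.
    """
    true_labels = np.asarray(true_labels)
    per_label: dict[int, float] = {}
    weights: dict[int, float] = {}
    for j, lab in enumerate(score_labels):
        pos = true_labels == lab
        if pos.sum() == 0:
            warnings.warn(f"label {lab} has no positive test instances; excluded")
            continue
        if pos.all():
            warnings.warn(f"label {lab} has no negative test instances; excluded")
            continue
        per_label[lab] = float(roc_auc_score(pos, scores[:, j]))
        weights[lab] = float(pos.sum())
    if not per_label:
        raise ValueError("no label had both positive and negative instances")
    total = sum(weights.values())
    weights = {k: v / total for k, v in weights.items()}
    weighted = float(sum(per_label[k] * weights[k] for k in per_label))
    return weighted, per_label, weights


def run_decoding(
    rec: NeuralRecording,
    events: WordEventTable,
    emb: EmbeddingMatrix,
    lags_ms: np.ndarray,
    n_folds: int = 5,
    ensemble: int = 10,
    min_repetitions: int = 5,
    config: DecoderConfig | None = None,
    seed: int = 0,
    electrodes: np.ndarray | None = None,
    selection_lags_ms: np.ndarray | None = None,
    selection_n_perm: int = 200,
) -> DecodingResult:
    """Full decoding pipeline across lags.

    Per lag and temporal fold: (optionally) select electrodes on the
    train+dev portion, train ``ensemble`` decoders with distinct
    initializations, score the test events against all eligible labels
    (>= ``min_repetitions`` training-set occurrences), and compute the
    frequency-weighted ROC-AUC. Per-lag AUC is the mean over test folds
    with its s.e.
    """
    lags_ms = np.atleast_1d(np.asarray(lags_ms, dtype=float))
    type_ids = events.type_ids
    aucs = np.zeros(lags_ms.size)
    ses = np.zeros(lags_ms.size)
    per_label_all = []
    fold_sizes = []
    for li, lag in enumerate(lags_ms):
        X, kept = bin_windows(rec, events, lag, return_kept=True)
        labels_kept = type_ids[kept]
        Yemb = emb.vectors[kept]
        folds = temporal_folds(X.shape[0], n_folds)
        fold_aucs = []
        lag_labels: dict[int, list[float]] = {}
        for fi, fold in enumerate(folds):
            if electrodes is None:
                sel = nested_electrode_selection(
                    rec, events.subset(kept), EmbeddingMatrix(Yemb, "derived"),
                    fold, selection_lags_ms if selection_lags_ms is not None else lags_ms,
                    n_perm=selection_n_perm, seed=seed + fi,
                )
            else:
                sel = np.asarray(electrodes)
            tr, dv, te = fold["train"], fold["dev"], fold["test"]
            train_counts = np.bincount(labels_kept[tr], minlength=type_ids.max() + 1)
            eligible = np.flatnonzero(train_counts >= min_repetitions)
            label_instances = {
                int(lab): Yemb[tr][labels_kept[tr] == lab] for lab in eligible
            }
            nets = [
                train_decoder(
                    X[tr][:, sel, :], Yemb[tr], X[dv][:, sel, :], Yemb[dv],
                    config=config, seed=seed * 1000 + fi * 10 + m,
                )
                for m in range(ensemble)
            ]
            probs, label_order = ensemble_label_scores(
                nets, X[te][:, sel, :], label_instances
            )
            try:
                w_auc, per_label, _ = roc_auc_weighted(probs, label_order, labels_kept[te])
            except ValueError:
                continue  # no scorable label in this test fold
            fold_aucs.append(w_auc)
            for lab, a in per_label.items():
                lag_labels.setdefault(lab, []).append(a)
            if li == 0:
                fold_sizes.append(len(tr))
        fold_aucs = np.asarray(fold_aucs)
        aucs[li] = fold_aucs.mean() if fold_aucs.size else np.nan
        ses[li] = (
            fold_aucs.std(ddof=1) / np.sqrt(fold_aucs.size) if fold_aucs.size > 1 else np.nan
        )
        per_label_all.append({k: float(np.mean(v)) for k, v in lag_labels.items()})
    return DecodingResult(
        lags_ms=lags_ms,
        weighted_auc=aucs,
        auc_se=ses,
        per_label_auc=per_label_all,
        fold_sizes=fold_sizes,
        ensemble_size=ensemble,
    )
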