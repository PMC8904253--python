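"""Lagged linear encoding: embeddings -> word-aligned neural responses.

For each electrode and each lag relative to word onset, the neural signal
is averaged over a 200-ms window centered on onset+lag; an ordinary
least-squares model (with intercept) maps embedding vectors to those
responses under tenfold cross-validation, and performance is the Pearson
correlation between concatenated held-out predictions and the actual
responses. The full procedure is repeated on a grid of lags (by default
161 lags, -2000..2000 ms in 25-ms steps).

The cross-validated OLS predictions depend on the design matrix and fold
assignment only through per-fold linear maps (test rows of the hat
matrix); :class:`CVLinearPredictor` precomputes those maps once so that
permutation procedures can re-predict thousands of surrogate response
matrices at matrix-multiplication cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .types import EmbeddingMatrix, LagEncodingMap, NeuralRecording, WordEventTable

__all__ = [
    "default_lag_grid",
    "WindowExtractor",
    "extract_lagged_responses",
    "make_folds",
    "CVLinearPredictor",
    "fit_encoding_cv",
    "encode_all_lags",
    "encode_by_prediction_split",
    "pearson_columns",
]

WINDOW_MS = 200.0


def default_lag_grid(start_ms: float = -2000.0, stop_ms: float = 2000.0, step_ms: float = 25.0) -> np.ndarray:
    """The standard lag grid: 161 lags from -2000 to 2000 ms in 25-ms steps."""
    n = int(round((stop_ms - start_ms) / step_ms)) + 1
    return start_ms + step_ms * np.arange(n)


def _window_bounds(
    rec: NeuralRecording, events: WordEventTable, lags_ms: np.ndarray, window_ms: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Start/stop sample indices (events x lags) plus the in-range event mask."""
    fs = rec.fs
    onset_idx = np.round(events.onsets * fs).astype(int)
    lag_samp = np.round(np.asarray(lags_ms) * fs / 1000.0).astype(int)
    half = int(round(window_ms / 2.0 * fs / 1000.0))
    centers = onset_idx[:, None] + lag_samp[None, :]
    starts = centers - half
    stops = centers + half  # [start, stop) -> 2*half samples
    ok = (starts.min(axis=1) >= 0) & (stops.max(axis=1) <= rec.n_samples)
    return starts, stops, ok


class WindowExtractor:
    """Precomputed window geometry for repeated response extraction.

    Stores the per-event, per-lag window bounds once so that surrogate
    signals (e.g. phase-randomized permutations, possibly stacked as
    ``n_perm * electrodes`` rows) can be reduced to lagged response
    matrices with a single cumulative-sum and gather.
    """

    def __init__(
        self,
        rec: NeuralRecording,
        events: WordEventTable,
        lags_ms: np.ndarray,
        window_ms: float = WINDOW_MS,
    ):
        lags = np.atleast_1d(np.asarray(lags_ms, dtype=float))
        starts, stops, ok = _window_bounds(rec, events, lags, window_ms)
        if not ok.all():
            warnings.warn(
                f"{int((~ok).sum())} events dropped: response window outside recording"
            )
        self.kept = np.flatnonzero(ok)
        self.starts = starts[self.kept]
        self.stops = stops[self.kept]
        self.n_samples = rec.n_samples
        self.n_lags = lags.size

    def apply(self, signal: np.ndarray) -> np.ndarray:
        """(rows x samples) signal -> (events x rows x lags) window means."""
        signal = np.atleast_2d(signal)
        csum = np.concatenate(
            [np.zeros((signal.shape[0], 1)), np.cumsum(signal, axis=1)], axis=1
        )
        width = self.stops - self.starts
        sums = csum[:, self.stops] - csum[:, self.starts]  # rows x events x lags
        return np.moveaxis(sums / width[None, :, :], 0, 1)


def extract_lagged_responses(
    rec: NeuralRecording,
    events: WordEventTable,
    lags_ms: float | np.ndarray,
    window_ms: float = WINDOW_MS,
    return_kept: bool = False,
):
    """Window-averaged responses per event, electrode and lag.

    For each event the signal is averaged over
    ``[onset + lag - window/2, onset + lag + window/2)``. Events whose
    window falls outside the recording at any requested lag are dropped
    (with a warning) so that rows align across the whole lag grid.

    Returns ``values`` with shape (events, electrodes) for a scalar lag or
    (events, electrodes, lags) for a grid; with ``return_kept=True`` also
    returns the indices of retained events.
    """
    scalar = np.isscalar(lags_ms)
    extractor = WindowExtractor(rec, events, lags_ms, window_ms)
    values = extractor.apply(rec.signal)
    if scalar:
        values = values[:, :, 0]
    if return_kept:
        return values, extractor.kept
    return values


def make_folds(n_events: int, n_folds: int = 10, seed: int = 0, contiguous: bool = False) -> np.ndarray:
    """Fold assignment per event: uniform random (default) or contiguous blocks."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n_events:
        raise ValueError("more folds than events")
    base = np.repeat(np.arange(n_folds), int(np.ceil(n_events / n_folds)))[:n_events]
    if contiguous:
        return np.sort(base)
    rng = np.random.default_rng(seed)
    return rng.permutation(np.sort(base))


class CVLinearPredictor:
    """Cross-validated OLS as a set of per-fold linear prediction maps.

    For fold ``f`` with training rows ``T_f`` and test rows ``S_f`` and the
    intercept-augmented design ``X``, held-out predictions are
    ``X[S_f] @ pinv(X[T_f]) @ Y[T_f]`` (minimum-norm on rank deficiency).
    Since the map does not depend on ``Y``, it is computed once and applied
    to arbitrary response matrices — the workhorse of the phase-randomization
    significance test.
    """

    def __init__(self, X: np.ndarray, fold_assignment: np.ndarray):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        fold_assignment = np.asarray(fold_assignment)
        if fold_assignment.shape[0] != n:
            raise ValueError("fold assignment must align with design rows")
        Xa = np.column_stack([np.ones(n), X])
        self.fold_assignment = fold_assignment
        self.n_events = n
        self._maps: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        self._pinvs: list[np.ndarray] = []
        for f in np.unique(fold_assignment):
            test = np.flatnonzero(fold_assignment == f)
            train = np.flatnonzero(fold_assignment != f)
            if train.size < Xa.shape[1]:
                warnings.warn("rank-deficient training design; minimum-norm solution")
            pinv_tr = np.linalg.pinv(Xa[train])
            self._pinvs.append(pinv_tr)
            self._maps.append((test, train, Xa[test] @ pinv_tr))

    def predict(self, Y: np.ndarray) -> np.ndarray:
        """Held-out predictions, same shape as ``Y`` (events x anything)."""
        Y = np.asarray(Y, dtype=float)
        flat = Y.reshape(Y.shape[0], -1)
        out = np.empty_like(flat)
        for test, train, T in self._maps:
            out[test] = T @ flat[train]
        return out.reshape(Y.shape)

    def fold_weights(self, Y: np.ndarray) -> list[np.ndarray]:
        """Per-fold OLS coefficients (intercept row first)."""
        flat = np.asarray(Y, dtype=float).reshape(Y.shape[0], -1)
        return [
            pinv_tr @ flat[train]
            for pinv_tr, (_, train, _) in zip(self._pinvs, self._maps)
        ]


def pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise Pearson correlation of two equally shaped 2-D arrays."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    denom = np.sqrt((a**2).sum(axis=0) * (b**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(denom > 0, r, 0.0)


def fit_encoding_cv(
    X: EmbeddingMatrix | np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
):
    """Tenfold cross-validated OLS encoding of one lagged response matrix.

    ``y`` is events x electrodes. Returns ``(r, predictions,
    fold_assignment)`` where ``r`` holds one held-out Pearson correlation
    per electrode, computed over the concatenated held-out predictions of
    all folds.
    """
    Xv = X.vectors if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    y2 = y[:, None] if y.ndim == 1 else y
    if y2.shape[0] != Xv.shape[0]:
        raise ValueError("X rows must align with y rows")
    if Xv.shape[0] < Xv.shape[1] + n_folds:
        raise ValueError("need at least dims + n_folds events")
    if fold_assignment is None:
        fold_assignment = make_folds(Xv.shape[0], n_folds, seed)
    predictor = CVLinearPredictor(Xv, fold_assignment)
    preds = predictor.predict(y2)
    r = pearson_columns(preds, y2)
    if y.ndim == 1:
        return r[0], preds[:, 0], fold_assignment
    return r, preds, fold_assignment


def encode_all_lags(
    rec: NeuralRecording,
    events: WordEventTable,
    emb: EmbeddingMatrix,
    lags_ms: np.ndarray | None = None,
    window_ms: float = WINDOW_MS,
    n_folds: int = 10,
    seed: int = 0,
    fold_assignment: np.ndarray | None = None,
) -> LagEncodingMap:
    """Electrodes x lags held-out encoding correlations.

    One fold assignment is drawn (seeded) and shared across all lags and
    electrodes. Events whose windows leave the recording at any lag are
    dropped from every lag to keep rows aligned.
    """
    if lags_ms is None:
        lags_ms = default_lag_grid()
    lags_ms = np.asarray(lags_ms, dtype=float)
    Y, kept = extract_lagged_responses(
        rec, events, lags_ms, window_ms, return_kept=True
    )  # events x electrodes x lags
    Xv = emb.vectors[kept]
    if fold_assignment is None:
        fold_assignment = make_folds(Xv.shape[0], n_folds, seed)
    predictor = CVLinearPredictor(Xv, fold_assignment)
    preds = predictor.predict(Y)
    n, E, L = Y.shape
    r = pearson_columns(preds.reshape(n, E * L), Y.reshape(n, E * L)).reshape(E, L)
    return LagEncodingMap(
        r=r,
        lags_ms=lags_ms,
        fold_assignment=fold_assignment,
        electrode_ids=list(rec.electrode_ids),
    )


@dataclass
class PredictionSplitMaps:
    """Encoding maps for the correct/incorrect prediction split."""

    correct_perceived: LagEncodingMap
    incorrect_predicted: LagEncodingMap
    incorrect_perceived: LagEncodingMap


def encode_by_prediction_split(
    rec: NeuralRecording,
    events: WordEventTable,
    emb_predicted: EmbeddingMatrix,
    emb_perceived: EmbeddingMatrix,
    correct: np.ndarray,
    lags_ms: np.ndarray | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> PredictionSplitMaps:
    """Three encoding maps conditioned on prediction accuracy.

    (1) correctly predicted words modeled with the perceived-word embedding;
    (2) incorrectly predicted words modeled with the predicted-word
    embedding; (3) the same incorrect words modeled with the perceived-word
    embedding.
    """
    correct = np.asarray(correct, dtype=bool)
    if correct.shape[0] != len(events):
        raise ValueError("split labels must cover all events")
    maps = {}
    for name, mask, emb in (
        ("correct_perceived", correct, emb_perceived),
        ("incorrect_predicted", ~correct, emb_predicted),
        ("incorrect_perceived", ~correct, emb_perceived),
    ):
        idx = np.flatnonzero(mask)
        if idx.size < emb.dim + n_folds:
            raise ValueError(
                f"split class {name!r} has too few events ({idx.size}) for "
                f"{emb.dim}-dim embeddings with {n_folds} folds"
            )
        sub_events = events.subset(idx)
        sub_emb = EmbeddingMatrix(emb.vectors[idx], kind="derived", note=name)
        maps[name] = encode_all_lags(
            rec, sub_events, sub_emb, lags_ms, n_folds=n_folds, seed=seed
        )
    return PredictionSplitMaps(**maps)
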