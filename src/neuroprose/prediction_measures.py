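"""Behavioral and model-based word-prediction measures.

Covers the behavioral predictability score (fraction of raters guessing
the next word), the confidence and surprise of a probabilistic next-word
model (entropy and cross-entropy, in nats by default), top-k accuracy
splits, calibration curves, cross-predictor agreement, context-window
sweeps, and count-based n-gram baselines with MLE or add-k smoothing.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter, defaultdict
from typing import Callable, Sequence

import numpy as np

from .types import BehavioralTable, PredictionSet, WordEventTable

__all__ = [
    "normalize_token",
    "predictability_score",
    "entropy",
    "cross_entropy",
    "accuracy_split",
    "calibration_curve",
    "agreement_rate",
    "context_window_sweep",
    "NGramModel",
]

_PUNCT = re.compile(r"[^\w\s]|_")


def normalize_token(token: str) -> str:
    """Case-fold and strip punctuation/whitespace for guess matching."""
    return _PUNCT.sub("", str(token)).strip().lower()


def predictability_score(table: BehavioralTable, events: WordEventTable) -> np.ndarray:
    """Per-event fraction of raters whose (normalized) guess is the actual word.

    1.0 means every rater correctly guessed the upcoming word; 0.0 means
    none did.
    """
    if table.n_raters == 0:
        raise ValueError("behavioral table has no raters")
    if table.n_events != len(events):
        raise ValueError("guesses not aligned to events")
    actual = np.array([normalize_token(t) for t in events.tokens], dtype=object)
    norm = np.vectorize(normalize_token, otypes=[object])(table.guesses)
    return (norm == actual[None, :]).mean(axis=0)


def _as_probs(dist: PredictionSet | np.ndarray) -> np.ndarray:
    if isinstance(dist, PredictionSet):
        return dist.probs
    p = np.atleast_2d(np.asarray(dist, dtype=float))
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    return p


def entropy(dist: PredictionSet | np.ndarray, base: str = "nats") -> np.ndarray | float:
    """Prediction confidence: H = -sum_i p_i log p_i, with 0 log 0 := 0.

    Low entropy means a confident (peaked) next-word distribution; the
    maximum, log n, is attained by the uniform distribution. ``base='bits'``
    uses log2.
    """
    p = _as_probs(dist)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=1)
    if base == "bits":
        h = h / np.log(2.0)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return h if isinstance(dist, PredictionSet) or np.asarray(dist).ndim == 2 else float(h[0])


def cross_entropy(
    dists: PredictionSet,
    clamp: bool = False,
    eps: float = 1e-10,
    base: str = "nats",
) -> np.ndarray:
    """Surprise of the actually spoken word: -log P(x_actual).

    The lower the probability assigned to the actual word before its
    onset, the higher the surprise. Zero probabilities raise unless
    ``clamp`` replaces them by ``eps`` (with a warning).
    """
    p_act = dists.p_actual
    if np.any(p_act <= 0):
        if not clamp:
            raise ValueError("P(actual) = 0 for some events; enable clamp")
        warnings.warn(f"clamping {(p_act <= 0).sum()} zero probabilities to {eps}")
        p_act = np.maximum(p_act, eps)
    ce = -np.log(p_act)
    if base == "bits":
        ce = ce / np.log(2.0)
    elif base != "nats":
        raise ValueError("base must be 'nats' or 'bits'")
    return ce


def accuracy_split(dists: PredictionSet, k: int = 5) -> np.ndarray:
    """Boolean per-event label: actual word among the model's top-k.

    Ties in probability are broken by vocabulary index (lower index wins),
    making the split deterministic.
    """
    if k > dists.n_vocab:
        raise ValueError("k exceeds vocabulary size")
    # lexsort: primary descending probability, secondary ascending index
    order = np.argsort(-dists.probs, axis=1, kind="stable")
    topk = order[:, :k]
    return (topk == dists.actual_index[:, None]).any(axis=1)


def calibration_curve(
    assigned_prob: np.ndarray,
    correct: np.ndarray,
    bin_edges: np.ndarray | None = None,
) -> dict:
    """Assigned probability vs realized top-1 accuracy per probability bin.

    Empty bins are reported as NaN accuracy with zero count, not as zero
    accuracy. A well-calibrated predictor's curve lies on the diagonal.
    """
    assigned_prob = np.asarray(assigned_prob, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if np.any((assigned_prob < 0) | (assigned_prob > 1)):
        raise ValueError("assigned probabilities must lie in [0, 1]")
    if bin_edges is None:
        bin_edges = np.linspace(0.0, 1.0, 11)
    bin_edges = np.asarray(bin_edges, dtype=float)
    idx = np.clip(np.digitize(assigned_prob, bin_edges) - 1, 0, bin_edges.size - 2)
    n_bins = bin_edges.size - 1
    counts = np.bincount(idx, minlength=n_bins)
    acc = np.full(n_bins, np.nan)
    mean_p = np.full(n_bins, np.nan)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            acc[b] = correct[mask].mean()
            mean_p[b] = assigned_prob[mask].mean()
    return {"bin_edges": bin_edges, "accuracy": acc, "mean_prob": mean_p, "count": counts}


def agreement_rate(
    top_a: Sequence[str],
    top_b: Sequence[str],
    correct_a: np.ndarray,
    correct_b: np.ndarray,
) -> dict:
    """Match rate of two predictors' top guesses plus joint-accuracy quadrants.

    Returns the fraction of events where the two top predictions match
    (irrespective of accuracy) and the fractions jointly correct, jointly
    incorrect, and discordant (summing to 1).
    """
    top_a, top_b = np.asarray(top_a, dtype=object), np.asarray(top_b, dtype=object)
    correct_a, correct_b = np.asarray(correct_a, bool), np.asarray(correct_b, bool)
    if not (len(top_a) == len(top_b) == len(correct_a) == len(correct_b)):
        raise ValueError("inputs must have equal length")
    norm = np.vectorize(normalize_token, otypes=[object])
    match = (norm(top_a) == norm(top_b)).mean()
    both = (correct_a & correct_b).mean()
    neither = (~correct_a & ~correct_b).mean()
    discordant = 1.0 - both - neither
    return {
        "agreement": float(match),
        "joint_correct": float(both),
        "joint_incorrect": float(neither),
        "discordant": float(discordant),
    }


def context_window_sweep(
    predictor: Callable[[Sequence[str], str], float],
    events: WordEventTable,
    behavioral_scores: np.ndarray,
    window_sizes: Sequence[int] = (2, 4, 8, 16, 32),
) -> dict:
    """Correlation of predictor probabilities with behavioral predictability.

    ``predictor(history_tokens, actual_token)`` returns the probability it
    assigns to the actual word given the trailing context window; windows
    larger than the available history use the full history. Events for
    which the predictor raises are skipped (logged in the result).
    """
    tokens = list(events.tokens)
    scores = np.asarray(behavioral_scores, dtype=float)
    out_sizes, out_r, skipped = [], [], []
    for w in window_sizes:
        probs = np.full(len(tokens), np.nan)
        n_skipped = 0
        for i, tok in enumerate(tokens):
            history = tokens[max(0, i - w) : i]
            try:
                probs[i] = predictor(history, tok)
            except Exception:
                n_skipped += 1
        ok = ~np.isnan(probs)
        if ok.sum() > 2 and probs[ok].std() > 0 and scores[ok].std() > 0:
            r = float(np.corrcoef(probs[ok], scores[ok])[0, 1])
        else:
            r = np.nan
        out_sizes.append(int(w))
        out_r.append(r)
        skipped.append(n_skipped)
    return {"window_sizes": out_sizes, "r": out_r, "skipped": skipped}


class NGramModel:
    """Count-based n-gram next-word model with MLE or add-k smoothing.

    The corpus is normalized (lowercased, punctuation removed) before
    counting. ``prob(history, word)`` conditions on the last ``order - 1``
    normalized tokens: MLE gives c(h, w)/c(h) (0 for an unseen history,
    flagged); add-k gives (c(h, w) + k) / (c(h) + k * V).
    """

    def __init__(
        self,
        corpus_tokens: Sequence[str],
        order: int = 2,
        smoothing: str = "mle",
        k: float = 1.0,
    ):
        if not 2 <= order <= 5:
            raise ValueError("order must be between 2 and 5")
        if smoothing not in ("mle", "add_k"):
            raise ValueError("smoothing must be 'mle' or 'add_k'")
        tokens = [normalize_token(t) for t in corpus_tokens]
        tokens = [t for t in tokens if t]
        if not tokens:
            raise ValueError("corpus is empty after normalization")
        self.order = order
        self.smoothing = smoothing
        self.k = float(k)
        self.vocab = sorted(set(tokens))
        self.V = len(self.vocab)
        self._ngram: Counter = Counter()
        self._hist: Counter = Counter()
        for i in range(len(tokens) - order + 1):
            h = tuple(tokens[i : i + order - 1])
            w = tokens[i + order - 1]
            self._ngram[(h, w)] += 1
            self._hist[h] += 1

    def prob(self, history: Sequence[str], word: str) -> tuple[float, bool]:
        """(probability, seen_history) for the word given trailing history."""
        h = tuple(normalize_token(t) for t in history)[-(self.order - 1):]
        w = normalize_token(word)
        c_h = self._hist.get(h, 0)
        c_hw = self._ngram.get((h, w), 0)
        if self.smoothing == "mle":
            if c_h == 0:
                return 0.0, False
            return c_hw / c_h, True
        return (c_hw + self.k) / (c_h + self.k * self.V), c_h > 0

    def event_probs(self, tokens: Sequence[str]) -> np.ndarray:
        """Probability of each token in a sequence given its preceding context."""
        toks = [normalize_token(t) for t in tokens]
        out = np.zeros(len(toks))
        for i in range(len(toks)):
            hist = toks[max(0, i - self.order + 1) : i]
            if len(hist) < self.order - 1:
                out[i] = np.nan  # not enough context
            else:
                out[i] = self.prob(hist, toks[i])[0]
        return out
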