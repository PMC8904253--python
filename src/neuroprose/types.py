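"""Core in-memory containers shared across the pipeline.

The containers are thin dataclasses around numpy arrays / pandas frames:
a vocabulary with relative type frequencies, a word-event table aligned to
a recording, embedding matrices tagged by kind, multi-electrode recordings
tagged by preprocessing stage, next-word prediction distributions, and the
result objects produced by the encoding, statistics and decoding stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Vocabulary",
    "WordEventTable",
    "EmbeddingMatrix",
    "NeuralRecording",
    "LagKernel",
    "GroundTruthLedger",
    "PredictionSet",
    "BehavioralTable",
    "LagEncodingMap",
    "SignificanceResult",
    "CouplingSeries",
    "DecodingResult",
    "LeakAuditReport",
]

EMBEDDING_KINDS = ("arbitrary", "static", "contextual", "derived")
RECORDING_STAGES = ("raw", "despiked", "rereferenced", "power", "smoothed")


@dataclass
class Vocabulary:
    """A set of word types with relative frequencies summing to one."""

    types: list[str]
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if len(self.types) != len(set(self.types)):
            raise ValueError("vocabulary types must be unique")
        if len(self.types) != self.frequencies.size:
            raise ValueError("types and frequencies length mismatch")
        if np.any(self.frequencies <= 0):
            raise ValueError("frequencies must be strictly positive")
        if abs(self.frequencies.sum() - 1.0) > 1e-12:
            raise ValueError("frequencies must sum to 1 within 1e-12")

    def __len__(self) -> int:
        return len(self.types)


@dataclass
class WordEventTable:
    """Ordered spoken-word events with onsets/offsets in seconds.

    ``type_id`` indexes into a :class:`Vocabulary`; ``repetition_count`` is
    the total number of occurrences of the event's type in this table.
    """

    df: pd.DataFrame  # columns: token, onset_s, offset_s, type_id, repetition_count

    REQUIRED = ("token", "onset_s", "offset_s", "type_id", "repetition_count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"event table missing columns {missing}")
        onsets = self.df["onset_s"].to_numpy()
        if onsets.size > 1 and np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(self.df["offset_s"].to_numpy() < onsets):
            raise ValueError("offsets must be >= onsets")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def tokens(self) -> np.ndarray:
        return self.df["token"].to_numpy()

    @property
    def onsets(self) -> np.ndarray:
        return self.df["onset_s"].to_numpy()

    @property
    def type_ids(self) -> np.ndarray:
        return self.df["type_id"].to_numpy()

    @property
    def repetition_counts(self) -> np.ndarray:
        return self.df["repetition_count"].to_numpy()

    def subset(self, index: np.ndarray) -> "WordEventTable":
        """Row subset preserving order; repetition counts are kept as-is."""
        return WordEventTable(self.df.iloc[np.asarray(index)].reset_index(drop=True))


@dataclass
class EmbeddingMatrix:
    """Per-event word vectors (events x dims) with a kind tag."""

    vectors: np.ndarray
    kind: str
    note: str = ""

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (events x dims)")
        if self.kind not in EMBEDDING_KINDS:
            raise ValueError(f"unknown embedding kind {self.kind!r}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding entries must be finite")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def n_events(self) -> int:
        return self.vectors.shape[0]


@dataclass
class NeuralRecording:
    """Multi-electrode signal (electrodes x samples) at a fixed sampling rate."""

    signal: np.ndarray
    fs: float
    electrode_ids: list[str] = field(default_factory=list)
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.stage not in RECORDING_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if not self.electrode_ids:
            self.electrode_ids = [f"e{i:03d}" for i in range(self.signal.shape[0])]
        if len(self.electrode_ids) != self.signal.shape[0]:
            raise ValueError("electrode_ids length mismatch")

    @property
    def n_electrodes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, signal: np.ndarray, stage: str) -> "NeuralRecording":
        return NeuralRecording(signal, self.fs, list(self.electrode_ids), stage)


@dataclass
class LagKernel:
    """Finite-support lag -> gain map describing the evoked response shape.

    ``times_ms`` are signed offsets relative to word onset (negative =
    pre-onset activity); ``gains`` are the corresponding kernel values.
    """

    times_ms: np.ndarray
    gains: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.gains = np.asarray(self.gains, dtype=float)
        if self.times_ms.shape != self.gains.shape or self.times_ms.ndim != 1:
            raise ValueError("times_ms and gains must be matching 1-D arrays")
        if self.times_ms.size and np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("times_ms must be strictly increasing")

    @classmethod
    def gaussian(
        cls,
        center_ms: float = 150.0,
        sigma_ms: float = 60.0,
        span_sigmas: float = 4.0,
        step_ms: float = 1.0,
    ) -> "LagKernel":
        """Gaussian bump peaking at ``center_ms`` (post-onset by default)."""
        half = span_sigmas * sigma_ms
        t = np.arange(center_ms - half, center_ms + half + step_ms / 2, step_ms)
        g = np.exp(-0.5 * ((t - center_ms) / sigma_ms) ** 2)
        return cls(t, g)

    @classmethod
    def delta(cls, at_ms: float = 150.0) -> "LagKernel":
        return cls(np.array([at_ms]), np.array([1.0]))

    def sample(self, fs: float) -> tuple[np.ndarray, int]:
        """Kernel resampled on the recording's sample grid.

        Returns ``(gains, offset_samples)`` where ``offset_samples`` is the
        (signed) sample index of the first kernel tap relative to onset.
        """
        if self.times_ms.size == 1:  # single tap: snap to nearest sample
            off = int(np.round(self.times_ms[0] * fs / 1000.0))
            return self.gains.copy(), off
        lo = int(np.floor(self.times_ms[0] * fs / 1000.0))
        hi = int(np.ceil(self.times_ms[-1] * fs / 1000.0))
        grid_ms = np.arange(lo, hi + 1) * 1000.0 / fs
        gains = np.interp(grid_ms, self.times_ms, self.gains, left=0.0, right=0.0)
        return gains, lo


@dataclass
class GroundTruthLedger:
    """Everything needed to audit a synthetic recording against its truth."""

    tuning: np.ndarray  # electrodes x dims projection vectors
    kernel: LagKernel
    context_strength: float
    snr: float
    noise_exponent: float
    seed: int
    evoked_variance: float
    noise_variance: float

    def to_dict(self) -> dict:
        return {
            "tuning": self.tuning.tolist(),
            "kernel_times_ms": self.kernel.times_ms.tolist(),
            "kernel_gains": self.kernel.gains.tolist(),
            "context_strength": self.context_strength,
            "snr": self.snr,
            "noise_exponent": self.noise_exponent,
            "seed": self.seed,
            "evoked_variance": self.evoked_variance,
            "noise_variance": self.noise_variance,
        }


@dataclass
class PredictionSet:
    """Per-event next-word probability vectors over a shared vocabulary.

    ``probs[i]`` is the model's distribution before event ``i``'s onset and
    ``actual_index[i]`` the vocabulary index of the word actually spoken.
    """

    probs: np.ndarray  # events x vocab
    actual_index: np.ndarray  # events

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.actual_index = np.asarray(self.actual_index, dtype=int)
        if self.probs.ndim != 2:
            raise ValueError("probs must be events x vocab")
        if self.actual_index.shape[0] != self.probs.shape[0]:
            raise ValueError("actual_index length mismatch")
        if np.any(self.probs < 0):
            raise ValueError("probabilities must be nonnegative")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each distribution must sum to 1 within 1e-9")
        if np.any(self.actual_index < 0) or np.any(
            self.actual_index >= self.probs.shape[1]
        ):
            raise ValueError("actual_index out of vocabulary range")

    @property
    def n_events(self) -> int:
        return self.probs.shape[0]

    @property
    def n_vocab(self) -> int:
        return self.probs.shape[1]

    @property
    def p_actual(self) -> np.ndarray:
        return self.probs[np.arange(self.n_events), self.actual_index]


@dataclass
class BehavioralTable:
    """Rater guesses (raters x events) aligned to a word-event table."""

    guesses: np.ndarray  # raters x events, dtype=object/str

    def __post_init__(self) -> None:
        self.guesses = np.asarray(self.guesses)
        if self.guesses.ndim != 2:
            raise ValueError("guesses must be raters x events")

    @property
    def n_raters(self) -> int:
        return self.guesses.shape[0]

    @property
    def n_events(self) -> int:
        return self.guesses.shape[1]


@dataclass
class LagEncodingMap:
    """Held-out encoding correlations on an electrodes x lags grid."""

    r: np.ndarray  # electrodes x lags
    lags_ms: np.ndarray
    fold_assignment: np.ndarray  # events
    electrode_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.atleast_2d(np.asarray(self.r, dtype=float))
        self.lags_ms = np.asarray(self.lags_ms, dtype=float)
        if self.r.shape[1] != self.lags_ms.size:
            raise ValueError("r columns must match lag grid")
        if not self.electrode_ids:
            self.electrode_ids = [f"e{i:03d}" for i in range(self.r.shape[0])]

    @property
    def n_electrodes(self) -> int:
        return self.r.shape[0]

    @property
    def mean_curve(self) -> np.ndarray:
        """Electrode-mean encoding performance per lag."""
        return self.r.mean(axis=0)


@dataclass
class SignificanceResult:
    """Electrode-level permutation significance with FDR control."""

    p: np.ndarray
    q: np.ndarray
    null_max: np.ndarray  # permutation maxima (pooled null)
    significant: np.ndarray  # boolean mask at the stated q threshold
    q_threshold: float
    observed_max_r: np.ndarray


@dataclass
class CouplingSeries:
    """Per-lag coupling of neural power with prediction measures."""

    lags_ms: np.ndarray
    partial_r_entropy: np.ndarray | None = None
    partial_r_cross_entropy: np.ndarray | None = None
    q_entropy: np.ndarray | None = None
    q_cross_entropy: np.ndarray | None = None
    class_means: dict | None = None  # label -> per-lag electrode mean
    class_se: dict | None = None


@dataclass
class DecodingResult:
    """Frequency-weighted word-classification ROC-AUC per lag."""

    lags_ms: np.ndarray
    weighted_auc: np.ndarray  # per lag
    auc_se: np.ndarray  # across test folds
    per_label_auc: list  # per lag: dict label -> AUC
    fold_sizes: list
    ensemble_size: int


@dataclass
class LeakAuditReport:
    """Acausal-leakage audit of the preprocessing chain."""

    backward_extent_ms: float
    forward_extent_ms: float
    threshold: float

    def __post_init__(self) -> None:
        if self.backward_extent_ms < 0 or self.forward_extent_ms < 0:
            raise ValueError("extents must be nonnegative")
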