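"""Embedding-matrix manipulations used as encoding control analyses.

Each operation removes or perturbs one specific kind of information in the
embeddings — semantic structure, occurrence-specific context, or the match
between a word and its vector — so that the downstream change in encoding
performance isolates that information's contribution.
"""

from __future__ import annotations

import numpy as np
from sklearn.decomposition import PCA

from .types import EmbeddingMatrix, WordEventTable

__all__ = [
    "assign_arbitrary",
    "average_by_type",
    "scramble_occurrences",
    "nonmatch_same_word",
    "concat_context_pca",
    "concat_prev_current",
]


def assign_arbitrary(events: WordEventTable, dim: int = 50, seed: int = 0) -> EmbeddingMatrix:
    """One uniform[-1, 1] vector per word type, broadcast to occurrences.

    Arbitrary embeddings carry word identity but no semantic or contextual
    structure, the baseline for identity-only encoding.
    """
    type_ids = events.type_ids
    n_types = int(type_ids.max()) + 1
    rng = np.random.default_rng(seed)
    per_type = rng.uniform(-1.0, 1.0, size=(n_types, dim))
    return EmbeddingMatrix(per_type[type_ids], kind="arbitrary")


def average_by_type(
    emb: EmbeddingMatrix,
    events: WordEventTable,
    min_repetitions: int = 5,
) -> tuple[EmbeddingMatrix, np.ndarray]:
    """Collapse contextual embeddings to one mean vector per word type.

    Every retained event's row is replaced by the mean over all occurrences
    of its type; events of types with fewer than ``min_repetitions``
    occurrences are dropped. Returns the collapsed matrix plus the indices
    of retained events (the index map into the original rows).
    """
    if emb.kind != "contextual":
        raise ValueError("average_by_type expects a contextual embedding matrix")
    type_ids = events.type_ids
    counts = np.bincount(type_ids)
    eligible = counts >= min_repetitions
    if not eligible.any():
        raise ValueError(f"no type has >= {min_repetitions} repetitions")
    kept = np.flatnonzero(eligible[type_ids])
    means = np.zeros((counts.size, emb.dim))
    np.add.at(means, type_ids, emb.vectors[: len(events)])
    means /= np.maximum(counts, 1)[:, None]
    out = EmbeddingMatrix(means[type_ids[kept]], kind="derived", note="averaged-by-type")
    return out, kept


def scramble_occurrences(
    emb: EmbeddingMatrix, events: WordEventTable, seed: int = 0
) -> EmbeddingMatrix:
    """Permute contextual embeddings across occurrences of the same word.

    Within each type the rows are permuted (derangement-preferring: a
    permutation with a fixed point is redrawn, up to a retry budget, which
    may be unavoidable for types with <= 3 occurrences). The multiset of
    rows per type is unchanged; only the pairing of occurrence and context
    is destroyed.
    """
    if emb.kind != "contextual":
        raise ValueError("scramble_occurrences expects a contextual embedding matrix")
    rng = np.random.default_rng(seed)
    vectors = emb.vectors.copy()
    type_ids = events.type_ids
    for t in np.unique(type_ids):
        idx = np.flatnonzero(type_ids == t)
        if idx.size < 2:
            continue
        perm = rng.permutation(idx.size)
        for _ in range(20):
            if not np.any(perm == np.arange(idx.size)):
                break
            perm = rng.permutation(idx.size)
        vectors[idx] = emb.vectors[idx[perm]]
    return EmbeddingMatrix(vectors, kind="derived", note="occurrence-scrambled")


def nonmatch_same_word(
    emb: EmbeddingMatrix, events: WordEventTable, seed: int = 0
) -> EmbeddingMatrix:
    """Swap static vectors between word types (no type keeps its own vector).

    All occurrences of a type still share a single vector, so identity
    information is preserved while the word-vector match is destroyed.
    """
    if emb.kind != "static":
        raise ValueError("nonmatch_same_word expects a static embedding matrix")
    type_ids = events.type_ids
    present = np.unique(type_ids)
    if present.size < 2:
        raise ValueError("need at least two word types to swap")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(present.size)
    while np.any(perm == np.arange(present.size)):
        # cyclic shift of any fixed points guarantees a derangement
        perm = np.roll(perm, 1) if np.all(perm == np.arange(present.size)) else rng.permutation(present.size)
    # representative vector per present type
    first_occurrence = {t: np.flatnonzero(type_ids == t)[0] for t in present}
    mapping = {t: emb.vectors[first_occurrence[present[perm[i]]]] for i, t in enumerate(present)}
    vectors = np.stack([mapping[t] for t in type_ids])
    return EmbeddingMatrix(vectors, kind="derived", note="nonmatch-same-word")


def concat_context_pca(
    static_emb: EmbeddingMatrix,
    events: WordEventTable,
    k: int = 10,
    out_dim: int = 50,
    fit_index: np.ndarray | None = None,
) -> EmbeddingMatrix:
    """Concatenate the k preceding static vectors and reduce by PCA.

    The concatenation (zero-padded at the start of the sequence) forms a
    ``k * dim`` context vector per event; PCA components are fit on
    ``fit_index`` rows only (all rows if None) to avoid leaking held-out
    events into the projection, then applied everywhere. ``k=1`` is the
    previous-word control.
    """
    n, d = static_emb.vectors.shape
    if out_dim > k * d:
        raise ValueError("out_dim exceeds concatenated dimension")
    context = np.zeros((n, k * d))
    for j in range(1, k + 1):
        context[j:, (j - 1) * d : j * d] = static_emb.vectors[: n - j]
    fit_rows = context if fit_index is None else context[np.asarray(fit_index)]
    pca = PCA(n_components=out_dim, svd_solver="full")
    pca.fit(fit_rows)
    reduced = pca.transform(context)
    return EmbeddingMatrix(reduced, kind="derived", note=f"context-concat-k{k}-pca{out_dim}")


def concat_prev_current(
    emb: EmbeddingMatrix, events: WordEventTable
) -> EmbeddingMatrix:
    """Concatenate previous-event and current-event rows (dim doubles).

    The first event's left half is zero (no history).
    """
    n, d = emb.vectors.shape
    prev = np.zeros((n, d))
    prev[1:] = emb.vectors[: n - 1]
    return EmbeddingMatrix(
        np.hstack([prev, emb.vectors]), kind="derived", note="prev+current"
    )
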