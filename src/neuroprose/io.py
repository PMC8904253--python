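"""On-disk formats: TSV event/behavioral tables, HDF5 containers, JSON ledgers.

Layout conventions:

* word events — TSV with columns token, onset_s, offset_s, type_id,
  repetition_count;
* recordings — HDF5 with ``/signal`` (electrodes x samples), ``/fs``,
  ``/electrode_ids`` and a ``stage`` attribute;
* embeddings — HDF5 datasets under ``/embeddings/<name>`` with ``kind``,
  ``dim`` and optional ``seed`` attributes;
* encoding maps — HDF5 with ``/r``, ``/lags_ms``, ``/fold_assignment``;
* ground-truth ledgers and reports — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (
    BehavioralTable,
    EmbeddingMatrix,
    LagEncodingMap,
    NeuralRecording,
    WordEventTable,
)

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_recording",
    "read_recording",
    "write_embeddings",
    "read_embeddings",
    "write_encoding_map",
    "read_encoding_map",
    "write_behavioral_tsv",
    "read_behavioral_tsv",
    "write_json",
    "read_json",
]


def write_events_tsv(events: WordEventTable, path: str | Path) -> None:
    events.df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> WordEventTable:
    df = pd.read_csv(path, sep="\t")
    return WordEventTable(df)


def write_recording(rec: NeuralRecording, path: str | Path, mode: str = "w") -> None:
    with h5py.File(path, mode) as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("fs", data=rec.fs)
        f.create_dataset(
            "electrode_ids", data=np.array(rec.electrode_ids, dtype=h5py.string_dtype())
        )
        f.attrs["stage"] = rec.stage


def read_recording(path: str | Path) -> NeuralRecording:
    with h5py.File(path, "r") as f:
        return NeuralRecording(
            signal=f["signal"][...],
            fs=float(f["fs"][()]),
            electrode_ids=[s.decode() if isinstance(s, bytes) else s for s in f["electrode_ids"][...]],
            stage=str(f.attrs.get("stage", "raw")),
        )


def write_embeddings(
    emb: EmbeddingMatrix, path: str | Path, name: str, seed: int | None = None
) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group("embeddings")
        if name in grp:
            del grp[name]
        ds = grp.create_dataset(name, data=emb.vectors)
        ds.attrs["kind"] = emb.kind
        ds.attrs["dim"] = emb.dim
        if emb.note:
            ds.attrs["note"] = emb.note
        if seed is not None:
            ds.attrs["seed"] = seed


def read_embeddings(path: str | Path, name: str) -> EmbeddingMatrix:
    with h5py.File(path, "r") as f:
        ds = f["embeddings"][name]
        return EmbeddingMatrix(
            vectors=ds[...],
            kind=str(ds.attrs["kind"]),
            note=str(ds.attrs.get("note", "")),
        )


def write_encoding_map(emap: LagEncodingMap, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("r", data=emap.r)
        f.create_dataset("lags_ms", data=emap.lags_ms)
        f.create_dataset("fold_assignment", data=emap.fold_assignment)
        f.create_dataset(
            "electrode_ids",
            data=np.array(emap.electrode_ids, dtype=h5py.string_dtype()),
        )


def read_encoding_map(path: str | Path) -> LagEncodingMap:
    with h5py.File(path, "r") as f:
        return LagEncodingMap(
            r=f["r"][...],
            lags_ms=f["lags_ms"][...],
            fold_assignment=f["fold_assignment"][...],
            electrode_ids=[
                s.decode() if isinstance(s, bytes) else s for s in f["electrode_ids"][...]
            ],
        )


def write_behavioral_tsv(table: BehavioralTable, path: str | Path) -> None:
    """Long format: rater_id, event_index, guess."""
    raters, events = np.meshgrid(
        np.arange(table.n_raters), np.arange(table.n_events), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "rater_id": raters.ravel(),
            "event_index": events.ravel(),
            "guess": table.guesses.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_behavioral_tsv(path: str | Path) -> BehavioralTable:
    df = pd.read_csv(path, sep="\t", dtype={"guess": str})
    n_raters = df["rater_id"].max() + 1
    n_events = df["event_index"].max() + 1
    guesses = np.empty((n_raters, n_events), dtype=object)
    guesses[df["rater_id"], df["event_index"]] = df["guess"].to_numpy(dtype=object)
    return BehavioralTable(guesses=guesses)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.bool_):
            return bool(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, cls=_NumpyEncoder))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
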