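"""Readers and writers for the on-disk dataset bundle.

A bundle directory holds arrays in HDF5 (``signal.h5`` with the recording and
embeddings), the word-event table as CSV (``events.csv``) and the planted
truth / generator config as JSON.  Files are schema-versioned; a mismatching
or unreadable file raises :class:`~laglayer.errors.SchemaError` rather than
returning silently corrupted arrays.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .types import EncodingTensor, LayeredEmbeddingSet, NeuralRecording, WordEventTable

__all__ = [
    "SCHEMA_VERSION",
    "write_bundle",
    "read_bundle",
    "write_encoding",
    "read_encoding",
]

SCHEMA_VERSION = "1"


def _check_version(found: str, where: str) -> None:
    if str(found) != SCHEMA_VERSION:
        raise SchemaError(
            f"{where}: expected schema version {SCHEMA_VERSION}, found {found!r}"
        )


def write_bundle(
    path,
    events: WordEventTable,
    embeddings: LayeredEmbeddingSet,
    recording: NeuralRecording,
    truth: dict | None = None,
    config: dict | None = None,
) -> Path:
    """Write a dataset bundle (HDF5 arrays + CSV events + JSON sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with h5py.File(path / "signal.h5", "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("signal", data=recording.signal)
        f.attrs["sampling_rate"] = recording.sampling_rate
        f.create_dataset(
            "electrode_ids", data=np.array(recording.electrode_ids, dtype="S")
        )
        f.create_dataset("roi_labels", data=np.array(recording.roi_labels, dtype="S"))
        f.create_dataset("embeddings", data=embeddings.values)
        f.create_dataset("layer_ids", data=embeddings.layer_ids)
        f.create_dataset("word_index", data=embeddings.word_index)
    # %.17g guarantees float64 round-trip through the text table
    events.to_frame().to_csv(path / "events.csv", index=False, float_format="%.17g")
    sidecar = {"schema_version": SCHEMA_VERSION}
    if truth is not None:
        sidecar["truth"] = _jsonable(truth)
    if config is not None:
        sidecar["config"] = _jsonable(config)
    (path / "meta.json").write_text(json.dumps(sidecar, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_bundle(path) -> tuple:
    """Read a bundle back as ``(events, embeddings, recording, meta)``."""
    path = Path(path)
    h5_path = path / "signal.h5"
    if not h5_path.exists():
        raise SchemaError(f"{h5_path} does not exist")
    try:
        with h5py.File(h5_path, "r") as f:
            _check_version(f.attrs.get("schema_version", "missing"), str(h5_path))
            recording = NeuralRecording(
                signal=f["signal"][()],
                sampling_rate=float(f.attrs["sampling_rate"]),
                electrode_ids=[s.decode() for s in f["electrode_ids"][()]],
                roi_labels=[s.decode() for s in f["roi_labels"][()]],
            )
            embeddings = LayeredEmbeddingSet(
                values=f["embeddings"][()],
                layer_ids=f["layer_ids"][()],
                word_index=f["word_index"][()],
            )
    except OSError as exc:
        raise SchemaError(f"cannot read {h5_path}: {exc}") from exc
    try:
        events = WordEventTable.from_frame(
            pd.read_csv(path / "events.csv", float_precision="round_trip")
        )
    except (ValueError, KeyError, FileNotFoundError) as exc:
        raise SchemaError(f"cannot read events.csv: {exc}") from exc
    meta = {}
    meta_path = path / "meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        _check_version(meta.get("schema_version", "missing"), str(meta_path))
    if events.n_words != embeddings.n_words:
        raise ValidationError("bundle events and embeddings disagree on word count")
    return events, embeddings, recording, meta


def write_encoding(path, tensor: EncodingTensor) -> Path:
    """Write an encoding tensor with its coordinate tables to HDF5."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("values", data=tensor.values)
        f.create_dataset("lags", data=tensor.lags)
        f.create_dataset("layer_ids", data=tensor.layer_ids)
        f.create_dataset("electrode_ids", data=np.array(tensor.electrode_ids, dtype="S"))
        f.create_dataset("roi_labels", data=np.array(tensor.roi_labels, dtype="S"))
    return path


def read_encoding(path) -> EncodingTensor:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            _check_version(f.attrs.get("schema_version", "missing"), str(path))
            return EncodingTensor(
                values=f["values"][()],
                lags=f["lags"][()],
                layer_ids=f["layer_ids"][()],
                electrode_ids=[s.decode() for s in f["electrode_ids"][()]],
                roi_labels=[s.decode() for s in f["roi_labels"][()]],
            )
    except OSError as exc:
        raise SchemaError(f"cannot read {path}: {exc}") from exc
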