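"""Persistence: corpora and datasets as HDF5, networks as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .edgenet import EdgeNetwork
from .pipeline import LabeledDataset, SignalCorpus

__all__ = [
    "save_corpus",
    "load_corpus",
    "save_dataset",
    "load_dataset",
    "save_network",
    "load_network",
]


def _write_meta(group: h5py.Group, meta: pd.DataFrame) -> None:
    sub = group.create_group("meta")
    for col in meta.columns:
        values = meta[col].to_numpy()
        if values.dtype == object:
            values = values.astype("S")
        sub.create_dataset(col, data=values)
    sub.attrs["columns"] = json.dumps(list(meta.columns))


def _read_meta(group: h5py.Group) -> pd.DataFrame:
    sub = group["meta"]
    cols = json.loads(sub.attrs["columns"])
    data = {}
    for col in cols:
        values = sub[col][()]
        if values.dtype.kind == "S":
            values = np.char.decode(values, "utf-8")
        data[col] = values
    return pd.DataFrame(data)


def save_corpus(path, corpus: SignalCorpus) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=corpus.signals)
        f.create_dataset("labels", data=corpus.y)
        f.create_dataset("gains", data=corpus.gains)
        f.attrs["n_receptors"] = corpus.n_receptors
        f.attrs["dt"] = corpus.dt
        _write_meta(f, corpus.meta)


def load_corpus(path) -> SignalCorpus:
    with h5py.File(path, "r") as f:
        return SignalCorpus(
            f["signals"][()],
            f["labels"][()].astype(np.int8),
            _read_meta(f),
            f["gains"][()],
            int(f.attrs["n_receptors"]),
            float(f.attrs["dt"]),
        )


def save_dataset(path, data: LabeledDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=data.X)
        f.create_dataset("labels", data=data.y)
        f.attrs["feature_names"] = json.dumps(list(data.feature_names))
        _write_meta(f, data.meta)


def load_dataset(path) -> LabeledDataset:
    with h5py.File(path, "r") as f:
        return LabeledDataset(
            f["X"][()],
            f["labels"][()].astype(np.int8),
            _read_meta(f),
            json.loads(f.attrs["feature_names"]),
        )


def save_network(path, net: EdgeNetwork, **metadata) -> None:
    payload = {
        "W1": net.W1.tolist(),
        "b1": net.b1.tolist(),
        "W2": net.W2.tolist(),
        "b2": net.b2,
        "use_table": net.use_table,
        "feature_names": net.feature_names,
        "metadata": metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_network(path) -> EdgeNetwork:
    payload = json.loads(Path(path).read_text())
    return EdgeNetwork(
        np.asarray(payload["W1"], dtype=np.float64),
        np.asarray(payload["b1"], dtype=np.float64),
        np.asarray(payload["W2"], dtype=np.float64),
        float(payload["b2"]),
        bool(payload["use_table"]),
        payload.get("feature_names"),
    )
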