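"""CSV and HDF5 readers/writers for feature matrices and recordings.

CSV carries 2-D data only (header row = channel/unit identifiers, index
column = stimulus identifiers); HDF5 carries n-D arrays under the dataset
names "features" and "responses" with identifiers and generator parameters
stored as attributes.
"""
from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import CategorySamples, FeatureMatrix, NeuralRecordingSet

__all__ = [
    "write_features_csv",
    "read_features_csv",
    "write_features_hdf5",
    "read_features_hdf5",
    "write_recordings_csv",
    "read_recordings_csv",
    "write_recordings_hdf5",
    "read_recordings_hdf5",
    "write_category_csv",
    "read_category_csv",
]

_LABEL_COLUMN = "label"


def write_features_csv(features: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        features.values, index=features.stimulus_ids, columns=features.channel_ids
    )
    df.to_csv(path, index_label="stimulus_id")


def read_features_csv(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path, index_col=0)
    return FeatureMatrix(
        df.to_numpy(dtype=float),
        stimulus_ids=[str(s) for s in df.index],
        channel_ids=[str(c) for c in df.columns],
    )


def _write_string_attr(group: h5py.Group | h5py.Dataset, key: str, values) -> None:
    group.attrs[key] = np.array([str(v) for v in values], dtype=h5py.string_dtype())


def _read_string_attr(obj, key: str) -> list[str]:
    return [v.decode() if isinstance(v, bytes) else str(v) for v in obj.attrs[key]]


def write_features_hdf5(
    features: FeatureMatrix, path: str | Path, **params
) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("features", data=features.values)
        _write_string_attr(ds, "stimulus_ids", features.stimulus_ids)
        _write_string_attr(ds, "channel_ids", features.channel_ids)
        for k, v in params.items():
            ds.attrs[k] = v


def read_features_hdf5(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        ds = f["features"]
        return FeatureMatrix(
            ds[...],
            stimulus_ids=_read_string_attr(ds, "stimulus_ids"),
            channel_ids=_read_string_attr(ds, "channel_ids"),
        )


def write_recordings_csv(recordings: NeuralRecordingSet, path: str | Path) -> None:
    if recordings.n_repeats != 1:
        raise ValueError(
            "CSV holds 2-D data only; recordings with repeats need HDF5"
        )
    df = pd.DataFrame(
        recordings.values[:, :, 0],
        index=recordings.stimulus_ids,
        columns=recordings.unit_ids,
    )
    df.to_csv(path, index_label="stimulus_id")


def read_recordings_csv(path: str | Path) -> NeuralRecordingSet:
    df = pd.read_csv(path, index_col=0)
    return NeuralRecordingSet(
        df.to_numpy(dtype=float)[:, :, None],
        stimulus_ids=[str(s) for s in df.index],
        unit_ids=[str(c) for c in df.columns],
    )


def write_recordings_hdf5(
    recordings: NeuralRecordingSet, path: str | Path, **params
) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("responses", data=recordings.values)
        _write_string_attr(ds, "stimulus_ids", recordings.stimulus_ids)
        _write_string_attr(ds, "unit_ids", recordings.unit_ids)
        for k, v in params.items():
            ds.attrs[k] = v


def read_recordings_hdf5(path: str | Path) -> NeuralRecordingSet:
    with h5py.File(path, "r") as f:
        ds = f["responses"]
        return NeuralRecordingSet(
            ds[...],
            stimulus_ids=_read_string_attr(ds, "stimulus_ids"),
            unit_ids=_read_string_attr(ds, "unit_ids"),
        )


def write_category_csv(data: CategorySamples, path: str | Path) -> None:
    df = pd.DataFrame(
        data.features.values,
        index=data.features.stimulus_ids,
        columns=data.features.channel_ids,
    )
    df[_LABEL_COLUMN] = data.labels
    df.to_csv(path, index_label="stimulus_id")


def read_category_csv(path: str | Path) -> CategorySamples:
    df = pd.read_csv(path, index_col=0)
    if _LABEL_COLUMN not in df.columns:
        raise ValueError(f"category CSV needs a '{_LABEL_COLUMN}' column")
    labels = df.pop(_LABEL_COLUMN).astype(str).to_numpy()
    features = FeatureMatrix(
        df.to_numpy(dtype=float),
        stimulus_ids=[str(s) for s in df.index],
        channel_ids=[str(c) for c in df.columns],
    )
    return CategorySamples(features=features, labels=labels)
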