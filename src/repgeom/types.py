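"""Core data containers.

Feature matrices (stimuli x channels), convolutional feature maps
(stimuli x channels x height x width), neural recording sets
(stimuli x units x repeats) and labeled category samples are the four
array shapes every analysis in this package consumes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureMatrix",
    "FeatureMapSet",
    "NeuralRecordingSet",
    "CategorySamples",
    "make_ids",
]


def make_ids(prefix: str, n: int) -> list[str]:
    """Zero-padded integer identifiers, stable for I/O round-trips."""
    width = max(4, len(str(max(n - 1, 0))))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _check_finite(a: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{what} contains non-finite values")


@dataclass
class FeatureMatrix:
    """Stimuli x channels activation/feature array."""

    values: np.ndarray
    stimulus_ids: list[str] | None = None
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got {self.values.ndim}-D")
        n, d = self.values.shape
        if n < 2:
            raise ValueError("feature matrix needs at least 2 stimuli")
        if d < 1:
            raise ValueError("feature matrix needs at least 1 channel")
        _check_finite(self.values, "feature matrix")
        if self.stimulus_ids is None:
            self.stimulus_ids = make_ids("stim", n)
        if self.channel_ids is None:
            self.channel_ids = make_ids("ch", d)
        self.stimulus_ids = [str(s) for s in self.stimulus_ids]
        self.channel_ids = [str(c) for c in self.channel_ids]
        if len(self.stimulus_ids) != n:
            raise ValueError("stimulus_ids length mismatch")
        if len(self.channel_ids) != d:
            raise ValueError("channel_ids length mismatch")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class FeatureMapSet:
    """Stimuli x channels x height x width convolutional feature maps."""

    values: np.ndarray
    stimulus_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError(f"feature maps must be 4-D, got {self.values.ndim}-D")
        if min(self.values.shape) < 1:
            raise ValueError("all feature-map dimensions must be >= 1")
        _check_finite(self.values, "feature maps")
        if self.stimulus_ids is None:
            self.stimulus_ids = make_ids("stim", self.values.shape[0])

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class NeuralRecordingSet:
    """Stimuli x units x repeats responses; repeats enable split-half reliability."""

    values: np.ndarray
    stimulus_ids: list[str] | None = None
    unit_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:  # single-repeat shorthand
            self.values = self.values[:, :, None]
        if self.values.ndim != 3:
            raise ValueError(f"recordings must be 2-D or 3-D, got {self.values.ndim}-D")
        _check_finite(self.values, "recordings")
        n, u, _ = self.values.shape
        if self.stimulus_ids is None:
            self.stimulus_ids = make_ids("stim", n)
        if self.unit_ids is None:
            self.unit_ids = make_ids("unit", u)
        self.stimulus_ids = [str(s) for s in self.stimulus_ids]
        self.unit_ids = [str(s) for s in self.unit_ids]
        if len(self.stimulus_ids) != n or len(self.unit_ids) != u:
            raise ValueError("identifier length mismatch")

    @property
    def n_stimuli(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    @property
    def n_repeats(self) -> int:
        return self.values.shape[2]

    def repeat_mean(self) -> np.ndarray:
        """Stimuli x units trial-averaged responses."""
        return self.values.mean(axis=2)


@dataclass
class CategorySamples:
    """Labeled feature matrix: M classes with samples per class."""

    features: FeatureMatrix
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.labels is None:
            raise ValueError("labels are required")
        self.labels = np.asarray(self.labels).astype(str)
        if self.labels.ndim != 1 or len(self.labels) != self.features.n_stimuli:
            raise ValueError("labels must be 1-D with one entry per stimulus")
        # a test batch may hold a single class; operations that need M >= 2
        # classes (generation, projection matrices) enforce it themselves

    @property
    def class_ids(self) -> np.ndarray:
        """Classes in sorted label order (the deterministic tie-break order)."""
        return np.unique(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    def class_matrix(self, class_id: str) -> np.ndarray:
        """Samples x channels array for one class."""
        mask = self.labels == str(class_id)
        if not mask.any():
            raise KeyError(f"unknown class {class_id!r}")
        return self.features.values[mask]
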