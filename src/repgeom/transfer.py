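"""Prototype-learning transfer to novel object categories.

A frozen representation is evaluated on few-shot category learning with the
simplest readout there is: each category's prototype is the mean training
activation pattern, and test stimuli are assigned to the nearest prototype
in Euclidean distance.  Besides top-1 accuracy we report the mean reciprocal
rank (MRR) of the true category in the distance-sorted prototype list, a
smoother measure of how discriminable categories are.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ._rng import spawn_rng
from .types import CategorySamples, FeatureMatrix

__all__ = [
    "PrototypeModel",
    "TransferResult",
    "fit_prototypes",
    "evaluate_prototypes",
    "monte_carlo_transfer",
]


@dataclass
class PrototypeModel:
    centroids: np.ndarray  # M x n_channels
    class_ids: np.ndarray  # sorted label order

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.class_ids = np.asarray(self.class_ids).astype(str)
        if self.centroids.ndim != 2 or len(self.class_ids) != self.centroids.shape[0]:
            raise ValueError("one centroid row per class required")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")


@dataclass
class TransferResult:
    accuracy: float
    mrr: float
    per_iteration_accuracy: np.ndarray
    per_iteration_mrr: np.ndarray
    n_iterations: int
    had_distance_ties: bool = False


def fit_prototypes(train: CategorySamples) -> PrototypeModel:
    """Per-class mean activation patterns (the prototype learning rule)."""
    class_ids = train.class_ids
    centroids = np.stack([train.class_matrix(c).mean(axis=0) for c in class_ids])
    return PrototypeModel(centroids=centroids, class_ids=class_ids)


def evaluate_prototypes(model: PrototypeModel, test: CategorySamples) -> TransferResult:
    """Rank classes by ascending Euclidean distance to each test sample.

    Accuracy is the fraction of samples whose true class ranks first; MRR is
    the mean of 1/rank of the true class.  Exact distance ties are broken by
    class-id order (stable sort) and flagged on the result.
    """
    if test.features.n_channels != model.centroids.shape[1]:
        raise ValueError("test channels do not match centroid channels")
    d = cdist(test.features.values, model.centroids)
    order = np.argsort(d, axis=1, kind="stable")
    class_index = {c: i for i, c in enumerate(model.class_ids)}
    try:
        true_idx = np.array([class_index[lab] for lab in test.labels])
    except KeyError as err:
        raise ValueError(f"test label {err} unknown to the prototype model") from None
    ranks = np.argmax(order == true_idx[:, None], axis=1) + 1
    rr = 1.0 / ranks
    ties = bool(np.any(np.diff(np.sort(d, axis=1), axis=1) == 0.0))
    return TransferResult(
        accuracy=float(np.mean(ranks == 1)),
        mrr=float(rr.mean()),
        per_iteration_accuracy=np.array([np.mean(ranks == 1)]),
        per_iteration_mrr=np.array([rr.mean()]),
        n_iterations=1,
        had_distance_ties=ties,
    )


def monte_carlo_transfer(
    data: CategorySamples,
    n_train: int = 50,
    n_test: int = 50,
    n_iterations: int = 10,
    seed: int = 0,
) -> TransferResult:
    """Monte-Carlo cross-validated prototype transfer.

    Each iteration draws a seeded disjoint train/test split within every
    class (n_train prototypes samples, n_test held-out samples), fits
    prototypes, and evaluates; accuracy and MRR are averaged per iteration
    and then across iterations.
    """
    if n_train < 1 or n_test < 1 or n_iterations < 1:
        raise ValueError("n_train, n_test, n_iterations must be >= 1")
    class_ids = data.class_ids
    per_class_idx = {c: np.flatnonzero(data.labels == c) for c in class_ids}
    short = [c for c, idx in per_class_idx.items() if len(idx) < n_train + n_test]
    if short:
        raise ValueError(
            f"classes {short[:3]}... need >= n_train + n_test = {n_train + n_test} samples"
        )
    rng = spawn_rng(seed, "monte_carlo_transfer")
    accs, mrrs = [], []
    any_ties = False
    values = data.features.values
    for _ in range(n_iterations):
        train_rows, test_rows, test_labels = [], [], []
        for c in class_ids:
            perm = rng.permutation(per_class_idx[c])
            train_rows.append(perm[:n_train])
            test_rows.append(perm[n_train : n_train + n_test])
            test_labels.extend([c] * n_test)
        centroids = np.stack([values[rows].mean(axis=0) for rows in train_rows])
        model = PrototypeModel(centroids=centroids, class_ids=class_ids)
        test = CategorySamples(
            features=FeatureMatrix(values[np.concatenate(test_rows)]),
            labels=np.array(test_labels),
        )
        res = evaluate_prototypes(model, test)
        accs.append(res.accuracy)
        mrrs.append(res.mrr)
        any_ties = any_ties or res.had_distance_ties
    accs, mrrs = np.array(accs), np.array(mrrs)
    return TransferResult(
        accuracy=float(accs.mean()),
        mrr=float(mrrs.mean()),
        per_iteration_accuracy=accs,
        per_iteration_mrr=mrrs,
        n_iterations=n_iterations,
        had_distance_ties=any_ties,
    )
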