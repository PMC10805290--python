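"""Projection-distance concentration along linear readout dimensions.

For a pair of categories (i, j), the readout vector is the unit-normalized
centroid difference

    w_ij = (mu_i - mu_j) / ||mu_i - mu_j||,

the direction a prototype classifier projects along.  Each sample x_k of
category i has a scalar projection distance p_k = |(x_k - mu_i) . w_ij|, and
the category's "radius" R_i = sqrt(mean per-dimension variance) normalizes
for feature scale.  The mean normalized projection distance
p-hat_ij = mean(p) / R_i concentrates toward 0 as latent dimensionality
grows — the concentration-of-measure effect that lets high-dimensional
representations separate novel categories.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import sample_uniform_ball, spawn_rng
from .types import CategorySamples

__all__ = [
    "ProjectionMatrix",
    "readout_vector",
    "projection_distances",
    "subspace_radius",
    "projection_matrix",
    "sphere_projection_demo",
]


@dataclass
class ProjectionMatrix:
    """M x M mean normalized projection distances; diagonal is undefined (NaN)."""

    values: np.ndarray
    class_ids: np.ndarray

    def mean_offdiagonal(self) -> float:
        m = self.values.shape[0]
        mask = ~np.eye(m, dtype=bool)
        return float(np.nanmean(self.values[mask]))


def readout_vector(xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """Unit-normalized centroid difference between two sample matrices."""
    mu_i = np.asarray(xi, dtype=float).mean(axis=0)
    mu_j = np.asarray(xj, dtype=float).mean(axis=0)
    diff = mu_i - mu_j
    norm = np.linalg.norm(diff)
    if norm == 0:
        raise ValueError("identical centroids: readout direction undefined")
    return diff / norm


def projection_distances(xi: np.ndarray, w: np.ndarray) -> np.ndarray:
    """|(x_k - mu_i) . w| for every sample of category i."""
    xi = np.asarray(xi, dtype=float)
    w = np.asarray(w, dtype=float)
    if xi.shape[1] != w.shape[0]:
        raise ValueError("sample and readout dimensions do not match")
    centered = xi - xi.mean(axis=0)
    return np.abs(centered @ w)


def subspace_radius(xi: np.ndarray) -> float:
    """sqrt(mean per-dimension variance): the category subspace "radius"."""
    xi = np.asarray(xi, dtype=float)
    if xi.shape[0] < 2:
        raise ValueError("radius needs at least 2 samples")
    return float(np.sqrt(xi.var(axis=0, ddof=1).mean()))


def projection_matrix(data: CategorySamples) -> ProjectionMatrix:
    """Mean normalized projection distances between every ordered class pair.

    Entry (i, j), i != j, is mean(projection_distances(X_i, w_ij)) / R_i.
    The matrix need not be symmetric; the diagonal is stored as NaN.
    """
    class_ids = data.class_ids
    mats = [data.class_matrix(c) for c in class_ids]
    if any(m.shape[0] < 2 for m in mats):
        raise ValueError("every class needs at least 2 samples")
    radii = np.array([subspace_radius(m) for m in mats])
    if np.any(radii == 0):
        bad = class_ids[radii == 0]
        raise ValueError(f"degenerate class (zero radius): {list(bad)}")
    centroids = np.stack([m.mean(axis=0) for m in mats])
    m_classes = len(class_ids)
    out = np.full((m_classes, m_classes), np.nan)
    for i in range(m_classes):
        centered = mats[i] - centroids[i]
        for j in range(m_classes):
            if i == j:
                continue
            diff = centroids[i] - centroids[j]
            norm = np.linalg.norm(diff)
            if norm == 0:
                raise ValueError(
                    f"identical centroids for classes {class_ids[i]} and {class_ids[j]}"
                )
            p = np.abs(centered @ (diff / norm))
            out[i, j] = p.mean() / radii[i]
    return ProjectionMatrix(values=out, class_ids=class_ids)


def sphere_projection_demo(
    d_list: list[int], n_samples: int = 10_000, seed: int = 0
) -> pd.DataFrame:
    """Projections of uniform-ball samples onto a random unit direction.

    For each dimensionality d, samples N points uniformly in the volume of a
    unit-radius d-ball and projects them along one random unit vector,
    giving the distribution of projection distances from the centroid.  In
    one dimension the mean |projection| is 1/2; in two, 4/(3*pi); the
    distribution concentrates around 0 as d grows.

    Returns one row per d with mean, standard error, and quartiles.
    """
    rows = []
    for d in d_list:
        if d < 1:
            raise ValueError("sphere dimension must be >= 1")
        rng = spawn_rng(seed, "sphere_demo", d)
        pts = sample_uniform_ball(rng, n_samples, d, radius=1.0)
        w = rng.standard_normal(d)
        w /= np.linalg.norm(w)
        p = np.abs(pts @ w)
        q25, q50, q75 = np.percentile(p, [25, 50, 75])
        rows.append(
            {
                "d": d,
                "n_samples": n_samples,
                "mean": p.mean(),
                "sem": p.std(ddof=1) / np.sqrt(n_samples),
                "q25": q25,
                "median": q50,
                "q75": q75,
            }
        )
    return pd.DataFrame(rows)
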