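"""Eigenspectra, effective dimensionality, pooling, and power-law fits.

Effective dimensionality (ED) is the participation ratio of a covariance
eigenspectrum,

    ED = (sum_i lambda_i)^2 / sum_i lambda_i^2,

a continuous count of how many principal components carry the variance of a
representation: 1 for variance confined to a single direction, n for an
isotropic n-dimensional cloud.  It is scale- and rotation-invariant, which is
what makes it comparable across feature spaces of different magnitude.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import FeatureMapSet, FeatureMatrix

__all__ = [
    "Eigenspectrum",
    "PowerLawFit",
    "DegenerateSpectrumError",
    "compute_eigenspectrum",
    "effective_dimensionality",
    "global_average_pool",
    "fit_power_law",
]


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum carries no variance (ED undefined)."""


@dataclass
class Eigenspectrum:
    """Ordered nonnegative variances of principal components."""

    lambdas: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambdas, dtype=float).ravel()
        if lam.size == 0:
            raise ValueError("empty spectrum")
        # eigensolvers can return tiny negative round-off
        if lam.min() < -1e-10 * max(lam.max(), 1.0):
            raise ValueError("eigenvalues must be nonnegative")
        lam = np.clip(lam, 0.0, None)
        if np.any(np.diff(lam) > 1e-9 * max(lam.max(), 1.0)):
            raise ValueError("eigenvalues must be sorted in descending order")
        self.lambdas = lam

    def __len__(self) -> int:
        return self.lambdas.size

    @property
    def total_variance(self) -> float:
        return float(self.lambdas.sum())


@dataclass
class PowerLawFit:
    """Log-log least-squares fit lambda_i ~ i^(-exponent) over fit_range."""

    exponent: float
    fit_range: tuple[int, int]
    goodness: float  # R^2 of the log-log regression


def compute_eigenspectrum(features: FeatureMatrix) -> Eigenspectrum:
    """Eigenvalues of the column-centered sample covariance (n-1 denominator).

    Computed from the singular values of the centered data matrix rather than
    by forming the covariance, for numerical stability with wide matrices.
    The spectrum has min(n_stimuli - 1, n_channels) estimated values and is
    zero-padded to n_channels.
    """
    x = features.values
    n, d = x.shape
    xc = x - x.mean(axis=0)
    s = np.linalg.svd(xc, compute_uv=False)
    lam = s**2 / (n - 1)
    lam = lam[: min(n - 1, d)]
    if lam.sum() <= 0:
        raise DegenerateSpectrumError("features are constant: zero total variance")
    out = np.zeros(d)
    out[: lam.size] = lam
    return Eigenspectrum(out)


def effective_dimensionality(spectrum: Eigenspectrum | np.ndarray) -> float:
    """Participation ratio (sum lambda)^2 / sum lambda^2 of an eigenspectrum.

    Accepts an :class:`Eigenspectrum` or a bare array of nonnegative
    variances (order does not matter: ED is permutation-invariant).
    """
    lam = spectrum.lambdas if isinstance(spectrum, Eigenspectrum) else np.asarray(
        spectrum, dtype=float
    )
    if lam.size == 0 or np.any(lam < 0):
        raise ValueError("spectrum must be a nonempty set of nonnegative variances")
    total = lam.sum()
    if total <= 0:
        raise DegenerateSpectrumError("all-zero spectrum: ED undefined")
    return float(total**2 / np.square(lam).sum())


def global_average_pool(maps: FeatureMapSet) -> FeatureMatrix:
    """Spatial mean per stimulus and channel: (n, c, h, w) -> (n, c).

    Pooling before PCA restricts the eigenspectrum to variance across image
    *features* (channels), discarding variance across space.
    """
    pooled = maps.values.mean(axis=(2, 3))
    return FeatureMatrix(pooled, stimulus_ids=list(maps.stimulus_ids))


def fit_power_law(
    spectrum: Eigenspectrum, fit_range: tuple[int, int] | None = None
) -> PowerLawFit:
    """Least-squares slope of log lambda_i vs log i over a 1-based index range.

    ``fit_range = (start, stop)`` is inclusive; defaults to the full positive
    part of the spectrum.  The exponent is reported positive for decaying
    spectra (lambda_i = i^-a yields exponent a exactly).
    """
    lam = spectrum.lambdas
    if fit_range is None:
        stop = int(np.count_nonzero(lam > 0))
        fit_range = (1, stop)
    start, stop = int(fit_range[0]), int(fit_range[1])
    if not 1 <= start <= stop <= lam.size:
        raise ValueError(f"fit_range {fit_range} outside spectrum of length {lam.size}")
    if stop - start + 1 < 3:
        raise ValueError("fit_range must cover at least 3 indices")
    window = lam[start - 1 : stop]
    if np.any(window <= 0):
        raise ValueError("zero eigenvalue inside fit_range")
    idx = np.arange(start, stop + 1, dtype=float)
    res = stats.linregress(np.log(idx), np.log(window))
    return PowerLawFit(
        exponent=float(-res.slope),
        fit_range=(start, stop),
        goodness=float(res.rvalue**2),
    )
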