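"""Seeded synthetic-data generators.

These emulate the statistical structure of the inputs the analyses assume:
feature clouds with controlled power-law eigenspectra, multi-trial neural
responses that are noisy linear readouts of a latent signal subspace, labeled
category clouds with controllable latent dimensionality, and convolutional
feature maps for pooling tests.  Fixed seeds give bit-identical outputs.
"""
from __future__ import annotations

import numpy as np
from scipy.special import gammaln

from ._rng import random_orthonormal, sample_uniform_ball, spawn_rng
from .types import CategorySamples, FeatureMapSet, FeatureMatrix, NeuralRecordingSet, make_ids

__all__ = [
    "power_law_spectrum",
    "analytic_participation_ratio",
    "gen_power_law_features",
    "gen_neural_responses",
    "gen_category_clouds",
    "gen_feature_maps",
]


def power_law_spectrum(n: int, alpha: float) -> np.ndarray:
    """Population eigenvalues lambda_i = i^(-alpha), i = 1..n."""
    if n < 1:
        raise ValueError("spectrum length must be >= 1")
    if alpha < 0:
        raise ValueError("power-law exponent must be >= 0")
    return np.arange(1, n + 1, dtype=float) ** (-alpha)


def analytic_participation_ratio(lambdas: np.ndarray) -> float:
    """(sum lambda)^2 / sum lambda^2 of a population spectrum."""
    lam = np.asarray(lambdas, dtype=float)
    return float(lam.sum() ** 2 / np.square(lam).sum())


def gen_power_law_features(
    n_stimuli: int, n_channels: int, alpha: float, seed: int
) -> FeatureMatrix:
    """Zero-mean Gaussian features whose population covariance eigenvalues
    decay as a power law i^(-alpha) in a random orthonormal eigenbasis.

    The participation ratio of the population spectrum is the generator's
    ground-truth effective dimensionality; use
    :func:`analytic_participation_ratio` on :func:`power_law_spectrum` for it.
    """
    if n_stimuli < 2 or n_channels < 1:
        raise ValueError("n_stimuli must be >= 2 and n_channels >= 1")
    lam = power_law_spectrum(n_channels, alpha)
    rng = spawn_rng(seed, "power_law_features")
    basis = random_orthonormal(rng, n_channels)
    z = rng.standard_normal((n_stimuli, n_channels))
    values = (z * np.sqrt(lam)) @ basis.T
    return FeatureMatrix(values)


def gen_neural_responses(
    features: FeatureMatrix,
    n_units: int,
    n_signal_dims: int,
    snr: float,
    n_repeats: int,
    seed: int,
) -> NeuralRecordingSet:
    """Noisy linear readouts of the leading principal subspace of ``features``.

    Each unit's response is a fixed random linear combination of the top
    ``n_signal_dims`` principal-component scores of the features, plus
    independent Gaussian noise per repeat scaled so that per-unit
    signal variance / noise variance equals ``snr``.  With two repeats the
    expected uncorrected split-half reliability is snr / (snr + 1).
    ``snr = numpy.inf`` gives noiseless (identical) repeats.
    """
    if n_units < 1 or n_repeats < 1:
        raise ValueError("n_units and n_repeats must be >= 1")
    if not 1 <= n_signal_dims <= features.n_channels:
        raise ValueError(
            f"n_signal_dims must be in [1, {features.n_channels}], got {n_signal_dims}"
        )
    if not snr > 0:
        raise ValueError("snr must be > 0")
    rng = spawn_rng(seed, "neural_responses")
    x = features.values - features.values.mean(axis=0)
    # principal-component scores of the feature cloud
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    k = min(n_signal_dims, int((s > s[0] * 1e-12).sum()) if s.size else 0)
    if k < 1:
        raise ValueError("features have no variance to read out")
    scores = u[:, :k] * s[:k]
    readout = rng.standard_normal((k, n_units)) / np.sqrt(k)
    signal = scores @ readout
    sig_var = signal.var(axis=0, ddof=1)
    noise_sd = np.zeros(n_units) if np.isinf(snr) else np.sqrt(sig_var / snr)
    noise = rng.standard_normal((features.n_stimuli, n_units, n_repeats))
    values = signal[:, :, None] + noise * noise_sd[None, :, None]
    return NeuralRecordingSet(
        values, stimulus_ids=list(features.stimulus_ids), unit_ids=make_ids("unit", n_units)
    )


def _centroid_scale(separation: float, latent_dim: int) -> float:
    """Per-coordinate s.d. of Gaussian centroids giving expected pairwise
    Euclidean distance ``separation`` in ``latent_dim`` dimensions.

    The difference of two iid N(0, s^2 I_d) vectors is N(0, 2 s^2 I_d) whose
    norm has mean 2 s Gamma((d+1)/2) / Gamma(d/2).
    """
    if separation == 0.0:
        return 0.0
    d = latent_dim
    chi_mean = np.exp(gammaln((d + 1) / 2.0) - gammaln(d / 2.0))
    return float(separation / (2.0 * chi_mean))


def gen_category_clouds(
    M: int,
    n_per_class: int,
    latent_dim: int,
    ambient_dim: int,
    radius: float,
    separation: float,
    seed: int,
) -> CategorySamples:
    """M labeled category clouds in a shared latent subspace.

    A single random orthonormal embedding maps a ``latent_dim``-dimensional
    latent space into ``ambient_dim`` channels; class centroids are drawn
    inside that latent space with expected pairwise distance ``separation``,
    and within-class samples are uniform in a latent ball of the given
    ``radius`` around each centroid.  ``latent_dim`` is therefore the latent
    dimensionality of the whole representation, the quantity effective
    dimensionality estimates.
    """
    if M < 2:
        raise ValueError("need at least 2 categories")
    if n_per_class < 2:
        raise ValueError("need at least 2 samples per category")
    if not 1 <= latent_dim <= ambient_dim:
        raise ValueError("need 1 <= latent_dim <= ambient_dim")
    if radius < 0 or separation < 0:
        raise ValueError("radius and separation must be >= 0")
    rng = spawn_rng(seed, "category_clouds")
    embed = random_orthonormal(rng, ambient_dim, latent_dim)  # ambient x latent
    centroids = _centroid_scale(separation, latent_dim) * rng.standard_normal(
        (M, latent_dim)
    )
    blocks = []
    for i in range(M):
        ball = sample_uniform_ball(rng, n_per_class, latent_dim, radius)
        blocks.append((centroids[i] + ball) @ embed.T)
    values = np.vstack(blocks)
    class_names = make_ids("class", M)
    labels = np.repeat(class_names, n_per_class)
    features = FeatureMatrix(values, stimulus_ids=make_ids("stim", M * n_per_class))
    return CategorySamples(features=features, labels=labels)


def gen_feature_maps(
    n_stimuli: int, n_channels: int, height: int, width: int, seed: int
) -> FeatureMapSet:
    """Standard-normal convolutional feature maps (pooling-test fodder)."""
    if min(n_stimuli, n_channels, height, width) < 1:
        raise ValueError("all dimensions must be >= 1")
    rng = spawn_rng(seed, "feature_maps")
    return FeatureMapSet(rng.standard_normal((n_stimuli, n_channels, height, width)))
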