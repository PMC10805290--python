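"""Subspace-alignment simulation of encoding-model performance.

The simulation instantiates a geometric account of why some representational
models predict brain activity better than others.  All representations are
projections of a common *natural* subspace: a Gaussian source with a
slowly-decaying spectrum inside a random low-dimensional span of the ambient
space.  An *ecological* (brain) subspace and a *model* subspace each project
these observations through their own orthonormal basis, with per-dimension
gains following a power law whose exponent controls the subspace's effective
dimensionality (ED), plus observation noise.  *Alignment pressure* (AP) in
[0, 1] controls how strongly the model basis is biased toward the ecological
basis: 0 gives an independently random basis, 1 reproduces the ecological
basis exactly, intermediate values interpolate and re-orthonormalize.

Cross-validated linear regression from model features to each ecological
dimension then yields an encoding score (mean held-out R^2), and sweeping
(ED, AP) grids reproduces the Alignment / Joint / Dimensionality regimes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

from ._rng import derive_seed, random_orthonormal, spawn_rng
from .synth import analytic_participation_ratio, power_law_spectrum

__all__ = [
    "SubspaceSimConfig",
    "sample_natural_observations",
    "make_aligned_subspace",
    "simulate_encoding_experiment",
    "run_regime_sweep",
    "dimensionality_regime_grid",
    "alignment_regime_grid",
    "joint_regime_grid",
    "alpha_for_target_ed",
]


@dataclass(frozen=True)
class SubspaceSimConfig:
    """Full parameterization of one simulated encoding experiment.

    ambient_dim
        Dimensionality of the embedding space (number of "neurons").
    natural_dim
        Rank of the natural image subspace all representations sample from.
    natural_alpha
        Power-law exponent of the natural source spectrum (0 = isotropic
        within its span; the default decays slowly).
    eco_alpha, model_alpha
        Power-law exponents of the ecological and model gain spectra; they
        set each subspace's effective dimensionality.
    alignment_pressure
        AP in [0, 1]: bias of the model basis toward the ecological basis.
    noise_sigma
        Scale of Gaussian observation noise added to both projections.
    n_train, n_test
        Sample counts for the cross-validated regression.
    regression
        "ols" (default) or "pls" (25 latent components, capped at rank).
    noise_before_projection
        If True, noise is added to the natural observations before they are
        projected (source noise) instead of after (observation noise).
    """

    ambient_dim: int = 100
    natural_dim: int = 60
    natural_alpha: float = 0.25
    eco_alpha: float = 0.8
    model_alpha: float = 0.8
    alignment_pressure: float = 0.5
    noise_sigma: float = 0.1
    n_train: int = 400
    n_test: int = 200
    seed: int = 0
    regression: str = "ols"
    noise_before_projection: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.natural_dim <= self.ambient_dim:
            raise ValueError("need 1 <= natural_dim <= ambient_dim")
        if not 0.0 <= self.alignment_pressure <= 1.0:
            raise ValueError("alignment_pressure must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_train < 2 or self.n_test < 2:
            raise ValueError("n_train and n_test must be >= 2")
        if self.regression not in ("ols", "pls"):
            raise ValueError("regression must be 'ols' or 'pls'")

    @property
    def model_ed(self) -> float:
        """Analytic participation ratio of the model gain spectrum."""
        return analytic_participation_ratio(
            power_law_spectrum(self.natural_dim, self.model_alpha)
        )

    @property
    def eco_ed(self) -> float:
        return analytic_participation_ratio(
            power_law_spectrum(self.natural_dim, self.eco_alpha)
        )


def sample_natural_observations(config: SubspaceSimConfig) -> np.ndarray:
    """(n_train + n_test) x ambient_dim draws from the natural subspace."""
    rng = spawn_rng(config.seed, "natural")
    basis = random_orthonormal(rng, config.ambient_dim, config.natural_dim)
    lam = power_law_spectrum(config.natural_dim, config.natural_alpha)
    n = config.n_train + config.n_test
    z = rng.standard_normal((n, config.natural_dim))
    return (z * np.sqrt(lam)) @ basis.T


def make_aligned_subspace(
    reference_basis: np.ndarray, target_alpha: float, ap: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis partially aligned with ``reference_basis``.

    Interpolates column-wise between an independent Haar-random basis
    (ap = 0) and the reference (ap = 1), then re-orthonormalizes by QR; the
    mean squared canonical correlation between the leading directions grows
    monotonically with ap.  Returns (basis, power-law spectrum).
    """
    if not 0.0 <= ap <= 1.0:
        raise ValueError("ap must lie in [0, 1]")
    ambient, k = reference_basis.shape
    rng = spawn_rng(seed, "aligned_subspace")
    if ap == 1.0:
        basis = reference_basis.copy()
    else:
        rand = random_orthonormal(rng, ambient, k)
        mix = (1.0 - ap) * rand + ap * reference_basis
        q, r = np.linalg.qr(mix)
        d = np.diagonal(r)
        basis = q * np.where(d == 0.0, 1.0, np.sign(d))
    return basis, power_law_spectrum(k, target_alpha)


def _holdout_r2(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """Per-column held-out R^2 (1 - SSE / centered SST)."""
    sse = np.square(y_true - y_pred).sum(axis=0)
    sst = np.square(y_true - y_true.mean(axis=0)).sum(axis=0)
    sst[sst == 0] = np.nan
    return 1.0 - sse / sst


def simulate_encoding_experiment(
    config: SubspaceSimConfig, return_raw: bool = False
) -> float | tuple[float, float]:
    """One simulated encoding experiment; returns mean held-out R^2.

    Natural observations are projected onto the ecological and model
    subspaces (each dimension scaled by the square root of its gain
    spectrum), observation noise is added, and a linear encoder is fit from
    model features to ecological responses on the train split.  The score is
    the mean held-out R^2 across ecological dimensions, clipped below at 0;
    with ``return_raw`` the unclipped mean is returned alongside.
    """
    cfg = config
    x = sample_natural_observations(cfg)
    rng = spawn_rng(cfg.seed, "experiment")
    eco_rot = random_orthonormal(rng, cfg.natural_dim)
    nat_basis = _natural_basis(cfg)
    eco_basis = nat_basis @ eco_rot
    eco_spec = power_law_spectrum(cfg.natural_dim, cfg.eco_alpha)
    model_basis, model_spec = make_aligned_subspace(
        eco_basis, cfg.model_alpha, cfg.alignment_pressure, derive_seed(cfg.seed, "model")
    )
    n = cfg.n_train + cfg.n_test
    if cfg.noise_before_projection and cfg.noise_sigma > 0:
        x = x + cfg.noise_sigma * rng.standard_normal(x.shape)
    y = (x @ eco_basis) * np.sqrt(eco_spec)
    z = (x @ model_basis) * np.sqrt(model_spec)
    if not cfg.noise_before_projection and cfg.noise_sigma > 0:
        y = y + cfg.noise_sigma * rng.standard_normal(y.shape)
        z = z + cfg.noise_sigma * rng.standard_normal(z.shape)
    tr, te = slice(0, cfg.n_train), slice(cfg.n_train, n)

    use_pls = cfg.regression == "pls" or cfg.n_train <= z.shape[1]
    if use_pls:  # OLS would be singular below n_train <= dims; fall back
        n_comp = min(25, cfg.n_train - 1, z.shape[1])
        pls = PLSRegression(n_components=n_comp, scale=False, max_iter=1000)
        pls.fit(z[tr], y[tr])
        pred = pls.predict(z[te])
    else:
        zc = z[tr] - z[tr].mean(axis=0)
        yc = y[tr] - y[tr].mean(axis=0)
        beta, *_ = np.linalg.lstsq(zc, yc, rcond=None)
        pred = (z[te] - z[tr].mean(axis=0)) @ beta + y[tr].mean(axis=0)
    r2 = _holdout_r2(y[te], pred)
    raw = float(np.nanmean(r2))
    score = max(raw, 0.0)
    return (score, raw) if return_raw else score


def _natural_basis(config: SubspaceSimConfig) -> np.ndarray:
    """The natural-subspace basis used by :func:`sample_natural_observations`."""
    rng = spawn_rng(config.seed, "natural")
    return random_orthonormal(rng, config.ambient_dim, config.natural_dim)


def run_regime_sweep(
    config_grid: list[SubspaceSimConfig], n_replicates: int, seed: int
) -> pd.DataFrame:
    """One encoding score per grid point per replicate.

    Returns rows (model_ED, AP, encoding_score, raw_score, replicate,
    grid_index); model_ED is the analytic participation ratio of the model
    gain spectrum, not an estimate.
    """
    if not config_grid:
        raise ValueError("config grid is empty")
    rows = []
    for gi, cfg in enumerate(config_grid):
        for rep in range(n_replicates):
            cfg_r = replace(cfg, seed=derive_seed(seed, "sweep", gi, rep))
            score, raw = simulate_encoding_experiment(cfg_r, return_raw=True)
            rows.append(
                {
                    "grid_index": gi,
                    "model_ED": cfg.model_ed,
                    "AP": cfg.alignment_pressure,
                    "model_alpha": cfg.model_alpha,
                    "encoding_score": score,
                    "raw_score": raw,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def alpha_for_target_ed(target_ed: float, n_dims: int) -> float:
    """Invert the ED(alpha) map of a truncated power-law spectrum by bisection."""
    if not 1.0 <= target_ed <= n_dims:
        raise ValueError(f"target ED must lie in [1, {n_dims}]")

    def ed(alpha: float) -> float:
        return analytic_participation_ratio(power_law_spectrum(n_dims, alpha))

    lo, hi = 0.0, 50.0  # ED is decreasing in alpha
    if target_ed >= ed(lo):
        return lo
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ed(mid) > target_ed:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def dimensionality_regime_grid(
    ed_grid: np.ndarray | None = None,
    ap: float = 0.25,
    **overrides,
) -> list[SubspaceSimConfig]:
    """Fixed moderate AP, log-spaced model-ED grid: ED drives performance."""
    base = SubspaceSimConfig(**overrides) if overrides else SubspaceSimConfig()
    if ed_grid is None:
        ed_grid = np.geomspace(2.0, 50.0, 8)
    return [
        replace(
            base,
            alignment_pressure=ap,
            model_alpha=alpha_for_target_ed(float(ed), base.natural_dim),
        )
        for ed in ed_grid
    ]


def alignment_regime_grid(
    ap_grid: np.ndarray | None = None,
    model_alpha: float = 0.8,
    **overrides,
) -> list[SubspaceSimConfig]:
    """Fixed model ED, AP grid 0..1: alignment drives performance."""
    base = SubspaceSimConfig(**overrides) if overrides else SubspaceSimConfig()
    if ap_grid is None:
        ap_grid = np.linspace(0.0, 1.0, 5)
    return [
        replace(base, model_alpha=model_alpha, alignment_pressure=float(ap))
        for ap in ap_grid
    ]


def joint_regime_grid(
    ed_grid: np.ndarray | None = None,
    ed_star: float = 10.0,
    log_width: float = 0.4,
    ap_max: float = 1.0,
    **overrides,
) -> list[SubspaceSimConfig]:
    """AP is a peaked (log-Gaussian) function of model ED: an optimal ED exists.

    AP(ED) = ap_max * exp(-(ln ED - ln ed_star)^2 / (2 log_width^2)).

    The preset pairs the peaked link with a concentrated ecological spectrum,
    low observation noise, and a capacity-limited PLS readout, the conditions
    under which alignment (not raw dimensionality) dominates performance.
    """
    defaults = dict(eco_alpha=1.5, noise_sigma=0.05, regression="pls")
    defaults.update(overrides)
    base = SubspaceSimConfig(**defaults)
    if ed_grid is None:
        ed_grid = np.geomspace(2.0, 50.0, 9)
    grid = []
    for ed in ed_grid:
        ap = ap_max * float(
            np.exp(-((np.log(ed) - np.log(ed_star)) ** 2) / (2.0 * log_width**2))
        )
        grid.append(
            replace(
                base,
                alignment_pressure=ap,
                model_alpha=alpha_for_target_ed(float(ed), base.natural_dim),
            )
        )
    return grid
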