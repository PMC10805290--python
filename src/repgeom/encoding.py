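"""Cross-validated neural encoding models and their noise ceiling.

The pipeline mirrors the standard encoding-model benchmark for primate
electrophysiology: features are optionally reduced by projecting onto the
principal components of a reference feature set, a partial-least-squares
(25 latent components) or ordinary-least-squares regression predicts each
unit's trial-averaged response under k-fold cross-validation, per-unit
Pearson correlations are aggregated by the median, and the aggregate is
normalized by the median split-half reliability across units via the squared
quotient (r / r_ceil)^2 — an explained-variance fraction relative to the
noise ceiling.  A representational-similarity alternative involving no
parameter fitting is also provided.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from ._rng import spawn_rng
from .types import FeatureMatrix, NeuralRecordingSet

__all__ = [
    "EncodingResult",
    "ReliabilitySet",
    "ReliabilityUnavailableError",
    "pca_reduce",
    "fit_cv_encoder",
    "split_half_reliability",
    "normalized_encoding_score",
    "rsa_score",
]

logger = logging.getLogger(__name__)


class ReliabilityUnavailableError(ValueError):
    """Raised when split-half reliability is requested without trial repeats."""


@dataclass
class EncodingResult:
    per_unit_r: np.ndarray
    median_r: float
    n_folds: int
    n_pls_components: int | None
    variant: str
    aggregate: str
    n_dropped_units: int = 0
    ceiling_median: float | None = None
    normalized_score: float | None = None


@dataclass
class ReliabilitySet:
    per_unit_ceiling: np.ndarray
    n_splits: int
    corrected: bool

    @property
    def median(self) -> float:
        return float(np.nanmedian(self.per_unit_ceiling))


def pca_reduce(
    features: FeatureMatrix, reference: FeatureMatrix, n_components: int = 1000
) -> FeatureMatrix:
    """Project features onto the top principal components of a reference set.

    The reference plays the role of an independent image sample used purely
    to fix the projection; features are centered by the reference mean and
    projected onto the reference's leading components.  If the reference
    supports fewer than ``n_components`` directions, the effective count is
    used (and reflected in the output channel count).
    """
    if features.n_channels != reference.n_channels:
        raise ValueError(
            f"channel mismatch: features have {features.n_channels}, "
            f"reference has {reference.n_channels}"
        )
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    mean = reference.values.mean(axis=0)
    refc = reference.values - mean
    _, s, vt = np.linalg.svd(refc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size and s[0] > 0 else 0
    if rank == 0:
        raise ValueError("reference features are constant")
    k = min(n_components, rank)
    if k < n_components:
        logger.info("pca_reduce: using %d of %d requested components", k, n_components)
    projected = (features.values - mean) @ vt[:k].T
    return FeatureMatrix(projected, stimulus_ids=list(features.stimulus_ids))


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r between two equally-shaped arrays; NaN where undefined."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    num = (ac * bc).sum(axis=0)
    den = np.sqrt(np.square(ac).sum(axis=0) * np.square(bc).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def _fold_indices(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Contiguous blocks of a seeded shuffle of the stimulus indices."""
    if not 2 <= n_folds <= n:
        raise ValueError(f"need 2 <= n_folds <= n_stimuli, got {n_folds} folds for {n}")
    perm = rng.permutation(n)
    return [np.sort(block) for block in np.array_split(perm, n_folds)]


def fit_cv_encoder(
    features: FeatureMatrix,
    recordings: NeuralRecordingSet,
    variant: str = "pls_monkey",
    n_components: int = 25,
    n_folds: int | None = None,
    seed: int = 0,
    aggregate: str = "fold_mean",
) -> EncodingResult:
    """Cross-validated linear encoding model from features to units.

    variant "pls_monkey": partial-least-squares regression with 25 latent
    components under 10-fold cross-validation; per-unit Pearson correlations
    between predicted and held-out responses are averaged across folds
    (``aggregate="fold_mean"``, the default) or computed once on the
    concatenated held-out predictions (``aggregate="concatenate"``).
    variant "ols_fmri": 9-fold cross-validated ordinary least squares with
    per-fold-mean correlations and no latent-component cap.

    Repeats are trial-averaged before fitting.  Units whose held-out
    responses have zero variance in a fold get an undefined correlation for
    that fold; such folds are excluded from the unit's aggregate.
    """
    if variant not in ("pls_monkey", "ols_fmri"):
        raise ValueError("variant must be 'pls_monkey' or 'ols_fmri'")
    if aggregate not in ("fold_mean", "concatenate"):
        raise ValueError("aggregate must be 'fold_mean' or 'concatenate'")
    if features.stimulus_ids != recordings.stimulus_ids:
        raise ValueError("features and recordings must share aligned stimulus_ids")
    if n_folds is None:
        n_folds = 10 if variant == "pls_monkey" else 9
    x = features.values
    y = recordings.repeat_mean()
    n, n_units = y.shape
    rng = spawn_rng(seed, "cv_folds")
    folds = _fold_indices(n, n_folds, rng)

    fold_rs = np.full((n_folds, n_units), np.nan)
    y_hat = np.full_like(y, np.nan)
    pls_components: int | None = None
    for fi, test_idx in enumerate(folds):
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        x_tr, y_tr = x[train_mask], y[train_mask]
        if variant == "pls_monkey":
            k = min(n_components, x_tr.shape[0] - 1, x_tr.shape[1])
            pls_components = k
            model = PLSRegression(n_components=k, scale=False, max_iter=1000)
            model.fit(x_tr, y_tr)
            pred = np.asarray(model.predict(x[test_idx]))
        else:
            mu_x, mu_y = x_tr.mean(axis=0), y_tr.mean(axis=0)
            beta, *_ = np.linalg.lstsq(x_tr - mu_x, y_tr - mu_y, rcond=None)
            pred = (x[test_idx] - mu_x) @ beta + mu_y
        if pred.ndim == 1:
            pred = pred[:, None]
        y_hat[test_idx] = pred
        fold_rs[fi] = _pearson_columns(pred, y[test_idx])

    if aggregate == "fold_mean":
        with np.errstate(invalid="ignore"):
            per_unit_r = np.nanmean(fold_rs, axis=0)
    else:
        per_unit_r = _pearson_columns(y_hat, y)
    n_dropped = int(np.isnan(per_unit_r).sum())
    if n_dropped:
        logger.warning("%d unit(s) had undefined correlations; excluded", n_dropped)
    return EncodingResult(
        per_unit_r=per_unit_r,
        median_r=float(np.nanmedian(per_unit_r)),
        n_folds=n_folds,
        n_pls_components=pls_components,
        variant=variant,
        aggregate=aggregate,
        n_dropped_units=n_dropped,
    )


def split_half_reliability(
    recordings: NeuralRecordingSet,
    n_splits: int = 10,
    corrected: bool = True,
    seed: int = 0,
) -> ReliabilitySet:
    """Per-unit split-half reliability (noise ceiling).

    Repeats are randomly partitioned into two halves; each half is averaged
    per stimulus and the two stimulus-wise means are correlated per unit.
    The correlation is averaged over ``n_splits`` random partitions, with the
    Spearman-Brown correction 2r/(1+r) applied to the averaged value when
    ``corrected`` (the correction predicts the reliability of the full set of
    repeats from that of half the repeats).
    """
    r = recordings.n_repeats
    if r < 2:
        raise ReliabilityUnavailableError(
            "split-half reliability needs at least 2 trial repeats"
        )
    rng = spawn_rng(seed, "split_half")
    vals = recordings.values
    accum = np.zeros(recordings.n_units)
    for _ in range(n_splits):
        perm = rng.permutation(r)
        half_a = vals[:, :, perm[: r // 2]].mean(axis=2)
        half_b = vals[:, :, perm[r // 2 :]].mean(axis=2)
        accum += _pearson_columns(half_a, half_b)  # NaN (constant unit) propagates
    ceiling = accum / n_splits
    if corrected:
        ceiling = 2.0 * ceiling / (1.0 + ceiling)
    return ReliabilitySet(per_unit_ceiling=ceiling, n_splits=n_splits, corrected=corrected)


def normalized_encoding_score(result: EncodingResult, reliability: ReliabilitySet) -> float:
    """Squared quotient (median r / median ceiling)^2: ceiling-relative
    explained variance."""
    ceil = reliability.median
    if not ceil > 0:
        raise ValueError(f"noise-ceiling median must be > 0, got {ceil}")
    return float((result.median_r / ceil) ** 2)


def _rdm(x: np.ndarray) -> np.ndarray:
    """Representational dissimilarity matrix: 1 - Pearson r across columns."""
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant rows: dissimilarity undefined")
    return 1.0 - np.corrcoef(x)


def rsa_score(features: FeatureMatrix, recordings: NeuralRecordingSet) -> float:
    """Representational similarity: Spearman rank correlation between the
    upper triangles of the feature and response dissimilarity matrices.

    Involves no parameter fitting, so it is immune to regression overfitting.
    """
    if features.stimulus_ids != recordings.stimulus_ids:
        raise ValueError("features and recordings must share aligned stimulus_ids")
    n = features.n_stimuli
    if n < 3:
        raise ValueError("RSA needs at least 3 stimuli")
    rdm_f = _rdm(features.values)
    rdm_r = _rdm(recordings.repeat_mean())
    iu = np.triu_indices(n, k=1)
    rho, _ = stats.spearmanr(rdm_f[iu], rdm_r[iu])
    return float(rho)
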