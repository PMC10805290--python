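"""Deterministic seed derivation.

Every stochastic operation derives its own seed from a global seed plus a
stable name, so changing one stage of a pipeline never perturbs another.
"""
from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "spawn_rng", "random_orthonormal", "sample_uniform_ball"]


def derive_seed(seed: int, *names: object) -> int:
    """Derive a child seed (< 2**31) from ``seed`` and a path of names."""
    key = "/".join(str(x) for x in (seed, *names))
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def spawn_rng(seed: int, *names: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(seed, *names))


def random_orthonormal(rng: np.random.Generator, n: int, k: int | None = None) -> np.ndarray:
    """Random n x k matrix with orthonormal columns (Haar via QR, sign-fixed)."""
    k = n if k is None else k
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got n={n}, k={k}")
    a = rng.standard_normal((n, k))
    q, r = np.linalg.qr(a)
    d = np.diagonal(r)
    q = q * np.where(d == 0.0, 1.0, np.sign(d))
    return q


def sample_uniform_ball(
    rng: np.random.Generator, n: int, d: int, radius: float = 1.0
) -> np.ndarray:
    """n points uniform in the volume of a d-ball: direction x radius*U^(1/d)."""
    if d < 1:
        raise ValueError("ball dimension must be >= 1")
    g = rng.standard_normal((n, d))
    norms = np.linalg.norm(g, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    u = rng.random(n) ** (1.0 / d)
    return radius * (g / norms) * u[:, None]
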