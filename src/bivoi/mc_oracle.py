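"""Monte-Carlo estimation of ``E(max(Y1, Y2, 0))`` for bivariate normal Y.

Serves as the independent verification oracle for the closed-form 2-D UNLI.
Sampling uses ``Y = mu + L @ Z`` with ``L`` the lower-triangular Cholesky
factor of the covariance and a generator seeded explicitly per call, so every
estimate is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bivoi.core_unli import BVNParams

__all__ = ["MCEstimate", "mc_max_expectation"]


@dataclass(frozen=True)
class MCEstimate:
    """A Monte-Carlo mean with its standard error and provenance."""

    mean: float
    se: float
    n: int
    seed: int


def _draw(p: BVNParams, n: int, seed: int) -> np.ndarray:
    """``n`` bivariate-normal draws, shape (n, 2), via the Cholesky factor."""
    cov = np.array(
        [
            [p.sigma1**2, p.rho * p.sigma1 * p.sigma2],
            [p.rho * p.sigma1 * p.sigma2, p.sigma2**2],
        ]
    )
    lower = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    return z @ lower.T + np.array([p.mu1, p.mu2])


def mc_max_expectation(p: BVNParams, n: int, seed: int) -> MCEstimate:
    """Estimate ``E(max(Y1, Y2, 0))`` from ``n`` bivariate-normal draws.

    Parameters
    ----------
    p
        Bivariate-normal parameters of ``(Y1, Y2)``.
    n
        Number of draws, at least 2 (the SE needs a sample variance).
    seed
        Seed for a fresh ``numpy.random.default_rng``; no global state.
    """
    if not isinstance(p, BVNParams):
        raise ValueError("p must be a BVNParams instance")
    n = int(n)
    if n < 2:
        raise ValueError(f"n must be >= 2, got {n}")
    y = _draw(p, n, seed)
    positive_part = np.maximum(np.max(y, axis=1), 0.0)
    mean = float(positive_part.mean())
    se = float(positive_part.std(ddof=1) / np.sqrt(n))
    return MCEstimate(mean=mean, se=se, n=n, seed=int(seed))
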