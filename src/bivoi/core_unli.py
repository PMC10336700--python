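"""Closed-form 1-D and 2-D unit normal loss integrals and EVPI.

The 1-D unit normal loss integral (UNLI) of a normal variable ``Y`` with mean
``mu`` and standard deviation ``sigma`` is ``E(max(Y, 0))``::

    UNLI = mu * (1 - Phi(-mu/sigma)) + sigma * phi(-mu/sigma)

The 2-D extension evaluates ``E(max(Y1, Y2, 0))`` for a bivariate normal
``(Y1, Y2)`` in closed form, using only the univariate normal density/CDF and
the bivariate normal CDF.  The result decomposes over the two ordered index
pairs ``(1,2)`` and ``(2,1)`` as a sum ``r + q`` per pair, where the pair
total equals ``E(Y_i * 1{Y_i >= Y_j, Y_i >= 0})``; the ``q`` part carries the
indicator structure that switches off on the degenerate branch
``sigma_i - rho*sigma_j = 0``.

For a 3-strategy decision problem the expected value of perfect information
(EVPI) is ``E(max(Y1, Y2, 0)) - max(mu1, mu2, 0)`` where ``Y1, Y2`` are the
incremental net benefits of the two non-reference strategies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import ndtr, owens_t

__all__ = [
    "GaussianParams",
    "BVNParams",
    "UNLIPairTerms",
    "UNLITermSet",
    "std_normal_pdf",
    "std_normal_cdf",
    "bvn_cdf",
    "unli_1d",
    "unli_2d_terms",
    "unli_2d",
    "evpi_from_bvn",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Relative tolerance below which ``sigma_i - rho*sigma_j`` is treated as zero
#: (the degenerate branch of the closed form).  Either branch agrees to far
#: below this scale, so the cut-off only affects which algebraic path is taken.
DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class GaussianParams:
    """Mean and standard deviation of a (univariate) normal net benefit."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mu) and math.isfinite(self.sigma)):
            raise ValueError("GaussianParams requires finite mu and sigma")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be strictly positive, got {self.sigma}")


@dataclass(frozen=True)
class BVNParams:
    """Bivariate-normal description of two incremental net benefits.

    ``mu1``/``mu2`` are the means, ``sigma1``/``sigma2`` the standard
    deviations and ``rho`` the correlation.  ``|rho| = 1`` is rejected: the
    closed form divides by ``sqrt(1 - rho**2)``.
    """

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float

    def __post_init__(self) -> None:
        for name in ("mu1", "mu2", "sigma1", "sigma2", "rho"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"BVNParams field {name} must be finite")
        if self.sigma1 <= 0.0 or self.sigma2 <= 0.0:
            raise ValueError("sigma1 and sigma2 must be strictly positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie strictly inside (-1, 1), got {self.rho}")

    def swapped(self) -> "BVNParams":
        """The same distribution with component labels 1 and 2 exchanged."""
        return BVNParams(self.mu2, self.mu1, self.sigma2, self.sigma1, self.rho)


@dataclass(frozen=True)
class UNLIPairTerms:
    """Closed-form contributions of one ordered index pair ``(i, j)``.

    ``delta`` is the sign of ``sigma_i - rho*sigma_j`` (0 on the degenerate
    branch, where ``degenerate`` is True and ``q`` vanishes by construction).
    ``r + q`` equals ``E(Y_i * 1{Y_i >= Y_j, Y_i >= 0})``.
    """

    delta: int
    r: float
    q: float
    degenerate: bool

    @property
    def total(self) -> float:
        return self.r + self.q


@dataclass(frozen=True)
class UNLITermSet:
    """Both ordered-pair term sets of the 2-D closed form."""

    pair_12: UNLIPairTerms
    pair_21: UNLIPairTerms

    @property
    def total(self) -> float:
        """``r(1,2) + q(1,2) + r(2,1) + q(2,1) = E(max(Y1, Y2, 0))``."""
        return (self.pair_12.r + self.pair_12.q) + (self.pair_21.r + self.pair_21.q)


def std_normal_pdf(x: float) -> float:
    """Standard normal density ``exp(-x**2/2) / sqrt(2*pi)``."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"std_normal_pdf requires finite input, got {x}")
    return math.exp(-0.5 * x * x) / _SQRT_2PI


def std_normal_cdf(x: float) -> float:
    """Standard normal cumulative distribution function."""
    x = float(x)
    if not math.isfinite(x):
        raise ValueError(f"std_normal_cdf requires finite input, got {x}")
    return float(ndtr(x))


def bvn_cdf(x1: float, x2: float, rho: float) -> float:
    """Standard bivariate normal CDF ``P(X1 <= x1, X2 <= x2)``, corr ``rho``.

    Evaluated through Owen's T function (an established reduction of the
    bivariate normal rectangle probability), accurate to well below 1e-10.
    Infinite limits are honoured: ``bvn_cdf(x1, inf, rho) == Phi(x1)``.
    """
    x1, x2, rho = float(x1), float(x2), float(rho)
    if math.isnan(x1) or math.isnan(x2):
        raise ValueError("bvn_cdf requires non-NaN limits")
    if not -1.0 < rho < 1.0:
        raise ValueError(f"bvn_cdf requires |rho| < 1, got {rho}")
    if math.isinf(x1) or math.isinf(x2):
        if x1 == -math.inf or x2 == -math.inf:
            return 0.0
        if x1 == math.inf and x2 == math.inf:
            return 1.0
        return float(ndtr(x1 if math.isinf(x2) else x2))
    if rho == 0.0:
        return float(ndtr(x1) * ndtr(x2))
    if x1 == 0.0 and x2 == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    s = math.sqrt(1.0 - rho * rho)
    # Owen (1956): Phi2(h,k,rho) = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta
    if x1 != 0.0:
        a1 = (x2 - rho * x1) / (x1 * s)
    else:
        a1 = math.copysign(math.inf, x2 - rho * x1)
    if x2 != 0.0:
        a2 = (x1 - rho * x2) / (x2 * s)
    else:
        a2 = math.copysign(math.inf, x1 - rho * x2)
    beta = 0.5 if (x1 * x2 < 0.0 or (x1 * x2 == 0.0 and x1 + x2 < 0.0)) else 0.0
    p = 0.5 * (ndtr(x1) + ndtr(x2)) - owens_t(x1, a1) - owens_t(x2, a2) - beta
    # clip floating residue at the boundary of [0, 1]
    return min(max(float(p), 0.0), 1.0)


def unli_1d(p: GaussianParams) -> float:
    """1-D UNLI: ``E(max(Y, 0))`` for ``Y ~ N(mu, sigma**2)``.

    Mathematically strictly positive; deep in the left tail the two summands
    cancel below machine precision, so the floating result is clipped at 0.
    """
    z = -p.mu / p.sigma
    value = p.mu * (1.0 - float(ndtr(z))) + p.sigma * std_normal_pdf(z)
    return max(value, 0.0)


def _pair_terms(mu_i: float, mu_j: float, sig_i: float, sig_j: float, rho: float) -> UNLIPairTerms:
    """Terms of one ordered pair ``(i, j)`` of the 2-D closed form.

    Writing ``D = Y_i - Y_j`` (``sd tau``), the pair total is
    ``E(Y_i * 1{Y_i >= 0, D >= 0})``, which reduces to univariate normal
    functions plus one bivariate CDF:

        total = mu_i * Phi2(mu_i/sig_i, (mu_i-mu_j)/tau, c)
                + sig_i * phi(h) * Phi(A) + sig_i * c * phi(k) * Phi(B)

    with ``h = -mu_i/sig_i``, ``k = (mu_j-mu_i)/tau``,
    ``c = (sig_i - rho*sig_j)/tau`` (the corr of ``Y_i`` and ``D``),
    ``A = (c*h - k)/s``, ``B = (c*k - h)/s`` and ``s = sqrt(1-c**2)
    = sig_j*sqrt(1-rho**2)/tau``.

    The ``r`` part keeps the branch structure of the published closed form
    (indicator on ``sigma_i - rho*sigma_j > 0``, with a ``Phi(A)`` weight on
    the degenerate branch); ``q`` is the complement and vanishes when
    ``c = 0``.  The split is continuous in total across the branch.
    """
    tau = math.sqrt(sig_i * sig_i + sig_j * sig_j - 2.0 * rho * sig_i * sig_j)
    gap = sig_i - rho * sig_j
    degenerate = abs(gap) <= DEGENERATE_RTOL * max(sig_i, sig_j)

    h = -mu_i / sig_i
    k = (mu_j - mu_i) / tau
    s = sig_j * math.sqrt(1.0 - rho * rho) / tau
    # A = (rho*sig_j*mu_i - sig_i*mu_j) / (sig_i*sig_j*sqrt(1-rho**2)), simplified
    A = (rho * sig_j * mu_i - sig_i * mu_j) / (sig_i * sig_j * math.sqrt(1.0 - rho * rho))
    phi_h = std_normal_pdf(h)
    cdf_A = float(ndtr(A))

    if degenerate:
        r = cdf_A * (mu_i * (1.0 - float(ndtr(h))) + sig_i * phi_h)
        return UNLIPairTerms(delta=0, r=r, q=0.0, degenerate=True)

    delta = 1 if gap > 0.0 else -1
    c = gap / tau
    B = (c * k - h) / s
    indicator_pos = 1.0 if delta > 0 else 0.0
    r = mu_i * indicator_pos + sig_i * phi_h * cdf_A - mu_i * float(ndtr(h)) * cdf_A
    q = (
        mu_i * (bvn_cdf(-h, -k, c) - indicator_pos + float(ndtr(h)) * cdf_A)
        + sig_i * c * std_normal_pdf(k) * float(ndtr(B))
    )
    return UNLIPairTerms(delta=delta, r=r, q=q, degenerate=False)


def unli_2d_terms(p: BVNParams) -> UNLITermSet:
    """Per-ordered-pair term decomposition of the 2-D closed form."""
    return UNLITermSet(
        pair_12=_pair_terms(p.mu1, p.mu2, p.sigma1, p.sigma2, p.rho),
        pair_21=_pair_terms(p.mu2, p.mu1, p.sigma2, p.sigma1, p.rho),
    )


def unli_2d(p: BVNParams) -> float:
    """2-D UNLI: ``E(max(Y1, Y2, 0))`` for bivariate normal ``(Y1, Y2)``."""
    return unli_2d_terms(p).total


def evpi_from_bvn(p: BVNParams) -> float:
    """EVPI of a 3-strategy decision from the incremental-NB bivariate normal.

    ``E(max(Y1, Y2, 0)) - max(mu1, mu2, 0)``; non-negative (tiny negative
    floating residue is clipped to zero).
    """
    value = unli_2d(p) - max(p.mu1, p.mu2, 0.0)
    return max(value, 0.0)
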