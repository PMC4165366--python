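"""Count distributions and transforms underlying allelic-imbalance inference.

The observation model for the reads covering one heterozygous SNV is
beta-binomial: conditional on a locus-level success probability drawn from a
Beta distribution with mean ``mu`` and intra-class correlation ``rho``, the
reference-allele count is binomial.  ``rho = 0`` collapses exactly to
Binomial(n, mu); otherwise the variance is inflated to
``mu (1 - mu) n (rho (n - 1) + 1)``.

Allelic proportions are mapped to an approximately normal scale with the
Freeman-Tukey double-arcsine transform, whose nominal variance ``1/(n + 0.5)``
does not depend on the underlying proportion.  A global "pre-existing bias"
parameter ``f`` (probability of observing a given allele when the two
haplotypes are expressed equally, e.g. reference-mapping bias) maps between
the transcript-scale haplotype frequency and the observed read-level mean via
an odds weighting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BetaBinomialSpec",
    "BiasSpec",
    "FtValue",
    "ft_transform",
    "ft_backtransform",
    "ft_variance",
    "bias_adjusted_mu",
    "bias_invert_mu",
    "betabin_sample",
]


@dataclass(frozen=True)
class BetaBinomialSpec:
    """Parameters of a beta-binomial read-count law at one locus.

    Parameters
    ----------
    n : int
        Total read count at the locus (> 0).
    mu : float
        Mean allele proportion, strictly inside (0, 1).
    rho : float
        Overdispersion (intra-class correlation) in [0, 1).
    """

    n: int
    mu: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be a positive integer, got {self.n}")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie strictly in (0, 1), got {self.mu}")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must lie in [0, 1), got {self.rho}")

    @property
    def mean(self) -> float:
        return self.n * self.mu

    @property
    def variance(self) -> float:
        return self.mu * (1.0 - self.mu) * self.n * (self.rho * (self.n - 1) + 1.0)

    def alpha_beta(self) -> tuple[float, float]:
        """(alpha, beta) of the mixing Beta; requires rho > 0."""
        if self.rho <= 0.0:
            raise ValueError("rho = 0 is binomial; no Beta mixing distribution")
        scale = (1.0 - self.rho) / self.rho
        return self.mu * scale, (1.0 - self.mu) * scale


@dataclass(frozen=True)
class BiasSpec:
    """Global pre-existing allelic bias.

    ``f_ref_null`` is the probability of observing the reference allele at a
    locus whose two haplotypes are expressed equally; 0.5 means no bias.
    """

    f_ref_null: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.f_ref_null < 1.0:
            raise ValueError("f_ref_null must lie strictly in (0, 1)")

    @property
    def is_neutral(self) -> bool:
        return self.f_ref_null == 0.5


@dataclass(frozen=True)
class FtValue:
    """A Freeman-Tukey transformed count with its nominal variance."""

    z: float
    variance: float
    n: int


def ft_transform(x, n, rho: float = 0.0):
    """Freeman-Tukey double-arcsine transform of count ``x`` out of ``n``.

    z = asin(sqrt(x / (n + 1))) + asin(sqrt((x + 1) / (n + 1)))

    Under a binomial model ``z`` is approximately normal with mean
    ``2 asin(sqrt(p))`` and variance ``1 / (n + 0.5)``; beta-binomial
    overdispersion inflates the variance by ``rho (n - 1) + 1``
    (delta-method propagation of the count variance).

    Accepts scalars (returns :class:`FtValue`) or arrays (returns
    ``(z, variance)`` arrays).
    """
    x_arr = np.asarray(x)
    n_arr = np.asarray(n)
    if np.any(n_arr < 1):
        raise ValueError("n must be >= 1")
    if np.any((x_arr < 0) | (x_arr > n_arr)):
        raise ValueError("x must satisfy 0 <= x <= n")
    z = np.arcsin(np.sqrt(x_arr / (n_arr + 1.0))) + np.arcsin(
        np.sqrt((x_arr + 1.0) / (n_arr + 1.0))
    )
    variance = (rho * (n_arr - 1.0) + 1.0) / (n_arr + 0.5)
    if np.isscalar(x) and np.isscalar(n):
        return FtValue(z=float(z), variance=float(variance), n=int(n))
    return z, variance


def ft_variance(n, rho: float = 0.0):
    """Variance of the FT score at total count ``n`` under overdispersion ``rho``."""
    n_arr = np.asarray(n, dtype=float)
    return (rho * (n_arr - 1.0) + 1.0) / (n_arr + 0.5)


def ft_backtransform(z):
    """Invert the FT mean map: return p with 2 asin(sqrt(p)) = z, clipped to [0, 1]."""
    z_arr = np.clip(np.asarray(z, dtype=float), 0.0, np.pi)
    p = np.sin(z_arr / 2.0) ** 2
    if np.isscalar(z):
        return float(p)
    return p


def bias_adjusted_mu(maf, f_allele_null):
    """Observed read-level mean for a haplotype at transcript frequency ``maf``.

    mu = maf * f / (maf * f + (1 - maf) * (1 - f))

    where ``f`` is the observation probability of that haplotype's allele under
    balanced expression.  Identity when f = 0.5.
    """
    maf_arr = np.asarray(maf, dtype=float)
    f_arr = np.asarray(f_allele_null, dtype=float)
    if np.any((maf_arr <= 0) | (maf_arr >= 1) | (f_arr <= 0) | (f_arr >= 1)):
        raise ValueError("maf and f_allele_null must lie strictly in (0, 1)")
    mu = maf_arr * f_arr / (maf_arr * f_arr + (1.0 - maf_arr) * (1.0 - f_arr))
    if np.isscalar(maf) and np.isscalar(f_allele_null):
        return float(mu)
    return mu


def bias_invert_mu(mu, f_allele_null):
    """Inverse of :func:`bias_adjusted_mu`: observed mean back to transcript MAF."""
    mu_arr = np.asarray(mu, dtype=float)
    f_arr = np.asarray(f_allele_null, dtype=float)
    if np.any((mu_arr <= 0) | (mu_arr >= 1) | (f_arr <= 0) | (f_arr >= 1)):
        raise ValueError("mu and f_allele_null must lie strictly in (0, 1)")
    maf = mu_arr * (1.0 - f_arr) / (mu_arr * (1.0 - f_arr) + f_arr * (1.0 - mu_arr))
    if np.isscalar(mu) and np.isscalar(f_allele_null):
        return float(maf)
    return maf


def betabin_draw(rng: np.random.Generator, n, mu, rho, size):
    """Vectorized beta-binomial draw on an existing Generator.

    ``n`` and ``mu`` broadcast against ``size``.  rho = 0 short-circuits to
    binomial sampling (no division by zero in the Beta parameterization).
    """
    n_arr = np.broadcast_to(np.asarray(n), size)
    if rho <= 0.0:
        return rng.binomial(n_arr, np.broadcast_to(np.asarray(mu), size))
    scale = (1.0 - rho) / rho
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), size)
    p = rng.beta(mu_arr * scale, (1.0 - mu_arr) * scale, size=size)
    return rng.binomial(n_arr, p)


def betabin_sample(spec: BetaBinomialSpec, size: int, seed: int) -> np.ndarray:
    """Draw ``size`` i.i.d. beta-binomial counts under ``spec``, reproducibly."""
    if size < 1:
        raise ValueError("size must be positive")
    rng = np.random.default_rng(seed)
    return betabin_draw(rng, spec.n, spec.mu, spec.rho, (size,))
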