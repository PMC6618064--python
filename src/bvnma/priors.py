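"""Prior distribution constructors shared by all model variants.

The defaults follow common vague-prior practice for hierarchical
normal-normal meta-analysis fitted in BUGS-family software: N(0, 10^4) on
pooled means, N(0, 10^3) on basic parameters, U(0, 2) on between-study and
ancillary standard deviations, a scaled Beta(1.5, 1.5) on correlations
(rho = 2B - 1 with B ~ Beta(1.5, 1.5), support exactly [-1, 1], symmetric
about zero and vanishing at the endpoints), and for the exchangeable
ancillary-variance hierarchy a truncated normal on each variance gamma^2
with a Gamma(1.0, 0.01) (shape-rate, mean 100) hyperprior on its scale.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


class PriorParameterError(ValueError):
    """A prior hyperparameter is outside its admissible range."""


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the shared prior family.

    sd_upper
        Upper bound of the uniform priors on between-study and ancillary
        standard deviations (same scale as the effect estimates).
    corr_beta_shape
        Common shape of the symmetric Beta prior behind every correlation.
    basic_param_var
        Variance of the normal prior on basic parameters d_j1k.
    pooled_mean_var
        Variance of the normal prior on pooled means beta_j.
    ancillary_var_gamma_shape / ancillary_var_gamma_rate
        Shape and rate (BUGS convention) of the Gamma hyperprior on the
        common scale v_j of the exchangeable ancillary variances.
    """

    sd_upper: float = 2.0
    corr_beta_shape: float = 1.5
    basic_param_var: float = 1e3
    pooled_mean_var: float = 1e4
    ancillary_var_gamma_shape: float = 1.0
    ancillary_var_gamma_rate: float = 0.01

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not (math.isfinite(v) and v > 0):
                raise PriorParameterError(f"{name} must be strictly positive, got {v!r}")

    def to_dict(self) -> dict:
        return asdict(self)


class ScaledBetaCorrelation:
    """Prior over [-1, 1] via rho = 2B - 1, B ~ Beta(shape, shape)."""

    def __init__(self, shape: float) -> None:
        if not (math.isfinite(shape) and shape > 0):
            raise PriorParameterError(f"shape must be > 0, got {shape!r}")
        self.shape = float(shape)
        self.support = (-1.0, 1.0)

    def logpdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        # density of rho = 2B - 1: f(r) = beta((r+1)/2) / 2
        out = stats.beta.logpdf((rho + 1.0) / 2.0, self.shape, self.shape) - math.log(2.0)
        return out

    def pdf(self, rho):
        return np.exp(self.logpdf(rho))

    def rvs(self, size=None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng() if rng is None else rng
        return 2.0 * rng.beta(self.shape, self.shape, size=size) - 1.0

    def moment_sd(self) -> float:
        """Closed-form prior sd of rho: 2 * sd(B) = 1/sqrt(2a+1)... times 2."""
        a = self.shape
        var_b = a * a / ((2 * a) ** 2 * (2 * a + 1))
        return 2.0 * math.sqrt(var_b)


class UniformSd:
    """Uniform prior on [0, upper] for a standard deviation."""

    def __init__(self, upper: float) -> None:
        if not (math.isfinite(upper) and upper > 0):
            raise PriorParameterError(f"upper must be > 0, got {upper!r}")
        self.upper = float(upper)
        self.support = (0.0, self.upper)

    def logpdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= 0) & (x <= self.upper)
        return np.where(inside, -math.log(self.upper), -np.inf)

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def rvs(self, size=None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng() if rng is None else rng
        return rng.uniform(0.0, self.upper, size=size)


class HalfNormalVariance:
    """Hierarchical prior for exchangeable ancillary variances.

    Each variance gamma^2 ~ N(0, v) truncated to [0, inf) given a common
    scale v ~ Gamma(shape, rate); v is shared across treatments within an
    outcome.  The truncated normal sits on the *variance*, not the sd; the
    sd is its square root.
    """

    def __init__(self, shape: float, rate: float) -> None:
        if not (shape > 0 and rate > 0):
            raise PriorParameterError("gamma shape and rate must be > 0")
        self.shape = float(shape)
        self.rate = float(rate)

    def v_mean(self) -> float:
        return self.shape / self.rate

    def logpdf_v(self, v):
        return stats.gamma.logpdf(v, a=self.shape, scale=1.0 / self.rate)

    def rvs_v(self, size=None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng() if rng is None else rng
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)

    def logpdf_var_given_v(self, gamma_sq, v):
        """Half-normal density of the variance gamma^2 given scale v."""
        gamma_sq = np.asarray(gamma_sq, dtype=float)
        return stats.halfnorm.logpdf(gamma_sq, scale=np.sqrt(v))

    def rvs_var_given_v(self, v, size=None, rng: np.random.Generator | None = None):
        rng = np.random.default_rng() if rng is None else rng
        return np.abs(rng.normal(0.0, np.sqrt(v), size=size))

    def rvs_var(self, size=None, rng: np.random.Generator | None = None):
        """Marginal draws of gamma^2 (scale mixture over v)."""
        rng = np.random.default_rng() if rng is None else rng
        v = self.rvs_v(size=size, rng=rng)
        return np.abs(rng.normal(0.0, np.sqrt(v)))


def scaled_beta_correlation(shape: float) -> ScaledBetaCorrelation:
    """Symmetric prior over [-1, 1] built from a Beta(shape, shape)."""
    return ScaledBetaCorrelation(shape)


def uniform_sd(upper: float) -> UniformSd:
    """Uniform prior on [0, upper] for a heterogeneity standard deviation."""
    return UniformSd(upper)


def half_normal_variance(shape: float, rate: float) -> HalfNormalVariance:
    """Truncated-normal-on-variance hierarchy with a Gamma scale hyperprior."""
    return HalfNormalVariance(shape, rate)
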