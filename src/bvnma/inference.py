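"""Posterior sampling, convergence diagnostics, summaries and DIC.

Sampling uses an affine-invariant ensemble sampler on the marginalised
posterior (latent study effects integrated out analytically).  Several
independent ensembles are run as "chains" for split-R-hat; draws within an
ensemble are pooled across walkers after warm-up and thinning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import emcee
import numpy as np
import pandas as pd

from .data_model import PosteriorSummary
from .models import ModelSpec, _bvn_logpdf, _LOG_2PI

logger = logging.getLogger(__name__)


class InitializationError(RuntimeError):
    """The log density is not finite at the initial ensemble."""


@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings.

    ``n_draws`` counts post-warm-up ensemble steps (before thinning); the
    stored number of draws per chain is ``n_draws // thin * n_walkers``.
    """

    n_chains: int = 2
    n_warmup: int = 500
    n_draws: int = 1000
    seed: int = 0
    n_walkers: int | None = None
    thin: int = 2
    rhat_threshold: float = 1.05
    min_ess: float = 100.0
    compute_diagnostics: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")
        if self.n_warmup <= 0 or self.n_draws <= 0:
            raise ValueError("warmup and draws must be positive")

    def with_seed(self, seed: int) -> "McmcConfig":
        return replace(self, seed=int(seed))


def _derive_seed(*keys: int) -> int:
    """Deterministic 31-bit seed from a tuple of integer keys."""
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


class PosteriorDraws:
    """Posterior draws of all catalogued (and derived) scalar parameters.

    ``theta`` has shape (n_chains, n_per_chain, ndim).  ``params`` maps a
    parameter name to an array (n_chains, n_per_chain); it contains every
    sampled scalar plus derived per-contrast quantities (contrast means
    d1/d2 and the between-study tau1/tau2/rho implied by ancillary
    structures), so downstream reports address parameters uniformly.
    """

    def __init__(
        self,
        model: ModelSpec,
        theta: np.ndarray,
        manifest: dict,
    ) -> None:
        self.model = model
        self.theta = theta
        self.manifest = manifest
        self.params: dict[str, np.ndarray] = {}
        for i, name in enumerate(model.layout.names):
            self.params[name] = theta[..., i]
        self._add_derived()

    def _add_derived(self) -> None:
        m = self.model
        means = m.contrast_means(self.theta)  # (chains, draws, C, 2)
        t11, t22, t12 = m.contrast_covs(self.theta)
        tau1 = np.sqrt(np.maximum(t11, 0.0))
        tau2 = np.sqrt(np.maximum(t22, 0.0))
        denom = np.where(tau1 * tau2 > 0, tau1 * tau2, 1.0)
        rho = np.clip(t12 / denom, -1.0, 1.0)
        for ci, (k, l) in enumerate(m.contrasts):
            lab = f"{k}{l}"
            self.params.setdefault(f"d1[{lab}]", means[..., ci, 0])
            self.params.setdefault(f"d2[{lab}]", means[..., ci, 1])
            if m.cov_structure in ("ancillary", "ancillary_hier") or (
                m.fixed_between is None and m.cov_structure == "free"
            ):
                self.params.setdefault(f"tau1[{lab}]", tau1[..., ci])
                self.params.setdefault(f"tau2[{lab}]", tau2[..., ci])
                self.params.setdefault(f"rho[{lab}]", rho[..., ci])

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_per_chain(self) -> int:
        return self.theta.shape[1]

    def get(self, name: str) -> np.ndarray:
        if name not in self.params:
            raise KeyError(f"unknown parameter {name!r}")
        return self.params[name]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def flat_theta(self) -> np.ndarray:
        return self.theta.reshape(-1, self.theta.shape[-1])


def _rhat_split(x: np.ndarray) -> float:
    """Split-R-hat of draws shaped (chains, draws)."""
    n_c, n_d = x.shape
    half = n_d // 2
    if half < 2:
        return float("nan")
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n = halves.shape
    means = halves.mean(axis=1)
    b = n * means.var(ddof=1)
    w = halves.var(axis=1, ddof=1).mean()
    if w <= 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(math.sqrt(var_plus / w))


def _ess_autocorr(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation.

    Draws within a chain are walker-pooled, so this is a conservative
    order-of-magnitude estimate used for the MC-error gate.
    """
    n_c, n_d = x.shape
    n_total = n_c * n_d
    rho_sum = 0.0
    for c in range(n_c):
        xc = x[c] - x[c].mean()
        var = np.dot(xc, xc) / n_d
        if var <= 0:
            return float(n_total)
        f = np.fft.rfft(xc, n=2 * n_d)
        acov = np.fft.irfft(f * np.conj(f))[:n_d] / n_d
        rho = acov / var
        s = 0.0
        for t in range(1, n_d - 1, 2):
            pair = rho[t] + rho[t + 1]
            if pair < 0:
                break
            s += pair
        rho_sum += s
    tau = 1.0 + 2.0 * rho_sum / n_c
    return float(n_total / max(tau, 1.0))


def fit(model: ModelSpec, cfg: McmcConfig) -> PosteriorDraws:
    """Sample the posterior; reproducible given (model, cfg.seed).

    Emits convergence diagnostics on the sampled scalars; if the R-hat
    threshold is breached the fit is flagged (``manifest["converged"]``)
    and a warning logged, but draws are still returned.
    """
    ndim = model.layout.size
    nw = cfg.n_walkers or max(2 * ndim + 2, 16)
    if nw % 2:
        nw += 1
    x0 = model.initial_point()
    lp0 = model.log_posterior(x0[None, :])[0]
    if not np.isfinite(lp0):
        raise InitializationError(
            f"log density not finite at the initial point for variant "
            f"{model.variant!r}: {lp0}"
        )

    chains = []
    lo, hi = model.layout.lower, model.layout.upper
    span = np.where(np.isfinite(hi - lo), hi - lo, 2.0)
    for c in range(cfg.n_chains):
        seed_c = _derive_seed(cfg.seed, c)
        rng = np.random.default_rng(seed_c)
        scale = np.minimum(0.05, 0.05 * span)
        p0 = x0[None, :] + scale * rng.standard_normal((nw, ndim))
        margin = 1e-3 * span
        p0 = np.clip(p0, lo + margin, np.where(np.isfinite(hi), hi - margin, np.inf))
        bad = ~np.isfinite(model.log_posterior(p0))
        if bad.any():
            p0[bad] = x0[None, :] + 1e-4 * scale * rng.standard_normal(
                (int(bad.sum()), ndim)
            )
            if not np.isfinite(model.log_posterior(p0)).all():
                raise InitializationError(
                    "could not initialise all walkers at finite log density"
                )
        sampler = emcee.EnsembleSampler(
            nw, ndim, model.log_posterior, vectorize=True
        )
        state = emcee.State(p0, random_state=np.random.RandomState(seed_c).get_state())
        sampler.run_mcmc(state, cfg.n_warmup + cfg.n_draws, progress=False)
        ch = sampler.get_chain(discard=cfg.n_warmup, thin=cfg.thin)  # (steps, nw, ndim)
        chains.append(ch.reshape(-1, ndim))
    theta = np.stack(chains)  # (n_chains, n_per_chain, ndim)

    manifest = {
        "variant": model.variant,
        "reference": model.data.reference,
        "treatment_order": list(model.data.treatments),
        "priors": model.priors.to_dict(),
        "seed": cfg.seed,
        "n_chains": cfg.n_chains,
        "n_walkers": nw,
        "n_warmup": cfg.n_warmup,
        "n_draws": cfg.n_draws,
        "thin": cfg.thin,
    }
    draws = PosteriorDraws(model, theta, manifest)

    if cfg.compute_diagnostics:
        diag = {}
        worst = 0.0
        for name in model.monitored_params():
            x = draws.get(name)
            r = _rhat_split(x)
            diag[name] = r
            if np.isfinite(r):
                worst = max(worst, r)
        manifest["max_rhat"] = worst
        manifest["converged"] = bool(worst <= cfg.rhat_threshold)
        if worst > cfg.rhat_threshold:
            culprits = [n for n, r in diag.items() if r > cfg.rhat_threshold]
            logger.warning(
                "R-hat above %.3f for %s (max %.3f); treat results with care",
                cfg.rhat_threshold,
                culprits[:5],
                worst,
            )
    return draws


def summarize(draws: PosteriorDraws, params: list[str]) -> pd.DataFrame:
    """Posterior summary table with equal-tailed 95% credible intervals.

    MC error is estimated as sd / sqrt(ESS).
    """
    rows = []
    for name in params:
        x = draws.get(name)
        flat = x.reshape(-1)
        sd = float(flat.std(ddof=1)) if flat.size > 1 else 0.0
        q = np.percentile(flat, [2.5, 50.0, 97.5])
        ess = _ess_autocorr(x) if sd > 0 else float(flat.size)
        rhat = _rhat_split(x) if sd > 0 else 1.0
        rows.append(
            PosteriorSummary(
                name=name,
                mean=float(flat.mean()),
                sd=sd,
                q2_5=float(q[0]),
                q50=float(q[1]),
                q97_5=float(q[2]),
                mcse=sd / math.sqrt(max(ess, 1.0)),
                ess=float(ess),
                rhat=float(rhat),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows]).set_index("name")


# ---------------------------------------------------------------------------
# latent effects and DIC
# ---------------------------------------------------------------------------


def conditional_mu_moments(
    model: ModelSpec, theta_flat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional posterior moments of the latent effects given the data.

    For each hyperparameter draw and study, the latent effect pair is
    Gaussian with precision Sigma_i^{-1} + T^{-1} (only the surrogate
    margin of Sigma contributes when the final-outcome estimate is
    missing).  Returns (mean, cov) with shapes (N, n, 2) and (N, n, 2, 2).
    """
    t11, t22, t12 = model.contrast_covs(theta_flat)
    means = model.contrast_means(theta_flat)
    ci = model._c_idx
    sgn = model._mean_sign
    m1 = sgn * means[..., ci, 0]
    m2 = sgn * means[..., ci, 1]
    T11, T22, T12 = t11[..., ci], t22[..., ci], t12[..., ci]
    s11, s22, s12 = model._s11, model._s22, model._s12
    y1 = model._y1
    y2 = np.where(model._missing, 0.0, model._y2)
    r1, r2 = y1 - m1, y2 - m2
    # complete rows: mu | y ~ N(m + G (y - m), T - G T), G = T (T + Sigma)^-1
    # (well-conditioned for singular T since Sigma is positive definite)
    w11, w22, w12 = T11 + s11, T22 + s22, T12 + s12
    detW = w11 * w22 - w12**2
    G11 = (T11 * w22 - T12 * w12) / detW
    G12 = (T12 * w11 - T11 * w12) / detW
    G21 = (T12 * w22 - T22 * w12) / detW
    G22 = (T22 * w11 - T12 * w12) / detW
    mu1_c = m1 + G11 * r1 + G12 * r2
    mu2_c = m2 + G21 * r1 + G22 * r2
    C11_c = T11 - (G11 * T11 + G12 * T12)
    C12_c = T12 - (G11 * T12 + G12 * T22)
    C22_c = T22 - (G21 * T12 + G22 * T22)
    # missing-final rows: condition on y1 only; cov(mu, y1) = (T11, T12)
    v1 = T11 + s11
    mu1_m = m1 + T11 / v1 * r1
    mu2_m = m2 + T12 / v1 * r1
    C11_m = T11 - T11**2 / v1
    C12_m = T12 - T11 * T12 / v1
    C22_m = T22 - T12**2 / v1
    miss = model._missing
    mu1 = np.where(miss, mu1_m, mu1_c)
    mu2 = np.where(miss, mu2_m, mu2_c)
    C11 = np.maximum(np.where(miss, C11_m, C11_c), 0.0)
    C12 = np.where(miss, C12_m, C12_c)
    C22 = np.maximum(np.where(miss, C22_m, C22_c), 0.0)
    mean = np.stack([mu1, mu2], axis=-1)
    cov = np.stack(
        [
            np.stack([C11, C12], axis=-1),
            np.stack([C12, C22], axis=-1),
        ],
        axis=-2,
    )
    return mean, cov


def sample_latent_effects(
    model: ModelSpec, theta_flat: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One latent-effect draw per hyperparameter draw, shape (N, n, 2)."""
    mean, cov = conditional_mu_moments(model, theta_flat)
    c11 = np.sqrt(np.maximum(cov[..., 0, 0], 0.0))
    safe = np.where(c11 > 0, c11, 1.0)
    l21 = np.where(c11 > 0, cov[..., 0, 1] / safe, 0.0)
    l22 = np.sqrt(np.maximum(cov[..., 1, 1] - l21**2, 0.0))
    z = rng.standard_normal(mean.shape)
    out = np.empty_like(mean)
    out[..., 0] = mean[..., 0] + c11 * z[..., 0]
    out[..., 1] = mean[..., 1] + l21 * z[..., 0] + l22 * z[..., 1]
    return out


def deviance_at(model: ModelSpec, mu: np.ndarray) -> np.ndarray:
    """-2 x within-study log likelihood at latent effects mu (..., n, 2)."""
    r1 = model._y1 - mu[..., 0]
    r2 = np.where(model._missing, 0.0, model._y2 - mu[..., 1])
    lw_full = _bvn_logpdf(r1, r2, model._s11, model._s22, model._s12)
    lw_y1 = (
        -0.5 * (_LOG_2PI + np.log(model._s11)) - 0.5 * r1 * r1 / model._s11
    )
    lw = np.where(model._missing, lw_y1, lw_full).sum(axis=-1)
    return -2.0 * lw


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float


def dic(
    draws: PosteriorDraws, model: ModelSpec | None = None, max_draws: int = 2000
) -> DicResult:
    """Deviance information criterion, conditional on the latent effects.

    DIC = Dbar + pD with pD = Dbar - D(mu_bar): the deviance is the
    within-study likelihood (known Sigma_i) evaluated at sampled latent
    effects, matching the default focus of BUGS-family software for this
    hierarchy.  Deterministic given the draws (internal seed derived from
    the fit seed).
    """
    model = draws.model if model is None else model
    theta = draws.flat_theta()
    if theta.shape[0] > max_draws:
        idx = np.linspace(0, theta.shape[0] - 1, max_draws).astype(int)
        theta = theta[idx]
    rng = np.random.default_rng(_derive_seed(draws.manifest.get("seed", 0), 424242))
    mu = sample_latent_effects(model, theta, rng)
    dev = deviance_at(model, mu)
    d_bar = float(dev.mean())
    d_hat = float(deviance_at(model, mu.mean(axis=0)))
    p_d = d_bar - d_hat
    return DicResult(dic=d_bar + p_d, p_d=p_d, mean_deviance=d_bar)
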