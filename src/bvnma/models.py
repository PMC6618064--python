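"""Joint probability models for bivariate (network) meta-analysis.

Every variant shares the within-study layer: the observed effect pair of
study i estimates latent true effects with a known 2x2 covariance built
from the reported standard errors and within-study correlation.  The
variants differ in the between-study layer (how the latent effects of the
studies on contrast kl scatter around the contrast mean) and in the mean
structure:

========  =======================  ==============================
variant   mean structure           between-study covariance
========  =======================  ==============================
brma      pooled (beta1, beta2)    one common (tau1, tau2, rho)
1a / 2a   consistency / exch.      free (tau1, tau2, rho) per contrast
1b / 2b   consistency / exch.      arm-level ancillary effects (2nd-order
                                   consistency), sd's uniform
1c / 2c   consistency / exch.      as 1b, variances exchangeable via a
                                   truncated-normal + Gamma hierarchy
1d / 2d   consistency / exch.      one common (tau1, tau2, rho)
========  =======================  ==============================

"consistency" puts independent normal priors on the basic parameters
(effects vs. the reference treatment) and derives every contrast mean by
first-order consistency; "exchangeable" replaces those priors by
treatment-level effects theta_jk with a bivariate exchangeable layer whose
correlation rho_t measures treatment-level surrogacy.

For sampling, the latent study effects are integrated out analytically
(both layers are Gaussian), so the marginal likelihood of study i is a
bivariate normal with covariance Sigma_i + T_kl.  The latent-inclusive
joint density is kept as :meth:`ModelSpec.joint_log_density` and is
validated against an independent brute-force density in the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    BetweenStudyCov,
    NetworkData,
    StructuralError,
    ValidationError,
)
from .priors import PriorConfig, ScaledBetaCorrelation

VARIANTS = ("brma", "1a", "1b", "1c", "1d", "2a", "2b", "2c", "2d")

_LOG_2PI = math.log(2.0 * math.pi)


class UnknownVariantError(ValueError):
    """Requested model variant is not one of the supported ones."""


def mean_structure(variant: str) -> str:
    if variant == "brma":
        return "pooled"
    if variant.startswith("1"):
        return "consistency"
    return "exchangeable"


def cov_structure(variant: str) -> str:
    if variant in ("brma", "1d", "2d"):
        return "common"
    if variant in ("1a", "2a"):
        return "free"
    if variant in ("1b", "2b"):
        return "ancillary"
    return "ancillary_hier"


# ---------------------------------------------------------------------------
# consistency and second-order consistency primitives
# ---------------------------------------------------------------------------


def consistency_effect(
    basic: Mapping[str, tuple[float, float]], k: str, l: str
) -> tuple[float, float]:
    """Mean effect pair of l vs. k from basic parameters (first-order
    consistency: d_jkl = d_j1l - d_j1k; antisymmetric in (k, l))."""
    if k not in basic:
        raise KeyError(f"unknown treatment {k!r}")
    if l not in basic:
        raise KeyError(f"unknown treatment {l!r}")
    dk, dl = basic[k], basic[l]
    return (dl[0] - dk[0], dl[1] - dk[1])


def second_order_tau(tau_bk: float, tau_bl: float, rho_bk_bl: float) -> float:
    """Heterogeneity sd of contrast kl implied by the sd's of bk and bl.

    tau_kl^2 = tau_bk^2 + tau_bl^2 - 2 rho tau_bk tau_bl; nonnegative by
    Cauchy-Schwarz and bounded by the triangle inequalities
    |tau_bl - tau_bk| <= tau_kl <= tau_bl + tau_bk.
    """
    if tau_bk < 0 or tau_bl < 0:
        raise ValidationError("heterogeneity sd's must be nonnegative")
    if abs(rho_bk_bl) > 1:
        raise ValidationError("correlation must lie in [-1, 1]")
    val = tau_bk**2 + tau_bl**2 - 2.0 * rho_bk_bl * tau_bk * tau_bl
    return math.sqrt(max(val, 0.0))


@dataclass(frozen=True)
class AncillaryStructure:
    """Arm-level random-effect scales and correlations.

    ``gamma[j, k]`` is the sd of the arm-level random effect of treatment
    k (0-based position) on outcome j; ``R`` is the 2*n_t x 2*n_t
    correlation matrix of those effects, ordered (outcome 1, treatment 1),
    (outcome 2, treatment 1), (outcome 1, treatment 2), ...  All contrast
    covariances are differences of these arm effects, so second-order
    consistency holds by construction whenever R is PSD.
    """

    gamma: np.ndarray  # (2, n_t)
    R: np.ndarray  # (2 n_t, 2 n_t)

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        R = np.asarray(self.R, dtype=float)
        if g.ndim != 2 or g.shape[0] != 2:
            raise ValidationError("gamma must have shape (2, n_t)")
        if np.any(g < 0):
            raise ValidationError("gamma entries must be nonnegative")
        m = 2 * g.shape[1]
        if R.shape != (m, m):
            raise ValidationError(f"R must be {m}x{m} for {g.shape[1]} treatments")
        if not np.allclose(R, R.T, atol=1e-10):
            raise StructuralError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise StructuralError("R must have a unit diagonal")
        w = np.linalg.eigvalsh((R + R.T) / 2.0)
        if w.min() < -1e-10:
            raise StructuralError(
                f"R is not positive semidefinite (min eigenvalue {w.min():.3e})"
            )
        object.__setattr__(self, "gamma", g)
        object.__setattr__(self, "R", R)

    @property
    def n_treatments(self) -> int:
        return self.gamma.shape[1]

    def index(self, j: int, k: int) -> int:
        """Row of R for outcome j (1-based) and treatment position k (0-based)."""
        return 2 * k + (j - 1)


def covariances_from_ancillary(
    anc: AncillaryStructure, k: int, l: int
) -> BetweenStudyCov:
    """Between-study (tau1, tau2, rho) of contrast (k, l) from arm effects.

    ``k`` and ``l`` are 0-based treatment positions.  The variance of the
    difference of two correlated arm effects gives tau^2 per outcome, and
    the cross-covariance expands into four correlation-weighted products.
    The full set over all treatment pairs satisfies the second-order
    consistency identities for every triple by construction.
    """
    if k == l:
        raise ValidationError("a contrast needs two distinct treatments")
    g, R = anc.gamma, anc.R
    i1k, i2k = anc.index(1, k), anc.index(2, k)
    i1l, i2l = anc.index(1, l), anc.index(2, l)
    t1_sq = g[0, k] ** 2 + g[0, l] ** 2 - 2.0 * R[i1k, i1l] * g[0, k] * g[0, l]
    t2_sq = g[1, k] ** 2 + g[1, l] ** 2 - 2.0 * R[i2k, i2l] * g[1, k] * g[1, l]
    cov12 = (
        g[0, k] * g[1, k] * R[i1k, i2k]
        - g[0, k] * g[1, l] * R[i1k, i2l]
        - g[0, l] * g[1, k] * R[i1l, i2k]
        + g[0, l] * g[1, l] * R[i1l, i2l]
    )
    tau1 = math.sqrt(max(t1_sq, 0.0))
    tau2 = math.sqrt(max(t2_sq, 0.0))
    denom = tau1 * tau2
    rho = cov12 / denom if denom > 0 else 0.0
    rho = min(1.0, max(-1.0, rho))
    return BetweenStudyCov(tau1=tau1, tau2=tau2, rho=rho)


def corr_cholesky_from_angles(angles: np.ndarray, m: int) -> np.ndarray:
    """Correlation matrix R = L^T L from spherical angles of L's columns.

    ``L`` is upper triangular with unit-norm columns; column c (0-based)
    is parameterised by c angles in (0, pi).  Works over arbitrary leading
    batch dimensions of ``angles`` (shape (..., m(m-1)/2)).
    """
    angles = np.asarray(angles, dtype=float)
    n_ang = m * (m - 1) // 2
    if angles.shape[-1] != n_ang:
        raise ValidationError(f"need {n_ang} angles for a {m}x{m} matrix")
    batch = angles.shape[:-1]
    L = np.zeros(batch + (m, m))
    L[..., 0, 0] = 1.0
    pos = 0
    for c in range(1, m):
        a = angles[..., pos : pos + c]
        pos += c
        sin_prod = np.ones(batch)
        for r in range(c):
            L[..., r, c] = np.cos(a[..., r]) * sin_prod
            sin_prod = sin_prod * np.sin(a[..., r])
        L[..., c, c] = sin_prod
    R = np.swapaxes(L, -1, -2) @ L
    # enforce exact unit diagonal against accumulated rounding
    idx = np.arange(m)
    R[..., idx, idx] = 1.0
    return R


class AncillaryPrior:
    """Prior sampler over :class:`AncillaryStructure`.

    Correlations come from the angular Cholesky construction (PSD by
    construction, unit diagonal); the arm-effect sd's gamma_jk come either
    from U(0, sd_upper) (second-order-consistency models with free
    variances) or, with ``hierarchical=True``, from the exchangeable
    truncated-normal-on-variance hierarchy.  The induced contrast-level
    priors depend on the treatment ordering; callers are expected to log
    the ordering used.
    """

    def __init__(
        self,
        n_treatments: int,
        priors: PriorConfig,
        hierarchical: bool = False,
    ) -> None:
        if n_treatments < 2:
            raise ValidationError("need at least two treatments")
        self.n_treatments = n_treatments
        self.priors = priors
        self.hierarchical = hierarchical
        self.m = 2 * n_treatments
        self.n_angles = self.m * (self.m - 1) // 2

    def rvs(self, rng: np.random.Generator | None = None) -> AncillaryStructure:
        rng = np.random.default_rng() if rng is None else rng
        angles = rng.uniform(0.0, math.pi, size=self.n_angles)
        R = corr_cholesky_from_angles(angles, self.m)
        if self.hierarchical:
            v = rng.gamma(
                self.priors.ancillary_var_gamma_shape,
                1.0 / self.priors.ancillary_var_gamma_rate,
                size=2,
            )
            gam_sq = np.abs(
                rng.normal(0.0, np.sqrt(v)[:, None], size=(2, self.n_treatments))
            )
            gamma = np.sqrt(gam_sq)
        else:
            gamma = rng.uniform(0.0, self.priors.sd_upper, size=(2, self.n_treatments))
        return AncillaryStructure(gamma=gamma, R=R)


def ancillary_prior(
    n_treatments: int, priors: PriorConfig, hierarchical: bool = False
) -> AncillaryPrior:
    return AncillaryPrior(n_treatments, priors, hierarchical=hierarchical)


# ---------------------------------------------------------------------------
# parameter layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParamDef:
    name: str
    lower: float
    upper: float


class ParamLayout:
    """Ordered catalogue of scalar parameters with box supports."""

    def __init__(self, defs: Sequence[ParamDef]) -> None:
        self.defs = tuple(defs)
        self.names = tuple(d.name for d in self.defs)
        self._index = {d.name: i for i, d in enumerate(self.defs)}
        self.lower = np.array([d.lower for d in self.defs])
        self.upper = np.array([d.upper for d in self.defs])

    @property
    def size(self) -> int:
        return len(self.defs)

    def index(self, name: str) -> int:
        if name not in self._index:
            raise KeyError(f"unknown parameter {name!r}")
        return self._index[name]

    def slice_of(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def inside(self, theta: np.ndarray) -> np.ndarray:
        return np.all((theta > self.lower) & (theta < self.upper), axis=-1)


def _contrast_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}{pair[1]}"


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------


def _bvn_logpdf(r1, r2, v11, v22, v12):
    """Log density of centred residuals under a 2x2 covariance."""
    det = v11 * v22 - v12 * v12
    det = np.maximum(det, 1e-300)
    q = (r1 * r1 * v22 - 2.0 * r1 * r2 * v12 + r2 * r2 * v11) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * q


class ModelSpec:
    """Likelihood, priors and parameter catalogue of one model variant.

    Not normally constructed directly; use :func:`build_model`.  The
    instance exposes the marginal log posterior used by the sampler
    (vectorised over parameter points) plus helpers mapping a parameter
    vector to contrast means and between-study covariances.
    ``fixed_between`` freezes the between-study covariance at a known 2x2
    matrix (used for closed-form validation against conjugate oracles).
    """

    def __init__(
        self,
        data: NetworkData,
        variant: str,
        priors: PriorConfig,
        fixed_between: np.ndarray | None = None,
    ) -> None:
        if variant not in VARIANTS:
            raise UnknownVariantError(
                f"unknown variant {variant!r}; choose one of {VARIANTS}"
            )
        self.data = data
        self.variant = variant
        self.priors = priors
        self.mean_structure = mean_structure(variant)
        self.cov_structure = cov_structure(variant)
        self.fixed_between = (
            None if fixed_between is None else np.asarray(fixed_between, dtype=float)
        )
        self.n_t = data.n_treatments
        self.contrasts = data.contrasts
        self.n_c = len(self.contrasts)
        self._rho_prior = ScaledBetaCorrelation(priors.corr_beta_shape)

        self._prepare_obs_arrays()
        self._build_layout()
        self._warn_sparse()

    # -- observation arrays ------------------------------------------------

    def _prepare_obs_arrays(self) -> None:
        d = self.data
        obs = d.observations
        self._y1 = np.array([o.y1 for o in obs])
        self._y2 = np.array([o.y2 if o.y2 is not None else np.nan for o in obs])
        self._missing = np.array([o.y2_missing for o in obs])
        se1 = np.array([o.se1 for o in obs])
        se2 = np.array([o.se2 for o in obs])
        rw = np.array([o.rho_w for o in obs])
        self._s11 = se1**2
        self._s22 = se2**2
        self._s12 = se1 * se2 * rw
        self._c_idx = d.contrast_indices()
        self._sign = d.orientation_signs()
        # BRMA pools all studies in their reported orientation: the pooled
        # mean applies without the canonical-contrast sign flip
        self._mean_sign = (
            np.ones_like(self._sign)
            if mean_structure(self.variant) == "pooled"
            else self._sign
        )
        self._complete = ~self._missing

    # -- layout ------------------------------------------------------------

    def _build_layout(self) -> None:
        inf = math.inf
        su = self.priors.sd_upper
        defs: list[ParamDef] = []

        if self.mean_structure == "pooled":
            defs += [ParamDef("beta1", -inf, inf), ParamDef("beta2", -inf, inf)]
        elif self.mean_structure == "consistency":
            for t in self.data.treatments[1:]:
                defs += [ParamDef(f"d1[{t}]", -inf, inf), ParamDef(f"d2[{t}]", -inf, inf)]
        else:  # exchangeable
            for t in self.data.treatments:
                defs += [
                    ParamDef(f"theta1[{t}]", -inf, inf),
                    ParamDef(f"theta2[{t}]", -inf, inf),
                ]
            defs += [
                ParamDef("omega1", 0.0, su),
                ParamDef("omega2", 0.0, su),
                ParamDef("rho_t", -1.0, 1.0),
            ]

        if self.fixed_between is not None:
            pass  # no covariance parameters
        elif self.cov_structure == "common":
            defs += [
                ParamDef("tau1", 0.0, su),
                ParamDef("tau2", 0.0, su),
                ParamDef("rho", -1.0, 1.0),
            ]
        elif self.cov_structure == "free":
            for c in self.contrasts:
                lab = _contrast_label(c)
                defs += [
                    ParamDef(f"tau1[{lab}]", 0.0, su),
                    ParamDef(f"tau2[{lab}]", 0.0, su),
                    ParamDef(f"rho[{lab}]", -1.0, 1.0),
                ]
        else:  # ancillary / ancillary_hier
            g_upper = su if self.cov_structure == "ancillary" else inf
            for t in self.data.treatments:
                defs += [
                    ParamDef(f"gamma1[{t}]", 0.0, g_upper),
                    ParamDef(f"gamma2[{t}]", 0.0, g_upper),
                ]
            m = 2 * self.n_t
            for i in range(m * (m - 1) // 2):
                defs.append(ParamDef(f"phi[{i}]", 0.0, math.pi))
            if self.cov_structure == "ancillary_hier":
                defs += [ParamDef("v1", 0.0, inf), ParamDef("v2", 0.0, inf)]

        self.layout = ParamLayout(defs)

        # frequently used index blocks
        lay = self.layout
        if self.mean_structure == "pooled":
            self._i_mean = lay.slice_of(["beta1", "beta2"])
        elif self.mean_structure == "consistency":
            names = []
            for t in self.data.treatments[1:]:
                names += [f"d1[{t}]", f"d2[{t}]"]
            self._i_mean = lay.slice_of(names)
        else:
            names = []
            for t in self.data.treatments:
                names += [f"theta1[{t}]", f"theta2[{t}]"]
            self._i_mean = lay.slice_of(names)
            self._i_omega = lay.slice_of(["omega1", "omega2", "rho_t"])

        if self.fixed_between is not None:
            self._i_cov = np.array([], dtype=int)
        elif self.cov_structure == "common":
            self._i_cov = lay.slice_of(["tau1", "tau2", "rho"])
        elif self.cov_structure == "free":
            names = []
            for c in self.contrasts:
                lab = _contrast_label(c)
                names += [f"tau1[{lab}]", f"tau2[{lab}]", f"rho[{lab}]"]
            self._i_cov = lay.slice_of(names)
        else:
            names = []
            for t in self.data.treatments:
                names += [f"gamma1[{t}]", f"gamma2[{t}]"]
            self._i_gamma = lay.slice_of(names)
            m = 2 * self.n_t
            self._i_phi = lay.slice_of(
                [f"phi[{i}]" for i in range(m * (m - 1) // 2)]
            )
            if self.cov_structure == "ancillary_hier":
                self._i_v = lay.slice_of(["v1", "v2"])

    def _warn_sparse(self) -> None:
        if self.cov_structure in ("free", "ancillary", "ancillary_hier"):
            counts = np.bincount(self._c_idx, minlength=self.n_c)
            sparse = [
                _contrast_label(self.contrasts[i])
                for i in range(self.n_c)
                if counts[i] < 2
            ]
            if sparse:
                warnings.warn(
                    f"contrast(s) {sparse} have fewer than 2 studies; their "
                    f"between-study correlation is prior-driven",
                    stacklevel=3,
                )

    # -- parameter-vector views --------------------------------------------

    def basic_parameters(self, theta: np.ndarray) -> np.ndarray:
        """Basic parameters d[j, k] vs. the reference, shape (..., 2, n_t).

        For the pooled (BRMA) mean structure the notion does not apply and
        the pooled means are returned broadcast to every treatment column.
        """
        theta = np.asarray(theta, dtype=float)
        batch = theta.shape[:-1]
        if self.mean_structure == "pooled":
            b = theta[..., self._i_mean]
            return np.broadcast_to(
                b[..., :, None], batch + (2, self.n_t)
            ).copy()
        d = np.zeros(batch + (2, self.n_t))
        if self.mean_structure == "consistency":
            vals = theta[..., self._i_mean].reshape(batch + (self.n_t - 1, 2))
            d[..., :, 1:] = np.swapaxes(vals, -1, -2)
        else:
            th = theta[..., self._i_mean].reshape(batch + (self.n_t, 2))
            th = np.swapaxes(th, -1, -2)  # (..., 2, n_t)
            d = th - th[..., :, :1]
        return d

    def contrast_means(self, theta: np.ndarray) -> np.ndarray:
        """Mean effect pair of each canonical contrast, shape (..., C, 2)."""
        theta = np.asarray(theta, dtype=float)
        batch = theta.shape[:-1]
        if self.mean_structure == "pooled":
            b = theta[..., self._i_mean]
            return np.broadcast_to(b[..., None, :], batch + (self.n_c, 2)).copy()
        d = self.basic_parameters(theta)  # (..., 2, n_t)
        out = np.empty(batch + (self.n_c, 2))
        for ci, (k, l) in enumerate(self.contrasts):
            ik, il = self.data.treatment_index(k), self.data.treatment_index(l)
            out[..., ci, 0] = d[..., 0, il] - d[..., 0, ik]
            out[..., ci, 1] = d[..., 1, il] - d[..., 1, ik]
        return out

    def contrast_covs(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Between-study covariance entries (t11, t22, t12), each (..., C)."""
        theta = np.asarray(theta, dtype=float)
        batch = theta.shape[:-1]
        if self.fixed_between is not None:
            T = self.fixed_between
            t11 = np.broadcast_to(T[0, 0], batch + (self.n_c,)).copy()
            t22 = np.broadcast_to(T[1, 1], batch + (self.n_c,)).copy()
            t12 = np.broadcast_to(T[0, 1], batch + (self.n_c,)).copy()
            return t11, t22, t12
        if self.cov_structure == "common":
            tau1 = theta[..., self._i_cov[0]]
            tau2 = theta[..., self._i_cov[1]]
            rho = theta[..., self._i_cov[2]]
            t11 = np.broadcast_to((tau1**2)[..., None], batch + (self.n_c,)).copy()
            t22 = np.broadcast_to((tau2**2)[..., None], batch + (self.n_c,)).copy()
            t12 = np.broadcast_to(
                (tau1 * tau2 * rho)[..., None], batch + (self.n_c,)
            ).copy()
            return t11, t22, t12
        if self.cov_structure == "free":
            vals = theta[..., self._i_cov].reshape(batch + (self.n_c, 3))
            tau1, tau2, rho = vals[..., 0], vals[..., 1], vals[..., 2]
            return tau1**2, tau2**2, tau1 * tau2 * rho
        # ancillary structures
        gam = theta[..., self._i_gamma].reshape(batch + (self.n_t, 2))
        gam = np.swapaxes(gam, -1, -2)  # (..., 2, n_t)
        R = corr_cholesky_from_angles(theta[..., self._i_phi], 2 * self.n_t)
        t11 = np.empty(batch + (self.n_c,))
        t22 = np.empty(batch + (self.n_c,))
        t12 = np.empty(batch + (self.n_c,))
        for ci, (k, l) in enumerate(self.contrasts):
            kp, lp = self.data.treatment_index(k), self.data.treatment_index(l)
            i1k, i2k, i1l, i2l = 2 * kp, 2 * kp + 1, 2 * lp, 2 * lp + 1
            g1k, g2k = gam[..., 0, kp], gam[..., 1, kp]
            g1l, g2l = gam[..., 0, lp], gam[..., 1, lp]
            t11[..., ci] = g1k**2 + g1l**2 - 2.0 * R[..., i1k, i1l] * g1k * g1l
            t22[..., ci] = g2k**2 + g2l**2 - 2.0 * R[..., i2k, i2l] * g2k * g2l
            t12[..., ci] = (
                g1k * g2k * R[..., i1k, i2k]
                - g1k * g2l * R[..., i1k, i2l]
                - g1l * g2k * R[..., i1l, i2k]
                + g1l * g2l * R[..., i1l, i2l]
            )
        return np.maximum(t11, 0.0), np.maximum(t22, 0.0), t12

    def between_cov(self, theta: np.ndarray, contrast: tuple[str, str]) -> BetweenStudyCov:
        """Between-study covariance of one contrast at a parameter point."""
        t11, t22, t12 = self.contrast_covs(np.atleast_1d(theta))
        ci = self.contrasts.index(contrast)
        tau1 = math.sqrt(max(float(t11[..., ci]), 0.0))
        tau2 = math.sqrt(max(float(t22[..., ci]), 0.0))
        denom = tau1 * tau2
        rho = float(t12[..., ci]) / denom if denom > 0 else 0.0
        return BetweenStudyCov(tau1, tau2, min(1.0, max(-1.0, rho)))

    # -- densities ----------------------------------------------------------

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        inside = self.layout.inside(theta)
        lp = np.where(inside, 0.0, -np.inf)
        safe = np.where(inside[..., None], theta, 0.5 * (np.clip(self.layout.lower, -1, 1) + np.clip(self.layout.upper, -1, 1)))

        su = self.priors.sd_upper
        if self.mean_structure == "pooled":
            b = safe[..., self._i_mean]
            lp = lp + stats.norm.logpdf(b, 0.0, math.sqrt(self.priors.pooled_mean_var)).sum(axis=-1)
        elif self.mean_structure == "consistency":
            d = safe[..., self._i_mean]
            lp = lp + stats.norm.logpdf(d, 0.0, math.sqrt(self.priors.basic_param_var)).sum(axis=-1)
        else:
            om = safe[..., self._i_omega]
            w1, w2, rt = om[..., 0], om[..., 1], om[..., 2]
            th = safe[..., self._i_mean].reshape(theta.shape[:-1] + (self.n_t, 2))
            # theta pairs ~ N(0, 0.5 * [[w1^2, rt w1 w2], [rt w1 w2, w2^2]])
            v11 = 0.5 * w1**2
            v22 = 0.5 * w2**2
            v12 = 0.5 * rt * w1 * w2
            det = v11 * v22 - v12**2
            bad = det <= 1e-300
            det = np.where(bad, 1.0, det)
            t1, t2 = th[..., 0], th[..., 1]
            q = (
                t1**2 * v22[..., None]
                - 2.0 * t1 * t2 * v12[..., None]
                + t2**2 * v11[..., None]
            ) / det[..., None]
            lp_theta = (-_LOG_2PI - 0.5 * np.log(det[..., None]) - 0.5 * q).sum(axis=-1)
            lp = lp + np.where(bad, -np.inf, lp_theta)
            lp = lp - 2.0 * math.log(su)  # omega1, omega2 uniform
            lp = lp + self._rho_prior.logpdf(rt)

        if self.fixed_between is not None:
            return lp
        if self.cov_structure == "common":
            rho = safe[..., self._i_cov[2]]
            lp = lp - 2.0 * math.log(su) + self._rho_prior.logpdf(rho)
        elif self.cov_structure == "free":
            vals = safe[..., self._i_cov].reshape(theta.shape[:-1] + (self.n_c, 3))
            lp = lp - 2.0 * self.n_c * math.log(su)
            lp = lp + self._rho_prior.logpdf(vals[..., 2]).sum(axis=-1)
        elif self.cov_structure == "ancillary":
            lp = lp - 2.0 * self.n_t * math.log(su)
            # angles uniform on (0, pi): constant
            lp = lp - self._i_phi.size * math.log(math.pi)
        else:  # ancillary_hier
            g = safe[..., self._i_gamma]
            v = safe[..., self._i_v]
            shape = self.priors.ancillary_var_gamma_shape
            rate = self.priors.ancillary_var_gamma_rate
            lp = lp + stats.gamma.logpdf(v, a=shape, scale=1.0 / rate).sum(axis=-1)
            # gamma^2 | v_j half-normal; sampling gamma adds Jacobian 2 gamma
            gb = g.reshape(theta.shape[:-1] + (self.n_t, 2))
            gsq = gb**2
            vj = v[..., None, :]  # broadcast outcome scale over treatments
            lp_g = stats.halfnorm.logpdf(gsq, scale=np.sqrt(vj)) + np.log(
                np.maximum(2.0 * gb, 1e-300)
            )
            lp = lp + lp_g.sum(axis=(-1, -2))
            lp = lp - self._i_phi.size * math.log(math.pi)
        return np.where(inside, lp, -np.inf)

    def log_marginal_likelihood(self, theta: np.ndarray) -> np.ndarray:
        """Log likelihood with latent study effects integrated out."""
        theta = np.asarray(theta, dtype=float)
        t11, t22, t12 = self.contrast_covs(theta)
        m = self.contrast_means(theta)  # (..., C, 2)
        ci = self._c_idx
        v11 = self._s11 + t11[..., ci]
        v22 = self._s22 + t22[..., ci]
        v12 = self._s12 + t12[..., ci]
        sgn = self._mean_sign
        m1 = sgn * m[..., ci, 0]
        m2 = sgn * m[..., ci, 1]
        r1 = self._y1 - m1
        r2 = np.where(self._missing, 0.0, self._y2 - m2)
        lp_full = _bvn_logpdf(r1, r2, v11, v22, v12)
        lp_y1 = -0.5 * (_LOG_2PI + np.log(v11)) - 0.5 * r1 * r1 / v11
        return np.where(self._missing, lp_y1, lp_full).sum(axis=-1)

    def log_posterior(self, theta: np.ndarray) -> np.ndarray:
        lp = self.log_prior(theta)
        out = np.full(np.shape(lp), -np.inf, dtype=float)
        ok = np.isfinite(lp)
        if np.ndim(lp) == 0:
            return lp + self.log_marginal_likelihood(theta) if ok else lp
        if np.any(ok):
            out[ok] = lp[ok] + self.log_marginal_likelihood(
                np.asarray(theta, dtype=float)[ok]
            )
        return out

    def joint_log_density(self, theta: np.ndarray, mu: np.ndarray) -> float:
        """Latent-inclusive joint log density at one parameter point.

        ``mu`` has shape (n_obs, 2): the true effect pair of each study (in
        the study's own orientation).  The value is the sum of the
        within-study bivariate-normal log likelihood given mu (only the
        surrogate margin for studies with a missing final-outcome
        estimate), the between-study log density of mu, and the log prior.
        """
        theta = np.asarray(theta, dtype=float)
        mu = np.asarray(mu, dtype=float)
        lp = float(self.log_prior(theta[None, :])[0])
        if not math.isfinite(lp):
            return -math.inf
        t11, t22, t12 = (a[0] for a in self.contrast_covs(theta[None, :]))
        m = self.contrast_means(theta[None, :])[0]
        ci = self._c_idx
        # within-study layer
        r1 = self._y1 - mu[:, 0]
        r2 = np.where(self._missing, 0.0, self._y2 - mu[:, 1])
        lw_full = _bvn_logpdf(r1, r2, self._s11, self._s22, self._s12)
        lw_y1 = -0.5 * (_LOG_2PI + np.log(self._s11)) - 0.5 * r1 * r1 / self._s11
        lw = np.where(self._missing, lw_y1, lw_full).sum()
        # between-study layer
        b1 = mu[:, 0] - self._mean_sign * m[ci, 0]
        b2 = mu[:, 1] - self._mean_sign * m[ci, 1]
        lb = _bvn_logpdf(b1, b2, t11[ci], t22[ci], t12[ci]).sum()
        return lp + lw + lb

    # -- initialisation -----------------------------------------------------

    def initial_point(self) -> np.ndarray:
        """Data-informed starting point strictly inside the support."""
        x = np.zeros(self.layout.size)
        # empirical contrast means in canonical orientation
        emp = np.zeros((self.n_c, 2))
        for ci in range(self.n_c):
            sel = self._c_idx == ci
            s = self._sign[sel]
            emp[ci, 0] = np.mean(s * self._y1[sel])
            y2 = self._y2[sel]
            ok = ~self._missing[sel]
            emp[ci, 1] = np.mean(s[ok] * y2[ok]) if ok.any() else emp[ci, 0]
        if self.mean_structure == "pooled":
            x[self._i_mean[0]] = float(np.mean(self._y1))
            obs2 = self._y2[self._complete]
            x[self._i_mean[1]] = float(np.mean(obs2)) if obs2.size else 0.0
        else:
            # least-squares basic parameters from empirical contrast means
            d_init = np.zeros((2, self.n_t))
            A = np.zeros((self.n_c, self.n_t - 1))
            for ci, (k, l) in enumerate(self.contrasts):
                ik, il = self.data.treatment_index(k), self.data.treatment_index(l)
                if ik > 0:
                    A[ci, ik - 1] = -1.0
                if il > 0:
                    A[ci, il - 1] = 1.0
            for j in range(2):
                sol, *_ = np.linalg.lstsq(A, emp[:, j], rcond=None)
                d_init[j, 1:] = sol
            if self.mean_structure == "consistency":
                x[self._i_mean] = d_init[:, 1:].T.ravel()
            else:
                x[self._i_mean] = d_init.T.ravel()
                x[self._i_omega] = [
                    min(0.5 * self.priors.sd_upper, 1.0),
                    min(0.5 * self.priors.sd_upper, 1.0),
                    0.0,
                ]
        if self.fixed_between is None:
            t0 = min(0.2, 0.1 * self.priors.sd_upper)
            if self.cov_structure == "common":
                x[self._i_cov] = [t0, t0, 0.0]
            elif self.cov_structure == "free":
                x[self._i_cov] = np.tile([t0, t0, 0.0], self.n_c)
            else:
                x[self._i_gamma] = t0
                x[self._i_phi] = math.pi / 2.0
                if self.cov_structure == "ancillary_hier":
                    x[self._i_v] = 1.0
        return x

    def parameter_catalogue(self) -> dict[str, tuple[float, float]]:
        """Name -> (lower, upper) support for every sampled scalar."""
        return {d.name: (d.lower, d.upper) for d in self.layout.defs}

    def monitored_params(self) -> list[str]:
        """Identifiable scalars monitored for convergence and reporting.

        Treatment-level effects theta_jk of the exchangeable variants are
        identified only up to a common shift and the ancillary angles only
        through the covariances they induce, so convergence is assessed on
        the induced contrast-level quantities instead.
        """
        names: list[str] = []
        if self.mean_structure == "pooled":
            names += ["beta1", "beta2"]
        else:
            for k, l in self.contrasts:
                names += [f"d1[{k}{l}]", f"d2[{k}{l}]"]
        if self.mean_structure == "exchangeable":
            names += ["omega1", "omega2", "rho_t"]
        if self.fixed_between is None:
            if self.cov_structure == "common":
                names += ["tau1", "tau2", "rho"]
            else:
                for k, l in self.contrasts:
                    names += [f"tau1[{k}{l}]", f"tau2[{k}{l}]", f"rho[{k}{l}]"]
        return names


def build_model(
    data: NetworkData,
    variant: str,
    priors: PriorConfig | None = None,
    fixed_between: np.ndarray | None = None,
) -> ModelSpec:
    """Construct the joint probability model for one variant.

    With only two treatments in the network every variant collapses to the
    standard bivariate meta-analysis structure (a single contrast with one
    mean pair and one between-study covariance).
    """
    priors = PriorConfig() if priors is None else priors
    return ModelSpec(data, variant, priors, fixed_between=fixed_between)
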