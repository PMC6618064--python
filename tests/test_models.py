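import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import bvnma
from bvnma.data_model import BetweenStudyCov, ValidationError
from bvnma.models import (
    AncillaryStructure,
    ModelSpec,
    UnknownVariantError,
    VARIANTS,
    ancillary_prior,
    build_model,
    consistency_effect,
    corr_cholesky_from_angles,
    covariances_from_ancillary,
    second_order_tau,
)
from bvnma.priors import PriorConfig


# ---------------------------------------------------------------------------
# independent brute-force joint density (deliberately coded from scratch)
# ---------------------------------------------------------------------------


def _chol_from_angles_reference(phi, m):
    """Reference construction of the upper-triangular unit-column factor."""
    L = np.zeros((m, m))
    L[0, 0] = 1.0
    pos = 0
    for col in range(1, m):
        a = phi[pos : pos + col]
        pos += col
        prod = 1.0
        for r in range(col):
            L[r, col] = math.cos(a[r]) * prod
            prod *= math.sin(a[r])
        L[col, col] = prod
    return L


def brute_force_joint_logpdf(model: ModelSpec, theta: np.ndarray, mu: np.ndarray) -> float:
    """Independently coded joint log density (within + between + priors)."""
    data = model.data
    pr = model.priors
    p = dict(zip(model.layout.names, theta))
    treatments = data.treatments
    n_t = len(treatments)
    lp = 0.0

    # --- mean structure and its prior
    if model.variant == "brma":
        d = {t: np.array([p["beta1"], p["beta2"]]) for t in treatments}
        lp += stats.norm.logpdf(p["beta1"], 0, math.sqrt(pr.pooled_mean_var))
        lp += stats.norm.logpdf(p["beta2"], 0, math.sqrt(pr.pooled_mean_var))
    elif model.variant.startswith("1"):
        d = {treatments[0]: np.zeros(2)}
        for t in treatments[1:]:
            d[t] = np.array([p[f"d1[{t}]"], p[f"d2[{t}]"]])
            lp += stats.norm.logpdf(d[t], 0, math.sqrt(pr.basic_param_var)).sum()
    else:
        th = {t: np.array([p[f"theta1[{t}]"], p[f"theta2[{t}]"]]) for t in treatments}
        d = {t: th[t] - th[treatments[0]] for t in treatments}
        w1, w2, rt = p["omega1"], p["omega2"], p["rho_t"]
        cov_t = 0.5 * np.array(
            [[w1**2, rt * w1 * w2], [rt * w1 * w2, w2**2]]
        )
        for t in treatments:
            lp += stats.multivariate_normal.logpdf(th[t], np.zeros(2), cov_t)
        lp += -2.0 * math.log(pr.sd_upper)
        lp += stats.beta.logpdf((rt + 1) / 2, pr.corr_beta_shape, pr.corr_beta_shape) - math.log(2)

    # --- between-study covariance per contrast and its prior
    def beta_corr_lp(r):
        return stats.beta.logpdf((r + 1) / 2, pr.corr_beta_shape, pr.corr_beta_shape) - math.log(2)

    T_of = {}
    if model.cov_structure == "common":
        t1, t2, r = p["tau1"], p["tau2"], p["rho"]
        T = np.array([[t1**2, t1 * t2 * r], [t1 * t2 * r, t2**2]])
        T_of = {c: T for c in data.contrasts}
        lp += -2.0 * math.log(pr.sd_upper) + beta_corr_lp(r)
    elif model.cov_structure == "free":
        for k, l in data.contrasts:
            lab = f"{k}{l}"
            t1, t2, r = p[f"tau1[{lab}]"], p[f"tau2[{lab}]"], p[f"rho[{lab}]"]
            T_of[(k, l)] = np.array(
                [[t1**2, t1 * t2 * r], [t1 * t2 * r, t2**2]]
            )
            lp += -2.0 * math.log(pr.sd_upper) + beta_corr_lp(r)
    else:
        m = 2 * n_t
        n_ang = m * (m - 1) // 2
        phi = np.array([p[f"phi[{i}]"] for i in range(n_ang)])
        L = _chol_from_angles_reference(phi, m)
        R = L.T @ L
        np.fill_diagonal(R, 1.0)
        gam = np.array(
            [[p[f"gamma1[{t}]"] for t in treatments], [p[f"gamma2[{t}]"] for t in treatments]]
        )
        # Gamma = V^{1/2} R V^{1/2}, sd order (g11, g21, g12, g22, ...)
        sds = np.empty(m)
        for kpos in range(n_t):
            sds[2 * kpos] = gam[0, kpos]
            sds[2 * kpos + 1] = gam[1, kpos]
        Gam = np.outer(sds, sds) * R
        for k, l in data.contrasts:
            kp, lp_ = treatments.index(k), treatments.index(l)
            M = np.zeros((2, m))
            M[0, 2 * lp_] = 1.0
            M[0, 2 * kp] = -1.0
            M[1, 2 * lp_ + 1] = 1.0
            M[1, 2 * kp + 1] = -1.0
            T_of[(k, l)] = M @ Gam @ M.T
        lp += -n_ang * math.log(math.pi)
        if model.cov_structure == "ancillary":
            lp += -2.0 * n_t * math.log(pr.sd_upper)
        else:
            v = np.array([p["v1"], p["v2"]])
            lp += stats.gamma.logpdf(
                v, a=pr.ancillary_var_gamma_shape, scale=1.0 / pr.ancillary_var_gamma_rate
            ).sum()
            for j in range(2):
                for kpos in range(n_t):
                    g = gam[j, kpos]
                    lp += stats.halfnorm.logpdf(g**2, scale=math.sqrt(v[j]))
                    lp += math.log(2.0 * g)

    # --- between- and within-study layers
    for i, o in enumerate(data.observations):
        c = data.contrast_of(o)
        if model.variant == "brma":
            mean = d[c[0]]  # pooled mean, orientation as reported
        else:
            sign = 1.0 if (o.treat_k, o.treat_l) == c else -1.0
            mean = sign * (d[c[1]] - d[c[0]])
        lp += stats.multivariate_normal.logpdf(mu[i], mean, T_of[c], allow_singular=True)
        Sig = np.array(
            [
                [o.se1**2, o.se1 * o.se2 * o.rho_w],
                [o.se1 * o.se2 * o.rho_w, o.se2**2],
            ]
        )
        if o.y2_missing:
            lp += stats.norm.logpdf(o.y1, mu[i][0], o.se1)
        else:
            lp += stats.multivariate_normal.logpdf([o.y1, o.y2], mu[i], Sig)
    return lp


def random_valid_point(model: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    theta = np.empty(model.layout.size)
    for i, pd_ in enumerate(model.layout.defs):
        lo, hi = pd_.lower, pd_.upper
        if math.isinf(lo) and math.isinf(hi):
            theta[i] = rng.normal(0, 1)
        elif math.isinf(hi):
            theta[i] = rng.uniform(0.1, 2.0) if not pd_.name.startswith("v") else rng.uniform(1.0, 50.0)
        else:
            span = hi - lo
            theta[i] = rng.uniform(lo + 0.05 * span, hi - 0.05 * span)
    return theta


class TestJointDensityOracle:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_brute_force_on_triangle_toy(self, variant, triangle_network, rng):
        model = build_model(triangle_network, variant)
        for _ in range(3):
            theta = random_valid_point(model, rng)
            mu = rng.normal(0, 1, size=(triangle_network.n_studies, 2))
            got = model.joint_log_density(theta, mu)
            want = brute_force_joint_logpdf(model, theta, mu)
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_final_outcome_enters_via_surrogate_margin(self, triangle_network, rng):
        masked = triangle_network.mask_final_outcome("t2")
        model = build_model(masked, "1a")
        theta = random_valid_point(model, rng)
        mu = rng.normal(0, 1, size=(3, 2))
        assert model.joint_log_density(theta, mu) == pytest.approx(
            brute_force_joint_logpdf(model, theta, mu), abs=1e-10
        )


class TestMarginalLikelihood:
    def test_equals_closed_form_gaussian_convolution(self, toy_pair_network, rng):
        # integrating the latent effects out of the two Gaussian layers
        # leaves y_i ~ N(mean, Sigma_i + T)
        model = build_model(toy_pair_network, "brma")
        theta = random_valid_point(model, rng)
        p = dict(zip(model.layout.names, theta))
        T = np.array(
            [
                [p["tau1"] ** 2, p["tau1"] * p["tau2"] * p["rho"]],
                [p["tau1"] * p["tau2"] * p["rho"], p["tau2"] ** 2],
            ]
        )
        want = 0.0
        for o in toy_pair_network.observations:
            Sig = np.array(
                [
                    [o.se1**2, o.se1 * o.se2 * o.rho_w],
                    [o.se1 * o.se2 * o.rho_w, o.se2**2],
                ]
            )
            want += stats.multivariate_normal.logpdf(
                [o.y1, o.y2], [p["beta1"], p["beta2"]], Sig + T
            )
        got = model.log_marginal_likelihood(theta[None, :])[0]
        assert got == pytest.approx(want, abs=1e-10)


class TestConsistency:
    def test_identity_and_figure_network_relation(self):
        basic = {"A": (0.0, 0.0), "B": (1.0, 2.0), "C": (2.5, 1.5), "D": (4.0, 3.25)}
        assert consistency_effect(basic, "C", "C") == (0.0, 0.0)
        # effect of D vs C decomposes through the common reference A
        d_cd = consistency_effect(basic, "C", "D")
        d_ad = consistency_effect(basic, "A", "D")
        d_ac = consistency_effect(basic, "A", "C")
        assert d_cd[1] == pytest.approx(d_ad[1] - d_ac[1])
        with pytest.raises(KeyError):
            consistency_effect(basic, "A", "Z")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    def test_loop_sum_telescopes_to_zero(self, vals):
        basic = {
            "A": (vals[0], vals[1]),
            "B": (vals[2], vals[3]),
            "C": (vals[4], vals[5]),
        }
        ab = consistency_effect(basic, "A", "B")
        bc = consistency_effect(basic, "B", "C")
        ca = consistency_effect(basic, "C", "A")
        for j in range(2):
            assert ab[j] + bc[j] + ca[j] == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_under_swap(self):
        basic = {"A": (0.0, 0.0), "B": (1.0, -2.0)}
        assert consistency_effect(basic, "A", "B") == tuple(
            -x for x in consistency_effect(basic, "B", "A")
        )


class TestSecondOrderTau:
    @pytest.mark.parametrize(
        "tbk,tbl,rho,expected",
        [
            (0.4, 0.4, 1.0, 0.0),
            (0.3, 0.6, 0.0, math.sqrt(0.45)),
            (0.3, 0.6, -1.0, 0.9),
        ],
    )
    def test_known_values(self, tbk, tbl, rho, expected):
        assert second_order_tau(tbk, tbl, rho) == pytest.approx(expected, abs=1e-12)

    def test_monte_carlo_cross_check(self, rng):
        # tau_kl is the sd of the difference of two correlated arm effects
        tbk, tbl, rho = 0.3, 0.6, 0.4
        n = 400_000
        z = rng.standard_normal((2, n))
        xk = tbk * z[0]
        xl = tbl * (rho * z[0] + math.sqrt(1 - rho**2) * z[1])
        emp = np.std(xl - xk)
        se = emp * math.sqrt(0.5 / n) * 2
        assert abs(emp - second_order_tau(tbk, tbl, rho)) < 3 * se

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        tbk=st.floats(0, 2),
        tbl=st.floats(0, 2),
        rho=st.floats(-1, 1),
    )
    def test_triangle_inequalities(self, tbk, tbl, rho):
        t = second_order_tau(tbk, tbl, rho)
        assert abs(tbl - tbk) - 1e-9 <= t <= tbl + tbk + 1e-9


class TestAncillaryCovariances:
    def test_identical_arms_cancel(self):
        n_t = 3
        R = np.ones((2 * n_t, 2 * n_t))
        anc = AncillaryStructure(gamma=np.full((2, n_t), 0.7), R=R)
        cov = covariances_from_ancillary(anc, 0, 1)
        assert cov.tau1 == pytest.approx(0.0, abs=1e-12)
        assert cov.tau2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_simulated_arm_effect_differences(self, rng):
        n_t, m = 3, 6
        angles = rng.uniform(0.3, math.pi - 0.3, size=m * (m - 1) // 2)
        R = corr_cholesky_from_angles(angles, m)
        gamma = rng.uniform(0.3, 1.2, size=(2, n_t))
        anc = AncillaryStructure(gamma=gamma, R=R)
        sds = np.array([gamma[j, k] for k in range(n_t) for j in range(2)])
        Gam = np.outer(sds, sds) * R
        n = 1_000_000
        zeta = rng.multivariate_normal(np.zeros(m), Gam, size=n)
        k, l = 0, 2
        d1 = zeta[:, 2 * l] - zeta[:, 2 * k]
        d2 = zeta[:, 2 * l + 1] - zeta[:, 2 * k + 1]
        cov = covariances_from_ancillary(anc, k, l)
        assert np.std(d1) == pytest.approx(cov.tau1, rel=5e-3)
        assert np.std(d2) == pytest.approx(cov.tau2, rel=5e-3)
        assert np.corrcoef(d1, d2)[0, 1] == pytest.approx(cov.rho, abs=5e-3)

    def test_covariance_consistency_identity_all_triples(self, rng):
        # cross-contrast identity checked against quadratic forms in Gamma
        n_t, m = 4, 8
        angles = rng.uniform(0.1, math.pi - 0.1, size=m * (m - 1) // 2)
        R = corr_cholesky_from_angles(angles, m)
        gamma = rng.uniform(0.2, 1.5, size=(2, n_t))
        anc = AncillaryStructure(gamma=gamma, R=R)
        sds = np.array([gamma[j, k] for k in range(n_t) for j in range(2)])
        Gam = np.outer(sds, sds) * R

        def u(j, k):  # difference-vector cross covariance via Gamma
            e = np.zeros(m)
            e[2 * k + j] = 1.0
            return e

        def cross_cov(j, kl, jp, kplp):
            a = u(j, kl[1]) - u(j, kl[0])
            b = u(jp, kplp[1]) - u(jp, kplp[0])
            return a @ Gam @ b

        from itertools import combinations

        for b, k, l in combinations(range(n_t), 3):
            lhs = covariances_from_ancillary(anc, k, l)
            lhs_cov12 = lhs.tau1 * lhs.tau2 * lhs.rho
            rhs = (
                cross_cov(0, (b, l), 1, (b, l))
                + cross_cov(0, (b, k), 1, (b, k))
                - cross_cov(0, (b, l), 1, (b, k))
                - cross_cov(0, (b, k), 1, (b, l))
            )
            assert lhs_cov12 == pytest.approx(rhs, abs=1e-12)

    def test_non_psd_matrix_rejected(self):
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.9
        R[0, 2] = R[2, 0] = 0.9
        R[1, 2] = R[2, 1] = -0.9
        with pytest.raises(Exception):
            AncillaryStructure(gamma=np.ones((2, 2)), R=R)


class TestAncillaryPrior:
    def test_two_treatment_prior_draws_valid(self, rng):
        prior = ancillary_prior(2, PriorConfig())
        rhos = []
        for _ in range(2000):
            anc = prior.rvs(rng)
            assert anc.R.shape == (4, 4)
            cov = covariances_from_ancillary(anc, 0, 1)
            assert abs(cov.rho) <= 1.0
            rhos.append(cov.rho)
        rhos = np.asarray(rhos)
        # induced contrast-level correlation prior symmetric about zero
        assert abs(np.mean(rhos)) < 3 * np.std(rhos) / math.sqrt(rhos.size)

    def test_hierarchical_gamma_draws_nonnegative(self, rng):
        prior = ancillary_prior(3, PriorConfig(), hierarchical=True)
        anc = prior.rvs(rng)
        assert np.all(anc.gamma >= 0)


class TestBuildModel:
    def test_unknown_variant(self, toy_pair_network):
        with pytest.raises(UnknownVariantError):
            build_model(toy_pair_network, "3z")

    def test_variant_1a_catalogue_counts(self, scenario1_data):
        model = build_model(scenario1_data, "1a")
        names = model.layout.names
        # 3 contrast-level (tau1, tau2, rho) triplets + 4 basic parameters
        assert sum(n.startswith("tau") for n in names) == 6
        assert sum(n.startswith("rho") for n in names) == 3
        assert sum(n.startswith("d") for n in names) == 4
        assert model.layout.size == 13

    def test_variant_2d_catalogue(self, scenario1_data):
        model = build_model(scenario1_data, "2d")
        names = set(model.layout.names)
        assert {"tau1", "tau2", "rho", "omega1", "omega2", "rho_t"} <= names
        assert sum(n.startswith("theta") for n in names) == 6
        assert model.layout.size == 12

    def test_two_treatments_collapse_to_pairwise_structure(self, toy_pair_network):
        # with a single contrast, the network models have exactly the
        # standard bivariate meta-analysis parameter count
        brma = build_model(toy_pair_network, "brma")
        m1a = build_model(toy_pair_network, "1a")
        m1d = build_model(toy_pair_network, "1d")
        assert m1a.layout.size == brma.layout.size
        assert m1d.layout.size == brma.layout.size

    def test_homogeneous_cov_parameter_count_independent_of_contrasts(
        self, toy_pair_network, scenario1_data
    ):
        n_cov = lambda m: sum(
            n.startswith(("tau", "rho")) for n in m.layout.names
        )
        assert n_cov(build_model(toy_pair_network, "1d")) == n_cov(
            build_model(scenario1_data, "1d")
        )

    def test_single_study_contrast_warns(self, triangle_network):
        with pytest.warns(UserWarning, match="prior-driven"):
            build_model(triangle_network, "1a")


class TestSecondOrderConsistencyAtPriorDraws:
    def test_triangle_and_covariance_identities_hold(self, scenario1_data, rng):
        # the induced covariance set of the second-order-consistency model
        # must satisfy both identities at every prior draw
        model = build_model(scenario1_data, "1b")
        n = 10_000
        theta = np.zeros((n, model.layout.size))
        theta[:, model._i_gamma] = rng.uniform(0.0, 2.0, size=(n, 6))
        theta[:, model._i_phi] = rng.uniform(0.0, math.pi, size=(n, 15))
        t11, t22, t12 = model.contrast_covs(theta)
        tau = np.stack([np.sqrt(t11), np.sqrt(t22)])  # (2, n, C=AB,AC,BC)
        # triangle inequalities for the (A,B,C) triple, both outcomes
        for j in range(2):
            for a, b, c in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
                viol = tau[j][:, a] - (tau[j][:, b] + tau[j][:, c])
                assert np.max(viol) < 1e-10
        # covariance identity: cov12(BC) from cov12 of AB, AC and crosses
        gam = theta[:, model._i_gamma].reshape(n, 3, 2).transpose(0, 2, 1)
        R = corr_cholesky_from_angles(theta[:, model._i_phi], 6)
        sds = np.stack(
            [gam[:, j, k] for k in range(3) for j in range(2)], axis=1
        )
        Gam = sds[:, :, None] * sds[:, None, :] * R

        def cross(j, kl, jp, kplp):
            a = np.zeros(6)
            a[2 * kl[1] + j] = 1.0
            a[2 * kl[0] + j] -= 1.0
            b = np.zeros(6)
            b[2 * kplp[1] + jp] = 1.0
            b[2 * kplp[0] + jp] -= 1.0
            return np.einsum("i,nij,j->n", a, Gam, b)

        # contrasts order: AB=(0,1), AC=(0,2), BC=(1,2); base b=A=0
        lhs = t12[:, 2]
        rhs = (
            cross(0, (0, 2), 1, (0, 2))
            + cross(0, (0, 1), 1, (0, 1))
            - cross(0, (0, 2), 1, (0, 1))
            - cross(0, (0, 1), 1, (0, 2))
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-10


class TestExchangeableLayer:
    def test_induced_mean_effect_covariance(self, rng):
        # the half factor in the treatment-level layer cancels in the
        # differences: cov(d1_kl, d2_kl) = [[w1^2, rt w1 w2], [., w2^2]]
        w1, w2, rt = 0.8, 1.2, 0.5
        n = 400_000
        cov_t = 0.5 * np.array([[w1**2, rt * w1 * w2], [rt * w1 * w2, w2**2]])
        th_k = rng.multivariate_normal(np.zeros(2), cov_t, size=n)
        th_l = rng.multivariate_normal(np.zeros(2), cov_t, size=n)
        d = th_l - th_k
        emp = np.cov(d.T)
        assert emp[0, 0] == pytest.approx(w1**2, rel=0.02)
        assert emp[1, 1] == pytest.approx(w2**2, rel=0.02)
        assert emp[0, 1] == pytest.approx(rt * w1 * w2, rel=0.05)


class TestCorrCholesky:
    def test_unit_diagonal_and_psd(self, rng):
        m = 6
        angles = rng.uniform(0, math.pi, size=(100, m * (m - 1) // 2))
        R = corr_cholesky_from_angles(angles, m)
        assert np.allclose(np.diagonal(R, axis1=-2, axis2=-1), 1.0)
        w = np.linalg.eigvalsh(R)
        assert w.min() > -1e-10
        assert np.abs(R).max() <= 1 + 1e-12
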