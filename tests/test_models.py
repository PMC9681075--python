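import numpy as np
import pytest

from stcar import models as M
from stcar.car import CarStructure, car_logdensity, leroux_precision, sample_car_field
from stcar.lattice import make_grid_lattice, temporal_path_lattice

from _oracles import dense_block_conditional, dense_conditional_from_joint


def _zeros_state(spec, D, T, p):
    st = M.ParameterState(beta=np.zeros(p), nu2=1.0)
    if spec.family == "st_anova":
        st.phi, st.delta = np.zeros(D), np.zeros(T)
        st.tau2_s = st.tau2_t = 1.0
        st.rho_s = st.rho_t = 0.5
        if spec.anova_interaction:
            st.gamma, st.tau2_i = np.zeros(D * T), 1.0
    elif spec.family == "st_linear":
        st.phi, st.delta, st.alpha = np.zeros(D), np.zeros(D), 0.0
        st.tau2_int = st.tau2_slo = 1.0
        st.rho_int = st.rho_slo = 0.5
    elif spec.family == "st_ar":
        st.phi = np.zeros(D * T)
        st.tau2_t, st.rho_s, st.rho_t = 1.0, 0.5, 0.5
    return st


class TestLinearPredictor:
    @pytest.mark.parametrize("family", M.FAMILIES)
    def test_zero_effects_give_x_beta(self, family, rng):
        D, T = 2, 3
        spec = M.ModelSpec(family=family, covariates=("c",))
        X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])
        st = _zeros_state(spec, D, T, 2)
        st.beta = np.array([1.0, -2.0])
        assert np.allclose(M.linear_predictor(st, spec, X, D, T), X @ st.beta)

    def test_anova_constant_effects(self):
        D, T = 3, 2
        spec = M.ModelSpec(family="st_anova", covariates=())
        st = _zeros_state(spec, D, T, 1)
        st.phi = np.ones(D)
        st.delta = np.full(T, 2.0)
        X = np.ones((D * T, 1))
        assert np.allclose(M.linear_predictor(st, spec, X, D, T), 3.0)

    def test_linear_trend_hand_value(self):
        # D=2, T=3, beta=0, phi=0, alpha=1, delta=(0,1):
        # at (d=2, t=3): (1 + 1) * (3 - 2)/3 = 2/3
        D, T = 2, 3
        spec = M.ModelSpec(family="st_linear", covariates=())
        st = _zeros_state(spec, D, T, 1)
        st.alpha = 1.0
        st.delta = np.array([0.0, 1.0])
        X = np.ones((D * T, 1)) * 0.0
        mu = M.linear_predictor(st, spec, X, D, T)
        assert mu[2 * D + 1] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        spec = M.ModelSpec(family="independent_glm", covariates=())
        st = _zeros_state(spec, 2, 3, 1)
        with pytest.raises(ValueError):
            M.linear_predictor(st, spec, np.ones((5, 1)), 2, 3)


class TestGaussianLoglik:
    def test_single_perfect_observation(self):
        assert M.gaussian_loglik(np.array([1.0]), np.array([1.0]), 1.0) == pytest.approx(
            -0.5 * np.log(2 * np.pi), abs=1e-12
        )

    def test_doubling_variance_at_mode(self):
        y = np.zeros(10)
        a = M.gaussian_loglik(y, y, 1.0)
        b = M.gaussian_loglik(y, y, 2.0)
        assert a - b == pytest.approx(10 * 0.5 * np.log(2), abs=1e-12)

    def test_matches_per_observation_sum(self, rng):
        y, mu, nu2 = rng.normal(size=9), rng.normal(size=9), 1.7
        naive = sum(
            -0.5 * np.log(2 * np.pi * nu2) - 0.5 * (yi - mi) ** 2 / nu2
            for yi, mi in zip(y, mu)
        )
        assert M.gaussian_loglik(y, mu, nu2) == pytest.approx(naive, abs=1e-12)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            M.gaussian_loglik(np.zeros(2), np.zeros(2), 0.0)


class TestUpdateBeta:
    def test_vague_prior_limit_is_ols(self, rng):
        n, p = 50, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        y = rng.normal(size=n)
        prior = M.PriorSpec(beta_prior_variance=1e12)
        P, b = M.full_conditional_beta(X, y, 1.0, prior)
        mean, _ = M.conditional_moments(P, b)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(mean, ols, atol=1e-8)

    def test_scalar_conjugacy(self):
        # single intercept, n=1, y=5, nu2=1, s2b=100000
        X = np.ones((1, 1))
        prior = M.PriorSpec(beta_prior_variance=100000.0)
        P, b = M.full_conditional_beta(X, np.array([5.0]), 1.0, prior)
        mean, _ = M.conditional_moments(P, b)
        assert mean[0] == pytest.approx(5.0 * 100000 / 100001, abs=1e-10)

    def test_monte_carlo_mean_matches_analytic(self, rng):
        n = 20
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        prior = M.PriorSpec(beta_prior_variance=10.0)
        spec = M.ModelSpec(family="independent_glm", covariates=("c",))
        P, b = M.full_conditional_beta(X, y, 1.0, prior)
        mean, cov = M.conditional_moments(P, b)
        S = 100_000
        draws = np.empty((S, 2))
        st = M.ParameterState(beta=np.zeros(2), nu2=1.0)
        for s in range(S):
            st.beta = np.zeros(2)
            draws[s] = M.update_beta(st, y, X, spec, n, 1, prior, rng)
        se = np.sqrt(np.diag(cov) / S)
        # 4 SE: two simultaneous comparisons, keep the false-alarm rate low
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        emp_cov = np.cov(draws.T)
        assert np.allclose(emp_cov, cov, atol=4 * np.abs(cov).max() / np.sqrt(S / 2))


class TestUpdateVariance:
    def test_prior_draw_when_empty(self, rng):
        prior = M.PriorSpec(ig_shape=3.0, ig_scale=2.0)
        draws = np.array([M.update_variance(0.0, 0, prior, rng) for _ in range(50_000)])
        # IG(3, 2): mean 1, var 1/2 -> SE of mean
        se = np.sqrt(0.5 / draws.size)
        assert abs(draws.mean() - 1.0) < 4 * se

    def test_posterior_parameters(self, rng):
        # count=4, sum_sq=2 with IG(1, 0.01) prior -> IG(3, 1.01), mean 0.505
        prior = M.PriorSpec()
        draws = np.array(
            [M.update_variance(2.0, 4, prior, rng) for _ in range(100_000)]
        )
        mean = 1.01 / 2.0
        var = 1.01**2 / (2.0**2 * 1.0)  # IG(3,1.01): b^2/((a-1)^2 (a-2))
        se = np.sqrt(var / draws.size)
        assert abs(draws.mean() - mean) < 3 * se

    def test_negative_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            M.update_variance(-1.0, 2, M.PriorSpec(), rng)


def _anova_setup(rng, D=4, T=3, interaction=False):
    lat = make_grid_lattice(2, 2)
    spec = M.ModelSpec(
        family="st_anova", covariates=("c",), anova_interaction=interaction
    )
    X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])
    st = _zeros_state(spec, D, T, 2)
    st.beta = np.array([0.5, -1.0])
    st.nu2 = 0.8
    st.tau2_s, st.tau2_t = 0.7, 1.3
    st.rho_s, st.rho_t = 0.4, 0.6
    st.phi = rng.normal(size=D) * 0.5
    st.delta = rng.normal(size=T) * 0.5
    if interaction:
        st.gamma = rng.normal(size=D * T) * 0.3
        st.tau2_i = 0.5
    y = rng.normal(size=D * T)
    return lat, spec, X, st, y, D, T


class TestDenseGaussianOracle:
    """Every full conditional vs textbook joint-normal conditioning, 1e-8."""

    def test_anova_phi(self, rng):
        lat, spec, X, st, y, D, T = _anova_setup(rng)
        P, b = M.full_conditional_phi(st, y, X, spec, lat, D, T)
        mean, cov = M.conditional_moments(P, b)
        Sigma = st.tau2_s * np.linalg.inv(leroux_precision(lat, st.rho_s))
        A = np.tile(np.eye(D), (T, 1))
        c = X @ st.beta + np.repeat(st.delta, D)
        omean, ocov = dense_conditional_from_joint(Sigma, A, c, st.nu2, y)
        assert np.allclose(mean, omean, atol=1e-8)
        assert np.allclose(cov, ocov, atol=1e-8)

    def test_anova_delta(self, rng):
        lat, spec, X, st, y, D, T = _anova_setup(rng)
        P, b = M.full_conditional_delta(st, y, X, spec, lat, D, T)
        mean, cov = M.conditional_moments(P, b)
        Qt = leroux_precision(temporal_path_lattice(T), st.rho_t)
        Sigma = st.tau2_t * np.linalg.inv(Qt)
        A = np.kron(np.eye(T), np.ones((D, 1)))
        c = X @ st.beta + np.tile(st.phi, T)
        omean, ocov = dense_conditional_from_joint(Sigma, A, c, st.nu2, y)
        assert np.allclose(mean, omean, atol=1e-8)
        assert np.allclose(cov, ocov, atol=1e-8)

    def test_anova_gamma(self, rng):
        lat, spec, X, st, y, D, T = _anova_setup(rng, interaction=True)
        prec, b = M.full_conditional_gamma(st, y, X, spec, D, T)
        Sigma = st.tau2_i * np.eye(D * T)
        A = np.eye(D * T)
        c = X @ st.beta + np.tile(st.phi, T) + np.repeat(st.delta, D)
        omean, ocov = dense_conditional_from_joint(Sigma, A, c, st.nu2, y)
        assert np.allclose(b / prec, omean, atol=1e-8)
        assert np.allclose(np.diag(1.0 / prec), ocov, atol=1e-8)

    def _linear_setup(self, rng, D=4, T=3):
        lat = make_grid_lattice(2, 2)
        spec = M.ModelSpec(family="st_linear", covariates=("c",))
        X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])
        st = _zeros_state(spec, D, T, 2)
        st.beta = np.array([0.2, 0.9])
        st.nu2 = 0.6
        st.alpha = -0.4
        st.tau2_int, st.tau2_slo = 0.9, 1.1
        st.rho_int, st.rho_slo = 0.3, 0.7
        st.phi = rng.normal(size=D) * 0.4
        st.delta = rng.normal(size=D) * 0.4
        y = rng.normal(size=D * T)
        return lat, spec, X, st, y, D, T

    def test_linear_slope_block(self, rng):
        lat, spec, X, st, y, D, T = self._linear_setup(rng)
        P, b = M.full_conditional_delta(st, y, X, spec, lat, D, T)
        mean, cov = M.conditional_moments(P, b)
        Sigma = st.tau2_slo * np.linalg.inv(leroux_precision(lat, st.rho_slo))
        s = M.trend_scale(T)
        A = np.kron(s[:, None], np.eye(D))  # row t*D+d multiplies delta_d by s_t
        c = X @ st.beta + np.tile(st.phi, T) + st.alpha * np.repeat(s, D)
        omean, ocov = dense_conditional_from_joint(Sigma, A, c, st.nu2, y)
        assert np.allclose(mean, omean, atol=1e-8)
        assert np.allclose(cov, ocov, atol=1e-8)

    def test_linear_alpha(self, rng):
        lat, spec, X, st, y, D, T = self._linear_setup(rng)
        prior = M.PriorSpec(beta_prior_variance=50.0)
        prec, b = M.full_conditional_alpha(st, y, X, spec, prior, D, T)
        s = M.trend_scale(T)
        A = np.repeat(s, D)[:, None]
        c = X @ st.beta + np.tile(st.phi, T) + np.repeat(s, D) * np.tile(st.delta, T)
        omean, ocov = dense_conditional_from_joint(
            np.array([[50.0]]), A, c, st.nu2, y
        )
        assert b / prec == pytest.approx(omean[0], abs=1e-8)
        assert 1.0 / prec == pytest.approx(ocov[0, 0], abs=1e-8)

    def _ar_setup(self, rng, D=4, T=3):
        lat = make_grid_lattice(2, 2)
        spec = M.ModelSpec(family="st_ar", covariates=("c",))
        X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])
        st = _zeros_state(spec, D, T, 2)
        st.beta = np.array([0.1, 0.5])
        st.nu2 = 0.9
        st.tau2_t, st.rho_s, st.rho_t = 1.2, 0.5, 0.6
        st.phi = rng.normal(size=D * T) * 0.5
        y = rng.normal(size=D * T)
        return lat, spec, X, st, y, D, T

    def _ar_joint_precision(self, st, lat, D, T):
        """Dense prior precision of the whole chain (block tridiagonal)."""
        Q = leroux_precision(lat, st.rho_s)
        K = np.zeros((D * T, D * T))
        rho, tau2 = st.rho_t, st.tau2_t
        for t in range(T):
            blk = slice(t * D, (t + 1) * D)
            K[blk, blk] += Q / tau2
            if t < T - 1:
                nxt = slice((t + 1) * D, (t + 2) * D)
                K[blk, blk] += rho**2 * Q / tau2
                K[blk, nxt] += -rho * Q / tau2
                K[nxt, blk] += -rho * Q / tau2
        return K

    @pytest.mark.parametrize("t", [0, 1, 2])
    def test_ar_slice(self, rng, t):
        lat, spec, X, st, y, D, T = self._ar_setup(rng)
        P, b_slice = M.full_conditional_ar_slice(st, y, X, lat, D, T, t)
        mean, cov = M.conditional_moments(P, b_slice)
        # oracle: posterior precision of full field, conditioned blockwise
        K = self._ar_joint_precision(st, lat, D, T)
        P_post = K + np.eye(D * T) / st.nu2
        b_full = (y - X @ st.beta) / st.nu2
        block = np.arange(t * D, (t + 1) * D)
        omean, ocov = dense_block_conditional(P_post, b_full, st.phi, block)
        assert np.allclose(mean, omean, atol=1e-8)
        assert np.allclose(cov, ocov, atol=1e-8)

    def test_ar_rho_zero_decouples_slices(self, rng):
        lat, spec, X, st, y, D, T = self._ar_setup(rng)
        st.rho_t = 0.0
        for t in range(T):
            P, b = M.full_conditional_ar_slice(st, y, X, lat, D, T, t)
            mean, cov = M.conditional_moments(P, b)
            # single-slice oracle: one CAR field seen once with data slice t
            Sigma = st.tau2_t * np.linalg.inv(leroux_precision(lat, st.rho_s))
            A = np.eye(D)
            c = (X @ st.beta).reshape(T, D)[t]
            omean, ocov = dense_conditional_from_joint(
                Sigma, A, c, st.nu2, y.reshape(T, D)[t]
            )
            assert np.allclose(mean, omean, atol=1e-8)
            assert np.allclose(cov, ocov, atol=1e-8)


class TestEffectUpdateLimits:
    def test_tiny_tau2_shrinks_block_to_zero(self, rng):
        lat, spec, X, st, y, D, T = _anova_setup(rng)
        st.tau2_s = 1e-12
        M.update_random_effects(st, y, X, spec, lat, D, T, M.PriorSpec(), rng)
        assert np.all(np.abs(st.phi) < 1e-4)

    def test_huge_nu2_recovers_prior_moments(self, rng):
        lat, spec, X, st, y, D, T = _anova_setup(rng)
        st.nu2 = 1e12
        P, b = M.full_conditional_phi(st, y, X, spec, lat, D, T)
        _, cov = M.conditional_moments(P, b)
        prior_cov = st.tau2_s * np.linalg.inv(leroux_precision(lat, st.rho_s))
        assert np.allclose(cov, prior_cov, atol=1e-6)

    def test_ar_tiny_tau2_zeroes_chain(self, rng):
        lat = make_grid_lattice(2, 2)
        D, T = 4, 3
        spec = M.ModelSpec(family="st_ar", covariates=())
        st = _zeros_state(spec, D, T, 1)
        st.phi = rng.normal(size=D * T)
        st.tau2_t = 1e-12
        X = np.ones((D * T, 1))
        y = rng.normal(size=D * T)
        # the prior pull propagates along the chain geometrically per sweep
        for _ in range(25):
            M.update_ar_chain(st, y, X, lat, D, T, rng)
        assert np.all(np.abs(st.phi) < 1e-4)


class TestCentering:
    @pytest.mark.parametrize("family", ["st_anova", "st_linear", "st_ar"])
    def test_centering_preserves_linear_predictor(self, family, rng):
        D, T = 4, 3
        lat = make_grid_lattice(2, 2)
        spec = M.ModelSpec(family=family, covariates=("c",))
        X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])
        st = _zeros_state(spec, D, T, 2)
        st.beta = rng.normal(size=2)
        # un-centred effects
        if family == "st_ar":
            st.phi = rng.normal(size=D * T)
        else:
            st.phi = rng.normal(size=D)
            st.delta = rng.normal(size=T if family == "st_anova" else D)
        mu_before = M.linear_predictor(st, spec, X, D, T)
        # apply exactly the centring transfer the updates perform
        m = st.phi.mean()
        st.phi = st.phi - m
        st.beta[0] += m
        if family == "st_anova":
            m = st.delta.mean()
            st.delta = st.delta - m
            st.beta[0] += m
        elif family == "st_linear":
            m = st.delta.mean()
            st.delta = st.delta - m
            st.alpha += m
        mu_after = M.linear_predictor(st, spec, X, D, T)
        assert np.allclose(mu_before, mu_after, atol=1e-10)


class TestUpdateRho:
    def test_draws_stay_inside_unit_interval(self, rng):
        lat = make_grid_lattice(2, 2)
        u = rng.normal(size=4)
        rho = 0.5
        for _ in range(500):
            rho, _ = M.update_rho(u, lat, 1.0, rho, 0.3, rng)
            assert 0.0 < rho < 1.0

    def test_chain_matches_grid_posterior(self, rng):
        """Metropolis marginal for rho vs a fine-grid numeric posterior."""
        lat = make_grid_lattice(2, 1)  # 2-node block
        u = np.array([0.8, 0.7])  # smooth pair -> informative about rho
        tau2 = 0.5
        grid = np.linspace(5e-4, 1 - 5e-4, 2000)
        logp = np.array(
            [car_logdensity(u, CarStructure(lat, r, tau2)) for r in grid]
        )
        w = np.exp(logp - logp.max())
        w /= w.sum()
        grid_mean = float(w @ grid)
        grid_p_half = float(w[grid < 0.5].sum())

        rho, draws = 0.5, []
        for _ in range(40_000):
            rho, _ = M.update_rho(u, lat, tau2, rho, 0.4, rng)
            draws.append(rho)
        draws = np.asarray(draws[2000:])
        assert abs(draws.mean() - grid_mean) < 0.02
        assert abs(np.mean(draws < 0.5) - grid_p_half) < 0.03

    def test_identical_proposal_always_accepted(self, rng):
        # proposal sd 0 proposes the current value -> accepted
        lat = make_grid_lattice(2, 1)
        rho, ok = M.update_rho(np.array([0.1, 0.2]), lat, 1.0, 0.37, 0.0, rng)
        assert ok and rho == 0.37


class TestGewekeJointDistribution:
    def test_gibbs_matches_prior_on_anova_model(self):
        """Joint-distribution check: alternating data-augmented Gibbs sweeps
        reproduce prior moments of beta, log nu2, log tau2 on a 4-area x
        3-year model (within 4 Monte-Carlo standard errors)."""
        rng = np.random.default_rng(2024)
        D, T = 4, 3
        lat = make_grid_lattice(2, 2)
        spec = M.ModelSpec(family="st_anova", covariates=("c",))
        # proper test prior with finite moments (IG(1, .01) has none)
        prior = M.PriorSpec(beta_prior_variance=1.0, ig_shape=3.0, ig_scale=2.0)
        X = np.column_stack([np.ones(D * T), rng.normal(size=D * T)])

        def prior_state():
            st = M.ParameterState(
                beta=np.sqrt(prior.beta_prior_variance) * rng.standard_normal(2),
                nu2=M.update_variance(0.0, 0, prior, rng),
            )
            st.tau2_s = M.update_variance(0.0, 0, prior, rng)
            st.tau2_t = M.update_variance(0.0, 0, prior, rng)
            st.rho_s, st.rho_t = rng.uniform(), rng.uniform()
            st.phi = sample_car_field(CarStructure(lat, st.rho_s, st.tau2_s), rng)
            st.delta = sample_car_field(
                CarStructure(temporal_path_lattice(T), st.rho_t, st.tau2_t), rng
            )
            return st

        def draw_y(st):
            mu = M.linear_predictor(st, spec, X, D, T)
            return mu + np.sqrt(st.nu2) * rng.standard_normal(D * T)

        def stats(st):
            return [
                st.beta[0], st.beta[1],
                np.log(st.nu2), np.log(st.tau2_s), np.log(st.tau2_t),
                st.rho_s,
            ]

        n_prior = 6000
        prior_stats = np.array([stats(prior_state()) for _ in range(n_prior)])

        # successive-conditional chain: y | theta, then one Gibbs sweep.
        # NOTE: no centring here — the Geweke identity needs the transition
        # kernel to leave the *unconstrained* prior invariant, so we call the
        # raw full-conditional draws rather than update_random_effects.
        n_sweeps, thin = 30_000, 5
        st = prior_state()
        prop = {"rho_s": 0.4, "rho_t": 0.4}
        chain = []
        for it in range(n_sweeps):
            y = draw_y(st)
            resid = y - M.psi_vector(st, spec, D, T)
            P, b = M.full_conditional_beta(X, resid, st.nu2, prior)
            st.beta = M.draw_mvn_from_precision(P, b, rng)
            P, b = M.full_conditional_phi(st, y, X, spec, lat, D, T)
            st.phi = M.draw_mvn_from_precision(P, b, rng)
            P, b = M.full_conditional_delta(st, y, X, spec, lat, D, T)
            st.delta = M.draw_mvn_from_precision(P, b, rng)
            M.update_variances(st, y, X, spec, lat, D, T, prior, rng)
            M.update_rhos(st, spec, lat, D, T, prop, rng)
            if (it + 1) % thin == 0:
                chain.append(stats(st))
        chain = np.array(chain)

        pm, ps = prior_stats.mean(axis=0), prior_stats.std(axis=0, ddof=1)
        cm = chain.mean(axis=0)
        # conservative chain SE via batch means (20 batches)
        batches = np.array_split(chain, 20)
        bmeans = np.array([b.mean(axis=0) for b in batches])
        cse = bmeans.std(axis=0, ddof=1) / np.sqrt(len(batches))
        pse = ps / np.sqrt(n_prior)
        tol = 4.0 * np.sqrt(cse**2 + pse**2)
        assert np.all(np.abs(cm - pm) < tol), (
            f"Geweke mismatch: prior {pm}, chain {cm}, tol {tol}"
        )
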