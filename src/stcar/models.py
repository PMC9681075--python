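"""Model families, likelihood, priors, and exact full-conditional updates.

The observation model for every family is Gaussian with a single
(homoscedastic) nugget variance nu2:

    y_dt ~ N(mu_dt, nu2),      mu_dt = x_dt' beta + psi_dt

and the families differ only in the structured space-time term psi_dt:

====================  =====================================================
independent_glm       psi = 0 (independent-error Bayesian GLM)
st_anova              psi_dt = phi_d + delta_t (+ gamma_dt, flag-gated)
st_linear             psi_dt = phi_d + (alpha + delta_d) * (t - tbar) / T
st_ar                 psi_dt = phi_dt, a first-order autoregressive chain
                      of CAR-distributed spatial slices
====================  =====================================================

Spatial blocks (phi in st_anova; intercept and slope fields in st_linear;
each innovation slice in st_ar) carry Leroux CAR priors on the areal
lattice; the st_anova temporal block delta carries the same prior on the
path graph of length T.  gamma_dt is iid N(0, tau2_i).  Regression
coefficients have independent N(0, sigma2_beta) priors, every variance an
inverse-gamma prior, every dependence parameter rho a Uniform(0, 1) prior.

All updates are exact draws from the full conditionals (conjugate Gaussian
and inverse-gamma steps) except the rho parameters, which use a reflected
random-walk Metropolis step.  Each Gaussian block is mean-centred right
after its draw, with the removed mean absorbed into the intercept (or into
alpha for the st_linear slope block), which keeps the linear predictor
bitwise unchanged while enforcing sum-to-zero identifiability.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .car import CarStructure, car_logdensity_multi, leroux_precision
from .lattice import SpatialLattice, temporal_path_lattice
from .panel import DEFAULT_COVARIATES

__all__ = [
    "FAMILIES",
    "ModelSpec",
    "PriorSpec",
    "ParameterState",
    "trend_scale",
    "psi_vector",
    "linear_predictor",
    "gaussian_loglik",
    "conditional_moments",
    "draw_mvn_from_precision",
    "full_conditional_beta",
    "full_conditional_phi",
    "full_conditional_delta",
    "full_conditional_gamma",
    "full_conditional_alpha",
    "full_conditional_ar_slice",
    "update_beta",
    "update_random_effects",
    "update_variance",
    "update_variances",
    "update_rho",
    "update_rhos",
    "update_ar_chain",
    "initial_state",
]

FAMILIES = ("independent_glm", "st_linear", "st_anova", "st_ar")

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Which family and which covariates define the joint model."""

    family: str = "st_anova"
    anova_interaction: bool = False
    covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {FAMILIES}"
            )
        object.__setattr__(self, "covariates", tuple(self.covariates))


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters shared by all families.

    beta_prior_variance
        Variance of the independent N(0, sigma2_beta) coefficient priors.
    ig_shape, ig_scale
        Inverse-gamma (shape a, scale b) hyperprior applied to every
        variance parameter (nu2 and all tau2's).  The default IG(1, 0.01)
        is weakly informative on the variance scale.
    """

    beta_prior_variance: float = 100000.0
    ig_shape: float = 1.0
    ig_scale: float = 0.01

    def __post_init__(self):
        if min(self.beta_prior_variance, self.ig_shape, self.ig_scale) <= 0:
            raise ValueError("all prior hyperparameters must be > 0")


@dataclass
class ParameterState:
    """Current values of every sampled quantity for one family.

    Only the blocks relevant to the family are populated; the rest stay
    ``None``.  Effect blocks live on the canonical time-major flat order
    where applicable (st_ar ``phi`` has length D*T).
    """

    beta: np.ndarray
    nu2: float
    # st_anova
    phi: np.ndarray | None = None      # also st_linear intercepts / st_ar field
    delta: np.ndarray | None = None    # st_anova temporal / st_linear slopes
    gamma: np.ndarray | None = None
    tau2_s: float | None = None
    tau2_t: float | None = None
    tau2_i: float | None = None
    rho_s: float | None = None
    rho_t: float | None = None
    # st_linear
    alpha: float | None = None
    tau2_int: float | None = None
    tau2_slo: float | None = None
    rho_int: float | None = None
    rho_slo: float | None = None

    def copy(self) -> "ParameterState":
        out = ParameterState(beta=self.beta.copy(), nu2=self.nu2)
        for name in (
            "phi", "delta", "gamma",
        ):
            v = getattr(self, name)
            setattr(out, name, None if v is None else v.copy())
        for name in (
            "tau2_s", "tau2_t", "tau2_i", "rho_s", "rho_t",
            "alpha", "tau2_int", "tau2_slo", "rho_int", "rho_slo",
        ):
            setattr(out, name, getattr(self, name))
        return out


def trend_scale(T: int) -> np.ndarray:
    """Centred, scaled time covariate s_t = (t - tbar)/T, t = 1..T, tbar=(T+1)/2."""
    t = np.arange(1, T + 1, dtype=float)
    return (t - (T + 1) / 2.0) / T


def psi_vector(state: ParameterState, spec: ModelSpec, D: int, T: int) -> np.ndarray:
    """Structured space-time term psi as a flat D*T vector (offset t*D + d)."""
    fam = spec.family
    if fam == "independent_glm":
        return np.zeros(D * T)
    if fam == "st_anova":
        psi = np.tile(state.phi, T) + np.repeat(state.delta, D)
        if spec.anova_interaction:
            psi = psi + state.gamma
        return psi
    if fam == "st_linear":
        s = np.repeat(trend_scale(T), D)
        return np.tile(state.phi, T) + s * (state.alpha + np.tile(state.delta, T))
    # st_ar
    return state.phi.copy()


def linear_predictor(
    state: ParameterState, spec: ModelSpec, X: np.ndarray, D: int, T: int
) -> np.ndarray:
    """mu = X beta + psi, flat length D*T in canonical order."""
    if X.shape[0] != D * T:
        raise ValueError(f"design has {X.shape[0]} rows, expected D*T = {D * T}")
    if X.shape[1] != state.beta.shape[0]:
        raise ValueError("beta length does not match design columns")
    return X @ state.beta + psi_vector(state, spec, D, T)


def gaussian_loglik(y: np.ndarray, mu: np.ndarray, nu2: float) -> float:
    """Homoscedastic Gaussian log-likelihood sum_i log N(y_i | mu_i, nu2)."""
    if nu2 <= 0:
        raise ValueError(f"nu2 must be > 0, got {nu2}")
    y = np.asarray(y, float)
    mu = np.asarray(mu, float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have equal lengths")
    n = y.size
    return float(
        -0.5 * n * (_LOG_2PI + np.log(nu2)) - 0.5 * np.sum((y - mu) ** 2) / nu2
    )


# ---------------------------------------------------------------------------
# Gaussian full-conditional machinery
# ---------------------------------------------------------------------------

def conditional_moments(P: np.ndarray, b: np.ndarray):
    """Mean and covariance of N with precision P and linear term b.

    The full conditional of a Gaussian block always has the form
    p(u | ...) ∝ exp(-u'Pu/2 + b'u); its moments are (P^{-1} b, P^{-1}).
    """
    P = np.atleast_2d(np.asarray(P, float))
    R = cholesky(P, lower=False)
    mean = cho_solve((R, False), np.asarray(b, float))
    cov = cho_solve((R, False), np.eye(P.shape[0]))
    return mean, cov


def draw_mvn_from_precision(
    P: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Exact draw from N(P^{-1} b, P^{-1}) via one Cholesky of P."""
    R = cholesky(np.atleast_2d(P), lower=False)  # P = R'R
    mean = cho_solve((R, False), b)
    z = rng.standard_normal(mean.shape[0])
    return mean + solve_triangular(R, z, lower=False)


# -- precision/linear-term builders (exact full conditionals) ---------------

def full_conditional_beta(X, resid, nu2, prior: PriorSpec, XtX=None):
    """(P, b) for beta | rest:  P = X'X/nu2 + I/s2b,  b = X'resid/nu2.

    ``resid`` is y minus the structured term psi (the part of mu not
    involving beta).
    """
    if XtX is None:
        XtX = X.T @ X
    p = X.shape[1]
    P = XtX / nu2 + np.eye(p) / prior.beta_prior_variance
    b = X.T @ resid / nu2
    return P, b


def _area_sums(r_flat: np.ndarray, D: int, T: int) -> np.ndarray:
    """sum over t of r_{dt} for each area d (r flat, time-major)."""
    return r_flat.reshape(T, D).sum(axis=0)


def _time_sums(r_flat: np.ndarray, D: int, T: int) -> np.ndarray:
    return r_flat.reshape(T, D).sum(axis=1)


def full_conditional_phi(
    state, y, X, spec, lattice: SpatialLattice, D, T, Q=None
):
    """(P, b) for the spatial block phi | rest.

    st_anova: phi_d enters T observations with coefficient 1 and carries the
    CAR(rho_s, tau2_s) prior.  st_linear: identical likelihood geometry, but
    the prior is CAR(rho_int, tau2_int).
    """
    if spec.family == "st_anova":
        rho, tau2 = state.rho_s, state.tau2_s
        r = y - X @ state.beta - np.repeat(state.delta, D)
        if spec.anova_interaction:
            r = r - state.gamma
    elif spec.family == "st_linear":
        rho, tau2 = state.rho_int, state.tau2_int
        s = np.repeat(trend_scale(T), D)
        r = y - X @ state.beta - s * (state.alpha + np.tile(state.delta, T))
    else:
        raise ValueError(f"no phi block for family {spec.family!r}")
    if Q is None:
        Q = leroux_precision(lattice, rho)
    P = Q / tau2 + (T / state.nu2) * np.eye(D)
    b = _area_sums(r, D, T) / state.nu2
    return P, b


def full_conditional_delta(
    state, y, X, spec, lattice: SpatialLattice, D, T, Q=None
):
    """(P, b) for the second random-effect block delta | rest.

    st_anova: temporal effects delta_t (CAR on the path graph, each hit by D
    observations).  st_linear: area slope effects delta_d (CAR on the areal
    lattice, each hit by the T trend covariates s_t).
    """
    if spec.family == "st_anova":
        rho, tau2 = state.rho_t, state.tau2_t
        r = y - X @ state.beta - np.tile(state.phi, T)
        if spec.anova_interaction:
            r = r - state.gamma
        if Q is None:
            Q = leroux_precision(temporal_path_lattice(T), rho)
        P = Q / tau2 + (D / state.nu2) * np.eye(T)
        b = _time_sums(r, D, T) / state.nu2
        return P, b
    if spec.family == "st_linear":
        rho, tau2 = state.rho_slo, state.tau2_slo
        s = trend_scale(T)
        s_flat = np.repeat(s, D)
        r = y - X @ state.beta - np.tile(state.phi, T) - state.alpha * s_flat
        if Q is None:
            Q = leroux_precision(lattice, rho)
        P = Q / tau2 + (float(np.sum(s**2)) / state.nu2) * np.eye(D)
        b = (r * s_flat).reshape(T, D).sum(axis=0) / state.nu2
        return P, b
    raise ValueError(f"no delta block for family {spec.family!r}")


def full_conditional_gamma(state, y, X, spec, D, T):
    """(diag precision, b) for the iid interaction gamma_dt | rest."""
    if spec.family != "st_anova" or not spec.anova_interaction:
        raise ValueError("gamma exists only for st_anova with interaction on")
    r = y - X @ state.beta - np.tile(state.phi, T) - np.repeat(state.delta, D)
    prec = np.full(D * T, 1.0 / state.tau2_i + 1.0 / state.nu2)
    b = r / state.nu2
    return prec, b


def full_conditional_alpha(state, y, X, spec, prior: PriorSpec, D, T):
    """(precision, b) scalars for the overall trend slope alpha | rest."""
    if spec.family != "st_linear":
        raise ValueError("alpha exists only for st_linear")
    s = trend_scale(T)
    s_flat = np.repeat(s, D)
    r = y - X @ state.beta - np.tile(state.phi, T) - s_flat * np.tile(state.delta, T)
    prec = D * float(np.sum(s**2)) / state.nu2 + 1.0 / prior.beta_prior_variance
    b = float(np.sum(s_flat * r)) / state.nu2
    return prec, b


def full_conditional_ar_slice(state, y, X, lattice: SpatialLattice, D, T, t, Q=None):
    """(P, b) for the st_ar time slice phi_t | phi_{t-1}, phi_{t+1}, y_t.

    The chain is phi_1 ~ N(0, tau2_t Q^{-1}),
    phi_t | phi_{t-1} ~ N(rho_t phi_{t-1}, tau2_t Q^{-1}).  Slice t feels
    its own transition, the transition into t+1 (if any), and the data.
    """
    if Q is None:
        Q = leroux_precision(lattice, state.rho_s)
    rho, tau2 = state.rho_t, state.tau2_t
    r = (y - X @ state.beta).reshape(T, D)
    phi = state.phi.reshape(T, D)
    P = Q / tau2 + np.eye(D) / state.nu2
    b = r[t] / state.nu2
    if t > 0:
        b = b + (rho / tau2) * (Q @ phi[t - 1])
    if t < T - 1:
        P = P + (rho**2 / tau2) * Q
        b = b + (rho / tau2) * (Q @ phi[t + 1])
    return P, b


# ---------------------------------------------------------------------------
# Gibbs updates (draws + identifiability centring)
# ---------------------------------------------------------------------------

def update_beta(state, y, X, spec, D, T, prior, rng, XtX=None) -> np.ndarray:
    """Draw beta from its exact Gaussian full conditional; updates state."""
    resid = y - psi_vector(state, spec, D, T)
    P, b = full_conditional_beta(X, resid, state.nu2, prior, XtX=XtX)
    state.beta = draw_mvn_from_precision(P, b, rng)
    return state.beta


def update_random_effects(
    state, y, X, spec, lattice, D, T, prior, rng, Q_cache=None
) -> None:
    """Draw every random-effect block of the family from its full conditional.

    Blocks are re-centred immediately after the draw: the removed mean goes
    into the intercept (st_anova, st_ar via :func:`update_ar_chain`,
    st_linear intercept field) or into alpha (st_linear slope field), which
    leaves the linear predictor unchanged.
    """
    fam = spec.family
    if fam == "independent_glm":
        return
    Q_cache = Q_cache or {}
    if fam == "st_anova":
        P, b = full_conditional_phi(
            state, y, X, spec, lattice, D, T, Q=Q_cache.get("spatial")
        )
        state.phi = draw_mvn_from_precision(P, b, rng)
        m = state.phi.mean()
        state.phi -= m
        state.beta[0] += m

        P, b = full_conditional_delta(
            state, y, X, spec, lattice, D, T, Q=Q_cache.get("temporal")
        )
        state.delta = draw_mvn_from_precision(P, b, rng)
        m = state.delta.mean()
        state.delta -= m
        state.beta[0] += m

        if spec.anova_interaction:
            prec, b = full_conditional_gamma(state, y, X, spec, D, T)
            state.gamma = b / prec + rng.standard_normal(D * T) / np.sqrt(prec)
            m = state.gamma.mean()
            state.gamma -= m
            state.beta[0] += m
        return
    if fam == "st_linear":
        P, b = full_conditional_phi(
            state, y, X, spec, lattice, D, T, Q=Q_cache.get("intercept")
        )
        state.phi = draw_mvn_from_precision(P, b, rng)
        m = state.phi.mean()
        state.phi -= m
        state.beta[0] += m

        P, b = full_conditional_delta(
            state, y, X, spec, lattice, D, T, Q=Q_cache.get("slope")
        )
        state.delta = draw_mvn_from_precision(P, b, rng)
        m = state.delta.mean()
        state.delta -= m
        state.alpha += m

        prec, lin = full_conditional_alpha(state, y, X, spec, prior, D, T)
        state.alpha = lin / prec + rng.standard_normal() / np.sqrt(prec)
        return
    if fam == "st_ar":
        update_ar_chain(state, y, X, lattice, D, T, rng, Q=Q_cache.get("spatial"))
        return
    raise ValueError(f"unknown family {fam!r}")


def update_ar_chain(state, y, X, lattice, D, T, rng, Q=None) -> np.ndarray:
    """Slice-wise Gibbs update of the st_ar chain phi_1..phi_T.

    Each slice is an exact Gaussian full-conditional draw given its
    neighbours in time and the data; afterwards the field's overall mean is
    transferred to the intercept.
    """
    if Q is None:
        Q = leroux_precision(lattice, state.rho_s)
    for t in range(T):
        P, b = full_conditional_ar_slice(state, y, X, lattice, D, T, t, Q=Q)
        state.phi[t * D : (t + 1) * D] = draw_mvn_from_precision(P, b, rng)
    m = state.phi.mean()
    state.phi -= m
    state.beta[0] += m
    return state.phi


def update_variance(sum_sq, count, prior: PriorSpec, rng) -> float:
    """Inverse-gamma conjugate draw: IG(a + count/2, b + sum_sq/2).

    ``sum_sq`` is the residual sum of squares (for nu2) or the CAR quadratic
    form u'Q(rho)u (for a tau2).  count=0, sum_sq=0 draws from the prior.
    """
    if sum_sq < 0 or count < 0:
        raise ValueError("sum_sq and count must be non-negative")
    shape = prior.ig_shape + 0.5 * count
    scale = prior.ig_scale + 0.5 * sum_sq
    # InverseGamma(shape, scale) = scale / Gamma(shape, 1)
    return float(scale / rng.gamma(shape))


def _quad(Q: np.ndarray, u: np.ndarray) -> float:
    return float(u @ Q @ u)


def _ar_innovations(state, D: int, T: int) -> np.ndarray:
    """(T, D) innovation slices e_1 = phi_1, e_t = phi_t - rho_t phi_{t-1}."""
    phi = state.phi.reshape(T, D)
    e = phi.copy()
    e[1:] -= state.rho_t * phi[:-1]
    return e


def update_variances(state, y, X, spec, lattice, D, T, prior, rng, Q_cache=None):
    """Conjugate inverse-gamma draws for nu2 and every active tau2."""
    Q_cache = Q_cache or {}
    mu = linear_predictor(state, spec, X, D, T)
    state.nu2 = update_variance(float(np.sum((y - mu) ** 2)), D * T, prior, rng)
    fam = spec.family
    if fam == "st_anova":
        Qs = Q_cache.get("spatial")
        if Qs is None:
            Qs = leroux_precision(lattice, state.rho_s)
        state.tau2_s = update_variance(_quad(Qs, state.phi), D, prior, rng)
        Qt = Q_cache.get("temporal")
        if Qt is None:
            Qt = leroux_precision(temporal_path_lattice(T), state.rho_t)
        state.tau2_t = update_variance(_quad(Qt, state.delta), T, prior, rng)
        if spec.anova_interaction:
            state.tau2_i = update_variance(
                float(np.sum(state.gamma**2)), D * T, prior, rng
            )
    elif fam == "st_linear":
        Qi = Q_cache.get("intercept")
        if Qi is None:
            Qi = leroux_precision(lattice, state.rho_int)
        state.tau2_int = update_variance(_quad(Qi, state.phi), D, prior, rng)
        Qs = Q_cache.get("slope")
        if Qs is None:
            Qs = leroux_precision(lattice, state.rho_slo)
        state.tau2_slo = update_variance(_quad(Qs, state.delta), D, prior, rng)
    elif fam == "st_ar":
        Q = Q_cache.get("spatial")
        if Q is None:
            Q = leroux_precision(lattice, state.rho_s)
        e = _ar_innovations(state, D, T)
        ss = float(np.einsum("ti,ij,tj->", e, Q, e))
        state.tau2_t = update_variance(ss, D * T, prior, rng)


def _reflect_unit(x: float) -> float:
    """Reflect a real into (0, 1) (symmetric proposal on the interval)."""
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


def update_rho(U, lattice, tau2, rho_current, prop_sd, rng):
    """Reflected random-walk Metropolis step for a CAR dependence parameter.

    ``U`` is one field (n,) or a stack (k, n) of iid fields sharing the
    structure.  The acceptance ratio uses the proper CAR log-density
    including the log-determinant term; the Uniform(0,1) prior is constant.

    Returns (rho_new, accepted).
    """
    U = np.atleast_2d(U)
    prop = _reflect_unit(rho_current + prop_sd * rng.standard_normal())
    # boundary values have prior probability zero under rho in (0,1)
    if prop <= 0.0 or prop >= 1.0:
        return rho_current, False
    if prop == rho_current:
        return rho_current, True
    cur = car_logdensity_multi(U, CarStructure(lattice, rho_current, tau2))
    new = car_logdensity_multi(U, CarStructure(lattice, prop, tau2))
    if np.log(rng.uniform()) < new - cur:
        return prop, True
    return rho_current, False


def _ar_rho_t_logtarget(phi, Q, rho, tau2, D, T) -> float:
    """Log-density of the st_ar chain as a function of rho_t (up to consts)."""
    ph = phi.reshape(T, D)
    e = ph.copy()
    e[1:] = ph[1:] - rho * ph[:-1]
    ss = float(np.einsum("ti,ij,tj->", e[1:], Q, e[1:]))
    return -0.5 * ss / tau2


def update_rhos(state, spec, lattice, D, T, prop_sds, rng, Q_cache=None):
    """Metropolis updates for every active rho; returns {name: accepted}."""
    accepted: dict[str, bool] = {}
    fam = spec.family
    if fam == "independent_glm":
        return accepted
    if fam == "st_anova":
        state.rho_s, accepted["rho_s"] = update_rho(
            state.phi, lattice, state.tau2_s, state.rho_s, prop_sds["rho_s"], rng
        )
        state.rho_t, accepted["rho_t"] = update_rho(
            state.delta,
            temporal_path_lattice(T),
            state.tau2_t,
            state.rho_t,
            prop_sds["rho_t"],
            rng,
        )
    elif fam == "st_linear":
        state.rho_int, accepted["rho_int"] = update_rho(
            state.phi, lattice, state.tau2_int, state.rho_int,
            prop_sds["rho_int"], rng,
        )
        state.rho_slo, accepted["rho_slo"] = update_rho(
            state.delta, lattice, state.tau2_slo, state.rho_slo,
            prop_sds["rho_slo"], rng,
        )
    elif fam == "st_ar":
        e = _ar_innovations(state, D, T)
        state.rho_s, accepted["rho_s"] = update_rho(
            e, lattice, state.tau2_t, state.rho_s, prop_sds["rho_s"], rng
        )
        # rho_t: Metropolis against the chain's joint density; the
        # log-determinant does not involve rho_t, only the quadratic forms.
        Q = leroux_precision(lattice, state.rho_s)
        prop = _reflect_unit(state.rho_t + prop_sds["rho_t"] * rng.standard_normal())
        ok = 0.0 < prop < 1.0
        if ok:
            cur = _ar_rho_t_logtarget(state.phi, Q, state.rho_t, state.tau2_t, D, T)
            new = _ar_rho_t_logtarget(state.phi, Q, prop, state.tau2_t, D, T)
            if np.log(rng.uniform()) < new - cur:
                state.rho_t, accepted["rho_t"] = prop, True
            else:
                accepted["rho_t"] = False
        else:
            accepted["rho_t"] = False
    if Q_cache is not None:
        _refresh_q_cache(Q_cache, state, spec, lattice, T)
    return accepted


def _refresh_q_cache(Q_cache, state, spec, lattice, T):
    fam = spec.family
    if fam == "st_anova":
        Q_cache["spatial"] = leroux_precision(lattice, state.rho_s)
        Q_cache["temporal"] = leroux_precision(temporal_path_lattice(T), state.rho_t)
    elif fam == "st_linear":
        Q_cache["intercept"] = leroux_precision(lattice, state.rho_int)
        Q_cache["slope"] = leroux_precision(lattice, state.rho_slo)
    elif fam == "st_ar":
        Q_cache["spatial"] = leroux_precision(lattice, state.rho_s)


def initial_state(spec: ModelSpec, y, X, D: int, T: int) -> ParameterState:
    """Deterministic starting point: intercept at the data mean, effects zero.

    Burn-in moves the chain to the posterior; the start only needs valid
    support (variances > 0, rhos in (0,1)).
    """
    p = X.shape[1]
    beta = np.zeros(p)
    beta[0] = float(np.mean(y))
    nu2 = max(float(np.var(y)), 1e-8)
    st = ParameterState(beta=beta, nu2=nu2)
    fam = spec.family
    if fam == "st_anova":
        st.phi = np.zeros(D)
        st.delta = np.zeros(T)
        st.tau2_s = st.tau2_t = 0.1 * nu2
        st.rho_s = st.rho_t = 0.5
        if spec.anova_interaction:
            st.gamma = np.zeros(D * T)
            st.tau2_i = 0.1 * nu2
    elif fam == "st_linear":
        st.phi = np.zeros(D)
        st.delta = np.zeros(D)
        st.alpha = 0.0
        st.tau2_int = st.tau2_slo = 0.1 * nu2
        st.rho_int = st.rho_slo = 0.5
    elif fam == "st_ar":
        st.phi = np.zeros(D * T)
        st.tau2_t = 0.1 * nu2
        st.rho_s = 0.5
        st.rho_t = 0.5
    return st
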