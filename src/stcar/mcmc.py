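"""Gibbs/Metropolis sweep orchestration, burn-in, thinning, draw storage.

The reference protocol is 100,000 post-burn-in sweeps after 20,000 burn-in
sweeps, thinned by 10 (10,000 stored draws); tests and small studies use
scaled-down configurations of the same shape.  One sweep updates, in order:
beta -> all random-effect blocks -> all variances -> all rho parameters.
Metropolis proposal scales adapt toward a 40-50% acceptance rate during
burn-in only and are frozen afterwards, so the post-burn-in chain is a
valid time-homogeneous Markov chain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import models as M
from .lattice import SpatialLattice
from .panel import SpaceTimePanel, build_design, validate_panel

__all__ = ["MCMCConfig", "PosteriorSamples", "run_mcmc", "run_mcmc_xy", "summarize"]

logger = logging.getLogger(__name__)

_VECTOR_BLOCKS = ("phi", "delta", "gamma")


@dataclass(frozen=True)
class MCMCConfig:
    """Sweep counts and reproducibility settings.

    n_burn
        Discarded initial sweeps (adaptation happens here).
    n_keep_iterations
        Post-burn-in sweeps; every ``thin``-th state is stored, giving
        ``floor(n_keep_iterations / thin)`` stored draws.
    seed
        Seed for the single numpy Generator driving the whole run.
    adapt_window
        Burn-in sweeps between Metropolis proposal-scale adjustments.
    """

    n_burn: int = 20000
    n_keep_iterations: int = 100000
    thin: int = 10
    seed: int = 0
    adapt_window: int = 50

    def __post_init__(self):
        if min(self.n_burn, self.n_keep_iterations, self.thin) < 1:
            raise ValueError("n_burn, n_keep_iterations and thin must be >= 1")
        if self.adapt_window < 1:
            raise ValueError("adapt_window must be >= 1")

    @property
    def n_stored(self) -> int:
        return self.n_keep_iterations // self.thin


@dataclass
class PosteriorSamples:
    """Thinned post-burn-in draws plus everything needed to assess the fit."""

    draws: dict[str, np.ndarray]
    mu: np.ndarray                      # (n_stored, D*T) linear predictor draws
    y: np.ndarray
    D: int
    T: int
    spec: M.ModelSpec
    config: MCMCConfig
    beta_names: tuple[str, ...]
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_stored(self) -> int:
        return self.mu.shape[0]

    def parameter_names(self) -> list[str]:
        """Scalar summary parameters in report (Table-1 style) order."""
        names = list(self.beta_names)
        order = (
            "alpha", "tau2_s", "tau2_t", "tau2_i",
            "tau2_int", "tau2_slo", "nu2",
            "rho_s", "rho_t", "rho_int", "rho_slo",
        )
        names += [k for k in order if k in self.draws]
        return names

    def scalar_draws(self, name: str) -> np.ndarray:
        """Draw array for a summary parameter (beta component or scalar)."""
        if name in self.beta_names:
            return self.draws["beta"][:, self.beta_names.index(name)]
        return self.draws[name]


def _scalar_names(spec: M.ModelSpec) -> tuple[str, ...]:
    fam = spec.family
    if fam == "independent_glm":
        return ("nu2",)
    if fam == "st_anova":
        base = ("nu2", "tau2_s", "tau2_t", "rho_s", "rho_t")
        return base + (("tau2_i",) if spec.anova_interaction else ())
    if fam == "st_linear":
        return ("nu2", "alpha", "tau2_int", "tau2_slo", "rho_int", "rho_slo")
    return ("nu2", "tau2_t", "rho_s", "rho_t")  # st_ar


def _vector_names(spec: M.ModelSpec, D: int, T: int) -> dict[str, int]:
    fam = spec.family
    if fam == "independent_glm":
        return {}
    if fam == "st_anova":
        out = {"phi": D, "delta": T}
        if spec.anova_interaction:
            out["gamma"] = D * T
        return out
    if fam == "st_linear":
        return {"phi": D, "delta": D}
    return {"phi": D * T}  # st_ar


def _rho_names(spec: M.ModelSpec) -> tuple[str, ...]:
    fam = spec.family
    if fam == "st_anova" or fam == "st_ar":
        return ("rho_s", "rho_t")
    if fam == "st_linear":
        return ("rho_int", "rho_slo")
    return ()


def run_mcmc(
    panel: SpaceTimePanel,
    lattice: SpatialLattice,
    spec: M.ModelSpec,
    prior: M.PriorSpec | None = None,
    config: MCMCConfig | None = None,
) -> PosteriorSamples:
    """Fit one model family to a validated panel.

    Builds the design matrix from ``spec.covariates`` (intercept first),
    then runs the Gibbs/Metropolis sweep.  Raises ``ValueError`` with the
    validation report if the panel is structurally invalid.
    """
    report = validate_panel(panel, lattice)
    if report:
        raise ValueError("panel failed validation:\n" + "\n".join(report))
    X, y, names = build_design(panel, spec.covariates)
    return run_mcmc_xy(
        X, y, panel.n_areas, panel.n_times, lattice, spec,
        prior=prior, config=config, beta_names=names,
    )


def run_mcmc_xy(
    X: np.ndarray,
    y: np.ndarray,
    D: int,
    T: int,
    lattice: SpatialLattice,
    spec: M.ModelSpec,
    prior: M.PriorSpec | None = None,
    config: MCMCConfig | None = None,
    beta_names: tuple[str, ...] | None = None,
) -> PosteriorSamples:
    """Engine entry point on an already-built design matrix.

    Rows must follow the canonical time-major order (offset t*D + d).
    Fully reproducible: the same seed and config give bitwise-identical
    stored draws.
    """
    prior = prior or M.PriorSpec()
    config = config or MCMCConfig()
    if lattice.n_areas != D:
        raise ValueError(f"lattice has {lattice.n_areas} areas, panel has {D}")
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if n != D * T or y.shape != (n,):
        raise ValueError("design/response shapes inconsistent with D*T")
    if beta_names is None:
        beta_names = ("Intercept",) + tuple(f"x{j}" for j in range(1, p))

    rng = np.random.default_rng(config.seed)
    state = M.initial_state(spec, y, X, D, T)
    XtX = X.T @ X

    Q_cache: dict[str, np.ndarray] = {}
    M._refresh_q_cache(Q_cache, state, spec, lattice, T)

    rho_names = _rho_names(spec)
    prop_sds = {r: 0.05 for r in rho_names}
    acc_window = {r: [0, 0] for r in rho_names}  # [accepted, proposed]
    acc_total = {r: [0, 0] for r in rho_names}

    S = config.n_stored
    scal = _scalar_names(spec)
    vecs = _vector_names(spec, D, T)
    draws: dict[str, np.ndarray] = {"beta": np.empty((S, p))}
    for k in scal:
        draws[k] = np.empty(S)
    for k, ln in vecs.items():
        draws[k] = np.empty((S, ln))
    mu_draws = np.empty((S, n))

    total = config.n_burn + config.n_keep_iterations
    log_every = max(1, total // 10)
    stored = 0
    for sweep in range(total):
        try:
            M.update_beta(state, y, X, spec, D, T, prior, rng, XtX=XtX)
            M.update_random_effects(
                state, y, X, spec, lattice, D, T, prior, rng, Q_cache=Q_cache
            )
            M.update_variances(
                state, y, X, spec, lattice, D, T, prior, rng, Q_cache=Q_cache
            )
            accepted = M.update_rhos(
                state, spec, lattice, D, T, prop_sds, rng, Q_cache=Q_cache
            )
        except np.linalg.LinAlgError as exc:
            raise RuntimeError(f"numerical failure at sweep {sweep}: {exc}") from exc

        in_burn = sweep < config.n_burn
        for r, ok in accepted.items():
            tracker = acc_window if in_burn else acc_total
            tracker[r][0] += int(ok)
            tracker[r][1] += 1
        if in_burn and (sweep + 1) % config.adapt_window == 0:
            for r in rho_names:
                a, m = acc_window[r]
                if m:
                    rate = a / m
                    if rate > 0.5:
                        prop_sds[r] = min(prop_sds[r] * 1.2, 1.0)
                    elif rate < 0.4:
                        prop_sds[r] = max(prop_sds[r] * 0.8, 1e-3)
                acc_window[r] = [0, 0]
        if not in_burn and (sweep - config.n_burn + 1) % config.thin == 0:
            if stored < S:
                draws["beta"][stored] = state.beta
                for k in scal:
                    draws[k][stored] = getattr(state, k)
                for k in vecs:
                    draws[k][stored] = getattr(state, k)
                mu_draws[stored] = M.linear_predictor(state, spec, X, D, T)
                stored += 1
        if (sweep + 1) % log_every == 0:
            logger.debug("sweep %d/%d (family=%s)", sweep + 1, total, spec.family)

    acceptance = {
        r: (acc_total[r][0] / acc_total[r][1] if acc_total[r][1] else float("nan"))
        for r in rho_names
    }
    if acceptance:
        logger.info(
            "family=%s post-burn-in acceptance rates: %s", spec.family,
            {k: round(v, 3) for k, v in acceptance.items()},
        )
    return PosteriorSamples(
        draws=draws,
        mu=mu_draws,
        y=y,
        D=D,
        T=T,
        spec=spec,
        config=config,
        beta_names=tuple(beta_names),
        acceptance=acceptance,
    )


def summarize(
    samples: PosteriorSamples, probs: tuple[float, float] = (0.025, 0.975)
) -> pd.DataFrame:
    """Posterior mean and equal-tailed credible interval per parameter.

    One row per regression coefficient and model scalar, in report order:
    columns ``parameter, estimate, lower, upper, excludes_zero``.  Quantiles
    use linear interpolation between order statistics.  A coefficient is
    read as influential iff its interval excludes zero.
    """
    if samples.n_stored < 2:
        raise ValueError("need at least 2 stored draws to summarize")
    lo, hi = probs
    if not 0 <= lo < hi <= 1:
        raise ValueError(f"invalid probability pair {probs}")
    rows = []
    for name in samples.parameter_names():
        d = samples.scalar_draws(name)
        ql, qh = np.quantile(d, [lo, hi])
        rows.append(
            {
                "parameter": name,
                "estimate": float(np.mean(d)),
                "lower": float(ql),
                "upper": float(qh),
                "excludes_zero": bool(ql > 0 or qh < 0),
            }
        )
    return pd.DataFrame(rows)
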