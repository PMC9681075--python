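"""Scikit-learn style estimator facade over the MCMC engine.

:class:`SpatioTemporalCAR` is the primary user-facing API: a
``BaseEstimator``/``RegressorMixin`` whose ``fit`` runs the full Bayesian
Gibbs/Metropolis analysis and whose fitted attributes expose the posterior
summaries, draws and comparison criteria.  It composes with sklearn
pipelines and ``clone``/``get_params`` based model selection; the
lower-level functions (``run_mcmc``, the criteria) remain available for
scripted use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import assessment
from .lattice import SpatialLattice
from .mcmc import MCMCConfig, run_mcmc_xy, summarize
from .models import FAMILIES, ModelSpec, PriorSpec
from .panel import SpaceTimePanel, build_design, validate_panel

__all__ = ["SpatioTemporalCAR", "fit_panel"]


class SpatioTemporalCAR(RegressorMixin, BaseEstimator):
    """Bayesian spatio-temporal CAR regression on an areal panel.

    The observation model is Gaussian, ``y = X beta + psi + eps``, with the
    structured space-time term ``psi`` chosen by ``family`` (see
    :mod:`stcar.models`) and Leroux CAR priors on the structured blocks.

    Parameters
    ----------
    family
        One of ``independent_glm``, ``st_linear``, ``st_anova``, ``st_ar``.
    lattice
        :class:`SpatialLattice` over the areas; its size fixes D.
    n_times
        Number of time points T; ``fit`` expects ``len(y) == D * T`` with
        rows in canonical time-major order (offset ``t*D + d``).
    anova_interaction
        Enable the iid space-time interaction block (st_anova only).
    beta_prior_variance, ig_shape, ig_scale
        Prior hyperparameters (see :class:`stcar.models.PriorSpec`).
    n_burn, n_keep, thin
        MCMC protocol; the reference protocol is 20000/100000/10, scaled
        down for small studies.
    random_state
        Seed for the run's single random Generator.

    Attributes
    ----------
    samples_ : PosteriorSamples
        Thinned post-burn-in draws of every parameter and effect block.
    summary_ : pandas.DataFrame
        Posterior means and 95% equal-tailed credible intervals.
    criteria_ : CriteriaBundle
        DIC/WAIC/LMPL/loglik + rmse/mae/crps/cvg of the in-sample fit.
    coef_, intercept_ : posterior-mean regression coefficients.
    """

    def __init__(
        self,
        family: str = "st_anova",
        lattice: SpatialLattice | None = None,
        n_times: int | None = None,
        anova_interaction: bool = False,
        beta_prior_variance: float = 100000.0,
        ig_shape: float = 1.0,
        ig_scale: float = 0.01,
        n_burn: int = 20000,
        n_keep: int = 100000,
        thin: int = 10,
        random_state: int = 0,
    ):
        self.family = family
        self.lattice = lattice
        self.n_times = n_times
        self.anova_interaction = anova_interaction
        self.beta_prior_variance = beta_prior_variance
        self.ig_shape = ig_shape
        self.ig_scale = ig_scale
        self.n_burn = n_burn
        self.n_keep = n_keep
        self.thin = thin
        self.random_state = random_state

    # -- sklearn plumbing ---------------------------------------------------

    def _make_specs(self, feature_names):
        spec = ModelSpec(
            family=self.family,
            anova_interaction=self.anova_interaction,
            covariates=tuple(feature_names),
        )
        prior = PriorSpec(
            beta_prior_variance=self.beta_prior_variance,
            ig_shape=self.ig_shape,
            ig_scale=self.ig_scale,
        )
        config = MCMCConfig(
            n_burn=self.n_burn,
            n_keep_iterations=self.n_keep,
            thin=self.thin,
            seed=self.random_state,
        )
        return spec, prior, config

    def fit(self, X, y, feature_names=None):
        """Run the MCMC analysis.

        ``X`` holds the covariate columns (no intercept column — one is
        added internally); rows follow the canonical time-major panel
        order.  ``feature_names`` labels the columns in summaries.
        """
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; one of {FAMILIES}")
        if self.lattice is None:
            raise ValueError("a SpatialLattice is required (lattice=...)")
        X = np.asarray(X, float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y, float).ravel()
        n = y.shape[0]
        D = self.lattice.n_areas
        T = self.n_times if self.n_times is not None else n // D
        if D * T != n or X.shape[0] != n:
            raise ValueError(
                f"n = {n} observations incompatible with D = {D}, T = {T}"
            )
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(X.shape[1])]
        spec, prior, config = self._make_specs(feature_names)
        Xd = np.column_stack([np.ones(n), X])
        self.samples_ = run_mcmc_xy(
            Xd, y, D, T, self.lattice, spec,
            prior=prior, config=config,
            beta_names=("Intercept", *feature_names),
        )
        self.summary_ = summarize(self.samples_)
        self.criteria_ = assessment.criteria_bundle(self.samples_)
        beta_mean = self.samples_.draws["beta"].mean(axis=0)
        self.intercept_ = float(beta_mean[0])
        self.coef_ = beta_mean[1:]
        self.n_features_in_ = X.shape[1]
        self.fitted_values_ = self.samples_.mu.mean(axis=0)
        return self

    def predict(self, X):
        """Posterior-mean prediction.

        For the training design (matching shape) this is the in-sample
        posterior-mean fitted value including the structured term psi; for
        new rows it is the fixed-effects part ``intercept_ + X @ coef_``
        (structured effects are panel-specific).
        """
        check_is_fitted(self, "samples_")
        X = np.asarray(X, float)
        fixed = self.intercept_ + X @ self.coef_
        if X.shape[0] == self.fitted_values_.shape[0]:
            return self.fitted_values_.copy()
        return fixed

    # -- convenience --------------------------------------------------------

    def fit_panel(self, panel: SpaceTimePanel, covariates=None):
        """Fit directly from a validated :class:`SpaceTimePanel`."""
        if self.lattice is None:
            raise ValueError("a SpatialLattice is required (lattice=...)")
        report = validate_panel(panel, self.lattice)
        if report:
            raise ValueError("panel failed validation:\n" + "\n".join(report))
        X, y, names = build_design(panel, covariates)
        self.n_times = panel.n_times
        return self.fit(X[:, 1:], y, feature_names=list(names[1:]))


def fit_panel(
    panel: SpaceTimePanel,
    lattice: SpatialLattice,
    family: str = "st_anova",
    **kwargs,
) -> SpatioTemporalCAR:
    """Thin functional wrapper: fit one family to a panel, return the estimator."""
    est = SpatioTemporalCAR(family=family, lattice=lattice, **kwargs)
    return est.fit_panel(panel)
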