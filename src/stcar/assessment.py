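"""Model choice criteria (DIC, WAIC, LMPL) and validation statistics.

Conventions, stated once:

* DIC = Dbar + p_D with p_D = Dbar - D(theta_hat); the plug-in deviance
  D(theta_hat) evaluates the likelihood at the posterior means of the
  linear predictor and of nu2 (p_D is parameterisation-dependent, so the
  plug-in point matters and is fixed here).
* WAIC = -2 (lppd - p_W); lppd sums log of the posterior-mean pointwise
  density, p_W sums the pointwise sample variances (denominator S-1) of the
  log-densities.
* LMPL = sum_i log CPO_i with the harmonic-mean CPO estimator
  CPO_i = [ mean_s 1/f(y_i | theta_s) ]^{-1}.
* The reported ``loglikelihood`` is the plug-in log-likelihood at the same
  posterior-mean point as DIC's D(theta_hat).
* Validation statistics are in-sample on the full panel.  The per-point
  predictive is Normal(m_i, s_i) where m_i and s_i^2 are the mean and
  variance of the per-draw predictive centers mu_i,s with the posterior
  mean of nu2 added in quadrature; CRPS uses the closed Gaussian form and
  cvg the central 95% interval of that same Normal.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import logsumexp, ndtri
from scipy.stats import norm

from .mcmc import PosteriorSamples

__all__ = [
    "CriteriaBundle",
    "pointwise_logdensity",
    "dic",
    "waic",
    "lmpl",
    "gaussian_crps",
    "validation_stats",
    "criteria_bundle",
    "aggregate_residuals_spatial",
    "aggregate_fitted_temporal",
    "compare_models",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: criteria where smaller is better; the rest are larger-better except cvg
_MINIMIZE = ("dic", "waic", "rmse", "mae", "crps")
_MAXIMIZE = ("lmpl", "loglikelihood")


@dataclass(frozen=True)
class CriteriaBundle:
    """One comparison-table row: choice criteria + validation statistics."""

    dic: float
    waic: float
    lmpl: float
    loglikelihood: float
    rmse: float
    mae: float
    crps: float
    cvg: float  # coverage of the 95% predictive interval, in percent

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def pointwise_logdensity(samples: PosteriorSamples) -> np.ndarray:
    """(S, n) matrix of log f(y_i | theta_s) = log N(y_i | mu_is, nu2_s)."""
    mu = samples.mu
    nu2 = samples.draws["nu2"][:, None]
    return -0.5 * (_LOG_2PI + np.log(nu2)) - 0.5 * (samples.y[None, :] - mu) ** 2 / nu2


def _plugin_loglik(samples: PosteriorSamples) -> float:
    mu_hat = samples.mu.mean(axis=0)
    nu2_hat = float(samples.draws["nu2"].mean())
    n = samples.y.size
    return float(
        -0.5 * n * (_LOG_2PI + np.log(nu2_hat))
        - 0.5 * np.sum((samples.y - mu_hat) ** 2) / nu2_hat
    )


def dic(samples: PosteriorSamples, logdens: np.ndarray | None = None) -> float:
    """Deviance information criterion Dbar + p_D (lower is better)."""
    if samples.n_stored < 2:
        raise ValueError("DIC needs at least 2 stored draws")
    if logdens is None:
        logdens = pointwise_logdensity(samples)
    dev = -2.0 * logdens.sum(axis=1)
    dbar = float(dev.mean())
    dhat = -2.0 * _plugin_loglik(samples)
    return dbar + (dbar - dhat)


def waic(samples: PosteriorSamples, logdens: np.ndarray | None = None) -> float:
    """Watanabe-Akaike information criterion -2(lppd - p_W) (lower is better)."""
    if samples.n_stored < 2:
        raise ValueError("WAIC needs at least 2 stored draws")
    if logdens is None:
        logdens = pointwise_logdensity(samples)
    S = logdens.shape[0]
    lppd = float(np.sum(logsumexp(logdens, axis=0) - np.log(S)))
    p_w = float(np.sum(np.var(logdens, axis=0, ddof=1)))
    return -2.0 * (lppd - p_w)


def lmpl(samples: PosteriorSamples, logdens: np.ndarray | None = None) -> float:
    """Log marginal predictive likelihood, sum of log CPO (higher is better).

    CPO_i is the harmonic mean of the per-draw densities; densities are
    floored at the smallest positive normal float as a numeric guard (an
    observation hitting the floor would signal severe misfit).
    """
    if logdens is None:
        logdens = pointwise_logdensity(samples)
    S = logdens.shape[0]
    tiny_log = np.log(np.finfo(float).tiny)
    logdens = np.maximum(logdens, tiny_log)
    # log CPO_i = -log mean_s exp(-logdens_si)
    log_cpo = -(logsumexp(-logdens, axis=0) - np.log(S))
    return float(np.sum(log_cpo))


def gaussian_crps(y, mu, sigma):
    """Closed-form CRPS of a Normal(mu, sigma^2) forecast at observation y.

    crps = sigma * [ z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi) ],
    z = (y - mu)/sigma.  Lower is better; elementwise on arrays.
    """
    y, mu, sigma = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(mu, float), np.asarray(sigma, float)
    )
    z = (y - mu) / sigma
    out = sigma * (
        z * (2.0 * norm.cdf(z) - 1.0) + 2.0 * norm.pdf(z) - 1.0 / np.sqrt(np.pi)
    )
    return float(out) if out.ndim == 0 else out


def _predictive_moments(samples: PosteriorSamples):
    m = samples.mu.mean(axis=0)
    nu2_hat = float(samples.draws["nu2"].mean())
    var_mu = samples.mu.var(axis=0, ddof=1) if samples.n_stored > 1 else 0.0
    s = np.sqrt(var_mu + nu2_hat)
    return m, s


def validation_stats(samples: PosteriorSamples, level: float = 0.95):
    """(rmse, mae, crps, cvg) of the in-sample fit.

    Residuals are against the posterior-mean fitted values; cvg is the
    percentage of observations inside the central ``level`` predictive
    interval (0-100 scale).
    """
    m, s = _predictive_moments(samples)
    e = samples.y - m
    rmse = float(np.sqrt(np.mean(e**2)))
    mae = float(np.mean(np.abs(e)))
    crps = float(np.mean(gaussian_crps(samples.y, m, s)))
    z = ndtri(0.5 + level / 2.0)
    inside = np.abs(e) <= z * s
    cvg = float(100.0 * np.mean(inside))
    return rmse, mae, crps, cvg


def criteria_bundle(samples: PosteriorSamples) -> CriteriaBundle:
    """Assemble the full comparison-table row for one fitted model."""
    logdens = pointwise_logdensity(samples)
    rmse, mae, crps, cvg = validation_stats(samples)
    return CriteriaBundle(
        dic=dic(samples, logdens),
        waic=waic(samples, logdens),
        lmpl=lmpl(samples, logdens),
        loglikelihood=_plugin_loglik(samples),
        rmse=rmse,
        mae=mae,
        crps=crps,
        cvg=cvg,
    )


def aggregate_residuals_spatial(
    samples: PosteriorSamples, area_labels=None
) -> pd.DataFrame:
    """Per-area mean and SD (over years) of the posterior-mean residuals.

    The spatial aggregation behind the residual-map diagnostic: a flat
    spatial profile means no unexplained spatial pattern remains.
    """
    D, T = samples.D, samples.T
    e = (samples.y - samples.mu.mean(axis=0)).reshape(T, D)
    if area_labels is None:
        area_labels = [str(d) for d in range(D)]
    return pd.DataFrame(
        {
            "area": list(area_labels),
            "residual_mean": e.mean(axis=0),
            "residual_sd": e.std(axis=0, ddof=1) if T > 1 else np.zeros(D),
        }
    )


def aggregate_fitted_temporal(
    samples: PosteriorSamples, level: float = 0.95, time_labels=None
) -> pd.DataFrame:
    """Per-year observed mean, fitted mean, and credible band.

    The band is the equal-tailed interval of the posterior draws of the
    area-averaged fitted value — the time-series fit diagnostic.
    """
    D, T = samples.D, samples.T
    obs = samples.y.reshape(T, D).mean(axis=1)
    # (S, T): area-average of each stored mu draw
    mu_t = samples.mu.reshape(samples.n_stored, T, D).mean(axis=2)
    fitted = mu_t.mean(axis=0)
    lo, hi = (1 - level) / 2.0, 1 - (1 - level) / 2.0
    lower = np.quantile(mu_t, lo, axis=0)
    upper = np.quantile(mu_t, hi, axis=0)
    if time_labels is None:
        time_labels = [str(t + 1) for t in range(T)]
    return pd.DataFrame(
        {
            "year": list(time_labels),
            "observed_mean": obs,
            "fitted_mean": fitted,
            "lower": lower,
            "upper": upper,
        }
    )


def compare_models(fits: dict[str, PosteriorSamples]) -> pd.DataFrame:
    """Comparison table: one row per fitted model, all eight criteria.

    All fits must be on identical data.  A ``best_<criterion>`` flag column
    marks the winner per criterion: minimum for dic/waic/rmse/mae/crps,
    maximum for lmpl/loglikelihood, closest to the nominal 95 for cvg.
    """
    if not fits:
        raise ValueError("need at least one fit to compare")
    items = list(fits.items())
    y0 = items[0][1].y
    for name, s in items[1:]:
        if s.y.shape != y0.shape or not np.allclose(s.y, y0):
            raise ValueError(f"fit {name!r} is not on the same data")
    rows = {name: criteria_bundle(s).as_dict() for name, s in items}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "model"
    df = df.reset_index()
    for c in _MINIMIZE:
        df[f"best_{c}"] = df[c] == df[c].min()
    for c in _MAXIMIZE:
        df[f"best_{c}"] = df[c] == df[c].max()
    df["best_cvg"] = (df["cvg"] - 95.0).abs() == (df["cvg"] - 95.0).abs().min()
    return df
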