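"""Binomial-logit mixed model with a random site intercept.

Repeated surveys of the same site are correlated: a site that suits the
target species tends to host it in every year. Ignoring that correlation
understates the uncertainty of a pairwise association. The model here is,
for surveys j of site i,

    y_ij ~ Bernoulli(p_ij),  logit(p_ij) = beta0 + beta1 x_ij + u_i,
    u_i ~ N(0, sigma^2) independent across sites,

with y the target's presence and x the predictor's. The marginal
likelihood integrates u_i out site by site; the integral is approximated
by Laplace's method (a one-dimensional mode-and-curvature approximation
per site, the same approximation lme4's default uses), and the
approximated likelihood is maximised by quasi-Newton over
(beta0, beta1, log sigma). An adaptive Gauss-Hermite evaluation of the
same likelihood is provided as an independent check of the Laplace
approximation.

The fixed-effect covariance comes from the inverse of a finite-difference
Hessian of the negative marginal log-likelihood at the optimum. The
variance parameter lives on the log scale with a boundary at
``exp(-10)``; when the best mixed fit does not improve on the sigma = 0
likelihood, the fit collapses to the plain logistic solution (the two
models coincide at the boundary, e.g. when there is no within-site
replication to identify sigma).

``z0``/``z1`` in the returned fit are the conditional (site effect = 0)
linear predictors beta0 and beta0 + beta1.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize

from .contingency import DirectedPair
from .estimation import PairModelFit, SurveyTable, _pair_arrays, _saturated_fit

__all__ = ["fit_pair_glmm", "marginal_loglik", "GlmmData"]

_LOG_SIGMA_FLOOR = -10.0
_LOG_SIGMA_CEIL = 5.0


class GlmmData:
    """Per-pair data grouped by site for the mixed-model likelihood."""

    def __init__(self, y: np.ndarray, x: np.ndarray, site_codes: np.ndarray):
        order = np.argsort(site_codes, kind="stable")
        self.y = np.asarray(y, dtype=np.float64)[order]
        self.x = np.asarray(x, dtype=np.float64)[order]
        codes = np.asarray(site_codes)[order]
        _, self.site = np.unique(codes, return_inverse=True)
        self.n_sites = int(self.site.max()) + 1
        self.n_obs = len(self.y)

    @classmethod
    def from_survey_table(cls, data: SurveyTable, pair: DirectedPair) -> "GlmmData":
        y, x = _pair_arrays(data, pair)
        codes = data.sites.astype("category").cat.codes.to_numpy()
        return cls(y, x, codes)


def _site_mode(beta0: float, beta1: float, sigma2: float, d: GlmmData,
               u0: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Newton solve for the per-site mode of the joint log-density.

    Returns the modes u_hat (one per site) and the negative curvature
    -f''(u_hat) there. The objective per site is concave, so undamped
    Newton from 0 converges quickly; a step cap guards early iterations.
    """
    u = np.zeros(d.n_sites) if u0 is None else u0.copy()
    for _ in range(100):
        eta = beta0 + beta1 * d.x + u[d.site]
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = np.bincount(d.site, weights=d.y - p, minlength=d.n_sites) - u / sigma2
        curv = np.bincount(d.site, weights=p * (1.0 - p), minlength=d.n_sites) + 1.0 / sigma2
        step = grad / curv
        np.clip(step, -5.0, 5.0, out=step)
        u += step
        if np.max(np.abs(step)) < 1e-11:
            break
    eta = beta0 + beta1 * d.x + u[d.site]
    p = 1.0 / (1.0 + np.exp(-eta))
    curv = np.bincount(d.site, weights=p * (1.0 - p), minlength=d.n_sites) + 1.0 / sigma2
    return u, curv


def _joint_logdens(beta0: float, beta1: float, sigma2: float, d: GlmmData,
                   u: np.ndarray) -> np.ndarray:
    """Per-site joint log-density log f(y_i, u_i) at site effects ``u``."""
    eta = beta0 + beta1 * d.x + u[d.site]
    ll_obs = d.y * eta - np.logaddexp(0.0, eta)
    per_site = np.bincount(d.site, weights=ll_obs, minlength=d.n_sites)
    per_site -= 0.5 * u**2 / sigma2 + 0.5 * math.log(2.0 * math.pi * sigma2)
    return per_site


def marginal_loglik(
    params: np.ndarray | tuple[float, float, float],
    d: GlmmData,
    *,
    method: str = "laplace",
    n_nodes: int = 21,
) -> float:
    """Marginal log-likelihood at (beta0, beta1, log sigma).

    ``method="laplace"`` is the approximation used for fitting;
    ``method="agq"`` evaluates the same site integrals by adaptive
    Gauss-Hermite quadrature centred and scaled at the Laplace mode,
    serving as an independent, more accurate oracle.
    """
    beta0, beta1, log_sigma = (float(v) for v in params)
    sigma2 = math.exp(2.0 * log_sigma)
    u_hat, curv = _site_mode(beta0, beta1, sigma2, d)
    if method == "laplace":
        f_hat = _joint_logdens(beta0, beta1, sigma2, d, u_hat)
        return float(np.sum(f_hat + 0.5 * np.log(2.0 * math.pi / curv)))
    if method != "agq":
        raise ValueError(f"unknown method {method!r}")
    nodes, weights = hermgauss(n_nodes)
    scale = 1.0 / np.sqrt(curv)  # per-site
    # integral = sqrt(2) s_i * sum_k w_k exp(t_k^2) exp(f(u_hat + sqrt2 s_i t_k))
    vals = np.empty((n_nodes, d.n_sites))
    for k, t in enumerate(nodes):
        u = u_hat + math.sqrt(2.0) * scale * t
        vals[k] = _joint_logdens(beta0, beta1, sigma2, d, u) + t * t
    m = vals.max(axis=0)
    integ = np.log(np.sum(weights[:, None] * np.exp(vals - m), axis=0)) + m
    return float(np.sum(integ + 0.5 * math.log(2.0) + np.log(scale)))


def _fd_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    k = len(x)
    h = np.eye(k) * step
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            fpp = fun(x + h[i] + h[j])
            fpm = fun(x + h[i] - h[j])
            fmp = fun(x - h[i] + h[j])
            fmm = fun(x - h[i] - h[j])
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step * step)
    return hess


def fit_pair_glmm(
    data: SurveyTable,
    pair: DirectedPair,
    *,
    tol: float = 1e-8,
    hessian_step: float = 1e-4,
) -> PairModelFit:
    """Fit the random-site-intercept logistic model for one pair.

    Maximises the Laplace-approximated marginal likelihood over
    (beta0, beta1, log sigma) by L-BFGS-B starting from the plain
    logistic solution. If no positive sigma improves on the sigma = 0
    (plain logistic) likelihood — e.g. with a single survey per site,
    where sigma is unidentified — the fit collapses to the logistic one
    with ``sigma_site = 0``. Empty-cell / separation pairs are returned
    as boundary logistic fits (the mixed model's fixed effects diverge
    the same way and the odds ratio is 0 or infinite regardless).
    """
    d = GlmmData.from_survey_table(data, pair)
    if d.n_sites < 2:
        raise ValueError("the mixed model needs at least two sites")
    n1 = int(d.x.sum())
    n0 = d.n_obs - n1
    k1 = int(d.y[d.x == 1].sum())
    k0 = int(d.y.sum()) - k1
    base = _saturated_fit(n0, k0, n1, k1, d.n_obs)
    if base.boundary:
        return base
    if d.n_obs == d.n_sites:
        # one survey per site: sigma is structurally unidentified (the
        # marginal likelihood is constant along a (beta, sigma) ridge),
        # so the model collapses to the plain logistic fit.
        return base

    def nll(theta: np.ndarray) -> float:
        return -marginal_loglik(theta, d, method="laplace")

    x0 = np.array(
        [
            float(np.clip(base.z0, -5.0, 5.0)),
            float(np.clip(base.z1 - base.z0, -8.0, 8.0)),
            math.log(0.5),
        ]
    )
    res = minimize(
        nll,
        x0,
        method="L-BFGS-B",
        bounds=[(-20.0, 20.0), (-20.0, 20.0), (_LOG_SIGMA_FLOOR, _LOG_SIGMA_CEIL)],
        options={"ftol": tol * 1e-2, "gtol": 1e-6, "maxiter": 500},
    )
    ll_mixed = -float(res.fun)
    # sigma = 0 reference: the exact logistic likelihood. If the mixed fit
    # cannot beat it, sigma is at (or effectively at) the boundary.
    if (not math.isfinite(ll_mixed)) or ll_mixed <= base.loglik + 1e-6:
        collapsed = _saturated_fit(n0, k0, n1, k1, d.n_obs)
        collapsed.converged = True
        return collapsed

    beta0, beta1, log_sigma = res.x
    hess = _fd_hessian(nll, res.x, step=hessian_step)
    at_floor = log_sigma <= _LOG_SIGMA_FLOOR + 0.5
    try:
        if at_floor:
            cov_beta = np.linalg.inv(hess[:2, :2])
        else:
            cov_beta = np.linalg.inv(hess)[:2, :2]
        ok_cov = bool(np.all(np.isfinite(cov_beta)) and cov_beta[0, 0] > 0 and cov_beta[1, 1] > 0)
    except np.linalg.LinAlgError:
        cov_beta = np.full((2, 2), np.nan)
        ok_cov = False
    return PairModelFit(
        z0=float(beta0),
        z1=float(beta0 + beta1),
        b=n1 / d.n_obs,
        coef_cov=cov_beta,
        sigma_site=float(math.exp(log_sigma)) if not at_floor else 0.0,
        converged=bool(res.success and ok_cov),
        boundary=at_floor,
        n_obs=d.n_obs,
        loglik=ll_mixed,
    )
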