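"""Model-based estimation of directed odds ratios with standard errors.

Every directed association is estimated from a per-pair regression of the
target species' presence on the predictor species' presence (a single
binary covariate):

* ``raw`` / ``logistic`` — ordinary logistic regression, appropriate when
  surveys are independent. With one binary covariate the model is
  saturated, so the maximum-likelihood fit is available in closed form
  (fitted probabilities equal the observed cell proportions and the
  Fisher information is the standard 2x2 form); ``raw`` computes all
  pairs at once from vectorised contingency counts, ``logistic`` goes
  pair by pair through an explicit :class:`PairModelFit`. The two agree
  to machine precision and both equal the closed-form contingency odds
  ratio exactly.
* ``glmm`` — a binomial-logit mixed model with a random site intercept
  (see :mod:`pairodds.mixed`), for repeated surveys of the same sites,
  where within-site correlation inflates the uncertainty of the plain
  logistic fit.

From a fit with linear predictors ``z0`` (predictor absent) and ``z1``
(predictor present) and predictor prevalence ``b``, the directed odds
ratio is

    OR = exp(z1 - g(pbar)),   pbar = (1-b) g^-1(z0) + b g^-1(z1)

where ``g`` is the logit: the conditional odds of the target given the
predictor's presence over the target's marginal odds reconstructed from
the fit. The standard error of log OR comes from the delta method, and
Wald confidence intervals and p-values from the normal approximation on
the log scale. Zero and infinite odds ratios (empty cells / separation)
carry no standard error, interval or p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr, ndtri

from .contingency import DirectedPair, PairContingency

__all__ = [
    "SurveyTable",
    "PairModelFit",
    "PairEstimate",
    "DegenerateDataError",
    "fit_pair_logistic",
    "fit_pair_glmm",
    "or_from_fit",
    "estimate_all_pairs",
    "estimates_to_frame",
]

Estimator = Literal["raw", "logistic", "glmm"]


class DegenerateDataError(ValueError):
    """A species needed by the model is constant across the surveys."""


# ---------------------------------------------------------------------------
# survey container


class SurveyTable:
    """Binary survey x species presence matrix with a site label per survey.

    Parameters
    ----------
    presence : DataFrame
        One row per survey, one 0/1 column per species. Column names are
        the species identifiers and must be unique and non-empty.
    sites : Series or sequence, optional
        Site identifier for each survey (aligned with ``presence`` rows).
        If omitted, every survey is its own site (independent surveys).
    """

    def __init__(self, presence: pd.DataFrame, sites: Sequence | pd.Series | None = None):
        presence = pd.DataFrame(presence)
        values = presence.to_numpy()
        if presence.shape[0] == 0:
            raise ValueError("survey table must have at least one survey")
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"presence entries must be 0/1; found {values[r, c]!r} at "
                f"survey {presence.index[r]!r}, species {presence.columns[c]!r}"
            )
        names = [str(s) for s in presence.columns]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        if any(n == "" for n in names):
            raise ValueError("species names must be non-empty")
        if presence.index.duplicated().any():
            raise ValueError("survey identifiers must be unique")
        self.presence = presence.astype(np.int8)
        self.presence.columns = names
        if sites is None:
            sites = pd.Series(np.arange(len(presence)), index=presence.index)
        else:
            sites = pd.Series(np.asarray(sites), index=presence.index)
        if sites.isna().any():
            raise ValueError("every survey must map to a site")
        self.sites = sites

    # -- basic accessors ---------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_surveys(self) -> int:
        return len(self.presence)

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    @property
    def n_sites(self) -> int:
        return self.sites.nunique()

    def prevalence(self) -> pd.Series:
        """Proportion of surveys in which each species is present."""
        return self.presence.mean(axis=0)

    def pair_table(self, species_a: str, species_b: str) -> PairContingency:
        """2x2 presence table for an ordered species pair (A, B)."""
        a = self.presence[species_a].to_numpy()
        b = self.presence[species_b].to_numpy()
        c = int(np.sum(a & b))
        return PairContingency(
            c=c,
            d=int(a.sum()) - c,
            e=int(b.sum()) - c,
            f=self.n_surveys - int(a.sum()) - int(b.sum()) + c,
        )

    def select_species(self, names: Sequence[str]) -> "SurveyTable":
        return SurveyTable(self.presence[list(names)], self.sites)

    def select_surveys(self, mask) -> "SurveyTable":
        mask = np.asarray(mask, dtype=bool)
        return SurveyTable(self.presence.loc[mask], self.sites.loc[mask])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SurveyTable({self.n_surveys} surveys, {self.n_species} species, "
            f"{self.n_sites} sites)"
        )


# ---------------------------------------------------------------------------
# fits and estimates


@dataclass
class PairModelFit:
    """Fitted per-pair model on the logit scale.

    ``z0``/``z1`` are the linear predictors for the target's presence with
    the predictor absent/present (for the mixed model, evaluated at a site
    effect of zero); ``b`` is the proportion of surveys with the predictor
    present; ``coef_cov`` is the covariance of (intercept, slope);
    ``sigma_site`` is the random-intercept standard deviation (0 for the
    plain logistic fit). Separation / empty-cell fits have infinite ``z``
    components and ``converged=False`` with ``boundary=True``.
    """

    z0: float
    z1: float
    b: float
    coef_cov: np.ndarray
    sigma_site: float = 0.0
    converged: bool = True
    boundary: bool = False
    n_obs: int = 0
    loglik: float = math.nan


@dataclass
class PairEstimate:
    """One directed association with its uncertainty.

    ``or_value`` may be exact 0 or ``inf`` (species never co-occurring /
    perfectly co-occurring); in that case the standard error, the upper
    interval bound and the p-value are undefined (NaN), mirroring how such
    estimates are reported rather than dropping them.
    """

    pair: DirectedPair
    or_value: float
    log_or_se: float
    ci_low: float
    ci_high: float
    p_value: float
    estimator: str
    status: str = "ok"  # ok | boundary | degenerate

    @property
    def target(self) -> str:
        return self.pair.target

    @property
    def predictor(self) -> str:
        return self.pair.predictor


def estimates_to_frame(estimates: Sequence[PairEstimate]) -> pd.DataFrame:
    """Flatten a list of estimates into a tidy table (one row per pair)."""
    return pd.DataFrame(
        {
            "target": [e.target for e in estimates],
            "predictor": [e.predictor for e in estimates],
            "odds_ratio": [e.or_value for e in estimates],
            "log_or_se": [e.log_or_se for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
            "p_value": [e.p_value for e in estimates],
            "estimator": [e.estimator for e in estimates],
            "status": [e.status for e in estimates],
        }
    )


# ---------------------------------------------------------------------------
# logistic fit (closed form: the model is saturated)


def _saturated_fit(n0: int, k0: int, n1: int, k1: int, n: int) -> PairModelFit:
    """Exact ML logistic fit of target on a binary predictor.

    ``n1``/``k1`` are the number of surveys with the predictor present and
    the target present among them; ``n0``/``k0`` the same with the
    predictor absent. The MLE puts the fitted probabilities at the cell
    proportions; the (intercept, slope) covariance is the inverse Fisher
    information, Var(b0) = 1/(n0 p0 q0), Var(b0+b1) = 1/(n1 p1 q1).
    """
    p0 = k0 / n0
    p1 = k1 / n1
    boundary = p0 in (0.0, 1.0) or p1 in (0.0, 1.0)
    with np.errstate(divide="ignore"):
        z0 = float(logit(p0))
        z1 = float(logit(p1))
        var0 = 1.0 / (n0 * p0 * (1.0 - p0)) if not p0 in (0.0, 1.0) else math.inf
        var1 = 1.0 / (n1 * p1 * (1.0 - p1)) if not p1 in (0.0, 1.0) else math.inf
    cov = np.array([[var0, -var0], [-var0, var0 + var1]])
    ll = 0.0
    for nn, kk, pp in ((n0, k0, p0), (n1, k1, p1)):
        if 0 < pp < 1:
            ll += kk * math.log(pp) + (nn - kk) * math.log(1 - pp)
    return PairModelFit(
        z0=z0,
        z1=z1,
        b=n1 / n,
        coef_cov=cov,
        sigma_site=0.0,
        converged=not boundary,
        boundary=boundary,
        n_obs=n,
        loglik=ll,
    )


def _pair_arrays(data: SurveyTable, pair: DirectedPair) -> tuple[np.ndarray, np.ndarray]:
    y = data.presence[pair.target].to_numpy(dtype=np.int8)
    x = data.presence[pair.predictor].to_numpy(dtype=np.int8)
    if x.min() == x.max():
        raise DegenerateDataError(
            f"predictor {pair.predictor!r} is constant across surveys"
        )
    if y.min() == y.max():
        raise DegenerateDataError(
            f"target {pair.target!r} is constant across surveys"
        )
    return y, x


def fit_pair_logistic(data: SurveyTable, pair: DirectedPair) -> PairModelFit:
    """Logistic regression of the target's presence on the predictor's.

    The covariate is binary, so the model is saturated and the exact
    maximum-likelihood fit is computed in closed form (verified against
    iteratively reweighted least squares in the test suite). Perfect
    separation or an empty cell yields infinite linear predictors and a
    ``boundary`` fit with ``converged=False``.
    """
    y, x = _pair_arrays(data, pair)
    n = len(y)
    n1 = int(x.sum())
    n0 = n - n1
    k1 = int(y[x == 1].sum())
    k0 = int(y.sum()) - k1
    return _saturated_fit(n0, k0, n1, k1, n)


def fit_pair_glmm(data: SurveyTable, pair: DirectedPair, **kwargs) -> PairModelFit:
    """Binomial-logit mixed model with a random site intercept.

    Thin wrapper re-exported from :mod:`pairodds.mixed`; see there for
    the Laplace-approximated likelihood and its options.
    """
    from .mixed import fit_pair_glmm as _fit

    return _fit(data, pair, **kwargs)


# ---------------------------------------------------------------------------
# OR + delta-method uncertainty from a fit


def _log_or_gradient(z0: float, z1: float, b: float) -> tuple[float, float, float]:
    """(d/d intercept, d/d slope) of log OR, and pbar.

    log OR = z1 - g(pbar) with z1 = intercept + slope, z0 = intercept,
    pbar = (1-b) s(z0) + b s(z1), s the inverse logit; s'(z) = p(1-p).
    """
    p0 = float(expit(z0))
    p1 = float(expit(z1))
    pbar = (1.0 - b) * p0 + b * p1
    w = pbar * (1.0 - pbar)
    d0 = p0 * (1.0 - p0)
    d1 = p1 * (1.0 - p1)
    g_intercept = 1.0 - ((1.0 - b) * d0 + b * d1) / w
    g_slope = 1.0 - b * d1 / w
    return g_intercept, g_slope, pbar


def or_from_fit(
    fit: PairModelFit,
    pair: DirectedPair | None = None,
    *,
    ci_level: float = 0.95,
    estimator: str = "logistic",
) -> PairEstimate:
    """Directed odds ratio with delta-method uncertainty from a pair fit.

    OR = exp(z1 - g(pbar)) with pbar = (1-b) g^-1(z0) + b g^-1(z1): the
    odds of the target given the predictor present over the marginal odds
    reconstructed from the fit. On a saturated logistic fit this equals
    the closed-form contingency odds ratio exactly. The log-OR variance is
    grad' Cov grad over (intercept, slope); the Wald interval and two-sided
    p-value follow on the log scale. Boundary fits (z0 or z1 infinite)
    return OR 0 / inf / a finite ratio with undefined SE, interval and
    p-value.
    """
    if pair is None:
        pair = DirectedPair(predictor="B", target="A")
    z0, z1, b = fit.z0, fit.z1, fit.b
    nan = math.nan

    if not math.isfinite(z0) or not math.isfinite(z1):
        # empty-cell / separation fit: the point estimate may still be
        # meaningful (0 when the pair never co-occurs, inf for perfect
        # co-occurrence) but Wald uncertainty is not.
        p0 = float(expit(z0))
        p1 = float(expit(z1))
        pbar = (1.0 - b) * p0 + b * p1
        if p1 == 0.0:
            or_value = 0.0
        elif p1 == 1.0 and pbar < 1.0:
            or_value = math.inf
        elif 0.0 < pbar < 1.0:
            or_value = (p1 / (1.0 - p1)) / (pbar / (1.0 - pbar))
        else:
            or_value = nan
        return PairEstimate(
            pair, or_value, nan, nan, nan, nan, estimator, status="boundary"
        )

    if z1 == z0:  # zero slope: conditional odds equal marginal odds
        log_or = 0.0
    else:
        _, _, pbar = _log_or_gradient(z0, z1, b)
        log_or = z1 - float(logit(pbar))
    g0, g1, _ = _log_or_gradient(z0, z1, b)
    grad = np.array([g0, g1])
    var = float(grad @ fit.coef_cov @ grad)
    se = math.sqrt(var) if var >= 0 and math.isfinite(var) else nan
    if math.isnan(se):
        return PairEstimate(
            pair, math.exp(log_or), nan, nan, nan, nan, estimator, status="boundary"
        )
    zcrit = float(ndtri(0.5 + ci_level / 2.0))
    ci_low = math.exp(log_or - zcrit * se)
    ci_high = math.exp(log_or + zcrit * se)
    if se == 0.0:
        p = 1.0 if log_or == 0.0 else 0.0
    else:
        p = 2.0 * float(ndtr(-abs(log_or) / se))
    status = "ok" if fit.converged else "boundary"
    return PairEstimate(
        pair, math.exp(log_or), se, ci_low, ci_high, p, estimator, status=status
    )


# ---------------------------------------------------------------------------
# vectorised all-pairs estimation


def _pair_counts(X: np.ndarray) -> dict[str, np.ndarray]:
    """Contingency counts for every ordered (target, predictor) pair.

    Returns matrices indexed [target, predictor]: ``c`` both present,
    ``n_t``/``n_p`` the marginal presence counts broadcast to matrix
    shape, and the survey total ``n``.
    """
    X = np.asarray(X, dtype=np.float64)
    n, _ = X.shape
    both = X.T @ X  # both[i, j] = co-occurrence count of species i and j
    tot = X.sum(axis=0)
    return {
        "c": both,
        "n_t": tot[:, None] + np.zeros_like(both),
        "n_p": tot[None, :] + np.zeros_like(both),
        "n": n,
    }


def _raw_or_matrices(X: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorised closed-form OR, SE and p for all ordered pairs.

    Entry [i, j] is the association of target species i indicated by
    predictor species j. Identical (to floating precision) to running
    :func:`fit_pair_logistic` + :func:`or_from_fit` pair by pair.
    """
    cts = _pair_counts(X)
    c, n_t, n_p, n = cts["c"], cts["n_t"], cts["n_p"], cts["n"]
    with np.errstate(divide="ignore", invalid="ignore"):
        n1 = n_p
        n0 = n - n_p
        p1 = c / n1
        p0 = (n_t - c) / n0
        b = n_p / n
        pbar = n_t / n
        q1 = 1.0 - p1
        q0 = 1.0 - p0
        w = pbar * (1.0 - pbar)
        log_or = logit(p1) - logit(pbar)
        # delta-method variance in a form finite whenever p1 is interior:
        # var0 (g0-g1)^2 + var1 g1^2 with var0 (g0-g1)^2 reduced
        # algebraically to (1-b)^2 p0 q0 / (n0 w^2).
        g1 = 1.0 - b * p1 * q1 / w
        var = ((1.0 - b) ** 2) * p0 * q0 / (n0 * w * w) + g1 * g1 / (n1 * p1 * q1)
        se = np.sqrt(var)
        # exact ratio form (c (n - n_t)) / ((n_p - c) n_t): keeps printed
        # round values like 3 exact instead of exp(log ...) rounding
        or_value = (c * (n - n_t)) / ((n_p - c) * n_t)
        or_value = np.where(c == 0, 0.0, or_value)  # never co-occur
        or_value = np.where((p1 == 1.0) & (pbar < 1.0), np.inf, or_value)
        boundary = (p1 <= 0.0) | (p1 >= 1.0) | (p0 <= 0.0) | (p0 >= 1.0)
        degenerate = (pbar <= 0.0) | (pbar >= 1.0) | (n_p == 0) | (n_p == n)
        se = np.where(boundary | degenerate, np.nan, se)
        pval = 2.0 * ndtr(-np.abs(log_or) / se)
    np.fill_diagonal(or_value, np.nan)
    return {
        "or": or_value,
        "log_or": log_or,
        "se": se,
        "p": pval,
        "boundary": boundary,
        "degenerate": degenerate,
    }


def estimate_all_pairs(
    data: SurveyTable,
    estimator: Estimator = "raw",
    *,
    ci_level: float = 0.95,
    glmm_options: Mapping | None = None,
) -> list[PairEstimate]:
    """One directed estimate for every ordered pair of species.

    ``n`` species yield ``n (n-1)`` estimates, computed independently per
    pair and returned sorted by (target, predictor) name. Pairs that
    cannot be estimated (a constant species, empty cells) are returned as
    flagged estimates rather than aborting the batch.
    """
    names = data.species_names
    if len(names) < 2:
        raise ValueError("need at least two species to estimate pairwise associations")
    zcrit = float(ndtri(0.5 + ci_level / 2.0))
    order = sorted(range(len(names)), key=lambda i: names[i])
    estimates: list[PairEstimate] = []

    if estimator == "raw":
        mats = _raw_or_matrices(data.presence.to_numpy())
        for i in order:
            for j in order:
                if i == j:
                    continue
                pair = DirectedPair(predictor=names[j], target=names[i])
                if mats["degenerate"][i, j]:
                    estimates.append(
                        PairEstimate(
                            pair, math.nan, math.nan, math.nan, math.nan, math.nan,
                            "raw", status="degenerate",
                        )
                    )
                    continue
                orv = float(mats["or"][i, j])
                se = float(mats["se"][i, j])
                if math.isnan(se):
                    estimates.append(
                        PairEstimate(
                            pair, orv, math.nan, math.nan, math.nan, math.nan,
                            "raw", status="boundary",
                        )
                    )
                    continue
                lo = float(np.exp(mats["log_or"][i, j] - zcrit * se))
                hi = float(np.exp(mats["log_or"][i, j] + zcrit * se))
                estimates.append(
                    PairEstimate(pair, orv, se, lo, hi, float(mats["p"][i, j]), "raw")
                )
        return estimates

    if estimator not in ("logistic", "glmm"):
        raise ValueError(f"unknown estimator {estimator!r}")

    for i in order:
        for j in order:
            if i == j:
                continue
            pair = DirectedPair(predictor=names[j], target=names[i])
            try:
                if estimator == "logistic":
                    fit = fit_pair_logistic(data, pair)
                else:
                    fit = fit_pair_glmm(data, pair, **(glmm_options or {}))
            except DegenerateDataError:
                estimates.append(
                    PairEstimate(
                        pair, math.nan, math.nan, math.nan, math.nan, math.nan,
                        estimator, status="degenerate",
                    )
                )
                continue
            estimates.append(
                or_from_fit(fit, pair, ci_level=ci_level, estimator=estimator)
            )
    return estimates
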