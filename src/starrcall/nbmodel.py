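"""Negative binomial (NB2) probability core and regression.

The background model: output fragment counts y_i in non-overlapping genomic
bins follow an NB2 distribution (Gamma-Poisson mixture) with mean mu_i and
dispersion theta, variance mu + mu^2/theta. The log mean is a linear
function of per-bin covariates (covariate mode) or of ln(input coverage)
entering as a fixed offset (rate mode, which models the transcription rate
y/t directly). Coefficients and dispersion are estimated by maximum
likelihood, alternating Fisher-scoring updates of beta with 1-D profile
likelihood updates of theta until both converge. Enrichment P-values are
upper-tail probabilities Pr(Y >= y_i) under the fitted null, corrected by
Benjamini-Hochberg over the tested bins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .covariates import CovariateMatrix

__all__ = [
    "nb_logpmf",
    "nb_pvalue",
    "NegativeBinomialRegressor",
    "NBFit",
    "fit_nb2",
    "fit_rate_mode",
    "bh_adjust",
    "DistributionFits",
    "fit_candidate_distributions",
    "pvalue_calibration",
]

THETA_MIN = 1e-3
THETA_MAX = 1e6
_ETA_CLIP = 30.0


def nb_logpmf(y, mu, theta):
    """Log pmf of the NB2 distribution, in log-gamma arithmetic.

    f(y; mu, theta) = Gamma(y+theta) / (Gamma(y+1) Gamma(theta))
                      * (theta/(theta+mu))^theta * (mu/(theta+mu))^y
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(y < 0) or np.any(y != np.floor(y)):
        raise ValueError("y must be a non-negative integer count")
    return (
        special.gammaln(y + theta)
        - special.gammaln(y + 1)
        - special.gammaln(theta)
        + theta * np.log(theta / (theta + mu))
        + y * np.log(mu / (theta + mu))
    )


def nb_pvalue(y, mu, theta):
    """Upper-tail probability Pr(Y >= y) = 1 - CDF(y - 1) under NB2.

    Evaluated through the regularized incomplete beta identity
    Pr(Y >= y) = I_{mu/(theta+mu)}(y, theta) for y >= 1; Pr(Y >= 0) = 1.
    Results are clipped to [0, 1].
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(mu <= 0) or np.any(theta <= 0):
        raise ValueError("mu and theta must be positive")
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    x = mu / (theta + mu)
    with np.errstate(invalid="ignore"):
        p = special.betainc(np.maximum(y, 1.0), theta, x)
    p = np.where(y < 1, 1.0, p)
    return np.clip(p, 0.0, 1.0)


def _design(X, fit_intercept):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if fit_intercept:
        return np.column_stack([np.ones(len(X)), X])
    return X


def _check_rank(Z, names):
    from scipy.linalg import qr

    _, r, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column(s): {bad}"
        )


class NegativeBinomialRegressor(BaseEstimator):
    """NB2 regression with a log link, fit by alternating maximization.

    Parameters
    ----------
    fit_intercept : include a constant term in the linear predictor.
    theta0 : initial dispersion; by default a method-of-moments estimate
        from warm-start residuals, floored/capped at [1e-3, 1e6].
    tol : convergence tolerance on the coefficient and log-dispersion
        updates and the score norm.
    max_iter : maximum number of alternating (beta, theta) rounds.

    Fitted attributes
    -----------------
    coef_, intercept_, theta_, llf_, aic_, bic_, n_iter_, converged_,
    loglik_path_ (log-likelihood after each alternating round; it is
    non-decreasing because each beta step is safeguarded by halving).
    """

    def __init__(self, fit_intercept: bool = True, theta0: float | None = None,
                 tol: float = 1e-8, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.theta0 = theta0
        self.tol = tol
        self.max_iter = max_iter

    # --- likelihood pieces -------------------------------------------------

    @staticmethod
    def _loglik(y, eta, theta):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        return float(np.sum(nb_logpmf(y, mu, theta)))

    @staticmethod
    def _profile_theta(y, eta, lo=THETA_MIN, hi=THETA_MAX):
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))

        def neg(logt):
            return -float(np.sum(nb_logpmf(y, mu, np.exp(logt))))

        res = optimize.minimize_scalar(neg, bounds=(np.log(lo), np.log(hi)),
                                       method="bounded",
                                       options={"xatol": 1e-10})
        return float(np.exp(res.x))

    def fit(self, X, y, offset=None, feature_names=None):
        y = np.asarray(y, dtype=float)
        Z = _design(X, self.fit_intercept)
        n, p = Z.shape
        if offset is None:
            offset = np.zeros(n)
        offset = np.asarray(offset, dtype=float)
        if feature_names is None:
            feature_names = [f"x{j}" for j in range(Z.shape[1] - int(self.fit_intercept))]
        names = (["intercept"] if self.fit_intercept else []) + list(feature_names)
        _check_rank(Z, names)

        # warm start: log-linear least squares on shifted counts
        beta = np.linalg.lstsq(Z, np.log(y + 0.5) - offset, rcond=None)[0]
        eta = Z @ beta + offset
        mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
        if self.theta0 is not None:
            theta = float(np.clip(self.theta0, THETA_MIN, THETA_MAX))
        else:
            excess = np.mean(((y - mu) ** 2 - mu) / np.maximum(mu**2, 1e-12))
            theta = float(np.clip(1.0 / max(excess, 1.0 / THETA_MAX), THETA_MIN, THETA_MAX))

        ll = self._loglik(y, eta, theta)
        path = [ll]
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # (a) Fisher scoring step for beta at fixed theta, safeguarded
            mu = np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))
            w = mu / (1.0 + mu / theta)
            z = (eta - offset) + (y - mu) / mu
            sw = np.sqrt(w)
            beta_new = np.linalg.lstsq(Z * sw[:, None], z * sw, rcond=None)[0]
            step = 1.0
            for _ in range(30):
                cand = beta + step * (beta_new - beta)
                ll_cand = self._loglik(y, Z @ cand + offset, theta)
                if ll_cand >= ll - 1e-12:
                    break
                step *= 0.5
            else:
                cand, ll_cand = beta, ll
            dbeta = np.max(np.abs(cand - beta))
            beta = cand
            eta = Z @ beta + offset
            # (b) profile-likelihood update of theta at fixed beta
            theta_new = self._profile_theta(y, eta)
            dtheta = abs(np.log(theta_new) - np.log(theta))
            theta = theta_new
            ll = self._loglik(y, eta, theta)
            path.append(ll)
            if dbeta < self.tol and dtheta < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"NB2 fit did not converge in {self.max_iter} iterations "
                f"(last updates: beta {dbeta:.2e}, log-theta {dtheta:.2e})",
                RuntimeWarning,
            )

        k = p + 1  # coefficients plus dispersion
        self.feature_names_ = list(feature_names)
        if self.fit_intercept:
            self.intercept_ = float(beta[0])
            self.coef_ = beta[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = beta.copy()
        self.theta_ = float(theta)
        self.llf_ = float(ll)
        self.aic_ = 2 * k - 2 * ll
        self.bic_ = k * np.log(n) - 2 * ll
        self.n_iter_ = it
        self.converged_ = converged
        self.loglik_path_ = np.asarray(path)
        self.n_features_in_ = Z.shape[1] - int(self.fit_intercept)
        return self

    def linear_predictor(self, X, offset=None):
        Z = _design(X, self.fit_intercept)
        beta = np.concatenate([[self.intercept_], self.coef_]) if self.fit_intercept else self.coef_
        eta = Z @ beta
        if offset is not None:
            eta = eta + np.asarray(offset, dtype=float)
        return eta

    def predict(self, X, offset=None):
        """Fitted mean mu = exp(x'beta [+ offset])."""
        return np.exp(np.clip(self.linear_predictor(X, offset), -_ETA_CLIP, _ETA_CLIP))


@dataclass
class NBFit:
    """Serializable record of a fitted NB2 background model."""

    beta: dict[str, float]
    theta: float
    mode: str  # "covariate" or "rate"
    log_likelihood: float
    aic: float
    bic: float
    iterations: int
    converged: bool
    standardization: dict | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "NBFit":
        with open(path) as fh:
            return cls(**json.load(fh))

    def predict_mean(self, X: np.ndarray, feature_names: list[str],
                     offset: np.ndarray | None = None) -> np.ndarray:
        eta = np.full(len(X), self.beta.get("intercept", 0.0))
        for j, name in enumerate(feature_names):
            eta = eta + self.beta[name] * X[:, j]
        if offset is not None:
            eta = eta + offset
        return np.exp(np.clip(eta, -_ETA_CLIP, _ETA_CLIP))


def _standardization_record(X: CovariateMatrix | None):
    if X is None or X.means is None:
        return None
    return {"names": list(X.names), "means": list(map(float, X.means)),
            "sds": list(map(float, X.sds))}


def fit_nb2(
    y: np.ndarray,
    X: CovariateMatrix | np.ndarray,
    mode: str = "covariate",
    t: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[NBFit, NegativeBinomialRegressor]:
    """Fit the NB2 background model on training bins.

    In covariate mode the (already transformed) covariate columns form the
    design; in rate mode ln(t) enters as a fixed offset (see
    :func:`fit_rate_mode`).
    """
    if mode == "rate":
        return fit_rate_mode(y, t, X, tol=tol, max_iter=max_iter)
    if mode != "covariate":
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(X, CovariateMatrix):
        names, values, std = X.names, X.values, _standardization_record(X)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = [f"x{j}" for j in range(values.shape[1])]
        std = None
    est = NegativeBinomialRegressor(tol=tol, max_iter=max_iter)
    est.fit(values, y, feature_names=names)
    beta = {"intercept": est.intercept_}
    beta.update({n: float(b) for n, b in zip(names, est.coef_)})
    fit = NBFit(beta=beta, theta=est.theta_, mode="covariate",
                log_likelihood=est.llf_, aic=est.aic_, bic=est.bic_,
                iterations=est.n_iter_, converged=est.converged_,
                standardization=std)
    return fit, est


def fit_rate_mode(
    y: np.ndarray,
    t: np.ndarray,
    X: CovariateMatrix | np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[NBFit, NegativeBinomialRegressor]:
    """Fit the rate parameterization: ln mu = ln t + intercept [+ covariates].

    The input coverage acts as an exposure with fixed coefficient 1, so the
    intercept is the log basal transcription rate; with no covariates and a
    rate of 1 it is ~0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("rate mode requires strictly positive input coverage t")
    offset = np.log(t)
    if X is None:
        values = np.empty((len(t), 0))
        names: list[str] = []
        std = None
    elif isinstance(X, CovariateMatrix):
        keep = [j for j, n in enumerate(X.names) if n != "log_input"]
        names = [X.names[j] for j in keep]
        values = X.values[:, keep]
        std = _standardization_record(X)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = [f"x{j}" for j in range(values.shape[1])]
        std = None
    est = NegativeBinomialRegressor(tol=tol, max_iter=max_iter)
    est.fit(values, y, offset=offset, feature_names=names)
    beta = {"intercept": est.intercept_}
    beta.update({n: float(b) for n, b in zip(names, est.coef_)})
    fit = NBFit(beta=beta, theta=est.theta_, mode="rate",
                log_likelihood=est.llf_, aic=est.aic_, bic=est.bic_,
                iterations=est.n_iter_, converged=est.converged_,
                standardization=std)
    return fit, est


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DistributionFits:
    """MLE fits of candidate count distributions to a coverage slice, with a
    Q-Q table of expected vs observed quantiles at integer percentiles."""

    poisson_lambda: float
    nb_mu: float
    nb_theta: float
    binomial_n: int | None
    binomial_p: float | None
    qq: pd.DataFrame
    degenerate: bool = False


def fit_candidate_distributions(
    y: np.ndarray,
    t: np.ndarray | None = None,
    min_size: int = 100,
) -> DistributionFits:
    """Fit Poisson, NB2, and (given input) binomial models to output counts.

    Intended for bins subsampled at a single input-coverage value (the
    median input coverage in practice), so the input's influence on the
    output distribution is held fixed. The binomial uses trials = mean
    total (input + output) coverage and success probability
    sum(y) / sum(y + t).
    """
    y = np.asarray(y, dtype=float)
    if len(y) < min_size:
        warnings.warn(f"distribution fitting on only {len(y)} bins", RuntimeWarning)
    lam = float(np.mean(y))
    degenerate = bool(np.var(y) == 0 or lam == 0)
    if degenerate:
        nb_mu, nb_theta = lam, THETA_MAX
    else:
        nb_mu = lam  # MLE of the NB2 mean is the sample mean

        def neg(logt):
            return -float(np.sum(nb_logpmf(y, nb_mu, np.exp(logt))))

        res = optimize.minimize_scalar(neg, bounds=(np.log(THETA_MIN), np.log(THETA_MAX)),
                                       method="bounded", options={"xatol": 1e-10})
        nb_theta = float(np.exp(res.x))
    binom_n = binom_p = None
    if t is not None:
        t = np.asarray(t, dtype=float)
        binom_n = int(round(float(np.mean(y + t))))
        tot = float(np.sum(y + t))
        binom_p = float(np.sum(y) / tot) if tot > 0 else 0.0

    pct = np.arange(101)
    q = pct / 100.0
    rows = {"percentile": pct, "observed": np.percentile(y, pct)}
    rows["poisson"] = stats.poisson.ppf(q, lam)
    rows["nb"] = stats.nbinom.ppf(q, nb_theta, nb_theta / (nb_theta + max(nb_mu, 1e-12)))
    if binom_n is not None:
        rows["binomial"] = stats.binom.ppf(q, binom_n, binom_p)
    qq = pd.DataFrame(rows)
    return DistributionFits(lam, nb_mu, nb_theta, binom_n, binom_p, qq, degenerate)


def pvalue_calibration(p_values: np.ndarray, n_quantiles: int = 100):
    """Observed-vs-uniform P value quantiles plus the KS distance.

    Under a well calibrated background model on null data the observed
    quantiles track the diagonal; enrichment shows up only as excess mass
    in the low-P tail.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return pd.DataFrame(columns=["quantile", "expected", "observed"]), float("nan")
    q = np.linspace(0, 1, n_quantiles + 1)
    table = pd.DataFrame({"quantile": q, "expected": q, "observed": np.quantile(p, q)})
    ks = float(stats.kstest(p, "uniform").statistic)
    return table, ks
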