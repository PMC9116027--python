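"""Likelihoods, moments and maximum-likelihood fitting for four count families.

Families: Poisson, negative binomial (NB), zero-inflated Poisson (ZIP) and
zero-inflated negative binomial (ZINB). Every model places the per-location
total ``N_i`` as a multiplicative offset in the count-component mean,

    mu_i = N_i * exp(beta0 + x_i' beta),

and (for ZI families) a single location-constant zero-inflation weight
``pi``. The NB dispersion ``phi`` enters through Var = mu + mu^2/phi; small
``phi`` means strong overdispersion. Optimization runs on unconstrained
transforms (log phi, logit pi) with analytic gradients.

A moment-based GEE plug-in estimator is provided as a fallback for genes
where the NB likelihood fails to converge (typically sample variance below
the mean, which drives phi to +infinity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import digamma, expit, gammaln

__all__ = [
    "FAMILIES",
    "PHI_CAP",
    "ModelFit",
    "MomentSet",
    "log_likelihood",
    "fit_gene",
    "fit_nb_gee",
    "fit_nb_with_fallback",
    "model_moments",
]

FAMILIES = ("poisson", "nb", "zip", "zinb")

#: Dispersion cap: phi at/above this is treated as a diverged (Poisson-limit)
#: NB fit; also the value assigned when the GEE moment equation has no
#: positive solution (sample variance <= mean).
PHI_CAP = 1e8

_GRAD_TOL = 1e-4
_ETA_CLIP = 500.0  # log-mean clip; counts here never approach exp(500)


@dataclass
class ModelFit:
    """One gene's fitted count model."""

    family: str
    beta0: float
    beta: np.ndarray
    phi: float | None
    pi: float | None
    loglik: float
    n_params: int
    aic: float
    converged: bool
    method: str = "mle"
    phi_capped: bool = False
    message: str = ""

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))


@dataclass
class MomentSet:
    mean: float
    variance: float
    zero_prop: float


# ---------------------------------------------------------------------------
# parameter packing: theta = [beta0, beta..., (log phi), (logit pi)]
# ---------------------------------------------------------------------------


def _design(n: int, covariates: np.ndarray | None) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    covariates = np.asarray(covariates, dtype=float)
    if covariates.ndim == 1:
        covariates = covariates[:, None]
    return np.column_stack([np.ones(len(covariates)), covariates])


def _unpack(family: str, theta: np.ndarray, n_mean: int):
    beta = theta[:n_mean]
    i = n_mean
    log_phi = logit_pi = None
    if family in ("nb", "zinb"):
        log_phi = theta[i]
        i += 1
    if family in ("zip", "zinb"):
        logit_pi = theta[i]
        i += 1
    return beta, log_phi, logit_pi


def n_free_params(family: str, n_covariates: int = 0) -> int:
    k = 1 + n_covariates
    if family in ("nb", "zinb"):
        k += 1
    if family in ("zip", "zinb"):
        k += 1
    return k


def _validate_y_offsets(y: np.ndarray, offsets: np.ndarray):
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if not np.allclose(yf, np.rint(yf), rtol=0, atol=1e-9):
            raise ValueError("counts must be integers")
        y = np.rint(yf).astype(np.int64)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    offsets = np.asarray(offsets, dtype=float)
    if (offsets <= 0).any():
        raise ValueError("offsets must be strictly positive")
    if y.shape != offsets.shape:
        raise ValueError("y and offsets must have the same length")
    return y.astype(float), offsets


def _softplus(x):
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# negative log-likelihood and gradient per family
# ---------------------------------------------------------------------------


def _nll_grad(theta, family, y, log_off, X):
    """Negative log-likelihood and its gradient w.r.t. packed theta."""
    n_mean = X.shape[1]
    beta, log_phi, logit_pi = _unpack(family, theta, n_mean)
    eta = np.clip(X @ beta + log_off, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    grad = np.zeros_like(theta)

    if family == "poisson":
        ll = y * eta - mu - gammaln(y + 1.0)
        grad[:n_mean] = X.T @ (y - mu)
        return -float(ll.sum()), -grad

    if family == "nb":
        phi = np.exp(log_phi)
        ll = (
            gammaln(y + phi)
            - gammaln(phi)
            - gammaln(y + 1.0)
            + phi * (log_phi - np.log(phi + mu))
            + y * (eta - np.log(phi + mu))
        )
        w = (y - mu) * phi / (phi + mu)
        grad[:n_mean] = X.T @ w
        dphi = (
            digamma(y + phi)
            - digamma(phi)
            + (log_phi - np.log(phi + mu))
            + (mu - y) / (phi + mu)
        ).sum()
        grad[n_mean] = phi * dphi
        return -float(ll.sum()), -grad

    # zero-inflated families: mixture mass at zero
    log_pi = -_softplus(-logit_pi)       # log pi
    log_1mpi = -_softplus(logit_pi)      # log (1 - pi)
    pi = expit(logit_pi)
    zero = y == 0

    if family == "zip":
        log_f0 = -mu
        d_logf0_eta = -mu           # d log f0 / d eta
        d_logf0_logphi = None
    else:  # zinb
        phi = np.exp(log_phi)
        log_f0 = phi * (log_phi - np.log(phi + mu))
        d_logf0_eta = -phi * mu / (phi + mu)
        d_logf0_logphi = phi * (log_phi - np.log(phi + mu) + mu / (phi + mu))

    # P(0) = pi + (1-pi) f0, on the log scale
    log_p0 = np.logaddexp(log_pi, log_1mpi + log_f0)
    # positive part: log(1-pi) + log f(y)
    if family == "zip":
        log_fpos = y * eta - mu - gammaln(y + 1.0)
    else:
        log_fpos = (
            gammaln(y + phi)
            - gammaln(phi)
            - gammaln(y + 1.0)
            + phi * (log_phi - np.log(phi + mu))
            + y * (eta - np.log(phi + mu))
        )
    ll = np.where(zero, log_p0, log_1mpi + log_fpos)

    # weight of the count component inside P(0): (1-pi) f0 / P(0)
    w0 = np.exp(log_1mpi + log_f0 - log_p0)

    # mean-part gradient
    d_eta = np.where(
        zero,
        w0 * d_logf0_eta,
        (y - mu) if family == "zip" else (y - mu) * phi / (phi + mu),
    )
    grad[:n_mean] = X.T @ d_eta

    i = n_mean
    if family == "zinb":
        d_pos_logphi = phi * (
            digamma(y + phi)
            - digamma(phi)
            + (log_phi - np.log(phi + mu))
            + (mu - y) / (phi + mu)
        )
        grad[i] = np.where(zero, w0 * d_logf0_logphi, d_pos_logphi).sum()
        i += 1

    # d ll / d logit_pi; dpi/dlogit = pi (1-pi)
    d_pi = np.where(zero, (1.0 - np.exp(log_f0)) / np.exp(log_p0), -1.0 / (1.0 - pi))
    grad[i] = (pi * (1.0 - pi) * d_pi).sum()
    return -float(ll.sum()), -grad


def log_likelihood(family, params, y, offsets, covariates=None) -> float:
    """Exact log-likelihood of a parameter set on one gene's counts.

    ``params`` is a mapping with keys ``beta0`` and optionally ``beta``
    (covariate coefficients), ``phi`` and ``pi`` as required by ``family``.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y, offsets = _validate_y_offsets(y, offsets)
    X = _design(len(y), covariates)
    beta = np.concatenate([[params["beta0"]], np.atleast_1d(params.get("beta", []))])
    if len(beta) != X.shape[1]:
        raise ValueError("beta length does not match covariates")
    theta = list(beta)
    if family in ("nb", "zinb"):
        phi = float(params["phi"])
        if phi <= 0:
            raise ValueError("phi must be positive")
        theta.append(np.log(phi))
    if family in ("zip", "zinb"):
        pi = float(params["pi"])
        if not 0 <= pi < 1:
            raise ValueError("pi must be in [0, 1)")
        # logit with guard for pi == 0
        theta.append(np.log(max(pi, 1e-300)) - np.log1p(-pi) if pi > 0 else -750.0)
    nll, _ = _nll_grad(np.asarray(theta, float), family, y, np.log(offsets), X)
    return -nll


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _fit_poisson(y, log_off, X):
    if X.shape[1] == 1:
        beta = np.array([np.log(y.sum() / np.exp(log_off).sum())])
        nll, grad = _nll_grad(beta, "poisson", y, log_off, X)
        return beta, -nll, True, float(np.abs(grad).max())
    theta0 = np.zeros(X.shape[1])
    theta0[0] = np.log(max(y.sum(), 0.5) / np.exp(log_off).sum())
    res = optimize.minimize(
        _nll_grad, theta0, args=("poisson", y, log_off, X),
        jac=True, method="L-BFGS-B",
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
    )
    ok = bool(res.success) and float(np.abs(res.jac).max()) < _GRAD_TOL
    return res.x, -res.fun, ok, float(np.abs(res.jac).max())


def _minimize(family, theta0, y, log_off, X, bounds):
    return optimize.minimize(
        _nll_grad, np.asarray(theta0, float), args=(family, y, log_off, X),
        jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-7},
    )


def _make_fit(family, res_x, loglik, converged, n_cov, n, message=""):
    n_mean = 1 + n_cov
    beta, log_phi, logit_pi = _unpack(family, np.asarray(res_x, float), n_mean)
    phi = float(np.exp(log_phi)) if log_phi is not None else None
    pi = float(expit(logit_pi)) if logit_pi is not None else None
    k = n_free_params(family, n_cov)
    return ModelFit(
        family=family,
        beta0=float(beta[0]),
        beta=beta[1:],
        phi=phi,
        pi=pi,
        loglik=float(loglik),
        n_params=k,
        aic=2.0 * k - 2.0 * float(loglik),
        converged=bool(converged),
        method="mle",
        phi_capped=(phi is not None and phi >= 0.99 * PHI_CAP),
        message=message,
    )


_LOG_PHI_BOUNDS = (np.log(1e-6), np.log(PHI_CAP))
_LOGIT_PI_BOUNDS = (-20.0, 9.0)  # pi in (~2e-9, ~0.99988)


def _phi_moment_start(y, mu):
    """Method-of-moments 1/phi from Pearson-type excess variance."""
    denom = (mu**2).sum()
    excess = ((y - mu) ** 2 - mu).sum()
    if denom <= 0 or excess <= 0:
        return 1e4
    return float(np.clip(denom / excess, 1e-3, 1e6))


def _excess_zero_start(y, mu):
    p_obs = float((y == 0).mean())
    p_exp = float(np.exp(-np.clip(mu, 0, 700)).mean())
    if p_obs <= p_exp:
        return 0.02
    return float(np.clip((p_obs - p_exp) / max(1.0 - p_exp, 1e-12), 0.02, 0.95))


def fit_gene(family, y, offsets, covariates=None) -> ModelFit:
    """Maximum-likelihood fit of one family to a single gene's counts.

    Requires at least one nonzero count (all-zero genes must be filtered
    upstream). ZI fits are tried from two zero-weight starts (0.05 and the
    excess-zero estimate) and the best log-likelihood is kept.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    y, offsets = _validate_y_offsets(y, offsets)
    if not (y > 0).any():
        raise ValueError("all-zero gene: filter before fitting")
    log_off = np.log(offsets)
    X = _design(len(y), covariates)
    n_cov = X.shape[1] - 1

    beta_p, ll_p, ok_p, g_p = _fit_poisson(y, log_off, X)
    if family == "poisson":
        fit = _make_fit("poisson", beta_p, ll_p, ok_p, n_cov, len(y))
        return fit

    mu_p = np.exp(np.clip(X @ beta_p + log_off, -_ETA_CLIP, _ETA_CLIP))

    if family == "nb":
        theta0 = np.concatenate([beta_p, [np.log(_phi_moment_start(y, mu_p))]])
        bounds = [(None, None)] * (1 + n_cov) + [_LOG_PHI_BOUNDS]
        res = _minimize("nb", theta0, y, log_off, X, bounds)
        gmax = float(np.abs(res.jac).max())
        phi_hat = float(np.exp(res.x[1 + n_cov]))
        ok = bool(res.success) and gmax < _GRAD_TOL and phi_hat < 0.99 * PHI_CAP
        return _make_fit("nb", res.x, -res.fun, ok, n_cov, len(y), res.message)

    pi_starts = [0.05, _excess_zero_start(y, mu_p)]
    best = None
    for pi0 in pi_starts:
        gamma0 = float(np.log(pi0) - np.log1p(-pi0))
        # count-component mean inflates by 1/(1-pi0) to keep E[y] matched
        beta_start = beta_p.copy()
        beta_start[0] -= np.log1p(-pi0)
        if family == "zip":
            theta0 = np.concatenate([beta_start, [gamma0]])
            bounds = [(None, None)] * (1 + n_cov) + [_LOGIT_PI_BOUNDS]
        else:
            theta0 = np.concatenate(
                [beta_start, [np.log(_phi_moment_start(y, mu_p))], [gamma0]]
            )
            bounds = (
                [(None, None)] * (1 + n_cov) + [_LOG_PHI_BOUNDS] + [_LOGIT_PI_BOUNDS]
            )
        res = _minimize(family, theta0, y, log_off, X, bounds)
        if best is None or res.fun < best.fun:
            best = res
    res = best
    gmax = float(np.abs(res.jac).max())
    ok = bool(res.success) and gmax < _GRAD_TOL
    if family == "zinb":
        phi_hat = float(np.exp(res.x[1 + n_cov]))
        ok = ok and phi_hat < 0.99 * PHI_CAP
    return _make_fit(family, res.x, -res.fun, ok, n_cov, len(y), res.message)


def fit_nb_gee(y, offsets, covariates=None) -> ModelFit:
    """Moment (GEE identity-working-correlation) plug-in NB fit.

    The mean parameters solve the Poisson-score estimating equations (for an
    intercept-only model this is exactly mu_hat = sum(y)/sum(N) per unit
    offset). The residual variance is estimated from squared residuals with
    an ``n - p`` denominator and phi solved from ``sigma^2 = mu + mu^2/phi``;
    when the equation has no positive root (variance <= mean) phi is set to
    the cap and flagged. The log-likelihood/AIC are the NB likelihood at the
    plug-in parameters.
    """
    y, offsets = _validate_y_offsets(y, offsets)
    if not (y > 0).any():
        raise ValueError("all-zero gene: filter before fitting")
    log_off = np.log(offsets)
    X = _design(len(y), covariates)
    n_cov = X.shape[1] - 1
    p = X.shape[1]

    beta, _, _, _ = _fit_poisson(y, log_off, X)
    mu_i = np.exp(np.clip(X @ beta + log_off, -_ETA_CLIP, _ETA_CLIP))
    n = len(y)
    dof = max(n - p, 1)
    sigma2 = float(((y - mu_i) ** 2).sum() / dof)
    mu_bar = float(mu_i.mean())

    capped = sigma2 <= mu_bar
    phi = PHI_CAP if capped else float(mu_bar**2 / (sigma2 - mu_bar))
    phi = min(phi, PHI_CAP)

    theta = np.concatenate([beta, [np.log(phi)]])
    nll, _ = _nll_grad(theta, "nb", y, log_off, X)
    k = n_free_params("nb", n_cov)
    return ModelFit(
        family="nb",
        beta0=float(beta[0]),
        beta=beta[1:],
        phi=phi,
        pi=None,
        loglik=-float(nll),
        n_params=k,
        aic=2.0 * k + 2.0 * float(nll),
        converged=True,
        method="gee_plugin",
        phi_capped=capped,
    )


def fit_nb_with_fallback(y, offsets, covariates=None) -> ModelFit:
    """NB fit: MLE when it converges, else best-AIC of MLE vs GEE plug-in."""
    mle = fit_gene("nb", y, offsets, covariates)
    if mle.converged:
        return mle
    gee = fit_nb_gee(y, offsets, covariates)
    return mle if mle.aic <= gee.aic else gee


def model_moments(fit: ModelFit, offset: float) -> MomentSet:
    """Mean, variance and zero probability implied by a fit at one offset.

    Uses the intercept-only mean ``mu = offset * exp(beta0)`` (covariates, if
    any, evaluated at zero / the reference composition).
    """
    if offset <= 0:
        raise ValueError("offset must be positive")
    mu = float(offset * np.exp(fit.beta0))
    if fit.family == "poisson":
        return MomentSet(mu, mu, float(np.exp(-mu)))
    if fit.family == "nb":
        phi = fit.phi
        return MomentSet(mu, mu + mu**2 / phi, float((1 + mu / phi) ** (-phi)))
    if fit.family == "zip":
        pi = fit.pi
        return MomentSet(
            (1 - pi) * mu,
            (1 - pi) * mu * (1 + pi * mu),
            pi + (1 - pi) * float(np.exp(-mu)),
        )
    if fit.family == "zinb":
        pi, phi = fit.pi, fit.phi
        return MomentSet(
            (1 - pi) * mu,
            (1 - pi) * (mu + mu**2 / phi) + pi * (1 - pi) * mu**2,
            pi + (1 - pi) * float((1 + mu / phi) ** (-phi)),
        )
    raise ValueError(f"unknown family {fit.family!r}")
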