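"""Cross-gene mean->zero-proportion and mean->variance trend fits.

Under a transcriptome-wide Poisson assumption the zero proportion is
``exp(-mu)`` and the variance equals the mean — neither has a free
parameter. The NB alternative introduces one common dispersion ``phi``:
zero proportion ``(1 + mu/phi)^(-phi)`` and variance ``mu + mu^2/phi``,
fitted by Gauss-Newton nonlinear least squares on the raw response scale
(phi optimized as log phi with step-halving; start phi = 1, stop when the
step falls below 1e-8 or after 50 iterations).

MSE is reported on the zero-proportion scale for the zero trend and on the
natural-log variance scale for the variance trend; genes with zero sample
variance are excluded from the log-variance MSE (count kept).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrendFit", "fit_zero_trend", "fit_variance_trend"]

_MAX_ITER = 50
_STEP_TOL = 1e-8
_LOG_PHI_LIM = (np.log(1e-8), np.log(1e12))  # keeps (1+mu/phi)^-phi finite


@dataclass
class TrendFit:
    model: str                 # "poisson" | "nb"
    response: str              # "zero_prop" | "log_variance"
    phi_hat: float | None
    predictions: np.ndarray
    mse: float
    converged: bool
    n_iter: int
    n_excluded: int = 0        # zero-variance genes dropped from log-MSE


def _nb_zero(mu, phi):
    return np.exp(-phi * np.log1p(mu / phi))


def _nb_zero_jac_logphi(mu, phi):
    # d/d(log phi) of (1+mu/phi)^(-phi)
    f = _nb_zero(mu, phi)
    dlogf_dphi = -np.log1p(mu / phi) + mu / (phi + mu)
    return f * dlogf_dphi * phi


def _nb_var(mu, phi):
    return mu + mu**2 / phi


def _nb_var_jac_logphi(mu, phi):
    return -(mu**2) / phi  # (-mu^2/phi^2) * phi


def _gauss_newton_logphi(target, mu, predict, jac_logphi, phi0=1.0):
    """Single-parameter Gauss-Newton with step-halving on log phi."""
    theta = np.log(phi0)
    converged = False
    it = 0
    sse = float(((target - predict(mu, np.exp(theta))) ** 2).sum())
    for it in range(1, _MAX_ITER + 1):
        phi = np.exp(theta)
        r = target - predict(mu, phi)
        J = jac_logphi(mu, phi)
        jtj = float(J @ J)
        if jtj <= 0 or not np.isfinite(jtj):
            break
        step = float(J @ r) / jtj
        if abs(step) < _STEP_TOL:
            converged = True
            break
        # step-halving line search: keep fixed points of plain Gauss-Newton
        new_theta, new_sse = theta, sse
        s = step
        for _ in range(30):
            cand = float(np.clip(theta + s, *_LOG_PHI_LIM))
            cand_sse = float(((target - predict(mu, np.exp(cand))) ** 2).sum())
            if cand_sse <= sse:
                new_theta, new_sse = cand, cand_sse
                break
            s *= 0.5
        if new_theta == theta:
            break
        theta, sse = new_theta, new_sse
        if abs(s) < _STEP_TOL:
            converged = True
            break
    else:
        it = _MAX_ITER
    return float(np.exp(theta)), converged, it


def fit_zero_trend(means, zero_props, model: str) -> TrendFit:
    """Fit the cross-gene zero-proportion vs mean relationship."""
    mu = np.asarray(means, dtype=float)
    p = np.asarray(zero_props, dtype=float)
    if (mu <= 0).any():
        raise ValueError("means must be positive")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("zero proportions must lie in [0, 1]")
    if model == "poisson":
        pred = np.exp(-mu)
        return TrendFit(
            "poisson", "zero_prop", None, pred,
            float(((p - pred) ** 2).mean()), True, 0,
        )
    if model != "nb":
        raise ValueError(f"unknown trend model {model!r}")
    if len(mu) < 2:
        raise ValueError("nb trend needs at least 2 genes")
    phi, converged, it = _gauss_newton_logphi(p, mu, _nb_zero, _nb_zero_jac_logphi)
    pred = _nb_zero(mu, phi)
    return TrendFit(
        "nb", "zero_prop", phi, pred, float(((p - pred) ** 2).mean()), converged, it
    )


def fit_variance_trend(means, variances, model: str) -> TrendFit:
    """Fit the cross-gene variance vs mean relationship.

    Residuals for the NB fit are on the raw variance scale; the reported MSE
    is on the natural-log variance scale.
    """
    mu = np.asarray(means, dtype=float)
    v = np.asarray(variances, dtype=float)
    if (mu <= 0).any():
        raise ValueError("means must be positive")
    if (v < 0).any():
        raise ValueError("variances must be non-negative")

    if model == "poisson":
        pred = mu.copy()
        phi = None
        converged, it = True, 0
    elif model == "nb":
        if len(mu) < 2:
            raise ValueError("nb trend needs at least 2 genes")
        phi, converged, it = _gauss_newton_logphi(v, mu, _nb_var, _nb_var_jac_logphi)
        pred = _nb_var(mu, phi)
    else:
        raise ValueError(f"unknown trend model {model!r}")

    ok = v > 0
    mse = float(((np.log(v[ok]) - np.log(pred[ok])) ** 2).mean()) if ok.any() else np.nan
    return TrendFit(
        model, "log_variance", phi, pred, mse, converged, it,
        n_excluded=int((~ok).sum()),
    )
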