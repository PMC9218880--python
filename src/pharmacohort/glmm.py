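"""Random-intercept logistic regression by maximum likelihood.

The repeated binary outcome (antimycotic dispensed: before/after, two
observations per patient) is modelled as

    y_ij ~ Bernoulli(expit(x_ij' beta + b_i)),   b_i ~ N(0, sigma^2),

with fixed effects for group, time and their interaction and one random
intercept per patient. The marginal likelihood integrates the random
intercept out with Gauss-Hermite quadrature; the integrated log-likelihood
is maximized over (beta, log sigma) with BFGS. Standard errors come from
the inverse observed information (numerical Hessian at the optimum).

With sigma fixed at zero the model reduces exactly to ordinary logistic
regression. Complete separation (diverging coefficients) triggers an
automatic rerun with a weak L2 penalty, flagged on the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools import numdiff

#: coefficient magnitude beyond which we declare separation
_SEPARATION_BOUND = 15.0
_RIDGE = 1e-3


@dataclass
class GlmmResult:
    """Fitted random-intercept logistic model."""

    params: pd.Series
    bse: pd.Series
    z_values: pd.Series
    p_values: pd.Series
    random_intercept_sd: float
    loglik: float
    n_patients: int
    n_obs: int
    converged: bool
    penalized: bool = False
    param_names: list = field(default_factory=list)

    @property
    def interaction_p_value(self) -> float:
        for name in self.params.index:
            if ":" in name:
                return float(self.p_values[name])
        raise KeyError("no interaction term in model")


def _patient_loglik_terms(beta: np.ndarray, sigma: float, y: np.ndarray,
                          X: np.ndarray, group_idx: np.ndarray,
                          n_groups: int, nodes: np.ndarray,
                          weights: np.ndarray) -> np.ndarray:
    """log marginal likelihood per patient (vectorized over quadrature)."""
    eta = X @ beta                                  # (n_obs,)
    # b values at quadrature nodes: sqrt(2) * sigma * t_k
    b = np.sqrt(2.0) * sigma * nodes                # (K,)
    # log p(y_ij | b_k): shape (n_obs, K)
    lin = eta[:, None] + b[None, :]
    logp = np.where(y[:, None] == 1, -np.logaddexp(0.0, -lin),
                    -np.logaddexp(0.0, lin))
    # sum within patient -> (n_groups, K)
    per_group = np.zeros((n_groups, logp.shape[1]))
    np.add.at(per_group, group_idx, logp)
    # integrate: sum_k w_k/sqrt(pi) * exp(per_group)
    logw = np.log(weights / np.sqrt(np.pi))
    return special.logsumexp(per_group + logw[None, :], axis=1)


def _negloglik(theta: np.ndarray, y, X, group_idx, n_groups, nodes, weights,
               fix_sigma: float | None, ridge: float) -> float:
    if fix_sigma is None:
        beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    else:
        beta, sigma = theta, fix_sigma
    ll = _patient_loglik_terms(beta, sigma, y, X, group_idx, n_groups,
                               nodes, weights).sum()
    return -ll + ridge * float(beta @ beta)


def _negloglik_grad(theta: np.ndarray, y, X, group_idx, n_groups, nodes,
                    weights, fix_sigma: float | None, ridge: float
                    ) -> tuple[float, np.ndarray]:
    """(value, gradient) of the penalized negative log-likelihood.

    The gradient weights each quadrature node by its per-patient posterior
    probability; the log-sigma component uses d b_k / d log sigma = b_k.
    """
    if fix_sigma is None:
        beta, sigma = theta[:-1], float(np.exp(theta[-1]))
    else:
        beta, sigma = theta, fix_sigma
    eta = X @ beta
    b = np.sqrt(2.0) * sigma * nodes
    lin = eta[:, None] + b[None, :]                       # (n_obs, K)
    logp = np.where(y[:, None] == 1, -np.logaddexp(0.0, -lin),
                    -np.logaddexp(0.0, lin))
    per_group = np.zeros((n_groups, logp.shape[1]))
    np.add.at(per_group, group_idx, logp)
    logw = np.log(weights / np.sqrt(np.pi))
    terms = per_group + logw[None, :]
    li = special.logsumexp(terms, axis=1)                 # (n_groups,)
    post = np.exp(terms - li[:, None])                    # posterior node weights
    resid = y[:, None] - special.expit(lin)               # (n_obs, K)
    w_obs = post[group_idx]                               # (n_obs, K)
    grad_beta = -X.T @ (w_obs * resid).sum(axis=1) + 2.0 * ridge * beta
    value = -float(li.sum()) + ridge * float(beta @ beta)
    if fix_sigma is None:
        resid_group = np.zeros_like(per_group)
        np.add.at(resid_group, group_idx, resid)
        grad_logsigma = -float((post * resid_group * b[None, :]).sum())
        return value, np.concatenate([grad_beta, [grad_logsigma]])
    return value, grad_beta


def fit_random_intercept_logit(y, X, groups, param_names=None,
                               n_quadrature: int = 25,
                               fix_sigma: float | None = None,
                               ) -> GlmmResult:
    """Fit the random-intercept logistic model.

    Parameters
    ----------
    y : (n_obs,) 0/1 outcomes.
    X : (n_obs, p) fixed-effects design (include the intercept column).
    groups : (n_obs,) patient labels tying observations together.
    fix_sigma : fix the random-intercept SD (0 -> plain logistic).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    codes, _ = pd.factorize(np.asarray(groups))
    n_groups = int(codes.max()) + 1
    nodes, weights = np.polynomial.hermite.hermgauss(n_quadrature)
    if param_names is None:
        param_names = [f"x{i}" for i in range(X.shape[1])]

    def make_args(ridge: float):
        return (y, X, codes, n_groups, nodes, weights, fix_sigma, ridge)

    start_beta = np.zeros(X.shape[1])
    theta0 = (start_beta if fix_sigma is not None
              else np.concatenate([start_beta, [np.log(0.5)]]))

    # log sigma is bounded to keep exp() finite; the lower bound is an
    # effective sigma = 0 (well below any resolvable variance)
    bounds = [(None, None)] * X.shape[1]
    if fix_sigma is None:
        bounds = bounds + [(-12.0, 3.0)]
    res = optimize.minimize(_negloglik_grad, theta0, args=make_args(0.0),
                            jac=True, method="L-BFGS-B", bounds=bounds,
                            options={"gtol": 1e-9, "ftol": 1e-13,
                                     "maxiter": 1000})
    penalized = False
    if np.max(np.abs(res.x[:X.shape[1]])) > _SEPARATION_BOUND:
        penalized = True
        res = optimize.minimize(_negloglik_grad, theta0, args=make_args(_RIDGE),
                                jac=True, method="L-BFGS-B", bounds=bounds,
                                options={"gtol": 1e-9, "ftol": 1e-13,
                                         "maxiter": 1000})

    theta = res.x
    hess = numdiff.approx_hess(theta, _negloglik,
                               args=make_args(_RIDGE if penalized else 0.0))
    p = X.shape[1]
    at_boundary = fix_sigma is None and theta[-1] <= -11.0
    if at_boundary:
        # sigma pinned at (effectively) zero: the log-sigma direction is
        # flat, so invert the fixed-effects block only
        hess = hess[:p, :p]
    try:
        cov = np.linalg.inv(hess)
        diag = np.diag(cov)
        se_all = np.sqrt(np.clip(diag, 0.0, None))
        if not np.isfinite(se_all).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        se_all = np.full(p if at_boundary else theta.shape[0], np.nan)
    if at_boundary:
        se_all = np.concatenate([se_all, [np.nan]])

    if fix_sigma is None:
        beta, sigma = theta[:-1], float(np.exp(theta[-1]))
        bse = se_all[:-1]
    else:
        beta, sigma = theta, fix_sigma
        bse = se_all

    params = pd.Series(beta, index=param_names)
    bse_s = pd.Series(bse, index=param_names)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse_s
    p = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=param_names)
    return GlmmResult(
        params=params, bse=bse_s, z_values=z, p_values=p,
        random_intercept_sd=sigma,
        loglik=-_negloglik(theta, *make_args(0.0)),
        n_patients=n_groups, n_obs=len(y), converged=bool(res.success),
        penalized=penalized, param_names=list(param_names))


def glmm_antimycotics(outcomes: pd.DataFrame,
                      fix_sigma: float | None = None) -> GlmmResult:
    """Group-by-time random-intercept logistic model on antimycotic outcomes.

    ``outcomes`` is the per-patient frame from
    :func:`pharmacohort.antimycotic.antimycotic_outcomes`; each patient
    contributes a before and an after observation. The headline contrast is
    the time-by-group interaction (did the change over time differ between
    intervention and control?).
    """
    long = pd.concat([
        pd.DataFrame({"patient_id": outcomes["patient_id"],
                      "group": outcomes["group"], "time": 0,
                      "y": outcomes["antimycotic_before"]}),
        pd.DataFrame({"patient_id": outcomes["patient_id"],
                      "group": outcomes["group"], "time": 1,
                      "y": outcomes["antimycotic_after"]}),
    ], ignore_index=True)
    g = (long["group"] == "sara").astype(float)
    t = long["time"].astype(float)
    X = np.column_stack([np.ones(len(long)), g, t, g * t])
    names = ["intercept", "group[sara]", "time[after]", "group[sara]:time[after]"]
    return fit_random_intercept_logit(long["y"].to_numpy(), X,
                                      long["patient_id"].to_numpy(),
                                      param_names=names,
                                      fix_sigma=fix_sigma)
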