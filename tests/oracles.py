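"""Independent reference computations used only by the tests.

These deliberately avoid the package's own algorithms: the PDC oracle
scans days one by one instead of merging intervals, and the mixed-model
oracle evaluates the integrated likelihood by trapezoid quadrature and
maximizes it by iterated grid refinement instead of gradient-based
optimization of a Gauss-Hermite approximation.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def glmm_loglik_trapezoid(beta, sigma, y, X, group_idx, n_groups,
                          n_points: int = 801, span: float = 8.0) -> float:
    """Integrated log-likelihood with the random intercept integrated out
    by trapezoid quadrature over the standardized intercept t = b/sigma."""
    ll = _batch_loglik(np.asarray(beta, dtype=float)[None, :], float(sigma),
                       np.asarray(y), np.asarray(X, dtype=float),
                       np.asarray(group_idx), n_groups, n_points, span)
    return float(ll[0])


def _batch_loglik(betas: np.ndarray, sigma: float, y, X, group_idx,
                  n_groups: int, n_points: int = 401,
                  span: float = 8.0) -> np.ndarray:
    """Log-likelihood for a (M, p) block of fixed-effect vectors at one
    sigma; returns shape (M,). Requires observations sorted by group."""
    group_idx = np.asarray(group_idx)
    if np.any(np.diff(group_idx) < 0):
        raise ValueError("observations must be sorted by group")
    boundaries = np.flatnonzero(np.r_[True, np.diff(group_idx) != 0])
    t = np.linspace(-span, span, n_points)
    log_phi = stats.norm.logpdf(t)
    dt = t[1] - t[0]
    eta = X @ betas.T                                    # (n_obs, M)
    lin = eta[:, :, None] + sigma * t[None, None, :]     # (n_obs, M, K)
    sign = np.where(np.asarray(y) == 1, -1.0, 1.0)[:, None, None]
    logp = -np.logaddexp(0.0, sign * lin)
    per_group = np.add.reduceat(logp, boundaries, axis=0)
    # trapezoid rule in log space: endpoints carry half weight
    logw = log_phi + np.log(dt)
    terms = per_group + logw[None, None, :]
    terms[..., 0] -= np.log(2.0)
    terms[..., -1] -= np.log(2.0)
    from scipy.special import logsumexp
    return logsumexp(terms, axis=2).sum(axis=0)


def glmm_grid_search(y, X, group_idx, n_groups, coarse_rounds: int = 5,
                     fine_rounds: int = 10, half_width: float = 3.0,
                     sigma_center: float = 2.0, sigma_half_width: float = 2.0,
                     n_points: int = 201, chunk: int = 1024):
    """Maximize the trapezoid likelihood by iterated joint grid refinement.

    Returns (beta_hat, sigma_hat, loglik). Each round lays a full grid
    over the fixed effects and sigma jointly (5 points per dimension in
    the coarse rounds, 3 in the fine rounds), keeps the best corner, and
    halves both half-widths; the final spacing is
    ~ half_width / 2**(coarse_rounds + fine_rounds - 1).
    """
    y = np.asarray(y)
    X = np.asarray(X, dtype=float)
    group_idx = np.asarray(group_idx)
    p = X.shape[1]
    center = np.zeros(p)
    w_beta = half_width
    s_center, w_sigma = sigma_center, sigma_half_width
    best = (-np.inf, center, s_center)
    schedule = [5] * coarse_rounds + [3] * fine_rounds
    for n_per_dim in schedule:
        axes = [np.linspace(c - w_beta, c + w_beta, n_per_dim)
                for c in center]
        combos = np.array(list(itertools.product(*axes)))
        sigma_axis = np.linspace(max(1e-3, s_center - w_sigma),
                                 s_center + w_sigma, n_per_dim)
        best_round = (-np.inf, None, None)
        for sigma in sigma_axis:
            for start in range(0, len(combos), chunk):
                block = combos[start:start + chunk]
                ll = _batch_loglik(block, float(sigma), y, X, group_idx,
                                   n_groups, n_points=n_points)
                k = int(np.argmax(ll))
                if ll[k] > best_round[0]:
                    best_round = (float(ll[k]), block[k], float(sigma))
        best = best_round
        _, center, s_center = best_round
        w_beta /= 2.0
        w_sigma /= 2.0
    return best[1], best[2], best[0]


def two_by_two_chi2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form Pearson chi-square for a 2x2 table [[a, b], [c, d]]."""
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def two_sample_power(delta: float, sd: float, n1: int, n2: int,
                     alpha: float = 0.05) -> float:
    """Closed-form power of the two-sided pooled t test (normal limit)."""
    se = sd * np.sqrt(1.0 / n1 + 1.0 / n2)
    z = delta / se
    za = stats.norm.isf(alpha / 2.0)
    return float(stats.norm.sf(za - z) + stats.norm.cdf(-za - z))
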