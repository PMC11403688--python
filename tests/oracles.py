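"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's solver code paths: the graphical
lasso and penalized Cox objectives are optimized by scipy's L-BFGS-B on a
smooth positive/negative-part splitting of the L1 term, and the Cox partial
likelihood is evaluated by direct risk-set summation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def glasso_oracle(S: np.ndarray, rho: float, penalize_diagonal: bool = True):
    """Maximize log det(T) - tr(S T) - rho ||T||_1 by bound-constrained
    quasi-Newton on T = P - N with P, N >= 0 (upper triangle as variables).

    Returns (theta, objective_value).
    """
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    iu = np.triu_indices(p)
    m = len(iu[0])
    is_diag = iu[0] == iu[1]
    sym_mult = np.where(is_diag, 1.0, 2.0)  # off-diagonals appear twice
    pen = sym_mult * rho * (1.0 if penalize_diagonal else ~is_diag)
    if not penalize_diagonal:
        pen = np.where(is_diag, 0.0, 2.0 * rho)

    def build(vec):
        T = np.zeros((p, p))
        T[iu] = vec
        return T + T.T - np.diag(np.diag(T))

    def fobj(x):
        pos, neg = x[:m], x[m:]
        T = build(pos - neg)
        try:
            np.linalg.cholesky(T)
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)
        _, logdet = np.linalg.slogdet(T)
        W = np.linalg.inv(T)
        f = -logdet + np.trace(S @ T) + pen @ (pos + neg)
        gvec = (S - W)[iu] * sym_mult
        return f, np.concatenate([gvec + pen, -gvec + pen])

    init = np.linalg.inv(S + (rho + 0.1) * np.eye(p))
    v = init[iu]
    x0 = np.concatenate([np.maximum(v, 0), np.maximum(-v, 0)])
    res = minimize(
        fobj, x0, jac=True, method="L-BFGS-B", bounds=[(0, None)] * (2 * m),
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    theta = build(res.x[:m] - res.x[m:])
    return theta, -res.fun


def cox_pll_brute(beta, X, time, event):
    """Breslow partial log-likelihood by direct term-by-term summation."""
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            ll += eta[i] - logsumexp(eta[risk])
    return ll


def cox_pll_grad_brute(beta, X, time, event):
    X = np.asarray(X, dtype=float)
    eta = X @ np.asarray(beta, dtype=float)
    g = np.zeros(X.shape[1])
    for i in range(len(time)):
        if event[i] == 1:
            risk = time >= time[i]
            w = np.exp(eta[risk])
            g += X[i] - (w @ X[risk]) / w.sum()
    return g


def cox_lasso_oracle(X, time, event, lam):
    """Maximize pll(beta) - lam ||beta||_1 via L-BFGS-B on beta = P - N.

    Returns (beta, objective_value).
    """
    X = np.asarray(X, dtype=float)
    p = X.shape[1]

    def fobj(x):
        beta = x[:p] - x[p:]
        f = -cox_pll_brute(beta, X, time, event) + lam * (x[:p] + x[p:]).sum()
        g = -cox_pll_grad_brute(beta, X, time, event)
        return f, np.concatenate([g + lam, -g + lam])

    res = minimize(
        fobj, np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options={"maxiter": 5000, "ftol": 1e-16, "gtol": 1e-12},
    )
    return res.x[:p] - res.x[p:], -res.fun


def km_hand(time, event):
    """Product-limit estimator computed directly from its definition."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    times = np.unique(time[event == 1])
    surv = []
    s = 1.0
    for t in times:
        n_at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / n_at_risk
        surv.append((t, s))
    return surv


def logrank_hand(time, event, groups):
    """Two-group log-rank chi-square from direct O/E/V summation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    assert len(levels) == 2
    g1 = groups == levels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2
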