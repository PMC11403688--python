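"""Penalized Cox survival modeling and density-based risk stratification.

The Cox proportional-hazards model h(t|x) = h0(t) exp(x beta) is fitted by
maximizing the lasso-penalized partial log-likelihood

    sum_{i: event} [ x_i beta - log sum_{j: Y_j >= Y_i} exp(x_j beta) ]
        - lambda ||beta||_1

(Breslow convention for ties; the baseline hazard h0 cancels and is never
estimated). The active-set size along the lambda path is capped by the
10-events-per-variable rule, pmax = ceil(events / 10). Each sample's
prognostic index PI = x beta-hat is thresholded at the local minimum of a
kernel density estimate between the two main modes of the PI distribution
(falling back to the median when unimodal) to form high-risk (HR) and
low-risk (LR) groups, compared by Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats


@dataclass
class SurvivalData:
    time: np.ndarray
    event: np.ndarray
    X: pd.DataFrame  # samples x features, aligned with time/event

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if (self.time < 0).any():
            raise ValueError("survival times must be nonnegative")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if len(self.time) != len(self.event) or len(self.time) != len(self.X):
            raise ValueError("inconsistent lengths")

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class CoxModel:
    beta: pd.Series  # per-gene coefficients on the original feature scale
    lam: float
    pmax: int | None = None
    converged: bool = True

    @property
    def active_set(self) -> list[str]:
        return list(self.beta.index[self.beta != 0.0])

    def to_json_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "pmax": self.pmax,
            "coefficients": {g: float(b) for g, b in self.beta.items() if b != 0.0},
        }


@dataclass
class RiskStratification:
    PI: pd.Series
    threshold: float
    group: pd.Series  # "HR" / "LR" per sample

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"PI": self.PI, "group": self.group}).rename_axis("sample_id")


@dataclass
class SurvivalCurves:
    curves: dict[str, pd.DataFrame]  # group -> columns time, survival, at_risk


@dataclass
class LogRankResult:
    statistic: float
    p_value: float
    df: int = 1
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compute_pmax(n_events: int) -> int:
    """10-events-per-variable cap on model size: ceil(events / 10)."""
    if n_events < 1:
        raise ValueError("need at least one event")
    return math.ceil(n_events / 10)


def _risk_set_quantities(time: np.ndarray, event: np.ndarray, eta: np.ndarray):
    """Breslow risk-set sums needed by the partial likelihood and its
    derivatives, computed over unique event times."""
    order = np.argsort(time, kind="stable")
    t_s, e_s, eta_s = time[order], event[order], eta[order]
    exp_s = np.exp(eta_s)
    # reverse cumulative sum: denominator of the risk set at each sorted time
    rev_cum = np.cumsum(exp_s[::-1])[::-1]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    denom_at_sample = rev_cum[first_idx]  # sum over {j: Y_j >= Y_i}
    return order, t_s, e_s, exp_s, denom_at_sample


def cox_partial_loglik(beta: np.ndarray, data: SurvivalData) -> float:
    """Breslow partial log-likelihood at beta (full scale, no penalty)."""
    if data.n_events == 0:
        raise ValueError("no events")
    eta = data.X.to_numpy(dtype=float) @ np.asarray(beta, dtype=float)
    _, _, e_s, _, denom = _risk_set_quantities(data.time, data.event, eta)
    order = np.argsort(data.time, kind="stable")
    eta_s = eta[order]
    mask = e_s == 1
    return float(np.sum(eta_s[mask] - np.log(denom[mask])))


def cox_penalized_loglik(beta: np.ndarray, data: SurvivalData, lam: float) -> float:
    """Partial log-likelihood minus lambda * ||beta||_1."""
    return cox_partial_loglik(beta, data) - lam * np.abs(np.asarray(beta)).sum()


def _pll_grad_hess(time, event, X, beta):
    """Gradient and diagonal-Hessian (Breslow) of the partial log-likelihood
    with respect to the linear predictor eta, mapped back through X."""
    n = len(time)
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    inv_order = np.empty(n, dtype=int)
    inv_order[order] = np.arange(n)
    t_s, e_s = time[order], event[order]
    exp_s = np.exp(eta[order])
    rev_cum = np.cumsum(exp_s[::-1])[::-1]
    first_idx = np.searchsorted(t_s, t_s, side="left")
    denom = rev_cum[first_idx]
    # for each sample i: A_i = sum over event times t_k <= Y_i of d_k / D_k
    #                    B_i = sum of d_k / D_k^2
    inc_a = np.where(e_s == 1, 1.0 / denom, 0.0)
    inc_b = np.where(e_s == 1, 1.0 / denom**2, 0.0)
    # events at the same time share first_idx/denominator, so cumulative sums
    # over sorted order accumulate d_k/D_k correctly
    ca, cb = np.cumsum(inc_a), np.cumsum(inc_b)
    # sample i (sorted position s) is in the risk set of all event times with
    # t_k <= t_s; take the cumulative sum at the last position with equal time
    last_idx = np.searchsorted(t_s, t_s, side="right") - 1
    A = ca[last_idx]
    B = cb[last_idx]
    mu = exp_s * A
    w = mu - exp_s**2 * B
    g_eta = e_s - mu
    g_eta_orig = g_eta[inv_order]
    w_orig = np.maximum(w[inv_order], 1e-10)
    return eta, g_eta_orig, w_orig


def cox_lambda_max(data: SurvivalData, standardize: bool = True) -> float:
    """Smallest lambda at which the penalized solution is exactly zero."""
    X, _, scale = _prepare_design(data, standardize)
    _, g, _ = _pll_grad_hess(data.time, data.event, X, np.zeros(X.shape[1]))
    return float(np.max(np.abs(X.T @ g)))


def _prepare_design(data: SurvivalData, standardize: bool):
    X = data.X.to_numpy(dtype=float)
    center = X.mean(axis=0)
    Xc = X - center
    if standardize:
        scale = Xc.std(axis=0, ddof=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(X.shape[1])
    return Xc / scale, center, scale


def _cox_cd_fit(time, event, X, lam, beta0, max_outer=100, tol=1e-7):
    """Newton coordinate descent for the lasso-penalized Cox model.

    Outer loop: quadratic (IRLS) approximation of the partial likelihood at
    the current linear predictor; inner loop: cyclic coordinate descent with
    soft-thresholding on the penalized weighted least squares problem.
    """
    n, p = X.shape
    beta = beta0.copy()
    for _ in range(max_outer):
        beta_prev = beta.copy()
        eta, g, w = _pll_grad_hess(time, event, X, beta)
        z = eta + g / w  # working response
        r = z - eta  # working residual
        wx2 = (w[:, None] * X**2).sum(axis=0)
        inner_tol = tol * 1e-2

        def sweep(indices) -> float:
            nonlocal r
            max_delta = 0.0
            for k in indices:
                num = X[:, k] @ (w * r) + wx2[k] * beta[k]
                new = np.sign(num) * max(abs(num) - lam, 0.0) / wx2[k]
                d = new - beta[k]
                if d != 0.0:
                    r -= X[:, k] * d
                    beta[k] = new
                    max_delta = max(max_delta, abs(d))
            return max_delta

        # glmnet-style: full sweeps interleaved with active-set iterations
        for _ in range(200):
            if sweep(range(p)) < inner_tol:
                break
            active = np.flatnonzero(beta)
            for _ in range(1000):
                if sweep(active) < inner_tol:
                    break
        # outer convergence: change in coefficients across the Newton step
        if np.max(np.abs(beta - beta_prev)) < tol:
            break
    return beta


def cox_lasso_path(
    data: SurvivalData,
    lambda_grid: np.ndarray | None = None,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 0.01,
    standardize: bool = True,
) -> list[CoxModel]:
    """Warm-started lasso path for the penalized Cox model.

    The grid descends log-linearly from lambda_max (smallest penalty with an
    all-zero solution) to ``lambda_min_ratio * lambda_max`` unless an
    explicit descending grid is given. Features are standardized internally;
    coefficients are returned on the original scale.
    """
    if data.n_events == 0:
        raise ValueError("at least one event required")
    Xs, _, scale = _prepare_design(data, standardize)
    lam_max = cox_lambda_max(data, standardize)
    if lambda_grid is None:
        lambda_grid = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambdas)
    else:
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        if np.any(np.diff(lambda_grid) > 0):
            raise ValueError("lambda_grid must be descending")
    models = []
    beta = np.zeros(Xs.shape[1])
    for lam in lambda_grid:
        if lam >= lam_max - 1e-12:
            beta = np.zeros(Xs.shape[1])
        else:
            beta = _cox_cd_fit(data.time, data.event, Xs, lam, beta)
        beta_orig = beta / scale
        models.append(
            CoxModel(beta=pd.Series(beta_orig, index=data.X.columns), lam=float(lam))
        )
    return models


def cox_kkt_residual(model: CoxModel, data: SurvivalData, standardize: bool = True) -> float:
    """Max-norm KKT violation of the penalized partial likelihood at a fit."""
    Xs, _, scale = _prepare_design(data, standardize)
    beta_std = model.beta.to_numpy() * scale
    _, g, _ = _pll_grad_hess(data.time, data.event, Xs, beta_std)
    grad = Xs.T @ g
    res = 0.0
    for k, b in enumerate(beta_std):
        if abs(b) > 1e-12:
            res = max(res, abs(grad[k] - model.lam * np.sign(b)))
        else:
            res = max(res, max(abs(grad[k]) - model.lam, 0.0))
    return res


def select_model(path: list[CoxModel], pmax: int) -> CoxModel:
    """Densest model on the path whose active set does not exceed pmax.

    Equivalently, the model at the smallest lambda with |active| <= pmax.
    The all-zero model at lambda_max always qualifies.
    """
    if not path:
        raise ValueError("empty path")
    if pmax == 0:
        warnings.warn("pmax = 0 selects the null model", stacklevel=2)
    candidates = [m for m in path if len(m.active_set) <= pmax]
    if not candidates:
        # the path should start at lambda_max with the empty model
        candidates = [min(path, key=lambda m: len(m.active_set))]
    chosen = min(candidates, key=lambda m: m.lam)
    chosen.pmax = pmax
    return chosen


def prognostic_index(X: pd.DataFrame, model: CoxModel) -> pd.Series:
    """PI_i = x_i beta-hat (linear predictor on the original feature scale)."""
    missing = [g for g in model.beta.index if g not in X.columns]
    if missing:
        raise ValueError(f"features missing from X: {missing[:5]}")
    pi = X[model.beta.index].to_numpy(dtype=float) @ model.beta.to_numpy()
    return pd.Series(pi, index=X.index, name="PI")


def kde_threshold(PI: pd.Series | np.ndarray) -> float:
    """Density-minimum stratification threshold for the prognostic index.

    Gaussian KDE with the rule-of-thumb bandwidth
    0.9 min(sd, IQR/1.34) n^{-1/5} on a 512-point grid spanning the data
    plus/minus 3 bandwidths. If the density has at least two local maxima
    of non-negligible height (>= 5% of the global maximum, which screens
    out stray single-sample bumps in the tails), the threshold is the
    argmin of the density between the two highest such maxima; otherwise
    (unimodal PI) the median.
    """
    x = np.asarray(PI, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples")
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    if sd == 0:
        raise ValueError("constant prognostic index")
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * len(x) ** (-0.2)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / h) ** 2).sum(axis=1)
    dens /= len(x) * h * np.sqrt(2 * np.pi)
    interior = np.arange(1, 510)
    is_max = (dens[interior] > dens[interior - 1]) & (dens[interior] >= dens[interior + 1])
    maxima = interior[is_max]
    maxima = maxima[dens[maxima] >= 0.05 * dens.max()]
    if len(maxima) < 2:
        return float(np.median(x))
    top_two = maxima[np.argsort(dens[maxima])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    between = np.arange(lo + 1, hi)
    if len(between) == 0:
        return float(np.median(x))
    k = between[np.argmin(dens[between])]
    return float(grid[k])


def stratify(PI: pd.Series, threshold: float) -> RiskStratification:
    """LR iff PI <= threshold, HR otherwise."""
    group = pd.Series(np.where(PI <= threshold, "LR", "HR"), index=PI.index, name="group")
    return RiskStratification(PI, float(threshold), group)


def km_estimate(data: SurvivalData, groups: pd.Series | np.ndarray) -> SurvivalCurves:
    """Product-limit (Kaplan-Meier) survival curves per group."""
    groups = np.asarray(groups)
    curves = {}
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(data.time[mask], data.event[mask])
        table = kmf.event_table
        curves[str(g)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )
    return SurvivalCurves(curves)


def logrank_test(data: SurvivalData, groups: pd.Series | np.ndarray) -> LogRankResult:
    """Two-group log-rank chi-square test (1 df)."""
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    m0, m1 = groups == levels[0], groups == levels[1]
    if m0.sum() == 0 or m1.sum() == 0:
        raise ValueError("both groups must be nonempty")
    res = _lifelines_logrank(
        data.time[m0], data.time[m1], data.event[m0], data.event[m1]
    )
    return LogRankResult(float(res.test_statistic), float(res.p_value))
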