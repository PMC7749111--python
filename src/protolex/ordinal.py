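"""Cumulative-link (proportional-odds) ordinal regression by maximum likelihood.

The latent-variable view: a rating Y falls in category k when a logistic
latent utility crosses the cutpoints, P(Y <= k) = logistic(tau_k - x'beta),
with strictly increasing cutpoints tau_1 < ... < tau_{K-1}.  ``fit_clm``
maximizes the fixed-effects likelihood with an analytic gradient;
``fit_clmm`` adds a Gaussian random intercept per participant, integrated
out by adaptive Gauss-Hermite quadrature.  Both report AIC for model
comparison (the random-intercept variance counts as one parameter).

Cutpoints are reparameterized during optimization as tau_1 plus positive
(log-transformed) increments, which keeps them ordered without constraints.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp, roots_hermite

__all__ = ["FitResult", "build_design", "fit_clm", "fit_clmm", "compare_by_aic",
           "predict_probs", "OrdinalFitError"]

_GTOL = 1e-6
_P_FLOOR = 1e-300


class OrdinalFitError(RuntimeError):
    """Rank deficiency or failure to converge, with diagnostics."""


@dataclass
class FitResult:
    """Coefficients, cutpoints and fit statistics of an ordinal model."""

    coefficients: dict[str, float]
    cutpoints: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_obs: int
    n_params: int
    sigma: float | None = None  # random-intercept sd (mixed fits)
    boundary: bool = False  # variance collapsed to (near) zero
    se: dict[str, float] = field(default_factory=dict)
    categories: tuple = ()
    response_hash: str = ""
    loglik_trace: list = field(default_factory=list)

    def slope(self, numeric_term: str, level_term: str | None = None) -> float:
        """Per-level slope: main slope plus, if given, its interaction contrast."""
        s = self.coefficients[numeric_term]
        if level_term is not None and level_term in self.coefficients:
            s += self.coefficients[level_term]
        return s


# ---------------------------------------------------------------------------
# design matrices


def _single_term(df: pd.DataFrame, term: str) -> tuple[np.ndarray, list[str]]:
    col = df[term]
    if pd.api.types.is_numeric_dtype(col) and not isinstance(col.dtype, pd.CategoricalDtype):
        return np.asarray(col, dtype=float)[:, None], [term]
    if isinstance(col.dtype, pd.CategoricalDtype):
        levels = list(col.cat.categories)
    else:
        levels = sorted(pd.unique(col.astype(str)))
        col = col.astype(str)
    mats, names = [], []
    for lvl in levels[1:]:  # treatment coding; first level is the reference
        mats.append((np.asarray(col) == lvl).astype(float)[:, None])
        names.append(f"{term}[T.{lvl}]")
    if not mats:
        raise OrdinalFitError(f"categorical term {term!r} has a single level")
    return np.hstack(mats), names


def build_design(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for the fixed effects (no intercept; cutpoints absorb it).

    Terms are column names; categorical columns expand to treatment-coded
    dummies against their first level; ``a:b`` denotes the interaction
    (elementwise products of the two expansions).
    """
    mats, names = [], []
    for term in terms:
        if ":" in term:
            left, right = term.split(":", 1)
            ml, nl = _single_term(df, left)
            mr, nr = _single_term(df, right)
            for i, ni in enumerate(nl):
                for j, nj in enumerate(nr):
                    mats.append((ml[:, i] * mr[:, j])[:, None])
                    names.append(f"{ni}:{nj}")
        else:
            m, n = _single_term(df, term)
            mats.append(m)
            names.extend(n)
    X = np.hstack(mats) if mats else np.empty((len(df), 0))
    if X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        raise OrdinalFitError(
            f"design matrix is rank deficient (rank < {X.shape[1]} columns: {names})"
        )
    return X, names


def _encode_response(y: pd.Series) -> tuple[np.ndarray, list]:
    cats = sorted(pd.unique(y))
    if len(cats) < 2:
        raise OrdinalFitError("need at least two observed rating levels")
    idx = {c: i for i, c in enumerate(cats)}
    return np.array([idx[v] for v in y], dtype=np.intp), cats


def _response_hash(k: np.ndarray) -> str:
    return hashlib.sha256(k.astype(np.int64).tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# likelihood pieces


def _unpack(theta: np.ndarray, p: int, K: int):
    beta = theta[:p]
    a1 = theta[p]
    if K > 2:
        tau = np.concatenate(([a1], a1 + np.cumsum(np.exp(theta[p + 1 : p + K - 1]))))
    else:
        tau = np.array([a1])
    return beta, tau


def _start_values(k: np.ndarray, K: int, p: int) -> np.ndarray:
    """Deterministic start: beta = 0, cutpoints at marginal cumulative logits."""
    props = np.bincount(k, minlength=K) / k.size
    cum = np.clip(np.cumsum(props)[:-1], 1e-6, 1 - 1e-6)
    tau0 = np.log(cum / (1 - cum))
    # enforce strict increase before taking log-diffs
    for j in range(1, tau0.size):
        tau0[j] = max(tau0[j], tau0[j - 1] + 1e-3)
    theta0 = np.zeros(p + K - 1)
    theta0[p] = tau0[0]
    if K > 2:
        theta0[p + 1 :] = np.log(np.diff(tau0))
    return theta0


def _clm_nll_grad(theta, X, k, K):
    n, p = X.shape
    beta, tau = _unpack(theta, p, K)
    eta = X @ beta if p else np.zeros(n)
    tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
    u_hi = tau_ext[k + 1] - eta
    u_lo = tau_ext[k] - eta
    F_hi = expit(u_hi)
    F_lo = expit(u_lo)
    prob = np.maximum(F_hi - F_lo, _P_FLOOR)
    nll = -np.log(prob).sum()
    f_hi = np.where(np.isfinite(u_hi), F_hi * (1 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(u_lo), F_lo * (1 - F_lo), 0.0)
    dll_deta = -(f_hi - f_lo) / prob
    grad = np.empty_like(theta)
    grad[:p] = -(X.T @ dll_deta)
    # cutpoint gradient: y=k contributes +f_hi/p at tau_{k+1}, -f_lo/p at tau_k
    gtau = np.bincount(k + 1, weights=f_hi / prob, minlength=K + 1)[1:K] - np.bincount(
        k, weights=f_lo / prob, minlength=K + 1
    )[1:K]
    grad[p] = -gtau.sum()
    if K > 2:
        d = np.exp(theta[p + 1 : p + K - 1])
        # tau_j depends on increment m for all j >= m (1-based increments)
        tail = np.cumsum(gtau[::-1])[::-1]
        grad[p + 1 :] = -(d * tail[1:])
    return nll, grad


def fit_clm(
    table: pd.DataFrame,
    terms: list[str],
    response: str = "rating",
) -> FitResult:
    """Maximum-likelihood proportional-odds fit with analytic gradients.

    Starts from beta = 0 and cutpoints at the marginal cumulative logits and
    runs BFGS to a gradient norm below 1e-6 (a small residual norm is
    tolerated when the line search stalls at numerical precision).
    """
    X, names = build_design(table, terms)
    k, cats = _encode_response(table[response])
    K = len(cats)
    n, p = X.shape
    theta0 = _start_values(k, K, p)
    trace: list[float] = []

    def fun(th):
        # optimize the per-observation mean so the gradient tolerance is
        # scale-free in n
        nll, g = _clm_nll_grad(th, X, k, K)
        return nll / n, g / n

    res = optimize.minimize(
        fun, theta0, jac=True, method="BFGS",
        options={"gtol": _GTOL, "maxiter": 1000},
        callback=lambda th: trace.append(-fun(th)[0] * n),
    )
    gnorm = float(np.max(np.abs(res.jac)))
    converged = bool(res.success or gnorm < 1e-4)
    if not converged:
        raise OrdinalFitError(
            f"CLM did not converge: {res.message}; |grad|_inf = {gnorm:.3g}, "
            f"nit = {res.nit}, n = {n}, p = {p}"
        )
    beta, tau = _unpack(res.x, p, K)
    loglik = -float(res.fun) * n
    n_params = p + K - 1
    se = _beta_se(lambda th: _clm_nll_grad(th, X, k, K)[1], res.x, p, names)
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        cutpoints=tau,
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        converged=converged,
        n_obs=n,
        n_params=n_params,
        se=se,
        categories=tuple(cats),
        response_hash=_response_hash(k),
        loglik_trace=trace,
    )


def _beta_se(grad_fn, theta_hat, p: int, names: list[str]) -> dict[str, float]:
    """Standard errors of the regression coefficients from the observed information."""
    if p == 0:
        return {}
    m = theta_hat.size
    H = np.empty((m, m))
    h = 1e-5 * np.maximum(1.0, np.abs(theta_hat))
    for j in range(m):
        step = np.zeros(m)
        step[j] = h[j]
        H[:, j] = (grad_fn(theta_hat + step) - grad_fn(theta_hat - step)) / (2 * h[j])
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        return {nm: float(np.sqrt(max(cov[i, i], 0.0))) for i, nm in enumerate(names)}
    except np.linalg.LinAlgError:
        return {}


def predict_probs(fit: FitResult, table: pd.DataFrame, terms: list[str]) -> np.ndarray:
    """Category probabilities per row (fixed effects; random intercept at 0)."""
    X, names = build_design(table, terms)
    beta = np.array([fit.coefficients[n] for n in names])
    eta = X @ beta
    tau_ext = np.concatenate(([-np.inf], fit.cutpoints, [np.inf]))
    cum = expit(tau_ext[None, :] - eta[:, None])
    return np.diff(cum, axis=1)


# ---------------------------------------------------------------------------
# mixed model: random intercept by adaptive Gauss-Hermite quadrature


def _logp_terms(alpha_row, eta, tau_ext, k):
    """log P(y_k | eta + alpha) and its first/second derivatives w.r.t. alpha."""
    u_hi = tau_ext[k + 1] - eta - alpha_row
    u_lo = tau_ext[k] - eta - alpha_row
    F_hi, F_lo = expit(u_hi), expit(u_lo)
    prob = np.maximum(F_hi - F_lo, _P_FLOOR)
    f_hi = np.where(np.isfinite(u_hi), F_hi * (1 - F_hi), 0.0)
    f_lo = np.where(np.isfinite(u_lo), F_lo * (1 - F_lo), 0.0)
    logp = np.log(prob)
    d1 = (f_lo - f_hi) / prob
    fp_hi = np.where(np.isfinite(u_hi), f_hi * (1 - 2 * F_hi), 0.0)
    fp_lo = np.where(np.isfinite(u_lo), f_lo * (1 - 2 * F_lo), 0.0)
    d2 = (fp_hi - fp_lo) / prob - d1 * d1
    return logp, d1, d2


def _clmm_nll(theta, X, k, K, group, n_groups, quad, alpha_state):
    p = X.shape[1]
    beta, tau = _unpack(theta[:-1], p, K)
    log_sigma = theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta if p else np.zeros(X.shape[0])
    tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
    inv_s2 = 1.0 / (sigma * sigma)

    # inner Newton for the per-group posterior modes (warm-started)
    alpha = alpha_state["alpha"]
    for _ in range(100):
        _, d1, d2 = _logp_terms(alpha[group], eta, tau_ext, k)
        g = np.bincount(group, weights=d1, minlength=n_groups) - alpha * inv_s2
        h = np.bincount(group, weights=d2, minlength=n_groups) - inv_s2
        step = g / h
        np.clip(step, -5.0, 5.0, out=step)
        alpha = alpha - step
        if np.max(np.abs(g)) < 1e-10:
            break
    alpha_state["alpha"] = alpha

    _, _, d2 = _logp_terms(alpha[group], eta, tau_ext, k)
    h = np.bincount(group, weights=d2, minlength=n_groups) - inv_s2
    s = 1.0 / np.sqrt(-h)

    nodes, logw = quad
    # h(alpha) evaluated at the shifted, scaled quadrature nodes
    vals = np.empty((nodes.size, n_groups))
    log_phi_const = -0.5 * np.log(2 * np.pi) - log_sigma
    for j, x in enumerate(nodes):
        a_g = alpha + np.sqrt(2.0) * s * x
        logp, _, _ = _logp_terms(a_g[group], eta, tau_ext, k)
        sum_logp = np.bincount(group, weights=logp, minlength=n_groups)
        vals[j] = (
            logw[j] + x * x + sum_logp - 0.5 * a_g * a_g * inv_s2 + log_phi_const
        )
    ll_groups = logsumexp(vals, axis=0) + 0.5 * np.log(2.0) + np.log(s)
    return -float(ll_groups.sum())


def fit_clmm(
    table: pd.DataFrame,
    terms: list[str],
    group_col: str = "participant_id",
    response: str = "rating",
    n_quad: int = 15,
) -> FitResult:
    """Proportional-odds model with a Gaussian random intercept per group.

    The random intercept is integrated out by adaptive Gauss-Hermite
    quadrature (default 15 nodes): per likelihood evaluation the posterior
    mode of each group's intercept is found by Newton's method and the nodes
    are centered and scaled there.  Starts from the fixed-effects fit.  A
    variance that collapses to the lower bound is reported as a boundary fit
    (``boundary=True``), not an error; AIC counts the variance as one
    parameter.
    """
    X, names = build_design(table, terms)
    k, cats = _encode_response(table[response])
    K = len(cats)
    n, p = X.shape
    groups, group_idx = np.unique(np.asarray(table[group_col]), return_inverse=True)
    n_groups = groups.size
    if n_groups < 2:
        raise OrdinalFitError("mixed fit needs at least two grouping levels")

    base = fit_clm(table, terms, response=response)
    theta_fix = np.concatenate(
        (
            [base.coefficients[nm] for nm in names],
            [base.cutpoints[0]],
            np.log(np.maximum(np.diff(base.cutpoints), 1e-3)) if K > 2 else [],
        )
    )
    log_sigma0 = np.log(0.5)
    theta0 = np.concatenate((theta_fix, [log_sigma0]))

    x_nodes, w_nodes = roots_hermite(n_quad)
    quad = (x_nodes, np.log(w_nodes))
    alpha_state = {"alpha": np.zeros(n_groups)}
    trace: list[float] = []

    def fun(th):
        return _clmm_nll(th, X, k, K, group_idx, n_groups, quad, alpha_state) / n

    lb = np.log(1e-4)
    bounds = [(None, None)] * (theta0.size - 1) + [(lb, np.log(50.0))]
    res = optimize.minimize(
        fun, theta0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7},
        callback=lambda th: trace.append(-fun(th) * n),
    )
    if not (res.success or res.status == 1):
        raise OrdinalFitError(f"CLMM did not converge: {res.message}")
    beta, tau = _unpack(res.x[:-1], p, K)
    sigma = float(np.exp(res.x[-1]))
    boundary = res.x[-1] <= lb + 1e-6
    loglik = -float(res.fun) * n
    n_params = p + K - 1 + 1
    return FitResult(
        coefficients=dict(zip(names, beta.tolist())),
        cutpoints=tau,
        loglik=loglik,
        aic=2 * n_params - 2 * loglik,
        converged=True,
        n_obs=n,
        n_params=n_params,
        sigma=sigma,
        boundary=boundary,
        categories=tuple(cats),
        response_hash=_response_hash(k),
        loglik_trace=trace,
    )


def compare_by_aic(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Rank fits of the same response vector by ascending AIC with deltas."""
    items = list(fits.items())
    ref = items[0][1]
    for name, f in items[1:]:
        if f.n_obs != ref.n_obs or f.response_hash != ref.response_hash:
            raise ValueError(
                f"fit {name!r} was made on a different response vector; "
                "AIC is only comparable within one response"
            )
    df = pd.DataFrame(
        {
            "model": [nm for nm, _ in items],
            "aic": [f.aic for _, f in items],
            "loglik": [f.loglik for _, f in items],
            "n_params": [f.n_params for _, f in items],
        }
    ).sort_values("aic", kind="stable", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df
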