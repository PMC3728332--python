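"""Poisson generalized linear mixed model with crossed random intercepts.

The diel analysis models hourly detection counts y_i ~ Poisson(mu_i),

    log mu_i = x_i' beta + u_{day(i)} + v_{tag(i)},
    u_d ~ N(0, sigma_day^2),  v_t ~ N(0, sigma_tag^2),

with day and transmitter as crossed random factors.  The marginal
likelihood is integrated by the Laplace approximation: for candidate
variance parameters the joint penalized log-likelihood is maximized over
(beta, u, v) by Newton iterations (sparse in the random effects), and

    log L(theta) ~= l(y | beta_hat, b_hat) - 1/2 b_hat' D^-1 b_hat
                    - 1/2 log|D| - 1/2 log|Z' W Z + D^-1|

is maximized over theta = log sigma by Nelder-Mead.  Fixed-effect
standard errors come from the profiled Fisher information
[X'WX - X'WZ (Z'WZ + D^-1)^-1 Z'WX]^-1 at the optimum, the same
conditional information used by standard mixed-model software.

Setting the variance components to zero reduces the model exactly to a
Poisson GLM (the random effects collapse to zero and the penalty and
determinant terms vanish), which is used as a correctness check.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse as sp
import scipy.special
import scipy.stats

_MIN_SD = 1e-6
_MAX_LOG_SD = 5.0


class DegenerateDesignError(ValueError):
    """The fixed-effect design matrix is rank deficient."""


@dataclasses.dataclass
class PoissonGLMMResult:
    """Fitted model: coefficient table, variance components, diagnostics."""

    params: pd.DataFrame  # index: term; columns: estimate, se, z, p
    vc_sd: dict[str, float]  # random-effect standard deviations
    loglik: float  # Laplace-approximated marginal log-likelihood
    converged: bool
    n_obs: int
    n_groups: dict[str, int]
    random_effects: dict[str, pd.Series]
    fitted: np.ndarray  # conditional means mu_hat
    message: str = ""

    @property
    def pearson_residuals(self) -> np.ndarray:
        return getattr(self, "_pearson", np.array([]))

    def residual_quantiles(self, n: int = 99) -> pd.DataFrame:
        """Theoretical-vs-sample quantiles of Pearson residuals for a
        quantile-quantile diagnostic plot."""
        r = np.sort(self.pearson_residuals)
        probs = (np.arange(1, n + 1)) / (n + 1)
        return pd.DataFrame(
            {
                "theoretical": scipy.stats.norm.ppf(probs),
                "sample": np.quantile(r, probs),
            }
        )


def _design(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    groups: list[str],
) -> tuple[np.ndarray, np.ndarray, list[sp.csr_matrix], list[str], list[np.ndarray]]:
    y = np.asarray(data[response], dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    X = np.column_stack([np.ones(len(data))] + [np.asarray(data[f], float) for f in fixed])
    names = ["intercept"] + list(fixed)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DegenerateDesignError(
            "fixed-effect design is rank deficient (constant or collinear covariates)"
        )
    Zs, levels = [], []
    for g in groups:
        codes, levs = pd.factorize(data[g])
        Z = sp.csr_matrix(
            (np.ones(len(codes)), (np.arange(len(codes)), codes)),
            shape=(len(codes), len(levs)),
        )
        Zs.append(Z)
        levels.append(np.asarray(levs))
    return y, X, Zs, names, levels


def _penalized_newton(
    y: np.ndarray,
    X: np.ndarray,
    Z: sp.csr_matrix | None,
    d_inv: np.ndarray | None,
    beta0: np.ndarray,
    b0: np.ndarray | None,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, bool]:
    """Maximize the (penalized) Poisson log-likelihood jointly over
    (beta, b).  Returns (beta, b, W diagonal, converged)."""
    p = X.shape[1]
    beta = beta0.copy()
    b = None if Z is None else b0.copy()
    for _ in range(max_iter):
        eta = X @ beta + (Z @ b if Z is not None else 0.0)
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        gX = X.T @ (y - mu)
        if Z is not None:
            gZ = Z.T @ (y - mu) - d_inv * b
            grad = np.concatenate([gX, gZ])
        else:
            grad = gX
        if np.max(np.abs(grad)) < tol * (1 + np.abs(y).sum()):
            return beta, b, mu, True
        XtW = X.T * mu
        Hxx = XtW @ X
        if Z is not None:
            WZ = Z.multiply(mu[:, None]).tocsr()
            Hxz = np.asarray((WZ.T @ X).T)
            Hzz = (Z.T @ WZ).toarray() + np.diag(d_inv)
            H = np.block([[Hxx, Hxz], [Hxz.T, Hzz]])
            step = np.linalg.solve(H, grad)
            beta = beta + step[:p]
            b = b + step[p:]
        else:
            beta = beta + np.linalg.solve(Hxx, gX)
    eta = np.clip(X @ beta + (Z @ b if Z is not None else 0.0), -30, 30)
    return beta, b, np.exp(eta), False


def _poisson_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(np.maximum(mu, 1e-300)) - mu
                        - scipy.special.gammaln(y + 1.0)))


def fit_poisson_glmm(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    groups: list[str],
    fix_vc_sd: dict[str, float] | None = None,
    max_outer_iter: int = 200,
) -> PoissonGLMMResult:
    """Fit the Poisson mixed model by Laplace approximation.

    Parameters
    ----------
    data : one row per cell (e.g. per tag, day and hour) with the count
        response and numeric fixed-effect covariates.
    fixed : covariate column names; an intercept is always included.
    groups : grouping column names for the crossed random intercepts
        (typically ``["day", "tag_id"]``); requires >= 2 levels each.
    fix_vc_sd : optionally pin random-effect standard deviations, e.g.
        ``{"day": 0.0, "tag_id": 0.0}`` for the GLM limit.

    Non-convergence is reported in ``result.converged`` and
    ``result.message``; no silent fallback.
    """
    y, X, Zs, names, levels = _design(data, response, fixed, groups)
    for g, lev in zip(groups, levels):
        if len(lev) < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")
    qs = [Z.shape[1] for Z in Zs]
    Zfull = sp.hstack(Zs).tocsr()
    fix_vc_sd = fix_vc_sd or {}

    free = [g for g in groups if g not in fix_vc_sd]
    p = X.shape[1]

    def expand_sd(theta: np.ndarray) -> np.ndarray:
        sds = []
        it = iter(theta)
        for g in groups:
            sds.append(fix_vc_sd[g] if g in fix_vc_sd else float(np.exp(next(it))))
        return np.asarray(sds)

    state = {"beta": np.zeros(p), "b": np.zeros(sum(qs))}
    state["beta"][0] = np.log(max(y.mean(), 1e-3))

    def neg2_laplace(theta: np.ndarray) -> float:
        sds = expand_sd(theta)
        active = sds > _MIN_SD
        if not active.any():
            beta, _, mu, _ = _penalized_newton(y, X, None, None, state["beta"], None)
            state["beta"] = beta
            return -2.0 * _poisson_loglik(y, mu)
        d = np.concatenate([np.full(q, max(s, _MIN_SD) ** 2) for q, s in zip(qs, sds)])
        d_inv = 1.0 / d
        beta, b, mu, _ = _penalized_newton(
            y, X, Zfull, d_inv, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b
        WZ = Zfull.multiply(mu[:, None]).tocsr()
        H = (Zfull.T @ WZ).toarray() + np.diag(d_inv)
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0:
            return np.inf
        ll = (
            _poisson_loglik(y, mu)
            - 0.5 * float(b @ (d_inv * b))
            - 0.5 * float(np.sum(np.log(d)))
            - 0.5 * logdet_H
        )
        return -2.0 * ll

    if free:
        theta0 = np.full(len(free), np.log(0.5))
        opt = scipy.optimize.minimize(
            neg2_laplace,
            theta0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-4,
                "fatol": 1e-6,
                "maxiter": max_outer_iter * len(free),
            },
        )
        theta_hat = np.clip(opt.x, -_MAX_LOG_SD * 4, _MAX_LOG_SD)
        converged = bool(opt.success)
        message = opt.message
    else:
        theta_hat = np.array([])
        converged, message = True, "variance components fixed"
    final_neg2 = neg2_laplace(theta_hat)
    sds = expand_sd(theta_hat)
    beta, b, mu = state["beta"], state["b"], None

    # refit at optimum for final state and SEs
    active = sds > _MIN_SD
    if active.any():
        d = np.concatenate([np.full(q, max(s, _MIN_SD) ** 2) for q, s in zip(qs, sds)])
        d_inv = 1.0 / d
        beta, b, mu, inner_ok = _penalized_newton(y, X, Zfull, d_inv, beta, b)
        WZ = Zfull.multiply(mu[:, None]).tocsr()
        Hzz = (Zfull.T @ WZ).toarray() + np.diag(d_inv)
        Hxz = np.asarray((WZ.T @ X).T)
        Hxx = (X.T * mu) @ X
        V = np.linalg.inv(Hxx - Hxz @ np.linalg.solve(Hzz, Hxz.T))
    else:
        beta, _, mu, inner_ok = _penalized_newton(y, X, None, None, beta, None)
        b = np.zeros(sum(qs))
        V = np.linalg.inv((X.T * mu) @ X)
    converged = converged and inner_ok

    se = np.sqrt(np.maximum(np.diag(V), 0.0))
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
    params = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": pvals}, index=names
    )
    ranef = {}
    off = 0
    for g, q, lev in zip(groups, qs, levels):
        ranef[g] = pd.Series(b[off : off + q], index=lev, name=g)
        off += q
    result = PoissonGLMMResult(
        params=params,
        vc_sd={g: float(s) for g, s in zip(groups, sds)},
        loglik=-0.5 * final_neg2,
        converged=converged,
        n_obs=len(y),
        n_groups={g: int(q) for g, q in zip(groups, qs)},
        random_effects=ranef,
        fitted=mu,
        message=str(message),
    )
    result._pearson = (y - mu) / np.sqrt(np.maximum(mu, 1e-12))
    return result
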