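"""Closed-form block updates for B, V, intercepts, sigma^2 and thresholds.

Given the working-response matrix Z from the majorization step, weights
and loadings solve least-squares subproblems: B is an ordinary multivariate
regression (the Kronecker-structured normal equations reduce to a single
P x P solve because V'V = I), V is an orthogonal Procrustes problem solved
by SVD, and the intercepts are column means.  The residual variance and
the ordinal thresholds are maximum-likelihood updates on the observed data
with all other parameters fixed.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

logger = logging.getLogger(__name__)


def update_B(Phi, Ztil, V) -> np.ndarray:
    """B = (Phi'Phi)^{-1} Phi' Z~ V, the least-squares update of the weights.

    Minimizes ||Z~ - Phi B V'||^2 for orthonormal V: the vec-form normal
    equations (H'H)^{-1}H'z~ with H = V (x) Phi collapse to this matrix
    form since H'H = I_S (x) Phi'Phi.
    """
    Phi = np.asarray(Phi, dtype=float)
    PtP = Phi.T @ Phi
    cond = np.linalg.cond(PtP)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            "Phi'Phi is (near-)singular; remove collinear predictors"
        )
    return np.linalg.solve(PtP, Phi.T @ Ztil @ V)


def update_V(Phi, B, Ztil, S=None) -> np.ndarray:
    """Orthogonal Procrustes update of the loadings.

    With M = B'Phi'Z~ = P Delta Q', the minimizer of ||Z~ - Phi B V'||^2
    over V'V = I is V = Q_S P_S'.  The product q_s p_s' is invariant to a
    joint sign flip of the singular-vector pair, so the SVD's own
    deterministic output fixes the solution; under exact ties the first S
    pairs as returned are used.
    """
    M = np.asarray(B).T @ np.asarray(Phi).T @ np.asarray(Ztil)
    if S is None:
        S = M.shape[0]
    P, _, Qt = np.linalg.svd(M, full_matrices=False)
    return Qt[:S].T @ P[:, :S].T


def update_intercepts(Ztil, ordinal_mask) -> np.ndarray:
    """Column means of Z - Phi B V' for numeric/binary; 0 for ordinal."""
    m = np.asarray(Ztil).mean(axis=0)
    m = np.where(np.asarray(ordinal_mask, dtype=bool), 0.0, m)
    return m


def update_sigma2(Y_num, fitted_num) -> float:
    """sigma^2 = sum of squared numeric residuals / (N * R_N - 1).

    Residuals are taken against the *observed* numeric responses; when
    kappa* = 1/sigma^2 the numeric working responses equal the
    observations, so this coincides with the working-matrix recipe.
    """
    E = np.asarray(Y_num, dtype=float) - np.asarray(fitted_num, dtype=float)
    n_total = E.size
    return float((E**2).sum() / (n_total - 1))


def _threshold_nll_grad(u, y, theta, C):
    """NLL and gradient in the (t_1, log-gaps) parameterization."""
    t = np.empty(C - 1)
    t[0] = u[0]
    if C > 2:
        t[1:] = u[0] + np.cumsum(np.exp(u[1:]))
    tpad = np.concatenate([[-np.inf], t, [np.inf]])
    Fhi = expit(tpad[y] - theta)
    Flo = expit(tpad[y - 1] - theta)
    pi = np.maximum(Fhi - Flo, 1e-300)
    nll = -np.log(pi).sum()
    # d nll / d t_c: -f(t_c - theta)/pi for i with y=c, +f(t_c - theta)/pi for y=c+1
    fhi = Fhi * (1 - Fhi)
    flo = Flo * (1 - Flo)
    grad_t = np.zeros(C - 1)
    np.add.at(grad_t, np.clip(y - 1, 0, C - 2), np.where(y <= C - 1, -fhi / pi, 0.0))
    np.add.at(grad_t, np.clip(y - 2, 0, C - 2), np.where(y >= 2, flo / pi, 0.0))
    # chain rule to u: t_c = u0 + sum_{j<=c, j>=1} exp(u_j)
    grad_u = np.empty_like(u)
    grad_u[0] = grad_t.sum()
    if C > 2:
        # d t_c / d u_j = exp(u_j) for c >= j  (1-based gap index j)
        rev_cum = np.cumsum(grad_t[::-1])[::-1]
        grad_u[1:] = np.exp(u[1:]) * rev_cum[1:]
    return nll, grad_u


def thresholds_from_proportions(y, C) -> np.ndarray:
    """Logits of empirical cumulative proportions (ML thresholds at theta=0)."""
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y - 1, minlength=C).astype(float)
    cum = np.cumsum(counts)[:-1] / y.size
    cum = np.clip(cum, 1e-10, 1 - 1e-10)
    return np.log(cum / (1 - cum))


def update_thresholds(y, theta, C, current=None, tol=1e-8, max_iter=200) -> np.ndarray:
    """ML thresholds of the cumulative-logit likelihood with theta fixed.

    Optimized unconstrained in (t_1, log-gaps), which enforces strict
    ordering by construction.  Warm-started from ``current`` so the update
    can only improve the likelihood.
    """
    y = np.asarray(y, dtype=int)
    theta = np.asarray(theta, dtype=float)
    if current is None:
        current = thresholds_from_proportions(y, C)
    t0 = np.asarray(current, dtype=float)
    u0 = np.empty(C - 1)
    u0[0] = t0[0]
    if C > 2:
        u0[1:] = np.log(np.maximum(np.diff(t0), 1e-8))
    res = minimize(
        _threshold_nll_grad,
        u0,
        args=(y, theta, C),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
    )
    if not np.all(np.isfinite(res.x)):
        raise RuntimeError(f"threshold optimization diverged: {res.message}")
    # keep the better of warm start and optimizer output (L-BFGS-B descends
    # from u0, so this only guards against pathological line searches)
    f0, _ = _threshold_nll_grad(u0, y, theta, C)
    u = res.x if res.fun <= f0 else u0
    t = np.empty(C - 1)
    t[0] = u[0]
    if C > 2:
        t[1:] = u[0] + np.cumsum(np.exp(u[1:]))
    return t
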