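"""Mixed negative log-likelihood and quadratic-majorization working set.

Each response family contributes a per-element loss in the canonical
parameter theta_ir = m_r + phi_i' B v_r:

* numeric  — Gaussian: (y - theta)^2 / (2 sigma^2) + log(2 pi sigma^2)/2
* binary   — Bernoulli-logit: -log F(q theta), q = 2y - 1
* ordinal  — cumulative logit: -log [F(t_c - theta) - F(t_{c-1} - theta)]

All three are majorized by a quadratic with shared curvature
kappa* = max(1/4, 1/sigma^2), turning every update into least squares on
the working responses z = theta - xi / kappa*, where xi is the per-element
first derivative (for ordinal responses, its EM expectation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

logger = logging.getLogger(__name__)

PROB_FLOOR = 1e-300
SMALL_VARIANCE = 0.05


def logistic_cdf(eta):
    """Standard logistic cdf F(eta) = 1 / (1 + exp(-eta)), saturating safely."""
    return expit(eta)


@dataclass
class WorkingSet:
    """Derivatives Xi, curvature bound kappa*, working responses Z."""

    Xi: np.ndarray
    kappa: float
    Z: np.ndarray


def canonical_params(Phi, m, B, V) -> np.ndarray:
    """Theta = 1 m' + Phi B V' (intercepts are zero for ordinal columns)."""
    Phi = np.asarray(Phi, dtype=float)
    m = np.asarray(m, dtype=float)
    B = np.asarray(B, dtype=float)
    V = np.asarray(V, dtype=float)
    if Phi.shape[1] != B.shape[0] or B.shape[1] != V.shape[1] or V.shape[0] != m.size:
        raise ValueError(
            f"dimension mismatch: Phi {Phi.shape}, B {B.shape}, V {V.shape}, m {m.shape}"
        )
    return m[None, :] + Phi @ B @ V.T


def ordinal_category_probs(theta, thresholds) -> np.ndarray:
    """Category probabilities of the cumulative-logit model.

    ``theta`` scalar or length-N; returns (..., C) with C = len(t) + 1.
    """
    t = np.asarray(thresholds, dtype=float)
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    cum = np.concatenate(
        [np.zeros((th.size, 1)), expit(t[None, :] - th[:, None]), np.ones((th.size, 1))],
        axis=1,
    )
    probs = np.diff(cum, axis=1)
    return probs[0] if np.isscalar(theta) or np.ndim(theta) == 0 else probs


def expected_p(y, theta, thresholds):
    """E(p | y, theta, t) for the latent-logistic ordinal model.

    With y* | y uniform (after the probability integral transform) on
    (F(t_{y-1}-theta), F(t_y-theta)), the expectation of
    p = F(y* - theta) is the interval midpoint:
    (F(t_{y-1}-theta) + F(t_y-theta)) / 2, with F(t_0-theta)=0 and
    F(t_C-theta)=1 at the boundary categories.
    """
    t = np.asarray(thresholds, dtype=float)
    y = np.asarray(y, dtype=int)
    th = np.asarray(theta, dtype=float)
    tpad = np.concatenate([[-np.inf], t, [np.inf]])
    lo = expit(tpad[y - 1] - th)
    hi = expit(tpad[y] - th)
    return (lo + hi) / 2.0


def kappa_star(sigma2=None, has_numeric=False) -> float:
    """Shared majorization curvature kappa* = max(1/4, 1/sigma^2)."""
    if not has_numeric:
        return 0.25
    if sigma2 is None or sigma2 <= 0:
        raise ValueError("sigma2 must be positive when numeric responses exist")
    if sigma2 < SMALL_VARIANCE:
        logger.warning(
            "estimated residual variance %.4g < %.2g: the working responses "
            "barely move and the algorithm may stall", sigma2, SMALL_VARIANCE
        )
    return max(0.25, 1.0 / sigma2)


def negative_loglik(dataset, Theta, thresholds, sigma2=None, per_element=False):
    """Total negative log-likelihood, optionally with the N x R loss matrix.

    ``thresholds`` maps response column index -> cutpoint array for the
    ordinal columns.
    """
    Y = dataset.Y
    num, binr, ordn = dataset.response_families()
    loss = np.zeros_like(Theta)
    if num.any():
        if sigma2 is None or sigma2 <= 0:
            raise ValueError("sigma2 required for numeric responses")
        resid = Y[:, num] - Theta[:, num]
        loss[:, num] = 0.5 * np.log(2 * np.pi * sigma2) + resid**2 / (2 * sigma2)
    if binr.any():
        q = 2.0 * Y[:, binr] - 1.0
        loss[:, binr] = -log_expit(q * Theta[:, binr])
    for r in np.flatnonzero(ordn):
        t = np.asarray(thresholds[r], dtype=float)
        y = Y[:, r].astype(int)
        th = Theta[:, r]
        tpad = np.concatenate([[-np.inf], t, [np.inf]])
        pi = expit(tpad[y] - th) - expit(tpad[y - 1] - th)
        if np.any(pi <= PROB_FLOOR):
            logger.warning("response %d: probabilities numerically 0 were floored", r)
            pi = np.maximum(pi, PROB_FLOOR)
        loss[:, r] = -np.log(pi)
    total = float(loss.sum())
    return (total, loss) if per_element else total


def working_matrix(dataset, Theta, thresholds, sigma2=None, kappa=None) -> WorkingSet:
    """Working responses Z = Theta - Xi / kappa* for the current support point."""
    Y = dataset.Y
    num, binr, ordn = dataset.response_families()
    if kappa is None:
        kappa = kappa_star(sigma2, has_numeric=bool(num.any()))
    Xi = np.zeros_like(Theta)
    if num.any():
        Xi[:, num] = (Theta[:, num] - Y[:, num]) / sigma2
    if binr.any():
        Xi[:, binr] = -(Y[:, binr] - expit(Theta[:, binr]))
    for r in np.flatnonzero(ordn):
        ep = expected_p(Y[:, r].astype(int), Theta[:, r], thresholds[r])
        Xi[:, r] = 1.0 - 2.0 * ep
    Z = Theta - Xi / kappa
    return WorkingSet(Xi=Xi, kappa=kappa, Z=Z)
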