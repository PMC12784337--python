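"""Maximum-likelihood fitting of the mixed reduced-rank regression model.

The outer loop alternates, per iteration on a freshly majorized working
matrix: quantification updates for each discrete predictor (cyclic), the
B regression step, the Procrustes V step, intercepts, residual variance
and the per-response threshold ML step, until the negative log-likelihood
decrease falls below the tolerance.  The converged solution is identified
by rotating to principal axes (U'U diagonal, descending) with a fixed sign
convention.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import majorization as mj
from . import parameter_updates as pu
from .model_spec import DataError, Dataset, build_indicator, standardize
from .optimal_scaling import Quantification, rescale_quantification, update_quantification

logger = logging.getLogger(__name__)


@dataclass
class FitOptions:
    """Rank, convergence and reproducibility settings for one fit."""

    rank: int = 2
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int | None = None
    verbose: bool = False


@dataclass
class FitResult:
    """Estimated parameters plus the NLL trace of the MM iterations."""

    m: np.ndarray
    B: np.ndarray
    V: np.ndarray
    thresholds: dict
    sigma2: float | None
    quantifications: list
    nll_trace: list = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    K: int | None = None
    predictor_specs: list = field(default_factory=list)
    response_specs: list = field(default_factory=list)
    train_stats: list = field(default_factory=list)  # (mean, sd) per numeric predictor

    @property
    def A(self) -> np.ndarray:
        """Implied P x R coefficient matrix B V'."""
        return self.B @ self.V.T

    @property
    def nll(self) -> float:
        return self.nll_trace[-1]

    def to_json(self, path=None) -> str:
        doc = {
            "rank": int(self.B.shape[1]),
            "m": self.m.tolist(),
            "B": self.B.tolist(),
            "V": self.V.tolist(),
            "A": self.A.tolist(),
            "thresholds": {str(k): v.tolist() for k, v in self.thresholds.items()},
            "sigma2": self.sigma2,
            "quantifications": [
                None if q is None else {"w": q.w.tolist(), "level": q.level, "direction": q.direction}
                for q in self.quantifications
            ],
            "train_stats": {
                s.name: list(st)
                for s, st in zip(self.predictor_specs, self.train_stats)
                if st is not None
            },
            "nll": self.nll,
            "nll_trace": [float(v) for v in self.nll_trace],
            "converged": self.converged,
            "n_iter": self.n_iter,
            "K": self.K,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text


def _indicator_cache(dataset: Dataset):
    inds = []
    for j, s in enumerate(dataset.predictor_specs):
        inds.append(
            build_indicator(dataset.X[:, j].astype(int), s.n_categories)
            if s.is_discrete
            else None
        )
    return inds


def build_phi(dataset: Dataset, quantifications, train_stats=None):
    """Assemble the N x P matrix of transformed predictors.

    Numeric columns are standardized (with training statistics when
    supplied); discrete columns are the quantified indicator products.
    """
    cols = []
    for j, s in enumerate(dataset.predictor_specs):
        if s.level == "numeric":
            x = dataset.X[:, j]
            if train_stats is not None and train_stats[j] is not None:
                mean, sd = train_stats[j]
                cols.append((x - mean) / sd)
            else:
                cols.append(standardize(x))
        else:
            q = quantifications[j]
            codes = dataset.X[:, j].astype(int)
            cols.append(q.w[codes - 1])
    return np.column_stack(cols)


def initialize(dataset: Dataset, S: int) -> FitResult:
    """Starting values from a classical reduced-rank regression.

    All variables are coded numerically (discrete predictors as
    standardized integer codes, ordinal responses as category indices,
    binary as 0/1; responses column-standardized), then the rank-S
    truncated SVD of the multivariate OLS fit provides B and V.
    """
    N, P, R = dataset.N, dataset.P, dataset.R
    if S < 1 or S > min(P, R):
        raise ValueError(f"rank must be in 1..min(P,R)={min(P, R)}")
    if N <= P:
        raise DataError(f"need N > P (got N={N}, P={P})")

    quants: list = []
    train_stats: list = []
    for j, s in enumerate(dataset.predictor_specs):
        if s.is_discrete:
            ind = build_indicator(dataset.X[:, j].astype(int), s.n_categories)
            w0 = rescale_quantification(np.arange(1, s.n_categories + 1, dtype=float), ind.frequencies)
            direction = "increasing" if s.level == "ordinal" else "n/a"
            quants.append(Quantification(w=w0, level=s.level, direction=direction))
            train_stats.append(None)
        else:
            x = dataset.X[:, j]
            quants.append(None)
            train_stats.append((float(x.mean()), float(x.std())))
    Phi0 = build_phi(dataset, quants, train_stats)

    Ystd = np.column_stack([standardize(dataset.Y[:, r]) for r in range(R)])
    C = np.linalg.lstsq(Phi0, Ystd, rcond=None)[0]
    fitted = Phi0 @ C
    _, _, Qt = np.linalg.svd(fitted, full_matrices=False)
    V0 = Qt[:S].T
    B0 = C @ V0

    num, binr, ordn = dataset.response_families()
    m0 = np.zeros(R)
    thresholds: dict = {}
    sigma2 = None
    for r in range(R):
        y = dataset.Y[:, r]
        if num[r]:
            m0[r] = y.mean()
        elif binr[r]:
            p = np.clip(y.mean(), 1e-6, 1 - 1e-6)
            m0[r] = np.log(p / (1 - p))
        else:
            thresholds[r] = pu.thresholds_from_proportions(
                y.astype(int), dataset.response_specs[r].n_categories
            )
    if num.any():
        Ynum = dataset.Y[:, num]
        Cn = np.linalg.lstsq(Phi0, Ynum - Ynum.mean(axis=0), rcond=None)[0]
        resid = Ynum - Ynum.mean(axis=0) - Phi0 @ Cn
        sigma2 = max(float(resid.var()), 0.1)

    return FitResult(
        m=m0, B=B0, V=V0, thresholds=thresholds, sigma2=sigma2,
        quantifications=quants,
        predictor_specs=list(dataset.predictor_specs),
        response_specs=list(dataset.response_specs),
        train_stats=train_stats,
    )


def identify(result: FitResult, Phi: np.ndarray) -> FitResult:
    """Rotate to the identified solution: U'U diagonal, descending.

    T holds the eigenvectors of (Phi B)'(Phi B); B <- BT, V <- VT leaves
    A = BV' unchanged.  Each V column's largest-magnitude entry is made
    positive.
    """
    U = Phi @ result.B
    evals, T = np.linalg.eigh(U.T @ U)
    order = np.argsort(evals)[::-1]
    T = T[:, order]
    B = result.B @ T
    V = result.V @ T
    for s in range(V.shape[1]):
        j = np.argmax(np.abs(V[:, s]))
        if V[j, s] < 0:
            V[:, s] = -V[:, s]
            B[:, s] = -B[:, s]
    result.B, result.V = B, V
    return result


def fit(dataset: Dataset, options: FitOptions | None = None, start: FitResult | None = None) -> FitResult:
    """Run the MM algorithm to the maximum-likelihood solution.

    ``start`` provides a warm start (used by cross-validation and the
    bootstrap); otherwise the reduced-rank starting values are used.  The
    NLL trace is guaranteed non-increasing; an increase beyond 1e-8 raises,
    as it would indicate a majorization bug.
    """
    options = options or FitOptions()
    S = options.rank
    res = initialize(dataset, S) if start is None else _copy_start(start)
    num, binr, ordn = dataset.response_families()
    has_numeric = bool(num.any())
    inds = _indicator_cache(dataset)
    discrete_idx = [j for j, s in enumerate(dataset.predictor_specs) if s.is_discrete]

    Phi = build_phi(dataset, res.quantifications, res.train_stats)
    Theta = mj.canonical_params(Phi, res.m, res.B, res.V)
    nll = mj.negative_loglik(dataset, Theta, res.thresholds, res.sigma2)
    res.nll_trace = [nll]

    for it in range(1, options.max_iter + 1):
        ws = mj.working_matrix(dataset, Theta, res.thresholds, res.sigma2)
        Z = ws.Z

        # (2) quantifications, cyclic over discrete predictors
        if discrete_idx:
            A = res.B @ res.V.T
            Zc = Z - res.m[None, :]
            E = Zc - Phi @ A
            for j in discrete_idx:
                Ztarget = E + np.outer(Phi[:, j], A[j])
                q = update_quantification(
                    Ztarget, A[j], inds[j],
                    dataset.predictor_specs[j].level,
                    previous=res.quantifications[j],
                )
                res.quantifications[j] = q
                Phi[:, j] = q.w[dataset.X[:, j].astype(int) - 1]
                E = Ztarget - np.outer(Phi[:, j], A[j])

        Ztil = Z - res.m[None, :]
        res.B = pu.update_B(Phi, Ztil, res.V)          # (3)
        res.V = pu.update_V(Phi, res.B, Ztil, S)       # (4)
        fitted_bilinear = Phi @ res.B @ res.V.T
        res.m = pu.update_intercepts(Z - fitted_bilinear, ordn)  # (5)

        Theta = res.m[None, :] + fitted_bilinear
        if has_numeric:                                # (6)
            sigma2_new = pu.update_sigma2(dataset.Y[:, num], Theta[:, num])
            if sigma2_new < mj.SMALL_VARIANCE:
                logger.warning(
                    "estimated residual variance %.4g < %.2g", sigma2_new, mj.SMALL_VARIANCE
                )
            # the (N R_N - 1) denominator is a hair above the ML minimizer;
            # keep the old value in the rare case the refresh would ascend
            if mj.negative_loglik(dataset, Theta, res.thresholds, sigma2_new) <= mj.negative_loglik(
                dataset, Theta, res.thresholds, res.sigma2
            ):
                res.sigma2 = max(sigma2_new, 1e-12)

        for r in np.flatnonzero(ordn):                 # (7)
            C = dataset.response_specs[r].n_categories
            res.thresholds[r] = pu.update_thresholds(
                dataset.Y[:, r].astype(int), Theta[:, r], C, current=res.thresholds[r]
            )

        nll_new = mj.negative_loglik(dataset, Theta, res.thresholds, res.sigma2)  # (8)
        if nll_new > nll + 1e-8:
            raise RuntimeError(
                f"NLL increased by {nll_new - nll:.3e} at iteration {it}: majorization bug"
            )
        res.nll_trace.append(nll_new)
        if options.verbose:
            logger.info("iter %d: nll %.8f", it, nll_new)
        decrease = nll - nll_new
        nll = nll_new
        if decrease < options.tol:
            res.converged = True
            res.n_iter = it
            break
    else:
        res.n_iter = options.max_iter
        logger.warning("not converged after %d iterations", options.max_iter)

    identify(res, Phi)
    from .model_selection import count_parameters

    res.K = count_parameters(dataset.specs, S)
    return res


def _copy_start(start: FitResult) -> FitResult:
    return FitResult(
        m=start.m.copy(), B=start.B.copy(), V=start.V.copy(),
        thresholds={k: v.copy() for k, v in start.thresholds.items()},
        sigma2=start.sigma2,
        quantifications=[
            None if q is None else Quantification(w=q.w.copy(), level=q.level, direction=q.direction)
            for q in start.quantifications
        ],
        predictor_specs=list(start.predictor_specs),
        response_specs=list(start.response_specs),
        train_stats=list(start.train_stats),
    )


def transform_new(result: FitResult, X_new: np.ndarray) -> np.ndarray:
    """Apply training transformations (standardization / quantification)
    to new predictor rows; unseen categories are an error."""
    X_new = np.asarray(X_new, dtype=float)
    cols = []
    for j, s in enumerate(result.predictor_specs):
        x = X_new[:, j]
        if s.level == "numeric":
            mean, sd = result.train_stats[j]
            cols.append((x - mean) / sd)
        else:
            codes = x.astype(int)
            if np.any((codes < 1) | (codes > s.n_categories)):
                bad = sorted(set(codes[(codes < 1) | (codes > s.n_categories)]))
                raise DataError(
                    f"{s.name}: unseen/invalid categories {bad}; no quantification exists"
                )
            cols.append(result.quantifications[j].w[codes - 1])
    return np.column_stack(cols)


def classify_ordinal(theta, thresholds) -> np.ndarray:
    """Class c with t_{c-1} <= theta < t_c (half-open latent intervals)."""
    t = np.asarray(thresholds, dtype=float)
    return np.searchsorted(t, np.atleast_1d(theta), side="right") + 1


def predict(result: FitResult, X_new) -> dict:
    """Canonical parameters and per-response predictions for new rows.

    Returns a dict with ``theta`` (n x R) and per-response entries:
    expected value (numeric), success probability (binary), or category
    probabilities plus the modal latent class (ordinal).
    """
    Phi_new = transform_new(result, np.atleast_2d(np.asarray(X_new, dtype=float)))
    Theta = mj.canonical_params(Phi_new, result.m, result.B, result.V)
    out = {"theta": Theta, "responses": {}}
    for r, s in enumerate(result.response_specs):
        th = Theta[:, r]
        if s.level == "numeric":
            out["responses"][s.name] = {"mean": th}
        elif s.level == "binary":
            out["responses"][s.name] = {"prob": mj.logistic_cdf(th)}
        else:
            t = result.thresholds[r]
            out["responses"][s.name] = {
                "probs": mj.ordinal_category_probs(th, t),
                "class": classify_ordinal(th, t),
            }
    return out
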