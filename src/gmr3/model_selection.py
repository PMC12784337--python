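"""Rank selection: parameter counting, information criteria, repeated
V-fold cross-validation and the balanced pairs bootstrap.

The number of free parameters of a rank-S model is

    K = (P + R - S) S + sum_{discrete p} (C_p - 2)
        + sum_{numeric/binary r} 1 + sum_{ordinal r} (C_r - 1),

counting the bilinear part on its Stiefel-quotient dimension, the
mean-0/variance-1-constrained quantifications, the intercepts and the
thresholds.  AIC/BIC/adjusted-McFadden compare ranks on the training
likelihood; cross-validation estimates out-of-sample prediction error per
participant; the balanced bootstrap yields confidence regions (ellipses)
for predictor weights and response loadings after Procrustes alignment of
each replicate to the parent solution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import orthogonal_procrustes
from scipy.stats import chi2

from . import majorization as mj
from .fit_driver import FitOptions, FitResult, fit, transform_new
from .model_spec import Dataset
from .parameter_updates import thresholds_from_proportions

logger = logging.getLogger(__name__)


def count_parameters(specs, S: int) -> int:
    """Total free-parameter count K of the rank-S model (Eq. above)."""
    pred = [s for s in specs if s.role == "predictor"]
    resp = [s for s in specs if s.role == "response"]
    P, R = len(pred), len(resp)
    if S > min(P, R) or S < 0:
        raise ValueError(f"rank {S} outside 0..min(P,R)")
    K = sum(1 for s in resp if s.level in ("numeric", "binary"))
    K += sum(s.n_categories - 1 for s in resp if s.level == "ordinal")
    if S > 0:  # null model has no predictor contribution at all
        K += (P + R - S) * S
        K += sum(s.n_categories - 2 for s in pred if s.is_discrete)
    return int(K)


def information_criteria(nll: float, nll_null: float, K: int, N: int) -> dict:
    """AIC = 2 NLL + 2K; BIC = 2 NLL + log(N) K; Ra2 = 1 - (NLL+K)/NLL0.

    Ra2 is the adjusted McFadden index with the *total* parameter count in
    the penalty (pass K minus the null model's count for the alternative
    reading).
    """
    return {
        "aic": 2.0 * nll + 2.0 * K,
        "bic": 2.0 * nll + np.log(N) * K,
        "ra2": 1.0 - (nll + K) / nll_null,
    }


def null_model_nll(dataset: Dataset) -> float:
    """NLL of the intercepts/thresholds-only model (no predictors)."""
    num, binr, ordn = dataset.response_families()
    N, R = dataset.N, dataset.R
    m = np.zeros(R)
    thresholds = {}
    sigma2 = None
    for r in range(R):
        y = dataset.Y[:, r]
        if num[r]:
            m[r] = y.mean()
        elif binr[r]:
            p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
            m[r] = np.log(p / (1 - p))
        else:
            thresholds[r] = thresholds_from_proportions(
                y.astype(int), dataset.response_specs[r].n_categories
            )
    if num.any():
        sigma2 = float(dataset.Y[:, num].var())
    Theta = np.tile(m, (N, 1))
    return mj.negative_loglik(dataset, Theta, thresholds, sigma2)


@dataclass
class SelectionTable:
    """Per-rank fit statistics (long layout, one row per candidate rank)."""

    table: pd.DataFrame
    fits: dict = field(default_factory=dict)

    def best(self, criterion: str = "bic") -> int:
        return int(self.table.loc[self.table[criterion].idxmin(), "S"])


def select_rank(dataset: Dataset, ranks, options: FitOptions | None = None) -> SelectionTable:
    """Fit every candidate rank and tabulate NLL, K, AIC, BIC and Ra2."""
    options = options or FitOptions()
    nll0 = null_model_nll(dataset)
    rows, fits = [], {}
    for S in ranks:
        opts = FitOptions(rank=S, tol=options.tol, max_iter=options.max_iter,
                          seed=options.seed, verbose=options.verbose)
        res = fit(dataset, opts)
        ic = information_criteria(res.nll, nll0, res.K, dataset.N)
        rows.append({"S": S, "nll": res.nll, "K": res.K, **ic})
        fits[S] = res
    return SelectionTable(table=pd.DataFrame(rows), fits=fits)


# ---------------------------------------------------------------- CV ----

@dataclass
class CVResult:
    """Mean out-of-fold prediction error per participant, per rank."""

    table: pd.DataFrame          # rank, cv, se
    fold_means: pd.DataFrame     # rank, repeat, fold, loss
    best_rank: int
    one_se_rank: int


def _subset(dataset: Dataset, idx) -> Dataset:
    return Dataset(
        X=dataset.X[idx], Y=dataset.Y[idx],
        predictor_specs=dataset.predictor_specs,
        response_specs=dataset.response_specs,
    )


def _all_categories_present(dataset: Dataset, idx) -> bool:
    for j, s in enumerate(dataset.predictor_specs):
        if s.is_discrete:
            if len(set(dataset.X[idx, j].astype(int))) < s.n_categories:
                return False
    for r, s in enumerate(dataset.response_specs):
        if s.level == "ordinal":
            if len(set(dataset.Y[idx, r].astype(int))) < s.n_categories:
                return False
        elif s.level == "binary":
            if len(set(dataset.Y[idx, r].astype(int))) < 2:
                return False
    return True


def _make_folds(dataset: Dataset, V: int, rng, max_retries: int = 50):
    """Random participant partition into V folds; every training split must
    retain all categories of all discrete variables."""
    N = dataset.N
    for _ in range(max_retries):
        perm = rng.permutation(N)
        folds = np.array_split(perm, V)
        if all(
            _all_categories_present(dataset, np.setdiff1d(perm, f))
            for f in folds
        ):
            return folds
    raise RuntimeError(
        f"could not build {V} folds retaining every category; use fewer folds"
    )


def held_out_loss(result: FitResult, test: Dataset) -> float:
    """Summed per-element NLL on held-out rows, averaged per participant."""
    Phi = transform_new(result, test.X)
    Theta = mj.canonical_params(Phi, result.m, result.B, result.V)
    total = mj.negative_loglik(test, Theta, result.thresholds, result.sigma2)
    return total / test.N


def cross_validate(
    dataset: Dataset,
    ranks,
    V: int = 10,
    L: int = 1,
    seed: int | None = None,
    options: FitOptions | None = None,
) -> CVResult:
    """L-times-repeated V-fold CV of the per-participant prediction error.

    Each training fit is warm-started from the full-data solution of the
    same rank.  The SE per rank is taken over the L*V fold-level means,
    the convention the one-standard-error rule assumes.
    """
    if V < 2:
        raise ValueError("V must be >= 2")
    options = options or FitOptions()
    rng = np.random.default_rng(seed)
    ranks = list(ranks)
    parents = {
        S: fit(dataset, FitOptions(rank=S, tol=options.tol, max_iter=options.max_iter))
        for S in set(ranks)
    }
    records = []
    for rep in range(L):
        folds = _make_folds(dataset, V, rng)
        for v, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(dataset.N), test_idx)
            train, test = _subset(dataset, train_idx), _subset(dataset, test_idx)
            for S in ranks:
                res = fit(
                    train,
                    FitOptions(rank=S, tol=options.tol, max_iter=options.max_iter),
                    start=parents[S],
                )
                records.append(
                    {"rank": S, "repeat": rep, "fold": v, "loss": held_out_loss(res, test)}
                )
    fold_means = pd.DataFrame(records)
    agg = (
        fold_means.groupby("rank")["loss"]
        .agg(cv="mean", se=lambda x: x.std(ddof=1) / np.sqrt(len(x)))
        .reset_index()
    )
    best = int(agg.loc[agg["cv"].idxmin(), "rank"])
    cutoff = agg["cv"].min() + float(agg.loc[agg["cv"].idxmin(), "se"])
    one_se = int(agg.loc[agg["cv"] <= cutoff, "rank"].min())
    return CVResult(table=agg, fold_means=fold_means, best_rank=best, one_se_rank=one_se)


# --------------------------------------------------------- bootstrap ----

@dataclass
class BootstrapResult:
    """Aligned replicate clouds and per-variable confidence ellipses."""

    B_rows: np.ndarray           # (n_kept, P, S)
    V_rows: np.ndarray           # (n_kept, R, S)
    ellipses: pd.DataFrame       # variable, side, center/cov, origin_outside
    n_dropped: int
    level: float

    def cloud_table(self) -> pd.DataFrame:
        rows = []
        for b in range(self.B_rows.shape[0]):
            for side, M in (("predictor", self.B_rows[b]), ("response", self.V_rows[b])):
                for j in range(M.shape[0]):
                    for s in range(M.shape[1]):
                        rows.append(
                            {"replicate": b, "side": side, "variable": j,
                             "dimension": s + 1, "value": M[j, s]}
                        )
        return pd.DataFrame(rows)


def balanced_indices(N: int, B_boot: int, rng) -> list[np.ndarray]:
    """Balanced resampling: permute B concatenated copies of 0..N-1 and
    slice, so each participant appears exactly B times overall."""
    pooled = rng.permutation(np.tile(np.arange(N), B_boot))
    return [pooled[b * N:(b + 1) * N] for b in range(B_boot)]


def ellipse_origin_outside(center, cov, S, level=0.95) -> bool:
    """True when the origin lies outside the (level) chi-square ellipse."""
    d2 = float(center @ np.linalg.solve(cov, center))
    return d2 > chi2.ppf(level, df=S)


def balanced_bootstrap(
    dataset: Dataset,
    S: int,
    B_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    options: FitOptions | None = None,
    parent: FitResult | None = None,
) -> BootstrapResult:
    """Balanced pairs bootstrap of (B, V) with Procrustes alignment.

    Each resample is refitted (warm-started from the parent fit) and its
    loadings are rotated onto the parent's; per predictor and response row
    a mean/covariance in the S-dimensional space gives the confidence
    ellipse, flagged significant when it excludes the origin.
    """
    if B_boot < 100:
        logger.warning("B_boot=%d is small; >= 100 recommended", B_boot)
    options = options or FitOptions()
    rng = np.random.default_rng(seed)
    if parent is None:
        parent = fit(dataset, FitOptions(rank=S, tol=options.tol, max_iter=options.max_iter))
    B_rows, V_rows, dropped = [], [], 0
    for idx in balanced_indices(dataset.N, B_boot, rng):
        boot = _subset(dataset, idx)
        if not _all_categories_present(dataset, idx):
            dropped += 1
            logger.warning("replicate dropped: resample lost a category")
            continue
        try:
            res = fit(boot, FitOptions(rank=S, tol=options.tol, max_iter=options.max_iter),
                      start=parent)
        except RuntimeError as exc:
            dropped += 1
            logger.warning("replicate dropped: %s", exc)
            continue
        T, _ = orthogonal_procrustes(res.V, parent.V)
        B_rows.append(res.B @ T)
        V_rows.append(res.V @ T)
    if dropped > 0.05 * B_boot:
        raise RuntimeError(f"{dropped}/{B_boot} bootstrap replicates failed")
    B_arr, V_arr = np.array(B_rows), np.array(V_rows)
    rows = []
    for side, arr, specs in (
        ("predictor", B_arr, dataset.predictor_specs),
        ("response", V_arr, dataset.response_specs),
    ):
        for j, spec in enumerate(specs):
            pts = arr[:, j, :]
            center = pts.mean(axis=0)
            cov = np.cov(pts, rowvar=False).reshape(S, S)
            rows.append(
                {"side": side, "variable": spec.name,
                 "center": center, "cov": cov,
                 "origin_outside": ellipse_origin_outside(center, cov, S, level)}
            )
    return BootstrapResult(
        B_rows=B_arr, V_rows=V_arr, ellipses=pd.DataFrame(rows),
        n_dropped=dropped, level=level,
    )
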