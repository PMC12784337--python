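"""Synthetic-data generators for the two built-in simulation studies.

Study 1 fixes P = R = 8 with a true rank of 2: weights B come from the QR
decomposition of a standard-normal matrix, loadings V have uniform(-1, 1)
entries, intercepts are zero.  Predictors are i.i.d. standard normal,
optionally discretized to five ordered levels (balanced .2/.4/.6/.8 or
unbalanced .1/.5/.7/.8 quantiles) or dichotomized; the generating linear
predictor uses per-category means of the latent values while the analysis
data carry integer codes.  Numeric responses add unit-variance Gaussian
noise, binary responses are Bernoulli(F(theta)) and ordinal responses are
multinomial draws from the cumulative-logit probabilities with thresholds
(-1, 0, 1).

Study 2 reuses the fully mixed scenario with true ranks 2/4/7; the "weak"
variants replace trailing singular values of B V' with 0.20.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .fit_driver import FitOptions, fit
from .model_spec import DataError, Dataset, VariableSpec
from .model_selection import information_criteria, null_model_nll

logger = logging.getLogger(__name__)

ORDINAL_THRESHOLDS = np.array([-1.0, 0.0, 1.0])
BALANCED_QUANTILES = (0.2, 0.4, 0.6, 0.8)
UNBALANCED_QUANTILES = (0.1, 0.5, 0.7, 0.8)

#: predictor / response level layouts of the seven study-1 scenarios
SCENARIOS = {
    "cond1": {
        "predictors": ["numeric"] * 8,
        "responses": ["numeric"] * 4 + ["binary"] * 4,
    },
    "gmr3-p1": {
        "predictors": [("ordinal", "balanced")] * 8,
        "responses": ["numeric"] * 4 + ["binary"] * 4,
    },
    "gmr3-p2": {
        "predictors": [("ordinal", "unbalanced")] * 8,
        "responses": ["numeric"] * 4 + ["binary"] * 4,
    },
    "gmr3-r1": {
        "predictors": ["numeric"] * 8,
        "responses": ["binary"] * 4 + ["ordinal"] * 4,
    },
    "gmr3-r2": {
        "predictors": ["numeric"] * 8,
        "responses": ["numeric"] * 4 + ["ordinal"] * 4,
    },
    "gmr3-pr": {
        "predictors": [("binary", "balanced"), ("binary", "unbalanced"),
                       ("ordinal", "balanced"), ("ordinal", "balanced"),
                       ("ordinal", "unbalanced"),
                       "numeric", "numeric", "numeric"],
        "responses": ["binary"] * 2 + ["ordinal"] * 3 + ["numeric"] * 3,
    },
}


@dataclass
class SimResult:
    """Generated dataset plus the generating structure."""

    dataset: Dataset
    A_true: np.ndarray
    B_true: np.ndarray
    V_true: np.ndarray
    thresholds: np.ndarray


def discretize(values, quantile_set="balanced", n_levels=5):
    """Quantile-discretize to ordered codes plus per-category means.

    Returns (codes 1..n_levels for analysis, substituted category means
    for generation).  The quantile boundaries follow the balanced
    (.2/.4/.6/.8) or unbalanced (.1/.5/.7/.8) scheme.
    """
    v = np.asarray(values, dtype=float)
    if v.size < n_levels:
        raise DataError("need at least n_levels values")
    qs = {"balanced": BALANCED_QUANTILES, "unbalanced": UNBALANCED_QUANTILES}[quantile_set]
    cuts = np.quantile(v, qs)
    if np.unique(cuts).size != len(cuts):
        raise DataError("duplicate quantile boundaries; degenerate input")
    codes = np.searchsorted(cuts, v, side="left") + 1
    gen = np.empty_like(v)
    for c in range(1, n_levels + 1):
        mask = codes == c
        if not mask.any():
            raise DataError(f"empty category {c} after discretization")
        gen[mask] = v[mask].mean()
    return codes, gen


def dichotomize(values, balance="balanced"):
    """Two-level analogue: split at the median (balanced) or the .8
    quantile (unbalanced); category means feed the generating predictor."""
    v = np.asarray(values, dtype=float)
    cut = np.quantile(v, 0.5 if balance == "balanced" else 0.8)
    codes = (v >= cut).astype(int) + 1
    gen = np.where(codes == 2, v[codes == 2].mean(), v[codes == 1].mean())
    return codes, gen


def weaken_structure(B_true, V_true, lam_weak=0.20):
    """Replace singular values 3..S_true of B V' with ``lam_weak``.

    Returns factors (B*, V*) whose product has the weakened spectrum while
    dimensions 1-2 are untouched.
    """
    S_true = B_true.shape[1]
    if S_true < 3:
        raise ValueError("nothing to weaken: true rank must be >= 3")
    P, lam, Qt = np.linalg.svd(B_true @ V_true.T, full_matrices=False)
    lam = lam.copy()
    lam[2:S_true] = lam_weak
    B_star = P[:, :S_true] * lam[:S_true]
    V_star = Qt[:S_true].T
    return B_star, V_star


def rmse(A_true, A_hat) -> float:
    """Root mean squared error over all P x R coefficient entries."""
    A_true, A_hat = np.asarray(A_true), np.asarray(A_hat)
    if A_true.shape != A_hat.shape:
        raise ValueError(f"shape mismatch {A_true.shape} vs {A_hat.shape}")
    return float(np.sqrt(np.mean((A_true - A_hat) ** 2)))


def _gen_structure(P, R, S_true, rng, strength="strong"):
    B = np.linalg.qr(rng.standard_normal((P, S_true)))[0]
    V = rng.uniform(-1.0, 1.0, size=(R, S_true))
    if strength == "weak":
        B, V = weaken_structure(B, V)
    elif strength != "strong":
        raise ValueError(f"unknown strength {strength!r}")
    return B, V


def gen_study1(scenario="cond1", N=250, seed=None, S_true=2, strength="strong") -> SimResult:
    """Generate one dataset of a study-1 scenario (or study-2 variant).

    ``scenario`` is one of cond1, gmr3-p1, gmr3-p2, gmr3-r1, gmr3-r2,
    gmr3-pr; study 2 uses gmr3-pr with S_true in {2, 4, 7} and strength
    "strong" or "weak".
    """
    layout = SCENARIOS[scenario]
    rng = np.random.default_rng(seed)
    P, R = len(layout["predictors"]), len(layout["responses"])
    B, V = _gen_structure(P, R, S_true, rng, strength)
    A_true = B @ V.T

    latent = rng.standard_normal((N, P))
    X_cols, X_gen, pred_specs = [], [], []
    for j, kind in enumerate(layout["predictors"]):
        name = f"x{j + 1}"
        if kind == "numeric":
            X_cols.append(latent[:, j])
            X_gen.append(latent[:, j])
            pred_specs.append(VariableSpec(name, "predictor", "numeric"))
        else:
            level, balance = kind
            if level == "ordinal":
                codes, gen = discretize(latent[:, j], balance)
                pred_specs.append(VariableSpec(name, "predictor", "ordinal", 5))
            else:
                codes, gen = dichotomize(latent[:, j], balance)
                pred_specs.append(VariableSpec(name, "predictor", "binary", 2))
            X_cols.append(codes.astype(float))
            # standardize the generating quantified column so the true BV'
            # acts on the same unit-variance scale the fitted model uses
            X_gen.append((gen - gen.mean()) / gen.std())
    Theta = np.column_stack(X_gen) @ A_true  # zero intercepts

    Y_cols, resp_specs = [], []
    for r, level in enumerate(layout["responses"]):
        name = f"y{r + 1}"
        th = Theta[:, r]
        if level == "numeric":
            Y_cols.append(th + rng.standard_normal(N))
            resp_specs.append(VariableSpec(name, "response", "numeric"))
        elif level == "binary":
            Y_cols.append(rng.binomial(1, expit(th)).astype(float))
            resp_specs.append(VariableSpec(name, "response", "binary", 2))
        else:
            cum = expit(ORDINAL_THRESHOLDS[None, :] - th[:, None])
            u = rng.uniform(size=N)
            codes = (u[:, None] > cum).sum(axis=1) + 1
            Y_cols.append(codes.astype(float))
            resp_specs.append(VariableSpec(name, "response", "ordinal", 4))

    dataset = Dataset(
        X=np.column_stack(X_cols), Y=np.column_stack(Y_cols),
        predictor_specs=pred_specs, response_specs=resp_specs,
    )
    return SimResult(dataset=dataset, A_true=A_true, B_true=B, V_true=V,
                     thresholds=ORDINAL_THRESHOLDS.copy())


def _replication_seed(master_seed, counter) -> np.random.Generator:
    # counter-based scheme: reproducible and order-independent across the grid
    return np.random.default_rng([int(master_seed), int(counter)])


def run_experiment(
    scenarios,
    sample_sizes,
    fitted_ranks,
    replications=250,
    seed=0,
    tol=1e-6,
    max_iter=1000,
    true_ranks=(2,),
    strengths=("strong",),
) -> pd.DataFrame:
    """Generate-fit-score grid runner; one row per (cell, replication, rank).

    Records RMSE of the implied coefficients, the NLL, K, AIC and BIC per
    fitted rank; fit failures are recorded and skipped.
    """
    rows = []
    counter = 0
    for scenario in scenarios:
        for S_true in true_ranks:
            for strength in strengths:
                if strength == "weak" and S_true < 3:
                    continue
                for N in sample_sizes:
                    for rep in range(replications):
                        counter += 1
                        rng = _replication_seed(seed, counter)
                        sim = gen_study1(scenario, N=N, seed=rng,
                                         S_true=S_true, strength=strength)
                        nll0 = null_model_nll(sim.dataset)
                        for S_fit in fitted_ranks:
                            rec = {
                                "scenario": scenario, "true_rank": S_true,
                                "strength": strength, "N": N,
                                "replication": rep, "fitted_rank": S_fit,
                            }
                            try:
                                res = fit(sim.dataset,
                                          FitOptions(rank=S_fit, tol=tol, max_iter=max_iter))
                                ic = information_criteria(res.nll, nll0, res.K, N)
                                rec.update(
                                    rmse=rmse(sim.A_true, res.A), nll=res.nll,
                                    K=res.K, aic=ic["aic"], bic=ic["bic"],
                                    converged=res.converged, failed=False,
                                )
                            except Exception as exc:  # noqa: BLE001 - record and continue
                                logger.warning("fit failed (%s): %s", rec, exc)
                                rec.update(rmse=np.nan, nll=np.nan, K=np.nan,
                                           aic=np.nan, bic=np.nan,
                                           converged=False, failed=True)
                            rows.append(rec)
    return pd.DataFrame(rows)


def selection_counts(results: pd.DataFrame, criterion="aic") -> pd.DataFrame:
    """Per-cell counts of the rank minimizing the criterion (table layout
    of the rank-selection experiment)."""
    ok = results[~results["failed"]]
    idx = ok.groupby(["scenario", "true_rank", "strength", "N", "replication"])[criterion].idxmin()
    winners = ok.loc[idx]
    return (
        winners.groupby(["scenario", "true_rank", "strength", "N", "fitted_rank"])
        .size()
        .rename("count")
        .reset_index()
    )
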