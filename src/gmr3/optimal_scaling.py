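"""Optimal scaling (quantification) of discrete predictors.

A discrete predictor with C categories is replaced by an estimated numeric
score per category.  Within the majorized least-squares problem the
unconstrained scores have a closed form; ordinal predictors are then
projected onto the monotone cone by weighted isotonic regression (run in
both directions, keeping the better fit), and every quantification is
rescaled so the quantified column G w has mean 0 and variance 1
(population convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .model_spec import DataError, IndicatorMatrix

logger = logging.getLogger(__name__)


@dataclass
class Quantification:
    """Category scores w (length C) for one discrete predictor."""

    w: np.ndarray
    level: str
    direction: str = "n/a"  # increasing / decreasing for ordinal


def weighted_monotone_regression(values, weights, direction="increasing"):
    """Weighted least-squares projection onto the monotone cone (PAVA).

    Minimizes sum_c weights_c (values_c - out_c)^2 subject to out being
    non-decreasing (``increasing``) or non-increasing (``decreasing``).
    Pooled blocks carry the weighted mean of their members.
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if direction == "decreasing":
        return -weighted_monotone_regression(-v, w, "increasing")
    if direction != "increasing":
        raise ValueError(f"unknown direction {direction!r}")
    # pool-adjacent-violators with (mean, weight, count) blocks
    means: list[float] = []
    wts: list[float] = []
    counts: list[int] = []
    for val, wt in zip(v, w):
        means.append(val)
        wts.append(wt)
        counts.append(1)
        while len(means) > 1 and means[-2] > means[-1]:
            m2, w2, c2 = means.pop(), wts.pop(), counts.pop()
            m1, w1, c1 = means.pop(), wts.pop(), counts.pop()
            means.append((w1 * m1 + w2 * m2) / (w1 + w2))
            wts.append(w1 + w2)
            counts.append(c1 + c2)
    return np.repeat(means, counts)


def rescale_quantification(w, frequencies) -> np.ndarray:
    """Affine-rescale scores so the quantified column is standardized.

    Frequency-weighted mean 0 and (population) variance 1; order preserved.
    """
    w = np.asarray(w, dtype=float)
    f = np.asarray(frequencies, dtype=float)
    n = f.sum()
    mean = (f * w).sum() / n
    var = (f * (w - mean) ** 2).sum() / n
    if var <= 0 or not np.isfinite(var):
        raise DataError("constant quantification cannot be rescaled")
    return (w - mean) / np.sqrt(var)


def update_quantification(
    Z_target: np.ndarray,
    a_p: np.ndarray,
    G_p: IndicatorMatrix,
    level: str,
    previous: Quantification | None = None,
) -> Quantification:
    """One majorized least-squares update of a predictor's category scores.

    ``Z_target`` is the working-response matrix with every other
    predictor's contribution removed; ``a_p`` is the predictor's row of
    the implied coefficient matrix A = BV'.  The normal equations of
    ||vec(Z~) - a_p (x) G_p w||^2 are diagonal, giving per category c

        w_c = sum_{i in c} (Z~ a_p)_i / (||a_p||^2 f_c).

    Ordinal levels are then cone-projected (both directions, best weighted
    SSE wins) and every level is rescaled to mean 0 / variance 1.
    """
    a = np.asarray(a_p, dtype=float)
    a2 = float(a @ a)
    f = G_p.frequencies.astype(float)
    if a2 <= 0:
        if previous is None:
            raise DataError("zero coefficient row and no previous quantification")
        logger.warning("predictor currently has no effect; keeping quantification")
        return previous
    target = Z_target @ a  # length N
    per_cat = G_p.G.T @ target  # sums within category
    w_unc = per_cat / (a2 * f)

    direction = "n/a"
    w = w_unc
    if level == "ordinal":
        w_inc = weighted_monotone_regression(w_unc, f, "increasing")
        w_dec = weighted_monotone_regression(w_unc, f, "decreasing")
        sse_inc = float(f @ (w_unc - w_inc) ** 2)
        sse_dec = float(f @ (w_unc - w_dec) ** 2)
        if sse_inc <= sse_dec:
            w, direction = w_inc, "increasing"
        else:
            w, direction = w_dec, "decreasing"
    w = rescale_quantification(w, f)
    if level in ("binary", "nominal") and w[0] > 0:
        # sign convention: first category negative (model-invariant flip)
        w = -w
    return Quantification(w=w, level=level, direction=direction)


def quantification_table(names, quantifications) -> "pandas.DataFrame":  # noqa: F821
    """Tidy (variable, category, quantification) table for export."""
    import pandas as pd

    rows = []
    for name, q in zip(names, quantifications):
        if q is None:
            continue
        for c, val in enumerate(q.w, start=1):
            rows.append({"variable": name, "category": c, "quantification": val})
    return pd.DataFrame(rows)
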