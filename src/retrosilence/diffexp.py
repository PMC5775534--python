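"""Negative-binomial differential expression for repeat-class count tables.

A compact two-group NB workflow in the DESeq2 tradition, built from first
principles:

1. median-of-ratios size factors;
2. per-feature method-of-moments dispersions on normalized counts (pooled
   within conditions), shrunk toward a fitted mean-dispersion trend
   ``alpha(mu) = a1/mu + a0`` by averaging log-dispersions;
3. per-feature NB GLM (log link, condition indicator) fitted by iteratively
   reweighted least squares, with a Wald test on the condition coefficient;
4. Benjamini-Hochberg adjustment across testable features.

The differential call follows the "more than twofold, p < 0.05" rule:
``|log2FC| > 1`` and raw ``p < 0.05``. Adjusted p-values are reported
alongside. This module approximates rather than replicates DESeq2 — no
independent filtering, no LFC shrinkage, no outlier handling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "estimate_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "adjust_bh",
    "run_diffexp",
]

DISPERSION_FLOOR = 1e-8
MAX_IRLS_ITER = 50
IRLS_TOL = 1e-8
FOLD_THRESHOLD_LOG2 = 1.0  # "more than twofold"
ALPHA_LEVEL = 0.05


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For each sample j, ``s_j = median_i(count_ij / geomean_i)`` over
    features whose geometric mean across samples is positive (i.e. no zero
    in any sample).
    """
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    all_positive = np.isfinite(logs).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no feature has nonzero counts in every sample; size factors "
            "undefined (consider a pseudo-reference fallback)"
        )
    log_geomean = logs[all_positive].mean(axis=1)
    log_sf = np.median(logs[all_positive] - log_geomean[:, None], axis=0)
    log_sf -= log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _fit_dispersion_trend(mu: np.ndarray, alpha: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of alpha = a1/mu + a0 over expressed features.

    Zero raw estimates stay in the fit: dropping them would condition on
    positive noise and inflate the trend.
    """
    use = mu > 0
    if use.sum() < 2:
        return 0.0, float(np.mean(alpha[use])) if use.any() else 0.0
    X = np.column_stack([1.0 / mu[use], np.ones(use.sum())])
    coef, *_ = np.linalg.lstsq(X, alpha[use], rcond=None)
    a1 = max(0.0, float(coef[0]))
    a0 = max(0.0, float(coef[1]))
    return a1, a0


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: pd.Series,
) -> pd.Series:
    """Per-feature NB dispersion with trend shrinkage.

    The raw estimate is method-of-moments on normalized counts,
    ``alpha = max(0, (var - mean) / mean^2)``, with mean and variance pooled
    within conditions (so the condition effect does not inflate the
    variance). Each raw estimate is shrunk toward the fitted trend by
    averaging the two log-dispersions, and the result is floored at the
    trend itself: with few replicates, below-trend raw estimates are almost
    entirely sampling noise, and letting them pull the final dispersion
    under the trend makes the Wald test anticonservative. Above-trend
    estimates keep their (shrunk) excess. Features with a zero raw estimate
    take the trend value; all-zero features get NaN (untestable).
    """
    norm = counts.to_numpy(dtype=float) / size_factors.reindex(counts.columns).to_numpy()
    cond = conditions.reindex(counts.columns).to_numpy()
    groups = [norm[:, cond == g] for g in pd.unique(cond)]
    for g in groups:
        if g.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition for dispersion")
    means = np.column_stack([g.mean(axis=1) for g in groups])
    varis = np.column_stack([g.var(axis=1, ddof=1) for g in groups])
    mu = means.mean(axis=1)
    var = varis.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(mu > 0, np.maximum(0.0, (var - mu) / mu**2), np.nan)

    a1, a0 = _fit_dispersion_trend(mu, np.nan_to_num(alpha_mom, nan=0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_trend = np.where(mu > 0, a1 / mu + a0, np.nan)
    alpha_trend = np.maximum(alpha_trend, DISPERSION_FLOOR)
    log_mom = np.log(np.maximum(alpha_mom, DISPERSION_FLOOR))
    shrunk = np.where(
        alpha_mom > 0,
        np.exp(0.5 * (log_mom + np.log(alpha_trend))),
        alpha_trend,
    )
    alpha = np.maximum(np.maximum(shrunk, alpha_trend), DISPERSION_FLOOR)
    alpha[mu == 0] = np.nan
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_irls(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Fit log mu = offset + b0 + b1*x for NB counts; returns (beta, se, ok)."""
    X = np.column_stack([np.ones_like(x), x])
    m0 = y[x == 0].mean()
    m1 = y[x == 1].mean()
    guard = max(y[y > 0].min(), 1.0) * 0.5 if (y > 0).any() else 0.5
    beta = np.array(
        [np.log(max(m0, guard)) - offset.mean(), np.log(max(m1, guard) / max(m0, guard))]
    )
    ok = False
    for _ in range(MAX_IRLS_ITER):
        eta = offset + X @ beta
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = eta - offset + (y - mu) / mu
        WX = X * w[:, None]
        A = X.T @ WX
        b = WX.T @ z
        try:
            new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return beta, np.full(2, np.nan), False
        if not np.isfinite(new).all():
            return beta, np.full(2, np.nan), False
        step = new - beta
        beta = new
        if np.abs(step).max() < IRLS_TOL:
            ok = True
            break
    eta = np.clip(offset + X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(A)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
        ok = False
    return beta, se, ok


@dataclass
class DEResult:
    """Per-feature differential expression table plus fitted nuisance terms."""

    table: pd.DataFrame  # log2fc, se, stat, pvalue, padj, call, converged
    size_factors: pd.Series
    dispersions: pd.Series

    @property
    def called(self) -> pd.Index:
        return self.table.index[self.table["call"].fillna(False)]


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    conditions: pd.Series,
    control: str = "A",
    depleted: str = "B",
    lfc_threshold: float = FOLD_THRESHOLD_LOG2,
    alpha_level: float = ALPHA_LEVEL,
) -> DEResult:
    """Two-group NB Wald test; log2FC is depleted over control.

    Features with zero counts in every sample are untestable: they get NaN
    statistics and are excluded from the BH denominator. The differential
    call combines ``|log2FC| > lfc_threshold`` with raw ``p < alpha_level``.
    """
    labels = conditions.reindex(counts.columns)
    if set(labels.unique()) != {control, depleted}:
        raise ValueError(
            f"conditions must be exactly {{{control!r}, {depleted!r}}}, "
            f"got {sorted(labels.unique())}"
        )
    x = (labels == depleted).to_numpy(dtype=float)
    offset = np.log(size_factors.reindex(counts.columns).to_numpy())
    mat = counts.to_numpy(dtype=float)

    n = len(counts)
    log2fc = np.full(n, np.nan)
    se_out = np.full(n, np.nan)
    stat = np.full(n, np.nan)
    pval = np.full(n, np.nan)
    converged = np.zeros(n, dtype=bool)
    ln2 = np.log(2.0)
    disp = dispersions.reindex(counts.index).to_numpy()
    for i in range(n):
        y = mat[i]
        if y.sum() == 0 or not np.isfinite(disp[i]):
            continue
        beta, se, ok = _nb_irls(y, x, offset, float(disp[i]))
        converged[i] = ok
        if not ok or not np.isfinite(se[1]) or se[1] == 0:
            continue
        log2fc[i] = beta[1] / ln2
        se_out[i] = se[1] / ln2
        stat[i] = beta[1] / se[1]
        pval[i] = 2.0 * stats.norm.sf(abs(stat[i]))

    padj = np.full(n, np.nan)
    tested = np.isfinite(pval)
    if tested.any():
        padj[tested] = adjust_bh(pval[tested])
    call = np.where(
        tested, (np.abs(log2fc) > lfc_threshold) & (pval < alpha_level), False
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "se": se_out,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "call": call.astype(bool),
            "converged": converged,
        },
        index=counts.index,
    )
    return DEResult(table, size_factors, dispersions.reindex(counts.index))


def adjust_bh(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_diffexp(
    counts: pd.DataFrame,
    conditions: pd.Series,
    control: str = "A",
    depleted: str = "B",
    lfc_threshold: float = FOLD_THRESHOLD_LOG2,
    alpha_level: float = ALPHA_LEVEL,
) -> DEResult:
    """Full workflow: size factors, dispersions, Wald test, BH, calls."""
    sf = estimate_size_factors(counts)
    disp = estimate_dispersions(counts, sf, conditions)
    return nb_wald_test(
        counts, sf, disp, conditions,
        control=control, depleted=depleted,
        lfc_threshold=lfc_threshold, alpha_level=alpha_level,
    )
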