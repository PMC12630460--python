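"""Normalization, rank correlation, and residual-based outlier detection.

The analysis stage normalizes each diversity variable with the
Yeo-Johnson power transformation (standardized to zero mean, unit SD),
assesses monotone association between all metric pairs with Spearman
rank correlations (two-sided p-values; exact permutation p below n = 10),
and flags regions whose metric value is unusually high or low for their
phylogenetic diversity: residuals from a LOWESS fit of metric on PD that
lie more than k standard deviations (default 2) from the mean residual.

Because Spearman correlation depends only on ranks and the Yeo-Johnson
transform is strictly monotone, the correlations are identical on raw and
transformed variables; the transform matters for the residual/outlier
step, which is therefore run on transformed values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .phylo_metrics import lowess_fit

logger = logging.getLogger("phytodiv")

#: Diversity metrics entering the correlation analysis.
METRIC_VARIABLES = ["H", "Hbc", "G", "J", "FAD", "MFAD", "APWD"]
#: Phylogeny-side variables the metrics are correlated against.
PHYLO_VARIABLES = ["PD", "SR", "PD_resid"]


@dataclass(frozen=True)
class TransformParams:
    """Fitted Yeo-Johnson parameters for one variable."""

    lmbda: float
    mean: float
    sd: float


@dataclass(frozen=True)
class AssociationResult:
    var_a: str
    var_b: str
    rho: float
    p: float
    n: int


@dataclass(frozen=True)
class OutlierReport:
    region: str
    metric: str
    residual: float
    z: float
    direction: str  # "high" or "low"


def yeo_johnson(
    values: Sequence[float], lmbda: Optional[float] = None
) -> tuple[np.ndarray, TransformParams]:
    """Yeo-Johnson transform with maximum-likelihood lambda, standardized.

    By default lambda maximizes the Gaussian profile log-likelihood over
    [-5, 5] (bounded Brent search); pass ``lmbda`` to fix it (lambda = 0
    is ln(x+1) on non-negative input).  The transformed values are
    standardized to mean 0, SD 1.  Nulls (NaN) are excluded from the fit
    and re-inserted as NaN.  The transform is strictly monotone, so ranks
    are preserved.
    """
    arr = np.asarray(values, dtype=float)
    mask = np.isfinite(arr)
    x = arr[mask]
    if x.size < 3:
        raise ValueError("need at least 3 finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant vector: Yeo-Johnson transform undefined")
    if lmbda is None:
        res = minimize_scalar(
            lambda lam: -stats.yeojohnson_llf(lam, x), bounds=(-5.0, 5.0), method="bounded"
        )
        lmbda = float(res.x)
    t = stats.yeojohnson(x, lmbda=lmbda)
    mean, sd = float(np.mean(t)), float(np.std(t))
    out = np.full_like(arr, np.nan)
    out[mask] = (t - mean) / sd
    return out, TransformParams(lmbda=lmbda, mean=mean, sd=sd)


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman rho (small n).

    Enumerates all n! orderings of the y-ranks (the exact conditional null
    given the observed rank patterns, midranks included).
    """
    n = len(xr)
    perms = np.array(list(itertools.permutations(range(n))))
    xs = (xr - xr.mean())
    ys = (yr - yr.mean())
    denom = math.sqrt((xs * xs).sum() * (ys * ys).sum())
    rhos = (ys[perms] @ xs) / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman(x: Sequence[float], y: Sequence[float],
             var_a: str = "x", var_b: str = "y") -> Optional[AssociationResult]:
    """Spearman rank correlation with two-sided p-value.

    rho is the Pearson correlation of midranked data.  The p-value uses
    the usual t approximation for n >= 10 and exact permutation
    enumeration for n < 10.  Incomplete (NaN) pairs are dropped; fewer
    than 3 complete pairs yields None.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    mask = np.isfinite(xa) & np.isfinite(ya)
    xa, ya = xa[mask], ya[mask]
    n = len(xa)
    if n < 3:
        logger.warning("fewer than 3 complete pairs: no correlation computed")
        return None
    rho, p = stats.spearmanr(xa, ya)
    if n < 10:
        xr = stats.rankdata(xa)
        yr = stats.rankdata(ya)
        p = _exact_spearman_p(xr, yr, float(rho))
    return AssociationResult(var_a=var_a, var_b=var_b, rho=float(rho), p=float(p), n=n)


def correlation_matrix(
    profiles: pd.DataFrame, variables: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """All pairwise Spearman correlations among diversity variables.

    By default pairs the metric variables with each other and with PD, SR
    and PD_resid.  Nulls are dropped pairwise, so a metric with missing
    cells (e.g. J) does not shrink unrelated comparisons; the per-pair n
    is reported.  Returns a tidy frame (var_a, var_b, rho, p, p_holm, n)
    covering each unordered pair once plus the unit diagonal; p_holm is a
    Holm step-down adjustment across the off-diagonal tests.
    """
    if len(profiles) < 10:
        raise ValueError("need >= 10 profiles for the correlation analysis")
    if variables is None:
        variables = [v for v in METRIC_VARIABLES + PHYLO_VARIABLES if v in profiles.columns]
    dropped = [v for v in variables if profiles[v].isna().all()]
    for v in dropped:
        logger.warning("variable %r is all-null: excluded from correlations", v)
    variables = [v for v in variables if v not in dropped]
    rows = []
    for i, a in enumerate(variables):
        for b in variables[i:]:
            if a == b:
                n = int(profiles[a].notna().sum())
                rows.append({"var_a": a, "var_b": b, "rho": 1.0, "p": 0.0, "n": n})
                continue
            res = spearman(profiles[a], profiles[b], var_a=a, var_b=b)
            if res is None:
                rows.append({"var_a": a, "var_b": b, "rho": np.nan, "p": np.nan, "n": 0})
            else:
                rows.append({"var_a": a, "var_b": b, "rho": res.rho, "p": res.p, "n": res.n})
    df = pd.DataFrame(rows, columns=["var_a", "var_b", "rho", "p", "n"])
    off = df["var_a"] != df["var_b"]
    df["p_holm"] = np.nan
    if off.any():
        df.loc[off, "p_holm"] = _holm(df.loc[off, "p"].to_numpy())
    return df[["var_a", "var_b", "rho", "p", "p_holm", "n"]]


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (NaNs passed through)."""
    adj = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    order = np.argsort(ps)
    out = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * ps[idx])
        out[idx] = min(1.0, running)
    adj[ok] = out
    return adj


def pivot_rho(tidy: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric rho matrix from the tidy correlation frame."""
    variables = list(dict.fromkeys(tidy["var_a"]))
    mat = pd.DataFrame(np.nan, index=variables, columns=variables)
    for row in tidy.itertuples(index=False):
        mat.loc[row.var_a, row.var_b] = row.rho
        mat.loc[row.var_b, row.var_a] = row.rho
    return mat


def flag_outliers(
    profiles: pd.DataFrame,
    x_var: str = "PD",
    y_var: str = "J",
    k: float = 2.0,
    frac: float = 2.0 / 3.0,
    it: int = 3,
    region_col: str = "region",
) -> list[OutlierReport]:
    """Regions whose ``y_var`` is >k residual SDs from its LOWESS fit on ``x_var``.

    Residuals come from a robust LOWESS of y on x; z-scores use the
    sample (n-1) SD of the residuals.  Output is sorted by region code,
    so it is invariant to input row order.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    cols = profiles[[region_col, x_var, y_var]].dropna()
    if len(cols) < 10:
        raise ValueError("need >= 10 complete profiles to flag outliers")
    cols = cols.sort_values(region_col, kind="stable")
    x = cols[x_var].to_numpy(dtype=float)
    y = cols[y_var].to_numpy(dtype=float)
    resid = y - lowess_fit(x, y, frac=frac, it=it)
    sd = resid.std(ddof=1)
    # residuals at numerical noise level mean the curve fits exactly
    if sd <= 1e-9 * max(1.0, float(np.abs(y).max())):
        return []
    z = (resid - resid.mean()) / sd
    reports = []
    for region, r, zz in zip(cols[region_col], resid, z):
        if zz > k:
            reports.append(OutlierReport(region, y_var, float(r), float(zz), "high"))
        elif zz < -k:
            reports.append(OutlierReport(region, y_var, float(r), float(zz), "low"))
    return reports


def plot_correlation_heatmap(tidy: pd.DataFrame, path) -> None:
    """Write a rho heatmap PNG for a tidy correlation frame (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = pivot_rho(tidy)
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(mat), 1.0 + 0.6 * len(mat)))
    im = ax.imshow(mat.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(mat)), mat.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)), mat.index)
    for i in range(len(mat)):
        for j in range(len(mat)):
            ax.text(j, i, f"{mat.iat[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
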