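"""Descriptive statistics and trait correlations.

Pearson correlation for pairs of continuous traits, polyserial correlation
(two-step estimator) for a continuous trait against an ordinal one, and a
GGE (genotype plus genotype-by-environment) biplot decomposition of
multi-environment adjusted means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import ndtr, ndtri

logger = logging.getLogger(__name__)

__all__ = [
    "descriptive_stats",
    "pearson_r",
    "polyserial_r",
    "gge_scores",
    "correlation_matrix",
    "GGEResult",
]


def descriptive_stats(v) -> dict:
    """min, max, mean, median and sample SD (n-1 denominator)."""
    x = np.asarray(pd.Series(v).dropna(), dtype=float)
    if x.size == 0:
        raise ValueError("empty trait vector")
    return {
        "min": float(x.min()),
        "max": float(x.max()),
        "mean": float(x.mean()),
        "median": float(np.median(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "n": int(x.size),
    }


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray, int]:
    x = pd.Series(x)
    y = pd.Series(y)
    if not x.index.equals(y.index):
        x, y = x.align(y, join="inner")
    ok = x.notna() & y.notna()
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d incomplete pairs", dropped)
    return x[ok].to_numpy(dtype=float), y[ok].to_numpy(dtype=float), dropped


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-based p-value
    (pairwise-complete alignment by index)."""
    xa, ya, _ = _pairwise_complete(x, y)
    if xa.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(xa) == 0.0 or np.std(ya) == 0.0:
        raise ValueError("undefined correlation: constant input")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def _polyserial_loglik(rho, z, tau_lo, tau_hi):
    """Conditional log-likelihood of the ordinal categories given the
    standardized continuous variable, under a latent bivariate normal."""
    s = np.sqrt(1.0 - rho * rho)
    p = ndtr((tau_hi - rho * z) / s) - ndtr((tau_lo - rho * z) / s)
    return float(np.sum(np.log(np.clip(p, 1e-300, None))))


def polyserial_r(x, y) -> tuple[float, float]:
    """Two-step polyserial correlation of continuous ``x`` with ordinal ``y``.

    Thresholds come from the inverse-normal cumulative category proportions;
    the latent correlation maximizes the conditional bivariate-normal
    likelihood over (-1, 1).  The p-value is a likelihood-ratio test against
    rho = 0 (chi-square, 1 df).
    """
    xa, ya, _ = _pairwise_complete(x, y)
    if xa.size < 10:
        raise ValueError("need at least 10 complete pairs")
    cats, inv = np.unique(ya, return_inverse=True)
    if cats.size < 2:
        raise ValueError("degenerate category structure: fewer than 2 categories")
    if np.std(xa) == 0.0:
        raise ValueError("constant continuous input")
    z = (xa - xa.mean()) / np.std(xa, ddof=1)
    props = np.bincount(inv) / inv.size
    tau = ndtri(np.cumsum(props)[:-1])
    tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
    tau_lo, tau_hi = tau_ext[inv], tau_ext[inv + 1]

    res = optimize.minimize_scalar(
        lambda r: -_polyserial_loglik(r, z, tau_lo, tau_hi),
        bounds=(-0.999, 0.999), method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    lr = 2.0 * (_polyserial_loglik(rho, z, tau_lo, tau_hi)
                - _polyserial_loglik(0.0, z, tau_lo, tau_hi))
    p = float(stats.chi2.sf(max(lr, 0.0), df=1))
    return rho, p


def correlation_matrix(traits: pd.DataFrame, ordinal: tuple = ()) -> pd.DataFrame:
    """Pairwise correlation matrix over line-aligned trait columns.

    Continuous x continuous pairs use Pearson; pairs involving a column
    named in ``ordinal`` use the polyserial estimator (with the ordinal
    trait as the categorical member).  Ordinal x ordinal pairs are skipped
    (NaN).
    """
    cols = list(traits.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            try:
                if a in ordinal and b in ordinal:
                    r = np.nan
                elif b in ordinal:
                    r, _ = polyserial_r(traits[a], traits[b])
                elif a in ordinal:
                    r, _ = polyserial_r(traits[b], traits[a])
                else:
                    r, _ = pearson_r(traits[a], traits[b])
            except ValueError:
                r = np.nan
            out.loc[a, b] = out.loc[b, a] = r
    return out


@dataclass
class GGEResult:
    line_scores: pd.DataFrame     # first two components per line
    env_scores: pd.DataFrame      # first two components per environment
    explained: np.ndarray         # proportion of variance per component


def gge_scores(gy: pd.DataFrame, n_components: int = 2) -> GGEResult:
    """GGE biplot scores from line x environment adjusted means.

    The matrix is environment-centred (removing the environment main
    effect) and decomposed by singular values; scores use symmetric
    scaling (each side carries the square root of the singular values).
    """
    if gy.shape[1] < 2:
        raise ValueError("need at least 2 environments")
    M = gy.to_numpy(dtype=float)
    if np.isnan(M).any():
        raise ValueError("missing cells in the line x environment table")
    C = M - M.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    k = min(n_components, s.size)
    ss_total = float(np.sum(s ** 2))
    explained = (s ** 2 / ss_total) if ss_total > 0 else np.zeros_like(s)
    root = np.sqrt(s[:k])
    line_scores = pd.DataFrame(
        U[:, :k] * root, index=gy.index,
        columns=[f"PC{i+1}" for i in range(k)])
    env_scores = pd.DataFrame(
        Vt[:k].T * root, index=gy.columns,
        columns=[f"PC{i+1}" for i in range(k)])
    return GGEResult(line_scores, env_scores, explained)
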