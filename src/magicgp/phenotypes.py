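"""Trait pre-processing.

Adjusted line means (BLUEs) from replicated raw measurements via a two-way
fixed-effects model, and per-line transpiration-rate values at a target VPD
obtained by fitting and selecting between linear and continuous two-segment
(broken-stick) responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TRFit",
    "compute_blues",
    "fit_tr_linear",
    "fit_tr_segmented",
    "select_tr_model",
    "tr_at_vpd",
    "tr_table_at_vpd",
]


# ---------------------------------------------------------------------------
# BLUEs

def compute_blues(raw: pd.DataFrame) -> pd.DataFrame:
    """BLUE adjusted means from a long table (line, replicate, value).

    Fits the two-way fixed-effects model value = line + replicate + error by
    least squares with a sum-to-zero constraint on replicate effects, so each
    line's BLUE is its estimate at the mean replicate level.  Returns a frame
    indexed by line with columns blue, se, ci_low, ci_high, estimable.
    Lines whose records are disconnected from the rest of the design are
    flagged (estimable=False), not dropped.
    """
    required = {"line", "replicate", "value"}
    if not required.issubset(raw.columns):
        raise ValueError(f"raw table must have columns {sorted(required)}")
    if raw.duplicated(["line", "replicate"]).any():
        raise ValueError("duplicate (line, replicate) records")
    if not np.isfinite(raw["value"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite trait values")
    lines = sorted(raw["line"].unique())
    reps = sorted(raw["replicate"].unique())
    if len(lines) < 2:
        raise ValueError("need at least 2 lines")
    li = raw["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    ri = raw["replicate"].map({r: i for i, r in enumerate(reps)}).to_numpy()
    y = raw["value"].to_numpy(dtype=float)
    n, nl, nr = len(y), len(lines), len(reps)

    # design: line dummies (full set) + sum-coded replicate (nr-1 columns)
    X = np.zeros((n, nl + nr - 1))
    X[np.arange(n), li] = 1.0
    for j in range(nr - 1):
        X[ri == j, nl + j] = 1.0
        X[ri == nr - 1, nl + j] = -1.0
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(XtX)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - rank, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(XtX)
    se = np.sqrt(np.clip(np.diag(cov)[:nl], 0.0, None))
    tcrit = stats.t.ppf(0.975, dof)

    # a line confined to replicates that contain no other line is adjusted
    # only through the sum-to-zero constraint, not the data: flag it
    estimable = np.ones(nl, dtype=bool)
    for i, l in enumerate(lines):
        own_reps = set(raw.loc[raw["line"] == l, "replicate"])
        others = set(raw.loc[raw["line"] != l, "replicate"])
        if not (own_reps & others):
            estimable[i] = False
    if not estimable.all():
        logger.warning("%d line(s) disconnected from the design; flagged inestimable",
                       int((~estimable).sum()))
    if rank < nl + nr - 1:
        logger.warning("BLUE design is rank-deficient (%d < %d)", rank, nl + nr - 1)
    out = pd.DataFrame(
        {
            "blue": coef[:nl],
            "se": se,
            "ci_low": coef[:nl] - tcrit * se,
            "ci_high": coef[:nl] + tcrit * se,
            "estimable": estimable,
        },
        index=pd.Index(lines, name="line"),
    )
    return out


# ---------------------------------------------------------------------------
# TR response to VPD

@dataclass
class TRFit:
    """Fitted TR-vs-VPD response for one line.

    kind is "linear" (tr = intercept + slope1 * vpd) or "segmented"
    (tr = intercept + slope1 * min(vpd, breakpoint)
            + slope2 * max(0, vpd - breakpoint), continuous at the
    breakpoint).  ``vpd_min``/``vpd_max`` record the fitted grid range so
    evaluation can warn on extrapolation.
    """

    kind: str
    intercept: float
    slope1: float
    r_squared: float
    sse: float
    vpd_min: float
    vpd_max: float
    slope2: float = float("nan")
    breakpoint: float = float("nan")
    line_id: str | None = None


def _r2(y: np.ndarray, fitted: np.ndarray) -> tuple[float, float]:
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0.0 else max(0.0, 1.0 - sse / sst)
    return r2, sse


def fit_tr_linear(vpd: np.ndarray, tr: np.ndarray, line_id: str | None = None) -> TRFit:
    """Ordinary least-squares line; R^2 defined as 0 for a constant response."""
    vpd = np.asarray(vpd, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if vpd.size < 3:
        raise ValueError("need at least 3 points for a linear TR fit")
    if not np.all(np.diff(vpd) > 0):
        raise ValueError("vpd grid must be strictly increasing")
    sxx = float(np.sum((vpd - vpd.mean()) ** 2))
    slope = float(np.sum((vpd - vpd.mean()) * (tr - tr.mean())) / sxx)
    intercept = float(tr.mean() - slope * vpd.mean())
    r2, sse = _r2(tr, intercept + slope * vpd)
    return TRFit("linear", intercept, slope, r2, sse,
                 float(vpd[0]), float(vpd[-1]), line_id=line_id)


def fit_tr_segmented(
    vpd: np.ndarray, tr: np.ndarray, grid_step: float = 0.01, line_id: str | None = None
) -> TRFit:
    """Continuous broken-stick fit with the breakpoint found by grid search.

    TR = b0 + b1*min(vpd, bp) + b2*max(0, vpd - bp); bp scans the interior
    of the grid (between the 2nd and penultimate points) at ``grid_step``
    minimizing SSE, with segment coefficients from OLS given bp.
    """
    vpd = np.asarray(vpd, dtype=float)
    tr = np.asarray(tr, dtype=float)
    if vpd.size < 5:
        raise ValueError("need at least 5 points for a segmented TR fit")
    if not np.all(np.diff(vpd) > 0):
        raise ValueError("vpd grid must be strictly increasing")
    lo, hi = vpd[1], vpd[-2]
    if hi <= lo:
        raise ValueError("too few interior points for a breakpoint grid")
    grid = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    best = None
    for bp in grid:
        X = np.column_stack([
            np.ones_like(vpd), np.minimum(vpd, bp), np.maximum(0.0, vpd - bp)
        ])
        coef, *_ = np.linalg.lstsq(X, tr, rcond=None)
        sse = float(np.sum((tr - X @ coef) ** 2))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, bp, coef)
    sse, bp, coef = best
    r2, sse = _r2(tr, coef[0] + coef[1] * np.minimum(vpd, bp)
                  + coef[2] * np.maximum(0.0, vpd - bp))
    return TRFit("segmented", float(coef[0]), float(coef[1]), r2, sse,
                 float(vpd[0]), float(vpd[-1]),
                 slope2=float(coef[2]), breakpoint=float(bp), line_id=line_id)


def select_tr_model(linear: TRFit, segmented: TRFit, min_gain: float = 0.01) -> TRFit:
    """Pick the segmented fit only when it buys more than ``min_gain`` R^2.

    Plain R^2 always favours the larger (nested) model, so a small gain
    threshold is required; the breakpoint must also be interior to the grid.
    """
    gain = segmented.r_squared - linear.r_squared
    interior = linear.vpd_min < segmented.breakpoint < linear.vpd_max
    return segmented if (gain > min_gain and interior) else linear


def tr_at_vpd(fit: TRFit, vpd: float) -> float:
    """Evaluate the fitted response; warns (but answers) outside the grid."""
    if not (fit.vpd_min <= vpd <= fit.vpd_max):
        warnings.warn(
            f"VPD {vpd} outside the fitted grid [{fit.vpd_min}, {fit.vpd_max}]; "
            "extrapolating", stacklevel=2,
        )
    if fit.kind == "linear":
        return fit.intercept + fit.slope1 * vpd
    return (fit.intercept + fit.slope1 * min(vpd, fit.breakpoint)
            + fit.slope2 * max(0.0, vpd - fit.breakpoint))


def tr_table_at_vpd(
    curves: pd.DataFrame,
    target_vpd: float = 2.7,
    grid_step: float = 0.01,
    min_gain: float = 0.01,
    use_nearest_raw: bool = False,
) -> pd.DataFrame:
    """Per-line TR at ``target_vpd`` from model-selected fits.

    ``curves`` is long format (line, vpd, tr).  Default reports the fitted
    value at the target VPD; ``use_nearest_raw`` switches to the raw
    measurement at the grid point closest to it.  Returns a frame indexed by
    line with columns kind, breakpoint, r2, tr.
    """
    rows = {}
    for line, sub in curves.groupby("line", sort=True):
        sub = sub.sort_values("vpd")
        v, t = sub["vpd"].to_numpy(), sub["tr"].to_numpy()
        lin = fit_tr_linear(v, t, line_id=str(line))
        seg = fit_tr_segmented(v, t, grid_step=grid_step, line_id=str(line))
        fit = select_tr_model(lin, seg, min_gain=min_gain)
        if use_nearest_raw:
            tr_val = float(t[np.argmin(np.abs(v - target_vpd))])
        else:
            tr_val = tr_at_vpd(fit, target_vpd)
        rows[line] = {
            "kind": fit.kind, "breakpoint": fit.breakpoint,
            "r2": fit.r_squared, "tr": tr_val,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "line"
    return out
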