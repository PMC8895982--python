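"""Leave-one-out cross-validation and prediction scores.

Scores: the halved Brier score (0 best, 1 worst), the proportion of cases
correctly classified (PCCC, modal category with ties broken toward the
lower label), and Pearson predictive ability between predictions and
observed adjusted means.  Two LOO units are supported: ``observation``
(one replicate record held out; its line keeps its other records) and
``line`` (all of a line's records held out and the line predicted through
its kernel rows).  For interval-censored traits, ``retain_bounds`` keeps
the held-out record in the fit as a bounds-only observation — an
information-leaking convention that is deliberately available and always
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .gp import (
    GPFit,
    MCMCSettings,
    PredictorSpec,
    fit_censored,
    fit_gaussian,
    fit_lognormal_count,
    fit_ordinal_threshold,
)
from .kernels import Kernel

__all__ = [
    "CVResult",
    "CV_SETTINGS",
    "loo_cross_validate",
    "brier_score",
    "pccc",
    "predictive_ability_r",
    "variance_component_table",
]

#: Reduced chain settings used inside CV folds unless overridden.
CV_SETTINGS = MCMCSettings(n_iter=6000, burn_in=1000, thin=5)


@dataclass
class CVResult:
    family: str
    unit: str
    retain_bounds: bool
    folds: pd.DataFrame          # one row per held-out unit/record
    scores: dict                 # brier/pccc or predictive_ability
    n_folds: int


# ---------------------------------------------------------------------------
# scores

def _check_probs(probs: np.ndarray) -> np.ndarray:
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    sums = probs.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-6):
        raise ValueError("probability rows must sum to 1 (tol 1e-6)")
    return probs


def brier_score(probs: np.ndarray, observed, labels) -> float:
    """Halved Brier score: (1/n) sum_i sum_c (pi_ic - d_ic)^2 / 2."""
    probs = _check_probs(probs)
    labels = list(labels)
    pos = {c: j for j, c in enumerate(labels)}
    obs = [pos[c] for c in observed]
    d = np.zeros_like(probs)
    d[np.arange(len(obs)), obs] = 1.0
    return float(np.mean(np.sum((probs - d) ** 2, axis=1)) / 2.0)


def pccc(probs: np.ndarray, observed, labels) -> float:
    """Modal-category accuracy; ties go to the lower category label."""
    probs = _check_probs(probs)
    labels = list(labels)
    modal = [labels[j] for j in np.argmax(probs, axis=1)]  # argmax -> first/lowest
    return float(np.mean([m == o for m, o in zip(modal, observed)]))


def predictive_ability_r(predicted, observed) -> float:
    """Sample Pearson correlation between predictions and observations."""
    x = np.asarray(predicted, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 entries")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: constant vector")
    return float(np.corrcoef(x, y)[0, 1])


def variance_component_table(fits: dict) -> pd.DataFrame:
    """Per-model variance components with their percent of the total.

    ``fits`` maps a model name to its :class:`GPFit`.  Components are the
    posterior means of each random-term variance plus the residual; percents
    sum to 100 within each model.
    """
    rows = []
    for model, fit in fits.items():
        vc = fit.variance_components["mean"]
        total = float(vc.sum())
        for comp, est in vc.items():
            rows.append({
                "model": model, "component": comp, "estimate": float(est),
                "percent": 100.0 * float(est) / total,
            })
        rows.append({"model": model, "component": "total",
                     "estimate": total, "percent": 100.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# LOO machinery

_FITTERS = {
    "gaussian": fit_gaussian,
    "censored": fit_censored,
    "ordinal": fit_ordinal_threshold,
    "lognormal": fit_lognormal_count,
}


def _predict_genetic(fit: GPFit, kernels: dict, new_line) -> float:
    """Genetic value of one unseen line from its kernel cross-rows."""
    total = 0.0
    for name in fit.effects:
        if name == "L":
            continue  # iid effect of an unseen line is 0
        kern: Kernel = kernels[name]
        rows = kern.cross_rows([new_line], fit.line_ids)
        u_mean = fit.effects[name]["mean"].to_numpy()
        V, lam = fit._kernel_spectra[name]
        alpha = V @ ((V.T @ u_mean) / lam)
        total += float((rows @ alpha)[0])
    return total


def _ordinal_probs(fit: GPFit, eta: np.ndarray) -> np.ndarray:
    gmean = fit.gamma["mean"].to_numpy()
    gext = np.concatenate(([-np.inf], gmean, [np.inf]))
    cdf = ndtr(gext[None, 1:-1] - eta[:, None])
    cdf = np.concatenate([np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1)
    return np.diff(cdf, axis=1)


def _beta_at(fit: GPFit, rep) -> float:
    if not len(fit.fixed_names):
        return 0.0
    if rep is not None and rep in fit.fixed_names:
        return float(fit.beta.loc[rep, "mean"])
    return float(fit.beta["mean"].mean())


def loo_cross_validate(
    data: pd.DataFrame | pd.Series,
    spec: PredictorSpec,
    family: str,
    kernels=None,
    settings: MCMCSettings | None = None,
    unit: str | None = None,
    retain_bounds: bool = False,
) -> CVResult:
    """Leave-one-out cross-validation of one model.

    ``data`` follows the family's fitting convention (long line/replicate/
    value for ordinal and count; per-line value or line/value/lower/upper
    for Gaussian and censored).  ``unit`` defaults to ``observation`` for
    replicated data and ``line`` otherwise.  Each fold refits the model at
    ``settings`` (default :data:`CV_SETTINGS`) with the fold index folded
    into the seed, and predicts the held-out unit.
    """
    if family not in _FITTERS:
        raise ValueError(f"unknown family {family!r}")
    settings = settings or CV_SETTINGS
    if isinstance(data, pd.Series):
        data = pd.DataFrame({"line": data.index, "value": data.to_numpy()})
    data = data.reset_index(drop=True)
    replicated = "replicate" in data.columns and family in ("ordinal", "lognormal")
    if unit is None:
        unit = "observation" if replicated else "line"
    if unit not in ("observation", "line"):
        raise ValueError("unit must be 'observation' or 'line'")
    if retain_bounds and family != "censored":
        raise ValueError("retain_bounds applies to the censored family only")
    kd = {}
    from .gp import _normalize_kernels  # shared normalization
    kd = _normalize_kernels(kernels)

    lines = list(pd.unique(data["line"]))
    if unit == "line":
        units = lines
    else:
        units = list(data.index)
    if len(units) < 3:
        raise ValueError("need at least 3 held-out units")
    if unit == "line" and len(lines) < 2:
        raise ValueError("line-level LOO needs more than one line")

    fold_rows = []
    for f, held in enumerate(units):
        fold_settings = replace(settings, seed=settings.seed + f)
        if unit == "line":
            mask = data["line"] == held
        else:
            mask = data.index == held
        test = data[mask]
        if retain_bounds:
            train = data.copy()
            train.loc[mask, "value"] = np.nan  # bounds stay, value hidden
        else:
            train = data[~mask]
        fit = _FITTERS[family](train, spec, kernels=kd, settings=fold_settings)

        held_lines_in_train = unit == "observation" or retain_bounds
        for _, rec in test.iterrows():
            line = rec["line"]
            rep = rec.get("replicate")
            if held_lines_in_train:
                eta = float(fit.fitted_for([line], [rep] if rep is not None else None)[0])
            else:
                eta = _predict_genetic(fit, kd, line) + _beta_at(fit, rep)
            row = {"fold": f, "line": line, "eta": eta}
            if rep is not None:
                row["replicate"] = rep
            if family == "ordinal":
                probs = _ordinal_probs(fit, np.array([eta]))[0]
                row["observed"] = int(rec["value"])
                for j, lab in enumerate(fit.category_labels):
                    row[f"p{lab}"] = probs[j]
                row["labels"] = tuple(fit.category_labels)
            elif family == "lognormal":
                row["observed"] = np.log(float(rec["value"]) + 1.0)
                row["predicted"] = eta
                row["predicted_count"] = np.exp(eta) - 1.0
            else:
                row["observed"] = float(rec["value"])
                row["predicted"] = eta
            fold_rows.append(row)

    folds = pd.DataFrame(fold_rows)
    scores: dict = {}
    if family == "ordinal":
        labels = fold_rows[0]["labels"]
        probs = folds[[f"p{lab}" for lab in labels]].to_numpy()
        scores["brier_score"] = brier_score(probs, folds["observed"], labels)
        scores["pccc"] = pccc(probs, folds["observed"], labels)
        folds = folds.drop(columns=["labels"])
    else:
        if family == "lognormal" and unit == "line":
            # score per line: predicted genetic value vs observed line mean
            per_line = folds.groupby("line").agg(
                predicted=("predicted", "mean"), observed=("observed", "mean"))
            scores["predictive_ability"] = predictive_ability_r(
                per_line["predicted"], per_line["observed"])
        else:
            scores["predictive_ability"] = predictive_ability_r(
                folds["predicted"], folds["observed"])
    return CVResult(
        family=family, unit=unit, retain_bounds=retain_bounds,
        folds=folds, scores=scores, n_folds=len(units),
    )
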