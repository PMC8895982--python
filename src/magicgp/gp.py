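"""Bayesian kernel-regression (GBLUP-family) Gibbs samplers.

One engine serves four response families:

* ``gaussian`` — y = fixed + L + g + gA + e, conjugate updates throughout;
* ``censored`` — Gaussian with interval observations a_i < y_i < b_i whose
  latent values are re-imputed from truncated normals each sweep;
* ``ordinal`` — probit threshold model: latent liabilities are imputed from
  truncated normals given the category cut-points, cut-points from their
  uniform full conditionals (Albert–Chib), residual variance fixed at 1;
* ``lognormal`` — counts analysed as log(y + 1) through the Gaussian engine,
  fitted values back-transformed.

Random effects with kernel covariance K*sigma^2 are sampled in the kernel
eigenbasis (u = V delta, delta_j ~ N(0, sigma^2 lambda_j)); for balanced
designs the full conditional of delta is diagonal, giving O(n) updates per
term.  Variance components get scaled-inverse-chi-square updates with a
weak proper prior (df 5, scale set from a prior variance split of the
response, see :class:`MCMCSettings`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .kernels import Kernel, eigendecompose, identity_kernel

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSpec",
    "MCMCSettings",
    "GPFit",
    "fit_gaussian",
    "fit_censored",
    "fit_ordinal_threshold",
    "fit_lognormal_count",
    "predict_new_lines",
]


# ---------------------------------------------------------------------------
# specs and settings

@dataclass(frozen=True)
class PredictorSpec:
    """Which linear predictors enter a model (the machine form of the five
    standard predictor sets: 1 R+L, 2 R+G, 3 R+G+GxG, 4 R+L+G, 5 all)."""

    include_replicate: bool = True
    include_line: bool = True
    include_markers: bool = True
    include_epistasis: bool = True

    def __post_init__(self) -> None:
        if not (self.include_line or self.include_markers):
            raise ValueError("model needs at least one of line (L) or marker (G) effects")
        if self.include_epistasis and not self.include_markers:
            raise ValueError("epistasis (GxG) requires the marker kernel (G)")

    @classmethod
    def from_model_number(cls, m: int) -> "PredictorSpec":
        table = {
            1: (True, False, False),
            2: (False, True, False),
            3: (False, True, True),
            4: (True, True, False),
            5: (True, True, True),
        }
        if m not in table:
            raise ValueError("model number must be 1..5")
        L, G, GxG = table[m]
        return cls(include_replicate=True, include_line=L,
                   include_markers=G, include_epistasis=GxG)

    @property
    def term_names(self) -> list[str]:
        out = []
        if self.include_line:
            out.append("L")
        if self.include_markers:
            out.append("G")
        if self.include_epistasis:
            out.append("GxG")
        return out


@dataclass(frozen=True)
class MCMCSettings:
    """Chain settings and prior hyper-parameters.

    Each variance component has a scaled-inverse-chi-square prior with
    ``prior_df`` degrees of freedom; prior scales are set so the prior mode
    splits ``prior_r2`` of the response variance equally among the included
    random terms, the rest going to the residual.
    """

    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not (0.0 < self.prior_r2 < 1.0):
            raise ValueError("prior_r2 must be in (0, 1)")


@dataclass
class GPFit:
    """Posterior summaries of one fitted model."""

    family: str
    spec: PredictorSpec
    settings: MCMCSettings
    line_ids: list
    fixed_names: list
    beta: pd.DataFrame                      # mean, ci_low, ci_high per fixed effect
    effects: dict                           # term -> DataFrame(mean, ci_low, ci_high) by line
    variance_components: pd.DataFrame       # mean, ci_low, ci_high, ess by component
    fitted: np.ndarray                      # posterior-mean linear predictor per obs
    obs_lines: list                         # line id per observation
    obs_replicates: list | None
    residual_fixed: bool
    gamma: pd.DataFrame | None = None       # thresholds (ordinal)
    category_labels: list | None = None
    fitted_probs: np.ndarray | None = None  # n_obs x C posterior-mean probabilities
    fitted_counts: np.ndarray | None = None # back-transformed (lognormal)
    anchored: dict | None = None            # ordinal: location-anchored beta/gamma
    beta_draws: np.ndarray | None = None
    gamma_draws: np.ndarray | None = None
    var_draws: dict | None = None
    _kernel_spectra: dict = field(default_factory=dict, repr=False)

    @property
    def n_draws(self) -> int:
        return 0 if self.beta_draws is None else self.beta_draws.shape[0]

    def genomic_values(self) -> pd.Series:
        """Posterior-mean total genetic value per training line."""
        total = np.zeros(len(self.line_ids))
        for term in self.effects:
            total = total + self.effects[term]["mean"].to_numpy()
        return pd.Series(total, index=pd.Index(self.line_ids, name="line"))

    def fitted_for(self, lines, replicates=None) -> np.ndarray:
        """Linear predictor for training lines at given (optional) replicates."""
        gv = self.genomic_values()
        eta = gv.loc[list(lines)].to_numpy()
        bmean = self.beta["mean"].to_numpy()
        if replicates is not None and self.obs_replicates is not None:
            rep_pos = {r: i for i, r in enumerate(self.fixed_names)}
            eta = eta + np.array([bmean[rep_pos[r]] for r in replicates])
        elif bmean.size:
            eta = eta + bmean.mean()
        return eta

    def summary_json(self) -> dict:
        out = {
            "family": self.family,
            "spec": {
                "replicate": self.spec.include_replicate,
                "line": self.spec.include_line,
                "markers": self.spec.include_markers,
                "epistasis": self.spec.include_epistasis,
            },
            "settings": {
                "n_iter": self.settings.n_iter, "burn_in": self.settings.burn_in,
                "thin": self.settings.thin, "seed": self.settings.seed,
                "prior_df": self.settings.prior_df, "prior_r2": self.settings.prior_r2,
            },
            "beta": self.beta.to_dict(orient="index"),
            "variance_components": self.variance_components.to_dict(orient="index"),
        }
        if self.gamma is not None:
            out["gamma"] = self.gamma.to_dict(orient="index")
        return out


# ---------------------------------------------------------------------------
# numerics

def _trunc_norm(rng, mean, sd, lo, hi):
    """Vectorized truncated-normal draws by inverse CDF, tail-safe."""
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    u = rng.uniform(np.minimum(a, b), np.maximum(a, b))
    u = np.clip(u, 1e-13, 1.0 - 1e-13)
    x = mean + sd * ndtri(u)
    return np.clip(x, lo, hi)


def _ess(x: np.ndarray) -> float:
    """Effective sample size via Geyer's initial positive sequence."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var <= 0 or n < 4:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (n * var)
    s, t = 0.0, 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        s += pair
        t += 2
    return float(min(n, n / (1.0 + 2.0 * s)))


def _summary_frame(draws: np.ndarray, names) -> pd.DataFrame:
    mean = draws.mean(axis=0)
    lo = np.quantile(draws, 0.025, axis=0)
    hi = np.quantile(draws, 0.975, axis=0)
    return pd.DataFrame({"mean": mean, "ci_low": lo, "ci_high": hi},
                        index=pd.Index(names))


def _normalize_kernels(kernels) -> dict:
    """Accept (G, GxG) tuples, single kernels, or {'G':..,'GxG':..} dicts."""
    if kernels is None:
        return {}
    if isinstance(kernels, Kernel):
        kernels = (kernels,)
    if isinstance(kernels, (tuple, list)):
        return {k.label: k for k in kernels}
    return dict(kernels)


def _aligned_kernel(kern: Kernel, line_ids: list) -> Kernel:
    if list(kern.line_ids) == list(line_ids):
        return kern if kern.eigenvalues is not None else eigendecompose(kern)
    missing = set(line_ids) - set(kern.line_ids)
    if missing:
        raise ValueError(f"kernel {kern.label} is missing lines {sorted(missing)[:5]}")
    return kern.subset(line_ids)


# ---------------------------------------------------------------------------
# the Gibbs engine

def _run_gibbs(
    *,
    family: str,
    y: np.ndarray,
    line_idx: np.ndarray,
    line_ids: list,
    rep_idx: np.ndarray | None,
    rep_names: list,
    spec: PredictorSpec,
    kernels: dict,
    settings: MCMCSettings,
    fixed_variances: dict | None = None,
    cat_idx: np.ndarray | None = None,
    n_cat: int = 0,
    cens_lo: np.ndarray | None = None,
    cens_hi: np.ndarray | None = None,
    cens_free: np.ndarray | None = None,
    include_intercept: bool = False,
) -> GPFit:
    rng = np.random.default_rng(settings.seed)
    fixed_variances = dict(fixed_variances or {})
    n_obs = y.size
    n = len(line_ids)
    counts = np.bincount(line_idx, minlength=n).astype(float)
    ordinal = family == "ordinal"
    censored = family == "censored"

    # --- fixed-effect design: replicate dummies XOR a lone intercept
    if rep_idx is not None:
        n_fixed = len(rep_names)
        fixed_counts = np.bincount(rep_idx, minlength=n_fixed).astype(float)
        fixed_names = list(rep_names)
    elif include_intercept:
        n_fixed = 1
        rep_idx = np.zeros(n_obs, dtype=int)
        fixed_counts = np.array([float(n_obs)])
        fixed_names = ["intercept"]
    else:
        n_fixed = 0
        fixed_counts = np.zeros(0)
        fixed_names = []

    # --- random terms in the eigenbasis
    terms = []
    for name in spec.term_names:
        if name == "L":
            kern = identity_kernel(line_ids)
        else:
            kern = kernels[name]
        lam = kern.eigenvalues
        keep = lam > 1e-10
        terms.append({
            "name": name,
            "identity": name == "L",
            "V": kern.eigenvectors[:, keep],
            "lam": lam[keep],
            "kern": kern,
        })
    balanced = bool(np.all(counts == counts[0]))

    # --- latent-response initialization (also anchors the prior scale)
    if ordinal:
        freq = np.bincount(cat_idx, minlength=n_cat).astype(float)
        empty = np.where(freq == 0)[0]
        if empty.size:
            warnings.warn(
                f"{empty.size} ordinal categor(ies) unobserved; their thresholds "
                "are weakly identified", stacklevel=3)
        cum = np.clip(np.cumsum(freq)[:-1] / freq.sum(), 1e-4, 1 - 1e-4)
        gamma = np.sort(ndtri(cum))
        # enforce strict increase for degenerate starts
        for c in range(1, gamma.size):
            if gamma[c] <= gamma[c - 1]:
                gamma[c] = gamma[c - 1] + 1e-4
        gext = np.concatenate(([-np.inf], gamma, [np.inf]))
        lo_i = gext[cat_idx]
        hi_i = gext[cat_idx + 1]
        y_lat = np.clip((np.nan_to_num(lo_i, neginf=gamma[0] - 1.0)
                         + np.nan_to_num(hi_i, posinf=gamma[-1] + 1.0)) / 2.0, -6, 6)
        cat_members = [np.where(cat_idx == c)[0] for c in range(n_cat)]
    else:
        gamma = np.zeros(0)
        y_lat = y.copy()
        if censored:
            mid = np.where(
                np.isfinite(cens_lo) & np.isfinite(cens_hi),
                (cens_lo + cens_hi) / 2.0, 0.0)
            y_lat = np.where(cens_free, mid, y_lat)
            y_lat = np.where(np.isnan(y_lat), 0.0, y_lat)

    # --- priors
    df0 = settings.prior_df
    if ordinal:
        var_y = 1.0
    else:
        var_y = float(np.var(y_lat))
        if not np.isfinite(var_y) or var_y <= 0.0:
            var_y = 1.0
    n_terms = max(len(terms), 1)
    prior_scale = {}
    for t in terms:
        mode = settings.prior_r2 * var_y / n_terms
        prior_scale[t["name"]] = mode * (df0 + 2.0) / df0
    prior_scale["residual"] = (1.0 - settings.prior_r2) * var_y * (df0 + 2.0) / df0

    # --- state
    sig2 = {t["name"]: fixed_variances.get(t["name"], settings.prior_r2 * var_y / n_terms)
            for t in terms}
    sig2_e = fixed_variances.get(
        "residual", 1.0 if ordinal else (1.0 - settings.prior_r2) * var_y)
    residual_fixed = ordinal or ("residual" in fixed_variances)
    u = {t["name"]: np.zeros(n) for t in terms}
    delta = {t["name"]: np.zeros(t["lam"].size) for t in terms}
    beta = np.zeros(n_fixed)

    e = y_lat.copy()
    if n_fixed:
        # start fixed effects at group means
        beta = np.bincount(rep_idx, weights=e, minlength=n_fixed) / np.maximum(fixed_counts, 1)
        e = e - beta[rep_idx]

    n_keep = -((settings.n_iter - settings.burn_in) // -settings.thin)
    beta_draws = np.empty((n_keep, n_fixed))
    gamma_draws = np.empty((n_keep, gamma.size))
    var_draws = {t["name"]: np.empty(n_keep) for t in terms}
    var_draws["residual"] = np.empty(n_keep)
    u_draws = {t["name"]: np.empty((n_keep, n)) for t in terms}
    eta_sum = np.zeros(n_obs)
    probs_sum = np.zeros((n_obs, n_cat)) if ordinal else None
    count_sum = np.zeros(n_obs) if family == "lognormal" else None
    kept = 0

    for it in range(settings.n_iter):
        # -- data augmentation
        if ordinal:
            eta = y_lat - e
            gext = np.concatenate(([-np.inf], gamma, [np.inf]))
            new_lat = _trunc_norm(rng, eta, 1.0, gext[cat_idx], gext[cat_idx + 1])
            e += new_lat - y_lat
            y_lat = new_lat
            # Albert–Chib uniform threshold updates
            for c in range(gamma.size):
                lo_c = gamma[c - 1] if c > 0 else -np.inf
                hi_c = gamma[c + 1] if c + 1 < gamma.size else np.inf
                mem_lo = cat_members[c]
                mem_hi = cat_members[c + 1]
                if mem_lo.size:
                    lo_c = max(lo_c, y_lat[mem_lo].max())
                if mem_hi.size:
                    hi_c = min(hi_c, y_lat[mem_hi].min())
                if np.isfinite(lo_c) and np.isfinite(hi_c) and hi_c > lo_c:
                    gamma[c] = rng.uniform(lo_c, hi_c)
                # else: keep the current value (unidentified window)
        elif censored and cens_free.any():
            eta = y_lat - e
            new_lat = y_lat.copy()
            new_lat[cens_free] = _trunc_norm(
                rng, eta[cens_free], np.sqrt(sig2_e),
                cens_lo[cens_free], cens_hi[cens_free])
            e += new_lat - y_lat
            y_lat = new_lat

        # -- fixed effects (flat prior; orthogonal dummy groups)
        if n_fixed:
            e += beta[rep_idx]
            gsum = np.bincount(rep_idx, weights=e, minlength=n_fixed)
            beta = gsum / fixed_counts + rng.standard_normal(n_fixed) * np.sqrt(
                sig2_e / fixed_counts)
            e -= beta[rep_idx]

        # -- random terms
        for t in terms:
            name = t["name"]
            e += u[name][line_idx]
            s = np.bincount(line_idx, weights=e, minlength=n)
            if t["identity"]:
                prec = counts / sig2_e + 1.0 / sig2[name] if sig2[name] > 0 else None
                if sig2[name] <= 0:
                    u_new = np.zeros(n)
                else:
                    mean = (s / sig2_e) / prec
                    u_new = mean + rng.standard_normal(n) / np.sqrt(prec)
                delta[name] = u_new
            else:
                V, lam = t["V"], t["lam"]
                if sig2[name] <= 0:
                    u_new = np.zeros(n)
                    delta[name] = np.zeros(lam.size)
                else:
                    w = V.T @ s
                    if balanced:
                        prec = counts[0] / sig2_e + 1.0 / (sig2[name] * lam)
                        d = (w / sig2_e) / prec + rng.standard_normal(lam.size) / np.sqrt(prec)
                    else:
                        P = (V.T * counts) @ V / sig2_e + np.diag(1.0 / (sig2[name] * lam))
                        C = np.linalg.cholesky(P)
                        mu_d = np.linalg.solve(C.T, np.linalg.solve(C, w / sig2_e))
                        d = mu_d + np.linalg.solve(C.T, rng.standard_normal(lam.size))
                    delta[name] = d
                    u_new = V @ d
            u[name] = u_new
            e -= u_new[line_idx]

            # variance update
            if name not in fixed_variances:
                if t["identity"]:
                    ss = float(u_new @ u_new)
                    m = n
                else:
                    ss = float(np.sum(delta[name] ** 2 / t["lam"]))
                    m = t["lam"].size
                sig2[name] = (df0 * prior_scale[name] + ss) / rng.chisquare(df0 + m)

        # -- residual variance
        if not residual_fixed:
            ss = float(e @ e)
            sig2_e = (df0 * prior_scale["residual"] + ss) / rng.chisquare(df0 + n_obs)

        # -- record
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            beta_draws[kept] = beta
            gamma_draws[kept] = gamma
            for t in terms:
                var_draws[t["name"]][kept] = sig2[t["name"]]
                u_draws[t["name"]][kept] = u[t["name"]]
            var_draws["residual"][kept] = sig2_e
            eta = y_lat - e
            eta_sum += eta
            if ordinal:
                gext = np.concatenate(([-np.inf], gamma, [np.inf]))
                cdf = ndtr(gext[None, 1:-1] - eta[:, None])
                cdf = np.concatenate(
                    [np.zeros((n_obs, 1)), cdf, np.ones((n_obs, 1))], axis=1)
                probs_sum += np.diff(cdf, axis=1)
            if count_sum is not None:
                count_sum += np.exp(eta) - 1.0
            kept += 1

    # --- summaries
    fitted = eta_sum / max(kept, 1)
    vc_rows = {}
    for name in [t["name"] for t in terms] + ["residual"]:
        d = var_draws[name]
        vc_rows[name] = {
            "mean": d.mean(), "ci_low": np.quantile(d, 0.025),
            "ci_high": np.quantile(d, 0.975), "ess": _ess(d),
        }
        if vc_rows[name]["ess"] < 100 and name not in fixed_variances and not (
                name == "residual" and residual_fixed):
            logger.warning("effective sample size for %s variance is %.0f (<100)",
                           name, vc_rows[name]["ess"])
    effects = {
        t["name"]: _summary_frame(u_draws[t["name"]], line_ids) for t in terms
    }
    fit = GPFit(
        family=family,
        spec=spec,
        settings=settings,
        line_ids=list(line_ids),
        fixed_names=fixed_names,
        beta=_summary_frame(beta_draws, fixed_names) if n_fixed else
             pd.DataFrame(columns=["mean", "ci_low", "ci_high"]),
        effects=effects,
        variance_components=pd.DataFrame.from_dict(vc_rows, orient="index"),
        fitted=fitted,
        obs_lines=[line_ids[i] for i in line_idx],
        obs_replicates=None,
        residual_fixed=residual_fixed,
        beta_draws=beta_draws,
        gamma_draws=gamma_draws if ordinal else None,
        var_draws=var_draws,
        _kernel_spectra={t["name"]: (t["V"], t["lam"]) for t in terms if not t["identity"]},
    )
    if ordinal:
        fit.gamma = _summary_frame(gamma_draws, [f"gamma{c+1}" for c in range(gamma.size)])
        fit.fitted_probs = probs_sum / max(kept, 1)
        # location anchoring: a constant can trade between beta and gamma
        shift = beta_draws.mean(axis=1, keepdims=True) if n_fixed else 0.0
        fit.anchored = {
            "beta": _summary_frame(beta_draws - shift, fixed_names),
            "gamma": _summary_frame(
                gamma_draws - (shift if n_fixed else 0.0),
                [f"gamma{c+1}" for c in range(gamma.size)]),
        }
    if count_sum is not None:
        fit.fitted_counts = count_sum / max(kept, 1)
    return fit


# ---------------------------------------------------------------------------
# public fitting fronts

def _prepare_replicated(obs: pd.DataFrame, spec: PredictorSpec, kernels):
    required = {"line", "value"}
    if not required.issubset(obs.columns):
        raise ValueError("observation table needs columns line, value")
    line_ids = sorted(pd.unique(obs["line"]))
    lpos = {l: i for i, l in enumerate(line_ids)}
    line_idx = obs["line"].map(lpos).to_numpy()
    if spec.include_replicate:
        if "replicate" not in obs.columns:
            raise ValueError("spec includes replicate effects but table has no replicate column")
        rep_names = sorted(pd.unique(obs["replicate"]))
        rpos = {r: i for i, r in enumerate(rep_names)}
        rep_idx = obs["replicate"].map(rpos).to_numpy()
    else:
        rep_names, rep_idx = [], None
    kd = _normalize_kernels(kernels)
    aligned = {}
    if spec.include_markers:
        aligned["G"] = _aligned_kernel(kd["G"], line_ids)
    if spec.include_epistasis:
        aligned["GxG"] = _aligned_kernel(kd["GxG"], line_ids)
    return line_ids, line_idx, rep_names, rep_idx, aligned


def fit_gaussian(
    obs: pd.DataFrame | pd.Series,
    spec: PredictorSpec,
    kernels=None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
    include_intercept: bool = True,
    family: str = "gaussian",
) -> GPFit:
    """Gaussian-response fit.

    ``obs`` is either a Series indexed by line (one record per line; the
    model then has a lone intercept unless ``include_intercept`` is False)
    or a long DataFrame (line, replicate, value) when the spec includes
    replicate effects.
    """
    settings = settings or MCMCSettings()
    if isinstance(obs, pd.Series):
        obs = pd.DataFrame({"line": obs.index, "value": obs.to_numpy()})
    line_ids, line_idx, rep_names, rep_idx, aligned = _prepare_replicated(obs, spec, kernels)
    y = obs["value"].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("missing response values; use fit_censored with bounds instead")
    fit = _run_gibbs(
        family=family, y=y, line_idx=line_idx, line_ids=line_ids,
        rep_idx=rep_idx, rep_names=rep_names, spec=spec, kernels=aligned,
        settings=settings, fixed_variances=fixed_variances,
        include_intercept=include_intercept and rep_idx is None,
    )
    fit.obs_replicates = list(obs["replicate"]) if "replicate" in obs.columns else None
    return fit


def fit_censored(
    obs: pd.DataFrame,
    spec: PredictorSpec,
    kernels=None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
    include_intercept: bool = True,
) -> GPFit:
    """Interval-censored Gaussian fit.

    ``obs`` has columns line, value, lower, upper.  Rows with
    lower < upper are treated as interval observations whose latent value is
    re-imputed each sweep (value may be NaN: bounds-only records are
    allowed); rows with lower == value == upper are exact observations.
    """
    settings = settings or MCMCSettings()
    for col in ("line", "value", "lower", "upper"):
        if col not in obs.columns:
            raise ValueError(f"censored table needs column {col!r}")
    lo = obs["lower"].to_numpy(dtype=float)
    hi = obs["upper"].to_numpy(dtype=float)
    y = obs["value"].to_numpy(dtype=float)
    degenerate = np.isclose(lo, hi)
    if np.any(lo[~degenerate] >= hi[~degenerate]):
        raise ValueError("interval bounds must satisfy a < b")
    if np.any(np.isnan(y) & degenerate):
        raise ValueError("point observations (a == b) need a value")
    free = ~degenerate
    line_ids, line_idx, rep_names, rep_idx, aligned = _prepare_replicated(obs, spec, kernels)
    fit = _run_gibbs(
        family="censored", y=np.where(degenerate, y, np.nan),
        line_idx=line_idx, line_ids=line_ids,
        rep_idx=rep_idx, rep_names=rep_names, spec=spec, kernels=aligned,
        settings=settings, fixed_variances=fixed_variances,
        cens_lo=lo, cens_hi=hi, cens_free=free,
        include_intercept=include_intercept and rep_idx is None,
    )
    fit.obs_replicates = list(obs["replicate"]) if "replicate" in obs.columns else None
    return fit


def fit_ordinal_threshold(
    obs: pd.DataFrame,
    spec: PredictorSpec,
    kernels=None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
) -> GPFit:
    """Probit threshold (TGBLUP) fit for ordinal categories.

    Residual variance is fixed at 1 for identification.  Category labels are
    taken as the full integer range between the smallest and largest
    observed label so unobserved intermediate categories keep their
    thresholds (sampled from their prior-bounded windows, with a warning).
    """
    settings = settings or MCMCSettings()
    vals = obs["value"].to_numpy()
    if not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValueError("ordinal values must be integer category labels")
    vals = vals.astype(int)
    labels = list(range(int(vals.min()), int(vals.max()) + 1))
    if len(labels) < 2:
        raise ValueError("degenerate ordinal response: single observed category")
    cat_idx = vals - labels[0]
    line_ids, line_idx, rep_names, rep_idx, aligned = _prepare_replicated(obs, spec, kernels)
    fv = dict(fixed_variances or {})
    fv["residual"] = 1.0
    fit = _run_gibbs(
        family="ordinal", y=np.zeros(vals.size), line_idx=line_idx,
        line_ids=line_ids, rep_idx=rep_idx, rep_names=rep_names, spec=spec,
        kernels=aligned, settings=settings, fixed_variances=fv,
        cat_idx=cat_idx, n_cat=len(labels),
    )
    fit.category_labels = labels
    fit.obs_replicates = list(obs["replicate"]) if "replicate" in obs.columns else None
    return fit


def fit_lognormal_count(
    obs: pd.DataFrame,
    spec: PredictorSpec,
    kernels=None,
    settings: MCMCSettings | None = None,
    fixed_variances: dict | None = None,
) -> GPFit:
    """Log-normal count fit: Gaussian model on log(y + 1), fitted counts
    reported back-transformed as exp(fitted) - 1."""
    vals = obs["value"].to_numpy()
    if np.any(vals < 0) or not np.all(np.equal(np.mod(vals, 1), 0)):
        raise ValueError("counts must be nonnegative integers")
    trans = obs.copy()
    trans["value"] = np.log(vals.astype(float) + 1.0)
    return fit_gaussian(
        trans, spec, kernels=kernels, settings=settings,
        fixed_variances=fixed_variances, family="lognormal",
    )


# ---------------------------------------------------------------------------
# prediction

def predict_new_lines(
    fit: GPFit,
    kernel_rows: dict,
    new_line_ids: list | None = None,
) -> pd.DataFrame:
    """Kernel-regression prediction for lines outside the training set.

    ``kernel_rows`` maps term name ("G", "GxG") to the n_new x n_train block
    of relationships between new and training lines.  Each term's predicted
    effect is K_cross @ K_train^+ @ posterior-mean effect (pseudo-inverse
    through the training kernel's spectrum); iid line effects of unseen
    lines are 0; the fixed-effect level is the mean of the fitted fixed
    effects.  Ordinal fits additionally return predicted category
    probabilities from the posterior-mean thresholds.
    """
    n_train = len(fit.line_ids)
    n_new = None
    eta = None
    for name, rows in kernel_rows.items():
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != n_train:
            raise ValueError(
                f"kernel rows for {name} have {rows.shape[1]} columns; "
                f"{n_train} training lines expected")
        if name not in fit.effects:
            raise ValueError(f"term {name} not in the fitted model")
        if n_new is None:
            n_new = rows.shape[0]
            eta = np.zeros(n_new)
        u_mean = fit.effects[name]["mean"].to_numpy()
        if name == "L":
            alpha = u_mean  # identity kernel: K^+ = I
        else:
            V, lam = fit._kernel_spectra[name]
            alpha = V @ ((V.T @ u_mean) / lam)
        eta = eta + rows @ alpha
    if eta is None:
        raise ValueError("no kernel rows supplied")
    if fit.beta.shape[0]:
        eta = eta + float(fit.beta["mean"].mean())
    idx = pd.Index(new_line_ids if new_line_ids is not None else range(n_new),
                   name="line")
    out = pd.DataFrame({"prediction": eta}, index=idx)
    if fit.family == "ordinal":
        gmean = fit.gamma["mean"].to_numpy()
        gext = np.concatenate(([-np.inf], gmean, [np.inf]))
        cdf = ndtr(gext[None, 1:-1] - eta[:, None])
        cdf = np.concatenate([np.zeros((len(eta), 1)), cdf,
                              np.ones((len(eta), 1))], axis=1)
        probs = np.diff(cdf, axis=1)
        for j, lab in enumerate(fit.category_labels):
            out[f"p{lab}"] = probs[:, j]
    if fit.family == "lognormal":
        out["predicted_count"] = np.exp(out["prediction"]) - 1.0
    return out
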