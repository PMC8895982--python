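"""Synthetic MAGIC-population data with known ground truth.

Emulates the study design the package targets: ~89 fully inbred 8-founder
MAGIC barley lines genotyped at ~20k biallelic SNPs, with

* an ordinal seminal-root-number (SRN) trait, 7 categories labelled 2..8,
  scored in 12 replicates and generated through a probit liability;
* the same liability architecture exponentiated into a count trait
  (the inverse of the log(y+1) analysis link);
* a continuous seminal-root-angle-like trait observed once per line with
  an uncertainty interval (BLUE +/- 2 SE);
* whole-plant transpiration-rate (TR) curves over a vapour-pressure-deficit
  (VPD) grid of 0.4-5.4 kPa, mixing linear and two-segment responses with
  breakpoints at 2.3-2.5 kPa.

Every generator returns the realized effect vectors so downstream samplers
have a parameter-recovery test surface, and is deterministic given
``config.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kernels import GenotypeMatrix, Kernel

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "TRCurveSet",
    "simulate_magic_genotypes",
    "simulate_ordinal_trait",
    "simulate_count_trait",
    "simulate_censored_trait",
    "simulate_tr_vpd_curves",
    "srn_ordinal_config",
    "srn_count_config",
    "sra_censored_config",
]

#: SRN category labels observed in the emulated population.
SRN_CATEGORIES = (2, 3, 4, 5, 6, 7, 8)


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic trait.

    variance_components holds trait-scale variances: sigma2_L (iid line),
    sigma2_g (additive genomic), sigma2_gA (additive x additive epistatic)
    and sigma2_e (residual; fixed at 1 on the liability scale for ordinal
    traits).  ``thresholds`` are the liability cut-points for ordinal traits
    and must be strictly increasing.  ``fixed_effects`` are the replicate
    effects beta_k (length n_replicates).
    """

    n_lines: int = 89
    n_markers: int = 20426
    n_founders: int = 8
    n_replicates: int = 12
    variance_components: dict = field(
        default_factory=lambda: {
            "sigma2_L": 0.02, "sigma2_g": 0.02, "sigma2_gA": 0.02, "sigma2_e": 1.0,
        }
    )
    thresholds: tuple = ()
    fixed_effects: tuple = ()
    maf_range: tuple = (0.1, 0.5)
    segment_length_mean: float = 250.0
    het_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1 or self.n_markers < 1:
            raise ValueError("n_lines and n_markers must be positive")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if any(v < 0 for v in self.variance_components.values()):
            raise ValueError("variance components must be nonnegative")
        g = np.asarray(self.thresholds, dtype=float)
        if g.size and not np.all(np.diff(g) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if not (0.0 <= self.het_rate <= 1.0):
            raise ValueError("het_rate must be in [0, 1]")


@dataclass
class TrueParameters:
    """Realized ground truth behind one simulated trait table."""

    line_ids: list
    L: np.ndarray
    g: np.ndarray
    gA: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    variance_components: dict

    @property
    def genetic_value(self) -> np.ndarray:
        return self.L + self.g + self.gA


@dataclass
class TRCurveSet:
    """Long-format TR curves plus the generating truth per line."""

    curves: pd.DataFrame  # columns: line, vpd, tr
    truth: pd.DataFrame   # columns: line, kind, intercept, slope1, slope2, breakpoint


# ---------------------------------------------------------------------------
# genotypes

def simulate_magic_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Fully inbred founder-mosaic genotypes.

    Each marker's minor allele is carried by k of the ``n_founders`` founders,
    with k chosen so the founder-panel frequency falls in ``maf_range``.  Each
    line is a mosaic of founder haplotypes with geometric block lengths
    (mean ``segment_length_mean`` markers), giving LD within blocks.  Lines
    are homozygous (dosage 0/2) unless ``het_rate`` > 0, in which case that
    fraction of cells is set to dosage 1.
    """
    rng = np.random.default_rng(config.seed)
    nf, nm, nl = config.n_founders, config.n_markers, config.n_lines

    # founder haplotypes: per marker, k of nf founders carry allele "1"
    lo, hi = config.maf_range
    target = rng.uniform(lo, hi, size=nm)
    if nf == 1:
        founders = np.zeros((1, nm), dtype=np.int8)
    else:
        k = np.clip(np.rint(target * nf).astype(int), 1, nf - 1)
        founders = np.zeros((nf, nm), dtype=np.int8)
        # vectorized "choose k founders per marker" via ranked uniforms
        ranks = rng.random((nf, nm)).argsort(axis=0)
        founders[ranks < k] = 1

    block = max(float(config.segment_length_mean), 1.0)
    dos = np.empty((nl, nm), dtype=float)
    for i in range(nl):
        # geometric block lengths until the chromosome of nm markers is tiled
        n_blocks = int(np.ceil(2.0 * nm / block)) + 8
        lens = rng.geometric(1.0 / block, size=n_blocks)
        while lens.sum() < nm:
            lens = np.concatenate([lens, rng.geometric(1.0 / block, size=n_blocks)])
        donors = rng.integers(0, nf, size=lens.size)
        path = np.repeat(donors, lens)[:nm]
        dos[i] = 2.0 * founders[path, np.arange(nm)]
    if config.het_rate > 0.0:
        het = rng.random(dos.shape) < config.het_rate
        dos[het] = 1.0
    line_ids = [f"M{i+1:03d}" for i in range(nl)]
    marker_ids = [f"snp{j+1:05d}" for j in range(nm)]
    return GenotypeMatrix(line_ids, marker_ids, dos)


# ---------------------------------------------------------------------------
# shared effect machinery

def _draw_kernel_effect(rng: np.random.Generator, kern: Kernel, sigma2: float) -> np.ndarray:
    """Draw u ~ N(0, K * sigma2) through the kernel's spectrum."""
    if sigma2 == 0.0:
        return np.zeros(kern.n_lines)
    if kern.eigenvalues is None:
        raise ValueError(f"kernel {kern.label} lacks its eigendecomposition")
    z = rng.standard_normal(kern.n_lines)
    return kern.eigenvectors @ (np.sqrt(np.clip(kern.eigenvalues, 0, None) * sigma2) * z)


def _realize_effects(
    rng: np.random.Generator,
    geno: GenotypeMatrix,
    kernels: tuple[Kernel, Kernel],
    config: SimulationConfig,
) -> TrueParameters:
    g_kern, ga_kern = kernels
    if list(g_kern.line_ids) != list(geno.line_ids) or list(ga_kern.line_ids) != list(geno.line_ids):
        raise ValueError("kernels must be indexed identically to the genotype lines")
    vc = config.variance_components
    n = geno.n_lines
    L = rng.standard_normal(n) * np.sqrt(vc.get("sigma2_L", 0.0))
    g = _draw_kernel_effect(rng, g_kern, vc.get("sigma2_g", 0.0))
    gA = _draw_kernel_effect(rng, ga_kern, vc.get("sigma2_gA", 0.0))
    beta = np.asarray(config.fixed_effects, dtype=float)
    if beta.size == 0:
        beta = np.zeros(config.n_replicates)
    if beta.size != config.n_replicates:
        raise ValueError("fixed_effects length must equal n_replicates")
    return TrueParameters(
        line_ids=list(geno.line_ids), L=L, g=g, gA=gA, beta=beta,
        gamma=np.asarray(config.thresholds, dtype=float),
        variance_components=dict(vc),
    )


def _replicated_latent(
    rng: np.random.Generator, truth: TrueParameters, n_rep: int, resid_sd: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Latent values per (line, replicate) cell, long order line-major."""
    n = len(truth.line_ids)
    line_idx = np.repeat(np.arange(n), n_rep)
    rep_idx = np.tile(np.arange(n_rep), n)
    eta = (
        truth.beta[rep_idx]
        + truth.genetic_value[line_idx]
        + rng.standard_normal(n * n_rep) * resid_sd
    )
    return eta, line_idx, rep_idx


# ---------------------------------------------------------------------------
# traits

def simulate_ordinal_trait(
    geno: GenotypeMatrix,
    kernels: tuple[Kernel, Kernel],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueParameters]:
    """Ordinal trait via a probit liability.

    l_ik = beta_k + L_i + g_i + gA_i + e_ik with e_ik ~ N(0, 1); the category
    is the interval of the threshold vector the liability falls into, with
    category labels starting at ``SRN_CATEGORIES[0]`` when the number of
    categories matches, else 1..C.
    """
    gamma = np.asarray(config.thresholds, dtype=float)
    if gamma.size == 0:
        raise ValueError("ordinal simulation requires thresholds in the config")
    if not np.all(np.diff(gamma) > 0):
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(config.seed)
    truth = _realize_effects(rng, geno, kernels, config)
    liab, line_idx, rep_idx = _replicated_latent(rng, truth, config.n_replicates, 1.0)
    cat_index = np.searchsorted(gamma, liab)  # 0..C-1
    n_cat = gamma.size + 1
    first = SRN_CATEGORIES[0] if n_cat == len(SRN_CATEGORIES) else 1
    labels = cat_index + first
    table = pd.DataFrame({
        "line": [truth.line_ids[i] for i in line_idx],
        "replicate": [f"rep{k+1:02d}" for k in rep_idx],
        "value": labels.astype(int),
    })
    return table, truth


def simulate_count_trait(
    geno: GenotypeMatrix,
    kernels: tuple[Kernel, Kernel],
    config: SimulationConfig,
) -> tuple[pd.DataFrame, TrueParameters]:
    """Count trait from a log-normal latent scale.

    eta_ik = beta_k + L_i + g_i + gA_i + eps_ik, eps ~ N(0, sigma2_e);
    y = max(0, round(exp(eta) - 1)) — the exact inverse of the log(y+1)
    analysis transform.
    """
    vc = config.variance_components
    s2e = vc.get("sigma2_e", 1.0)
    if s2e < 0:
        raise ValueError("sigma2_e must be nonnegative")
    rng = np.random.default_rng(config.seed)
    truth = _realize_effects(rng, geno, kernels, config)
    eta, line_idx, rep_idx = _replicated_latent(rng, truth, config.n_replicates, np.sqrt(s2e))
    counts = np.maximum(0, np.rint(np.exp(eta) - 1.0)).astype(int)
    table = pd.DataFrame({
        "line": [truth.line_ids[i] for i in line_idx],
        "replicate": [f"rep{k+1:02d}" for k in rep_idx],
        "value": counts,
    })
    return table, truth


def simulate_censored_trait(
    geno: GenotypeMatrix,
    kernels: tuple[Kernel, Kernel],
    config: SimulationConfig,
    obs_sd: float | np.ndarray = 0.0,
) -> tuple[pd.DataFrame, TrueParameters]:
    """One continuous record per line with an uncertainty interval.

    y_i = mu + L_i + g_i + gA_i + eps_i (eps ~ N(0, sigma2_e)), where mu is
    the first entry of ``fixed_effects`` (a grand mean); the emitted interval
    is (y_i - 2*obs_sd_i, y_i + 2*obs_sd_i), mirroring a BLUE reported with
    its standard error.
    """
    obs_sd = np.broadcast_to(np.asarray(obs_sd, dtype=float), (config.n_lines,)).copy()
    if np.any(obs_sd < 0):
        raise ValueError("obs_sd must be nonnegative")
    rng = np.random.default_rng(config.seed)
    truth = _realize_effects(rng, geno, kernels, config)
    s2e = config.variance_components.get("sigma2_e", 1.0)
    mu = truth.beta[0] if truth.beta.size else 0.0
    y = mu + truth.genetic_value + rng.standard_normal(config.n_lines) * np.sqrt(s2e)
    table = pd.DataFrame({
        "line": truth.line_ids,
        "value": y,
        "lower": y - 2.0 * obs_sd,
        "upper": y + 2.0 * obs_sd,
    })
    return table, truth


def simulate_tr_vpd_curves(
    n_lines: int,
    vpd_grid: np.ndarray | None = None,
    fraction_linear: float = 28.0 / 90.0,
    breakpoint_range: tuple[float, float] = (2.3, 2.5),
    slopes: tuple[float, float] = (1.5, 3.5),
    noise_sd: float = 0.3,
    seed: int = 0,
    intercept_range: tuple[float, float] = (0.5, 1.5),
    slope2_factor_range: tuple[float, float] = (0.05, 0.35),
) -> TRCurveSet:
    """Transpiration-rate responses to VPD, linear or two-segment.

    A ``fraction_linear`` share of lines respond linearly; the rest follow a
    continuous two-segment response whose slope drops after a breakpoint
    drawn in ``breakpoint_range`` (defaults emulate the 0.4-5.4 kPa grid
    with breakpoints at 2.3-2.5 kPa and 28/90 linear lines).
    """
    if vpd_grid is None:
        vpd_grid = np.arange(0.4, 5.41, 0.5)
    vpd_grid = np.asarray(vpd_grid, dtype=float)
    if not (vpd_grid[0] < breakpoint_range[0] and breakpoint_range[1] < vpd_grid[-1]):
        raise ValueError("breakpoint_range must lie strictly inside the vpd grid")
    if not (0.0 <= fraction_linear <= 1.0):
        raise ValueError("fraction_linear must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_linear = int(round(fraction_linear * n_lines))
    kinds = np.array(["linear"] * n_linear + ["segmented"] * (n_lines - n_linear))
    rng.shuffle(kinds)

    rows, truth_rows = [], []
    for i in range(n_lines):
        line = f"M{i+1:03d}"
        b0 = rng.uniform(*intercept_range)
        s1 = rng.uniform(*slopes)
        if kinds[i] == "linear":
            tr = b0 + s1 * vpd_grid
            s2, bp = np.nan, np.nan
        else:
            bp = rng.uniform(*breakpoint_range)
            s2 = s1 * rng.uniform(*slope2_factor_range)
            tr = b0 + s1 * np.minimum(vpd_grid, bp) + s2 * np.maximum(0.0, vpd_grid - bp)
        tr = tr + rng.standard_normal(vpd_grid.size) * noise_sd
        rows.append(pd.DataFrame({"line": line, "vpd": vpd_grid, "tr": tr}))
        truth_rows.append(
            {"line": line, "kind": kinds[i], "intercept": b0,
             "slope1": s1, "slope2": s2, "breakpoint": bp}
        )
    return TRCurveSet(
        curves=pd.concat(rows, ignore_index=True),
        truth=pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# study-condition defaults

def _srn_thresholds() -> tuple:
    """Liability cut-points giving a bell-shaped 7-category distribution.

    Chosen so the modal category (5 roots) has marginal probability ~0.5
    with liability variance ~1.06 (unit residual plus small genetic terms),
    matching the emulated SRN distribution.
    """
    from scipy.stats import norm

    cum = np.array([0.01, 0.06, 0.21, 0.71, 0.92, 0.985])
    return tuple(norm.ppf(cum) * np.sqrt(1.06))


def srn_ordinal_config(seed: int = 0, n_lines: int = 89, n_markers: int = 20426) -> SimulationConfig:
    """Ordinal SRN under the emulated study conditions (variance fractions
    from the full L+G+GxG model: 0.02 each on a unit-residual liability).

    Study-condition factories use ~35 founder segments per line
    (segment_length_mean = n_markers / 35), the order expected after an
    8-way funnel with a handful of meioses across 7 chromosomes."""
    return SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, n_replicates=12,
        segment_length_mean=max(1.0, n_markers / 35),
        variance_components={"sigma2_L": 0.02, "sigma2_g": 0.02,
                             "sigma2_gA": 0.02, "sigma2_e": 1.0},
        thresholds=_srn_thresholds(),
        fixed_effects=tuple(np.linspace(-0.15, 0.15, 12)),
        seed=seed,
    )


def srn_count_config(seed: int = 0, n_lines: int = 89, n_markers: int = 20426) -> SimulationConfig:
    """SRN as counts on the log(y+1) scale: mean log-count log(6) ~ 1.79
    (5 roots), residual and genetic scales giving counts spanning 2-8."""
    return SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, n_replicates=12,
        segment_length_mean=max(1.0, n_markers / 35),
        variance_components={"sigma2_L": 0.004, "sigma2_g": 0.004,
                             "sigma2_gA": 0.004, "sigma2_e": 0.02},
        fixed_effects=tuple(np.log(6.0) + np.linspace(-0.03, 0.03, 12)),
        seed=seed,
    )


def sra_censored_config(seed: int = 0, n_lines: int = 89, n_markers: int = 20426) -> SimulationConfig:
    """Seminal-root-angle-like continuous trait centred near 87 degrees with
    SD ~9 degrees, one adjusted mean per line."""
    return SimulationConfig(
        n_lines=n_lines, n_markers=n_markers, n_replicates=1,
        segment_length_mean=max(1.0, n_markers / 35),
        variance_components={"sigma2_L": 15.0, "sigma2_g": 15.0,
                             "sigma2_gA": 15.0, "sigma2_e": 40.0},
        fixed_effects=(86.6,),
        seed=seed,
    )
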