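"""File I/O, configuration and end-to-end orchestration.

CSV dialects
------------
* genotype table: first column line ID, remaining columns marker dosages,
  header row of marker names; dosages {0,1,2} (a {-1,0,1} dialect is
  auto-detected and shifted by +1); non-numeric cells are missing;
* phenotype tables: ``long`` (line, replicate, value), ``means``
  (line, blue, se, ...), ``tr`` (line, vpd, tr), ``wide`` (line + one
  column per environment);
* configuration: flat ``key = value`` text; ``seed`` is mandatory.

``run_pipeline`` chains the full analysis (descriptives, correlations,
kernels, trait prep, model fits, LOO CV) and writes a manifest with
content hashes so a run is reproducible from its config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import correlations as corr
from . import evaluate, gp, kernels as kmod, phenotypes, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "read_genotype_csv",
    "write_genotype_csv",
    "read_phenotype_csv",
    "write_phenotype_csv",
    "write_kernel_txt",
    "read_kernel_txt",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# readers / writers

def read_genotype_csv(path) -> kmod.GenotypeMatrix:
    """Read the comma-delimited genotype dialect (lines x markers)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate line IDs in genotype file")
    dos = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    n_missing = int(np.isnan(dos).sum())
    if np.isnan(dos).all(axis=0).any():
        raise ValueError("genotype file contains an all-missing marker column")
    finite = dos[np.isfinite(dos)]
    if finite.size and finite.min() < 0:
        logger.info("detected {-1,0,1} dosage dialect; shifting by +1")
        dos = dos + 1.0
    geno = kmod.GenotypeMatrix(list(df.index.astype(str)),
                               list(df.columns.astype(str)), dos)
    logger.info("read genotypes: %d lines x %d markers, %d missing cells",
                geno.n_lines, geno.n_markers, n_missing)
    return geno


def write_genotype_csv(geno: kmod.GenotypeMatrix, path) -> None:
    df = geno.to_dataframe()
    df.index.name = "line"
    df.to_csv(path)


_SCHEMAS = {
    "long": ["line", "replicate", "value"],
    "means": ["line", "blue", "se"],
    "tr": ["line", "vpd", "tr"],
    "censored": ["line", "value", "lower", "upper"],
}


def read_phenotype_csv(path, schema: str) -> pd.DataFrame:
    """Schema-validated phenotype reader (``wide`` = line + env columns)."""
    df = pd.read_csv(path)
    if schema == "wide":
        if df.shape[1] < 3:
            raise ValueError("wide table needs a line column plus >= 2 environments")
        return df.set_index(df.columns[0])
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise ValueError(f"schema {schema!r}: missing column(s) {missing}")
    return df


def write_phenotype_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=isinstance(table.index, pd.Index)
                 and table.index.name is not None)


def write_kernel_txt(kern: kmod.Kernel, path) -> None:
    """Plain-text symmetric matrix with a line-ID header row/column."""
    pd.DataFrame(kern.matrix, index=kern.line_ids,
                 columns=kern.line_ids).to_csv(path)


def read_kernel_txt(path, label: str = "G") -> kmod.Kernel:
    df = pd.read_csv(path, index_col=0)
    return kmod.eigendecompose(
        kmod.Kernel(label, list(df.index.astype(str)), df.to_numpy(dtype=float)))


# ---------------------------------------------------------------------------
# configuration

_TRUE = {"1", "true", "yes", "on"}


@dataclass
class PipelineConfig:
    """Flat configuration for a pipeline run; ``seed`` is mandatory."""

    seed: int
    out_dir: str = "magicgp_out"
    genotypes: str = "synthetic"          # path or "synthetic"
    srn: str = "synthetic"
    sra: str = "synthetic"
    tr: str = "synthetic"
    gy: str = "synthetic"
    n_lines: int = 89
    n_markers: int = 2000
    models: tuple = (1, 5)
    families: tuple = ("ordinal", "lognormal", "censored")
    n_iter: int = 6000
    burn_in: int = 1000
    thin: int = 5
    cv: bool = True
    cv_unit: str = "line"
    retain_bounds: bool = False
    max_missing_rate: float = 0.1
    min_maf: float = 0.0
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            if "=" not in ln:
                raise ValueError(f"config line not key = value: {ln!r}")
            k, v = (s.strip() for s in ln.split("=", 1))
            raw[k] = v
        if "seed" not in raw:
            raise ValueError("config must set seed")
        kw: dict = {"seed": int(raw.pop("seed"))}
        ints = {"n_lines", "n_markers", "n_iter", "burn_in", "thin"}
        floats = {"max_missing_rate", "min_maf"}
        bools = {"cv", "retain_bounds"}
        for k, v in raw.items():
            if k in ints:
                kw[k] = int(v)
            elif k in floats:
                kw[k] = float(v)
            elif k in bools:
                kw[k] = v.lower() in _TRUE
            elif k == "models":
                kw[k] = tuple(int(s) for s in v.split(",") if s)
            elif k == "families":
                kw[k] = tuple(s.strip() for s in v.split(",") if s.strip())
            elif k in {"out_dir", "genotypes", "srn", "sra", "tr", "gy", "cv_unit"}:
                kw[k] = v
            else:
                kw.setdefault("extra", {})[k] = v
        cfg = cls(**kw)
        for path_field in ("genotypes", "srn", "sra", "tr", "gy"):
            val = getattr(cfg, path_field)
            if val != "synthetic" and not Path(val).exists():
                raise ValueError(f"{path_field} path does not exist: {val}")
        return cfg

    def settings(self) -> gp.MCMCSettings:
        return gp.MCMCSettings(n_iter=self.n_iter, burn_in=self.burn_in,
                               thin=self.thin, seed=self.seed)


# ---------------------------------------------------------------------------
# orchestration

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _synthetic_gy(truth: simulate.TrueParameters, seed: int,
                  envs=("FioIN", "FioLN", "MarIN", "AdaIN", "KonIN")) -> pd.DataFrame:
    """Line x environment adjusted means sharing the genetic signal."""
    rng = np.random.default_rng(seed + 77)
    g = truth.genetic_value
    g = (g - g.mean()) / (g.std() or 1.0)
    cols = {}
    for j, env in enumerate(envs):
        base = rng.uniform(3.0, 7.0)  # t/ha-scale environment mean
        cols[env] = base + 0.4 * g + rng.standard_normal(g.size) * 0.5
    return pd.DataFrame(cols, index=pd.Index(truth.line_ids, name="line"))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: list[Path] = []
    results: dict = {}

    @_stage("genotypes")
    def load_geno():
        if config.genotypes == "synthetic":
            cfg = simulate.SimulationConfig(
                n_lines=config.n_lines, n_markers=config.n_markers, seed=seed)
            return simulate.simulate_magic_genotypes(cfg)
        return read_genotype_csv(config.genotypes)

    geno = load_geno()

    @_stage("kernels")
    def build_kernels():
        filt, report = kmod.filter_and_impute(
            geno, config.max_missing_rate, config.min_maf)
        G = kmod.vanraden_g(filt)
        GxG = kmod.epistatic_kernel(G)
        write_kernel_txt(G, out / "kernel_G.csv")
        write_kernel_txt(GxG, out / "kernel_GxG.csv")
        artifacts.extend([out / "kernel_G.csv", out / "kernel_GxG.csv"])
        results["genotype_filter"] = report.__dict__
        return {"G": G, "GxG": GxG}

    kern = build_kernels()
    kpair = (kern["G"], kern["GxG"])

    @_stage("phenotypes")
    def load_phenos():
        tabs = {}
        if config.srn == "synthetic":
            cfg = simulate.srn_ordinal_config(seed=seed, n_lines=config.n_lines,
                                              n_markers=config.n_markers)
            tabs["srn"], tabs["srn_truth"] = simulate.simulate_ordinal_trait(
                geno, kpair, cfg)
        else:
            tabs["srn"] = read_phenotype_csv(config.srn, "long")
        if config.sra == "synthetic":
            cfg = simulate.sra_censored_config(seed=seed + 1, n_lines=config.n_lines,
                                               n_markers=config.n_markers)
            tabs["sra"], tabs["sra_truth"] = simulate.simulate_censored_trait(
                geno, kpair, cfg, obs_sd=1.5)
        else:
            tabs["sra"] = read_phenotype_csv(config.sra, "censored")
        if config.tr == "synthetic":
            tabs["tr_curves"] = simulate.simulate_tr_vpd_curves(
                n_lines=config.n_lines, seed=seed + 2).curves
        else:
            tabs["tr_curves"] = read_phenotype_csv(config.tr, "tr")
        if config.gy == "synthetic":
            truth = tabs.get("sra_truth")
            if truth is None:
                raise ValueError("synthetic GY needs the synthetic SRA stage")
            tabs["gy"] = _synthetic_gy(truth, seed)
        else:
            tabs["gy"] = read_phenotype_csv(config.gy, "wide")
        return tabs

    phen = load_phenos()
    srn, sra, gy = phen["srn"], phen["sra"], phen["gy"]

    @_stage("trait_prep")
    def prep():
        tr_fit = phenotypes.tr_table_at_vpd(phen["tr_curves"], target_vpd=2.7)
        tr_fit.to_csv(out / "tr_fits.csv")
        artifacts.append(out / "tr_fits.csv")
        sra_means = sra.set_index("line")["value"]
        results["tr_segmented_fraction"] = float((tr_fit["kind"] == "segmented").mean())
        return tr_fit, sra_means

    tr_fit, sra_means = prep()

    @_stage("descriptives")
    def descriptives():
        desc = pd.DataFrame({
            "SRA": corr.descriptive_stats(sra_means),
            "SRN": corr.descriptive_stats(srn["value"]),
            "TR_2.7kPa": corr.descriptive_stats(tr_fit["tr"]),
        }).T
        desc.to_csv(out / "descriptives.csv")
        artifacts.append(out / "descriptives.csv")
        return desc

    results["descriptives"] = descriptives().to_dict(orient="index")

    @_stage("correlations")
    def correlate():
        srn_line = srn.groupby("line")["value"].mean().round().astype(int)
        traits = pd.DataFrame({
            "SRA": sra_means, "TR": tr_fit["tr"], "SRN": srn_line,
        }).join(gy)
        cmat = corr.correlation_matrix(traits, ordinal=("SRN",))
        cmat.to_csv(out / "trait_correlations.csv")
        gge = corr.gge_scores(gy)
        gge.line_scores.to_csv(out / "gge_line_scores.csv")
        gge.env_scores.to_csv(out / "gge_env_scores.csv")
        artifacts.extend([out / "trait_correlations.csv",
                          out / "gge_line_scores.csv", out / "gge_env_scores.csv"])
        results["gge_explained"] = [float(v) for v in gge.explained[:2]]
        return cmat

    correlate()

    settings = config.settings()
    fit_specs = {m: gp.PredictorSpec.from_model_number(m) for m in config.models}

    @_stage("model_fits")
    def fits():
        all_fits = {}
        for fam in config.families:
            for m, spec in fit_specs.items():
                name = f"{fam}-model{m}"
                if fam == "ordinal":
                    fit = gp.fit_ordinal_threshold(srn, spec, kern, settings)
                elif fam == "lognormal":
                    fit = gp.fit_lognormal_count(srn, spec, kern, settings)
                elif fam == "censored":
                    pl_spec = gp.PredictorSpec(
                        include_replicate=False, include_line=spec.include_line,
                        include_markers=spec.include_markers,
                        include_epistasis=spec.include_epistasis)
                    fit = gp.fit_censored(sra, pl_spec, kern, settings)
                else:
                    raise ValueError(f"unknown family {fam!r}")
                all_fits[name] = fit
                (out / f"fit_{name}.json").write_text(
                    json.dumps(fit.summary_json(), indent=1, default=float))
                artifacts.append(out / f"fit_{name}.json")
        vtab = evaluate.variance_component_table(all_fits)
        vtab.to_csv(out / "variance_components.tsv", sep="\t", index=False)
        artifacts.append(out / "variance_components.tsv")
        return all_fits

    all_fits = fits()
    results["models_fitted"] = sorted(all_fits)

    if config.cv:
        @_stage("cross_validation")
        def cross_validate():
            agg = {}
            for fam in config.families:
                m = max(config.models)
                spec = fit_specs[m]
                if fam == "ordinal":
                    res = evaluate.loo_cross_validate(
                        srn, spec, "ordinal", kern, settings=settings,
                        unit=config.cv_unit)
                elif fam == "lognormal":
                    res = evaluate.loo_cross_validate(
                        srn, spec, "lognormal", kern, settings=settings,
                        unit=config.cv_unit)
                else:
                    pl_spec = gp.PredictorSpec(
                        include_replicate=False, include_line=spec.include_line,
                        include_markers=spec.include_markers,
                        include_epistasis=spec.include_epistasis)
                    res = evaluate.loo_cross_validate(
                        sra, pl_spec, "censored", kern, settings=settings,
                        unit="line", retain_bounds=config.retain_bounds)
                name = f"{fam}-model{m}"
                res.folds.to_csv(out / f"cv_{name}.csv", index=False)
                artifacts.append(out / f"cv_{name}.csv")
                agg[name] = {**res.scores, "unit": res.unit,
                             "retain_bounds": res.retain_bounds,
                             "n_folds": res.n_folds}
            (out / "cv_scores.json").write_text(json.dumps(agg, indent=1))
            artifacts.append(out / "cv_scores.json")
            return agg

        results["cv"] = cross_validate()

    manifest = {
        "seed": seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items() if k != "extra"},
        "results": results,
        "artifacts": {str(p.name): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
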