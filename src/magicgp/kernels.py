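"""Genomic relationship kernels.

Builds the additive genomic relationship matrix ``G`` (VanRaden method 1)
from biallelic SNP dosages and derives the first-order additive x additive
epistatic kernel ``G_A`` as the element-wise (Hadamard) square of ``G``.
Kernels carry their spectral decomposition so downstream samplers can work
in the eigenbasis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "Kernel",
    "FilterReport",
    "filter_and_impute",
    "vanraden_g",
    "epistatic_kernel",
    "identity_kernel",
    "eigendecompose",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage table; dosages in [0, 2], NaN = missing."""

    line_ids: list
    marker_ids: list
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.marker_ids = list(self.marker_ids)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValueError("duplicate marker ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] or be missing (NaN)")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_rate(self) -> float:
        return float(np.isnan(self.dosages).mean())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.line_ids, columns=self.marker_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GenotypeMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))


@dataclass
class Kernel:
    """A labelled line x line relationship matrix with optional spectrum.

    ``eigenvalues`` are nonincreasing and clipped at zero (clip events are
    logged); ``eigenvectors`` columns are orthonormal.
    """

    label: str
    line_ids: list
    matrix: np.ndarray
    eigenvalues: np.ndarray | None = field(default=None)
    eigenvectors: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.line_ids = list(self.line_ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("kernel matrix must be square over the line ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("kernel matrix must be symmetric (tol 1e-10)")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, keep: list) -> "Kernel":
        """Restrict the kernel to a subset of lines (spectrum recomputed)."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        idx = np.array([pos[l] for l in keep], dtype=int)
        sub = Kernel(self.label, list(keep), self.matrix[np.ix_(idx, idx)])
        return eigendecompose(sub) if self.eigenvalues is not None else sub

    def cross_rows(self, new_lines: list, train_lines: list) -> np.ndarray:
        """Relationship rows of ``new_lines`` against ``train_lines``."""
        pos = {l: i for i, l in enumerate(self.line_ids)}
        ri = np.array([pos[l] for l in new_lines], dtype=int)
        ci = np.array([pos[l] for l in train_lines], dtype=int)
        return self.matrix[np.ix_(ri, ci)]


@dataclass
class FilterReport:
    n_input: int
    n_monomorphic: int
    n_high_missing: int
    n_low_maf: int
    n_retained: int
    n_imputed_cells: int


def filter_and_impute(
    geno: GenotypeMatrix,
    max_missing_rate: float = 0.1,
    min_maf: float = 0.0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop monomorphic / high-missing / low-MAF markers, mean-impute the rest.

    Markers are removed when (in this order of attribution) their missing
    rate exceeds ``max_missing_rate``, they are monomorphic among the
    observed calls, or their minor-allele frequency falls below ``min_maf``.
    Remaining missing dosages are replaced by the marker mean.
    """
    if not (0.0 <= max_missing_rate <= 1.0 and 0.0 <= min_maf <= 0.5):
        raise ValueError("max_missing_rate in [0,1] and min_maf in [0,0.5] required")
    X = geno.dosages
    miss = np.isnan(X)
    miss_rate = miss.mean(axis=0)
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
        col_min = np.nanmin(np.where(miss, np.nan, X), axis=0)
        col_max = np.nanmax(np.where(miss, np.nan, X), axis=0)
    all_missing = miss.all(axis=0)
    high_missing = (miss_rate > max_missing_rate) | all_missing
    mono = (~high_missing) & (col_min == col_max)
    p = col_mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    low_maf = (~high_missing) & (~mono) & (maf < min_maf)
    keep = ~(high_missing | mono | low_maf)
    if not keep.any():
        raise ValueError("empty genotype: every marker was filtered out")
    Xk = X[:, keep].copy()
    n_imputed = int(np.isnan(Xk).sum())
    if n_imputed:
        fill = np.nanmean(Xk, axis=0)
        idx = np.where(np.isnan(Xk))
        Xk[idx] = fill[idx[1]]
    report = FilterReport(
        n_input=geno.n_markers,
        n_monomorphic=int(mono.sum()),
        n_high_missing=int(high_missing.sum()),
        n_low_maf=int(low_maf.sum()),
        n_retained=int(keep.sum()),
        n_imputed_cells=n_imputed,
    )
    logger.info(
        "filter_and_impute: retained %d/%d markers (%d monomorphic, %d high-missing, "
        "%d low-MAF removed); imputed %d cells",
        report.n_retained, report.n_input, report.n_monomorphic,
        report.n_high_missing, report.n_low_maf, n_imputed,
    )
    out = GenotypeMatrix(
        geno.line_ids,
        [m for m, k in zip(geno.marker_ids, keep) if k],
        Xk,
    )
    return out, report


def vanraden_g(geno: GenotypeMatrix) -> Kernel:
    """VanRaden method-1 genomic relationship matrix.

    With observed allele frequency p_j per marker, W = dosages - 2p and
    G = W W' / (2 sum_j p_j (1 - p_j)).  Requires complete dosages
    (run :func:`filter_and_impute` first).
    """
    X = geno.dosages
    if np.isnan(X).any():
        raise ValueError("missing dosages present; run filter_and_impute first")
    p = X.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    W = X - 2.0 * p
    G = (W @ W.T) / denom
    G = 0.5 * (G + G.T)  # symmetrize roundoff
    return eigendecompose(Kernel("G", geno.line_ids, G))


def epistatic_kernel(g: Kernel) -> Kernel:
    """First-order additive x additive kernel: the Hadamard square of G.

    PSD by the Schur product theorem.
    """
    if g.label != "G":
        raise ValueError("epistatic kernel is derived from the additive kernel G")
    return eigendecompose(Kernel("GxG", g.line_ids, g.matrix * g.matrix))


def identity_kernel(line_ids: list) -> Kernel:
    n = len(line_ids)
    return Kernel(
        "identity", line_ids, np.eye(n),
        eigenvalues=np.ones(n), eigenvectors=np.eye(n),
    )


def eigendecompose(k: Kernel, clip_tol: float = 1e-10) -> Kernel:
    """Populate the spectral fields of a kernel.

    Eigenvalues below ``clip_tol`` are clipped to zero (events logged) so the
    matrix is PSD to working precision for the eigenbasis samplers.
    """
    lam, V = np.linalg.eigh(k.matrix)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    if lam.size and lam[-1] < -1e-8 * max(1.0, abs(lam[0])):
        logger.warning(
            "kernel %s has eigenvalue %.3e well below zero; clipping", k.label, lam[-1]
        )
    n_clip = int(np.sum(lam < clip_tol))
    if n_clip:
        logger.info("kernel %s: clipped %d eigenvalues below %.1e to 0",
                    k.label, n_clip, clip_tol)
    lam = np.where(lam < clip_tol, 0.0, lam)
    return replace(k, eigenvalues=lam, eigenvectors=V)
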