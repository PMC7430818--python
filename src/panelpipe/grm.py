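"""Genomic relationship matrices and marker-density subsampling.

The GRM follows the GCTA (Yang et al.) estimator: with dosage
``x_ij in {0,1,2}`` and sample alt-allele frequency ``p_i`` estimated
from the non-missing calls of marker *i*,

    G_jk = mean_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i))      (j != k)
    G_jj = 1 + mean_i (x_ij^2 - (1 + 2 p_i) x_ij + 2 p_i^2) / (2 p_i (1 - p_i))

where each mean runs over the markers non-missing in both samples
(GCTA's missing-data behaviour; no imputation).  Monomorphic and
all-missing markers are skipped.

The density analysis repeatedly draws random marker subsets of
increasing size, correlates each subset GRM with the full-pool GRM over
distinct sample pairs, and reports the mean +/- SE correlation per
subset size — the curve used to pick the smallest panel density whose
GRM still agrees with the full marker set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dataset import MISSING, GenotypeDataset
from .stats import UndefinedStatisticError

__all__ = [
    "GrmMatrix",
    "DensityCurve",
    "compute_grm",
    "grm_correlation",
    "density_curve",
    "min_density_for",
    "GenomicRelationship",
    "MarkerDensityAnalysis",
]


@dataclass
class GrmMatrix:
    """Symmetric pairwise relationship estimates with per-pair marker counts."""

    sample_ids: list[str]
    values: np.ndarray
    pair_marker_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.pair_marker_counts = np.asarray(self.pair_marker_counts, dtype=np.int64)
        n = len(self.sample_ids)
        if self.values.shape != (n, n) or self.pair_marker_counts.shape != (n, n):
            raise ValueError("GRM matrices must be square over the sample ids")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class DensityCurve:
    """Subset size -> mean +/- SE correlation of subset GRM vs full GRM."""

    sizes: np.ndarray
    means: np.ndarray
    ses: np.ndarray
    reps: int
    seed: int
    correlations: np.ndarray  # shape (len(sizes), reps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": self.sizes, "mean_r": self.means, "se": self.ses, "reps": self.reps}
        )


class _GrmWorkspace:
    """Shared standardized matrices so subset GRMs reuse the full-pool setup.

    Allele frequencies are estimated once from the dataset; subsetting
    markers does not change the per-marker frequencies, so the
    standardized dosage matrix can simply be row-sliced per subset.
    """

    def __init__(self, ds: GenotypeDataset):
        if ds.n_samples < 2:
            raise ValueError("GRM requires at least two samples")
        X = ds.calls.astype(float)
        present = ds.calls != MISSING
        X[~present] = np.nan
        n_obs = present.sum(axis=1)
        with np.errstate(invalid="ignore"):
            p = np.nansum(X, axis=1) / (2.0 * np.maximum(n_obs, 1))
        usable = (n_obs > 0) & (p > 0) & (p < 1)
        if not usable.any():
            raise ValueError("no polymorphic markers with observed calls")
        self.usable = usable
        self.sample_ids = list(ds.samples)
        X = X[usable]
        present = present[usable]
        p = p[usable]
        denom = 2.0 * p * (1.0 - p)
        centered = X - 2.0 * p[:, None]
        self.Z = np.where(present, centered / np.sqrt(denom)[:, None], 0.0)
        self.M = present.astype(float)
        # per-call diagonal contribution (x^2 - (1+2p)x + 2p^2) / (2p(1-p))
        diag_terms = (X * X - (1.0 + 2.0 * p)[:, None] * X + (2.0 * p * p)[:, None]) / denom[
            :, None
        ]
        self.D = np.where(present, diag_terms, 0.0)
        self.n_markers = self.Z.shape[0]

    def grm(self, rows: np.ndarray | slice = slice(None)) -> GrmMatrix:
        Z = self.Z[rows]
        M = self.M[rows]
        D = self.D[rows]
        counts = M.T @ M
        with np.errstate(invalid="ignore", divide="ignore"):
            G = (Z.T @ Z) / counts
        G[counts == 0] = np.nan
        diag_counts = M.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            diag = 1.0 + D.sum(axis=0) / diag_counts
        diag[diag_counts == 0] = np.nan
        np.fill_diagonal(G, diag)
        np.fill_diagonal(counts, diag_counts)
        return GrmMatrix(self.sample_ids, G, counts.astype(np.int64))


def compute_grm(ds: GenotypeDataset) -> GrmMatrix:
    """GCTA-style GRM over all usable (polymorphic, observed) markers."""
    return _GrmWorkspace(ds).grm()


def grm_correlation(
    g1: GrmMatrix, g2: GrmMatrix, include_diagonal: bool = False
) -> float:
    """Pearson correlation of relationship estimates between two GRMs.

    Computed over the upper-triangle off-diagonal entries defined (finite)
    in both matrices; ``include_diagonal`` adds the diagonal entries.
    """
    if g1.sample_ids != g2.sample_ids:
        raise ValueError("GRMs are over different sample sets")
    n = len(g1.sample_ids)
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    a = g1.values[iu]
    b = g2.values[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 defined pairs shared by the GRMs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero variance in relationship estimates")
    return float(np.corrcoef(a, b)[0, 1])


def density_curve(
    ds: GenotypeDataset,
    sizes,
    reps: int = 50,
    seed: int = 0,
    include_diagonal: bool = False,
) -> DensityCurve:
    """Correlate random marker-subset GRMs against the full-pool GRM.

    For each subset size ``n`` the analysis draws ``reps`` independent
    subsets of ``n`` distinct markers from the shared pool (replicates
    are drawn independently, so a marker can recur across replicates),
    computes each subset GRM and its correlation to the full GRM, and
    reports mean and standard error (sample SD / sqrt(reps)) per size.
    """
    sizes = np.asarray(sorted(int(s) for s in sizes))
    if reps < 2:
        raise ValueError("reps must be >= 2")
    work = _GrmWorkspace(ds)
    if sizes.max() > work.n_markers:
        raise ValueError(
            f"subset size {sizes.max()} exceeds the usable marker pool ({work.n_markers})"
        )
    if sizes.min() < 1:
        raise ValueError("subset sizes must be >= 1")
    rng = np.random.default_rng(seed)
    full = work.grm()
    corr = np.empty((len(sizes), reps))
    for si, n in enumerate(sizes):
        for r in range(reps):
            idx = rng.choice(work.n_markers, size=n, replace=False)
            corr[si, r] = grm_correlation(work.grm(idx), full, include_diagonal)
    means = corr.mean(axis=1)
    ses = corr.std(axis=1, ddof=1) / np.sqrt(reps)
    return DensityCurve(sizes, means, ses, reps, seed, corr)


def min_density_for(curve: DensityCurve, threshold: float) -> int | None:
    """Smallest subset size whose mean correlation reaches the threshold.

    Returns ``None`` when no size on the curve qualifies.
    """
    if len(curve.sizes) == 0:
        raise ValueError("empty density curve")
    for n, m in zip(curve.sizes, curve.means):
        if m >= threshold:
            return int(n)
    return None


# ----------------------------------------------------------- estimators ----
class GenomicRelationship(BaseEstimator):
    """Estimator wrapper: ``fit`` computes the GRM of a dataset.

    Attributes
    ----------
    grm_ : GrmMatrix
    """

    def fit(self, X: GenotypeDataset, y=None):
        self.grm_ = compute_grm(X)
        return self

    def fit_predict(self, X: GenotypeDataset) -> GrmMatrix:
        return self.fit(X).grm_


class MarkerDensityAnalysis(BaseEstimator):
    """Marker-density subsampling analysis with a target GRM correlation.

    Parameters
    ----------
    sizes : sequence of int
        Subset sizes to evaluate.
    reps : int
        Replicates per size.
    threshold : float
        Desired minimum mean correlation for the panel.
    random_state : int
        Seed for subset draws.

    Attributes
    ----------
    curve_ : DensityCurve
    min_density_ : int or None
        Smallest evaluated size reaching ``threshold``.
    """

    def __init__(self, sizes=(100, 500, 1000, 2000, 4000), reps: int = 50,
                 threshold: float = 0.98, random_state: int = 0,
                 include_diagonal: bool = False):
        self.sizes = sizes
        self.reps = reps
        self.threshold = threshold
        self.random_state = random_state
        self.include_diagonal = include_diagonal

    def fit(self, X: GenotypeDataset, y=None):
        self.curve_ = density_curve(
            X, self.sizes, self.reps, self.random_state, self.include_diagonal
        )
        self.min_density_ = min_density_for(self.curve_, self.threshold)
        return self
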