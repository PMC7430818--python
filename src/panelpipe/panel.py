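"""QC-score ranking and final panel selection.

Each post-QC marker is scored by a weighted combination of its quality
metrics,

    QC score = 1.4 * CR + 2.4 * MAF + Rep_Avg + RD - HWE/10 - MI

with CR the call rate (0-1), MAF the minor-allele frequency (0-0.5),
Rep_Avg the replicate concordance (0-1), RD the standardized read depth
(marker mean depth over the largest observed mean depth, 0-1), HWE the
Hardy-Weinberg deviation as a percentage (capped at 100 so the penalty
is bounded at 10) and MI the Mendelian-error rate as a proportion (0-1).
The top-N markers by score form the panel; N defaults to 4236, the size
used for the original probe synthesis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import GenotypeDataset
from . import stats as ms
from .grm import compute_grm, grm_correlation
from .stats import UndefinedStatisticError

__all__ = [
    "qc_score",
    "select_panel",
    "validate_panel",
    "PanelSelection",
    "PanelSelector",
    "standardized_depth",
]

# re-exported: RD is defined with the marker statistics
standardized_depth = ms.standardized_depth

SCORE_COLUMNS = ["CR", "MAF", "Rep_Avg", "RD", "HWE_dev", "MI"]


def qc_score(metrics: pd.DataFrame | dict) -> np.ndarray | float:
    """Weighted quality score per marker (higher is better).

    Accepts a metrics table with columns ``CR, MAF, Rep_Avg, RD,
    HWE_dev, MI`` (or a single mapping of the same keys).
    """
    single = isinstance(metrics, dict)
    tbl = pd.DataFrame([metrics]) if single else metrics
    missing = [c for c in SCORE_COLUMNS if c not in tbl.columns]
    if missing:
        raise KeyError(f"metrics table lacks columns {missing}")
    hwe = np.minimum(tbl["HWE_dev"].to_numpy(dtype=float), 100.0)
    score = (
        1.4 * tbl["CR"].to_numpy(dtype=float)
        + 2.4 * tbl["MAF"].to_numpy(dtype=float)
        + tbl["Rep_Avg"].to_numpy(dtype=float)
        + tbl["RD"].to_numpy(dtype=float)
        - hwe / 10.0
        - tbl["MI"].to_numpy(dtype=float)
    )
    return float(score[0]) if single else score


@dataclass
class PanelSelection:
    """Ranked markers with scores and the selected top-N subset."""

    ranking: pd.DataFrame  # index marker_id, columns: score + components, sorted
    selected_ids: list[str]
    n_requested: int

    def __post_init__(self) -> None:
        if not set(self.selected_ids) <= set(self.ranking.index):
            raise ValueError("selected ids not all present in the ranking")


def select_panel(scores: pd.DataFrame, n: int) -> PanelSelection:
    """Pick the top-``n`` markers by QC score.

    ``scores`` must be indexed by marker id with a ``score`` column and,
    for tie-breaking, ``MAF`` and ``CR`` columns.  Ties are broken by
    higher MAF, then higher CR, then input order.  When fewer than ``n``
    markers are available all are selected and a warning is issued.
    """
    if n < 1:
        raise ValueError("panel size must be >= 1")
    tbl = scores.copy()
    tbl["_order"] = np.arange(len(tbl))
    ranked = tbl.sort_values(
        by=["score", "MAF", "CR", "_order"],
        ascending=[False, False, False, True],
        kind="stable",
    ).drop(columns="_order")
    n_take = min(n, len(ranked))
    if n_take < n:
        warnings.warn(
            f"requested a panel of {n} markers but only {n_take} are available",
            stacklevel=2,
        )
    return PanelSelection(ranked, list(ranked.index[:n_take]), n)


def validate_panel(
    ds: GenotypeDataset,
    selection: PanelSelection | list[str],
    ld_r2_threshold: float = 0.8,
) -> dict:
    """Concordance report for a selected panel against the full marker set.

    Returns the panel-vs-full GRM correlation, panel MAF/CR summaries and
    the panel marker pairs in strong LD (dosage r^2 above the report
    threshold).
    """
    ids = selection.selected_ids if isinstance(selection, PanelSelection) else list(selection)
    unknown = set(ids) - set(ds.marker_ids)
    if unknown:
        raise KeyError(f"panel contains markers absent from the dataset: {sorted(unknown)[:5]}")
    panel = ds.subset_markers(ids)
    full_grm = compute_grm(ds)
    panel_grm = compute_grm(panel)
    corr = grm_correlation(panel_grm, full_grm)
    mafs = ms.maf(panel.calls)
    crs = ms.call_rate(panel.calls)
    ld = ld_pairs(panel, ld_r2_threshold)
    return {
        "grm_correlation": corr,
        "n_panel": panel.n_markers,
        "n_full": ds.n_markers,
        "mean_maf": float(np.nanmean(mafs)),
        "mean_call_rate": float(np.mean(crs)),
        "ld_pairs": ld,
    }


def ld_pairs(ds: GenotypeDataset, r2_threshold: float = 0.8) -> pd.DataFrame:
    """All marker pairs with pairwise-complete dosage r^2 above a threshold.

    Report-only: strong-LD markers are flagged, never removed.  Uses the
    algebraic pairwise-complete Pearson correlation so the full pair grid
    is computed with matrix products.
    """
    X = ds.calls.astype(float)
    present = ds.calls != -1
    X[~present] = 0.0
    M = present.astype(float)
    n = M @ M.T
    Sa = X @ M.T
    Sb = Sa.T
    Sab = X @ X.T
    Saa = (X * X) @ M.T
    Sbb = Saa.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sab - Sa * Sb
        var_a = n * Saa - Sa * Sa
        var_b = n * Sbb - Sb * Sb
        r2 = (cov * cov) / (var_a * var_b)
    r2[(var_a <= 0) | (var_b <= 0) | (n < 2)] = np.nan
    iu = np.triu_indices(ds.n_markers, k=1)
    vals = r2[iu]
    hit = np.nonzero(vals > r2_threshold)[0]
    ids = np.asarray(ds.marker_ids, dtype=object)
    return pd.DataFrame(
        {
            "marker_a": ids[iu[0][hit]],
            "marker_b": ids[iu[1][hit]],
            "r2": vals[hit],
        }
    )


class PanelSelector(BaseEstimator, TransformerMixin):
    """Estimator that ranks markers by QC score and selects the panel.

    Parameters
    ----------
    n_markers : int
        Panel size (default 4236).

    Attributes
    ----------
    metrics_ : pandas.DataFrame
        Per-marker metrics computed on the fitted dataset.
    ranking_ : pandas.DataFrame
        Metrics + score, sorted by descending score.
    selected_ids_ : list of str
        The chosen panel, ``min(n_markers, available)`` entries.
    """

    def __init__(self, n_markers: int = 4236):
        self.n_markers = n_markers

    def fit(self, X: GenotypeDataset, y=None):
        metrics = ms.compute_marker_metrics(X)
        metrics = metrics.copy()
        metrics["score"] = qc_score(metrics)
        sel = select_panel(metrics, self.n_markers)
        self.metrics_ = metrics
        self.ranking_ = sel.ranking
        self.selection_ = sel
        self.selected_ids_ = sel.selected_ids
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.selected_ids_)
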