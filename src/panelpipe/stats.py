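"""Per-marker population-genetic statistics.

Everything the filtering cascade and the QC-score ranking consume lives
here: call rate, minor-allele frequency, technical repeatability, read
depth, the Hardy-Weinberg exact test (the standard conditional test that
PLINK's ``--hwe`` computes), the Mendelian-inheritance trio scan and
dosage-correlation LD.

Statistics treat technical replicates as one sample: replicate groups are
collapsed to the best-call-rate copy before anything is counted (see
:func:`panelpipe.dataset.primary_sample_indices`), except repeatability,
which is precisely the replicate concordance.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dataset import MISSING, GenotypeDataset, PedigreeError, primary_sample_indices

__all__ = [
    "call_rate",
    "maf",
    "hwe_exact",
    "mi_scan",
    "repeatability",
    "ld_r2",
    "hwe_deviation_pct",
    "mean_depth",
    "standardized_depth",
    "genotype_counts_by_pop",
    "hwe_p_by_pop",
    "compute_marker_metrics",
    "MENDELIAN_ERROR_TABLE",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """A statistic has no defined value on the given input."""


def _as_call_matrix(calls) -> np.ndarray:
    calls = np.asarray(calls)
    return calls[None, :] if calls.ndim == 1 else calls


def call_rate(calls) -> np.ndarray | float:
    """Proportion of non-missing calls per marker."""
    mat = _as_call_matrix(calls)
    if mat.shape[1] == 0:
        raise ValueError("call rate requires at least one sample")
    cr = (mat != MISSING).mean(axis=1)
    return float(cr[0]) if np.ndim(calls) == 1 else cr


def maf(calls) -> np.ndarray | float:
    """Minor-allele frequency per marker; NaN when all calls are missing."""
    mat = _as_call_matrix(calls)
    present = mat != MISSING
    n = present.sum(axis=1)
    alt = np.where(present, mat, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2.0 * n), np.nan)
    out = np.minimum(p, 1.0 - p)
    return float(out[0]) if np.ndim(calls) == 1 else out


# ----------------------------------------------------------------- HWE ----
def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided Hardy-Weinberg exact test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count no more probable than the observed one
    (Wigginton-style SNP-HWE; PLINK's default ``--hwe`` test, not mid-p).
    """
    counts = (int(n_hom_ref), int(n_het), int(n_hom_alt))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype is required")
    _, n_het, _ = counts
    rare = 2 * min(counts[0], counts[2]) + n_het  # minor-allele copies
    if rare == 0:
        return 1.0
    # heterozygote counts compatible with the allele counts share the
    # parity of the rare-allele count and run up to `rare` (rare <= n)
    h = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - h) // 2
    hom_common = n - h - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_common + 1)
        - gammaln(h + 1)
        - gammaln(hom_rare + 1)
        + h * np.log(2.0)
    )
    probs = np.exp(logp - logsumexp(logp))
    obs = probs[np.searchsorted(h, n_het)]
    # tolerance guards against ties lost to floating-point rounding
    return float(min(1.0, probs[probs <= obs * (1 + 1e-12)].sum()))


def genotype_counts_by_pop(
    ds: GenotypeDataset, populations: pd.Series | None = None
) -> dict[str, np.ndarray]:
    """Per-population (n_hom_ref, n_het, n_hom_alt) count arrays.

    Replicate copies are collapsed first.  Returns ``{pop: (n_markers, 3)}``.
    """
    pops = populations if populations is not None else ds.populations
    if pops is None or len(pops) == 0:
        raise ValueError("no population map available")
    # map each population member to its replicate-group representative so
    # a technical re-run can stand in for the individual it duplicates
    primary = primary_sample_indices(ds)
    rep_col: dict[object, int] = {}
    if ds.replicate_groups is not None and len(ds.replicate_groups):
        primary_set = set(primary.tolist())
        for s, g in ds.replicate_groups.items():
            i = ds.sample_index(s)
            if i in primary_set:
                rep_col[g] = i
    out: dict[str, np.ndarray] = {}
    for pop in pd.unique(pops):
        cols = []
        for s in pops.index[pops == pop]:
            g = None
            if ds.replicate_groups is not None and s in ds.replicate_groups.index:
                g = ds.replicate_groups[s]
            cols.append(rep_col[g] if g is not None and g in rep_col else ds.sample_index(s))
        sub = ds.calls[:, sorted(set(cols))]
        out[str(pop)] = np.stack(
            [(sub == 0).sum(axis=1), (sub == 1).sum(axis=1), (sub == 2).sum(axis=1)], axis=1
        )
    return out


def hwe_p_by_pop(
    ds: GenotypeDataset, populations: pd.Series | None = None
) -> pd.DataFrame:
    """Exact HWE p-value per marker per designated population."""
    counts = genotype_counts_by_pop(ds, populations)
    data = {}
    for pop, mat in counts.items():
        ps = np.ones(len(mat))
        for i, (a, h, b) in enumerate(mat):
            total = a + h + b
            ps[i] = 1.0 if total == 0 else hwe_exact(a, h, b)
        data[pop] = ps
    return pd.DataFrame(data, index=ds.marker_ids)


def hwe_deviation_pct(
    ds: GenotypeDataset, populations: pd.Series | None = None
) -> np.ndarray:
    """HWE deviation as a percentage, averaged over designated populations.

    Per population the deviation is ``100 * |Ho - He| / He`` with Ho the
    observed heterozygosity and He = 2p(1-p); monomorphic markers
    (He = 0) contribute 0.  Falls back to a single pooled population when
    the dataset carries no population map.
    """
    pops = populations if populations is not None else ds.populations
    if pops is None or len(pops) == 0:
        idx = primary_sample_indices(ds)
        sub = ds.calls[:, idx]
        counts = {
            "all": np.stack(
                [(sub == 0).sum(axis=1), (sub == 1).sum(axis=1), (sub == 2).sum(axis=1)],
                axis=1,
            )
        }
    else:
        counts = genotype_counts_by_pop(ds, pops)
    parts = []
    for mat in counts.values():
        n = mat.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = (mat[:, 1] + 2 * mat[:, 2]) / (2 * n)
            ho = mat[:, 1] / n
            he = 2 * p * (1 - p)
            dev = np.where(he > 0, 100.0 * np.abs(ho - he) / he, 0.0)
        parts.append(np.where(n > 0, dev, 0.0))
    return np.mean(parts, axis=0)


# ------------------------------------------------------------ Mendelian ----
def _build_mendelian_error_table() -> np.ndarray:
    """err[sire, dam, progeny] over dosages 0..2, True when impossible."""
    gametes = {0: {0}, 1: {0, 1}, 2: {1}}
    err = np.ones((3, 3, 3), dtype=bool)
    for s in range(3):
        for d in range(3):
            for a in gametes[s]:
                for b in gametes[d]:
                    err[s, d, a + b] = False
    return err


MENDELIAN_ERROR_TABLE = _build_mendelian_error_table()


def mi_scan(
    ds: GenotypeDataset, trios: list[tuple[str, str, str]] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Scan trios for Mendelian-inheritance errors.

    A trio is informative at a marker iff progeny, sire and dam are all
    non-missing; an error is a progeny call impossible under Mendelian
    transmission from the parent calls.

    Returns
    -------
    mi_rate : ndarray, shape (n_markers,)
        Erroneous informative trios / informative trios (0 where none
        informative).
    flags : ndarray of bool, shape (n_markers, n_trios)
        True where the progeny call of that trio is a Mendelian error.
    """
    trios = ds.trios if trios is None else trios
    n_trios = len(trios)
    flags = np.zeros((ds.n_markers, n_trios), dtype=bool)
    informative = np.zeros(ds.n_markers, dtype=np.int64)
    errors = np.zeros(ds.n_markers, dtype=np.int64)
    for t, (progeny, sire, dam) in enumerate(trios):
        p = ds.calls[:, ds.sample_index(progeny)]
        s = ds.calls[:, ds.sample_index(sire)]
        d = ds.calls[:, ds.sample_index(dam)]
        info = (p != MISSING) & (s != MISSING) & (d != MISSING)
        err = np.zeros(ds.n_markers, dtype=bool)
        err[info] = MENDELIAN_ERROR_TABLE[s[info], d[info], p[info]]
        flags[:, t] = err
        informative += info
        errors += err
    with np.errstate(invalid="ignore"):
        rate = np.where(informative > 0, errors / np.maximum(informative, 1), 0.0)
    return rate, flags


# ---------------------------------------------------------- repeatability ----
def repeatability(ds: GenotypeDataset) -> np.ndarray:
    """Replicate concordance per marker.

    Over all within-replicate-group sample pairs with both calls
    non-missing, the proportion of identical calls.  Markers with no
    comparable pair default to 1.0 (no evidence of irrepeatability), so a
    dataset without replicates never loses markers to this statistic.
    When the provider shipped a ``rep_avg`` column and the dataset has no
    replicate groups, that value is used instead.
    """
    if ds.replicate_groups is None or len(ds.replicate_groups) == 0:
        rep = ds.markers.get("rep_avg")
        if rep is not None and rep.notna().any():
            return rep.fillna(1.0).to_numpy(dtype=float)
        return np.ones(ds.n_markers)
    concordant = np.zeros(ds.n_markers, dtype=np.int64)
    comparable = np.zeros(ds.n_markers, dtype=np.int64)
    groups: dict[object, list[int]] = {}
    for s, g in ds.replicate_groups.items():
        groups.setdefault(g, []).append(ds.sample_index(s))
    for members in groups.values():
        for i, j in combinations(members, 2):
            a, b = ds.calls[:, i], ds.calls[:, j]
            both = (a != MISSING) & (b != MISSING)
            comparable += both
            concordant += both & (a == b)
    with np.errstate(invalid="ignore"):
        rep = np.where(comparable > 0, concordant / np.maximum(comparable, 1), 1.0)
    return rep


# -------------------------------------------------------------------- LD ----
def ld_r2(calls_a, calls_b) -> float:
    """Squared Pearson correlation of alt-dosage vectors (pairwise complete)."""
    a = np.asarray(calls_a, dtype=float)
    b = np.asarray(calls_b, dtype=float)
    both = (a != MISSING) & (b != MISSING)
    if both.sum() < 2:
        raise UndefinedStatisticError("fewer than 2 pairwise-complete samples")
    a, b = a[both], b[both]
    if a.std() == 0 or b.std() == 0:
        raise UndefinedStatisticError("zero dosage variance at a marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


# ----------------------------------------------------------------- depth ----
def mean_depth(ds: GenotypeDataset) -> np.ndarray:
    """Mean total reads over non-missing calls, per marker."""
    depth = ds.total_depth()
    present = ds.calls != MISSING
    n = present.sum(axis=1)
    with np.errstate(invalid="ignore"):
        md = np.where(n > 0, np.where(present, depth, 0).sum(axis=1) / np.maximum(n, 1), 0.0)
    return md


def standardized_depth(mean_depths) -> np.ndarray:
    """RD: per-marker mean depth divided by the largest observed mean depth."""
    d = np.asarray(mean_depths, dtype=float)
    if d.size == 0:
        return d
    if (d < 0).any():
        raise ValueError("depths must be non-negative")
    top = d.max()
    return d / top if top > 0 else np.zeros_like(d)


# ---------------------------------------------------------------- metrics ----
def compute_marker_metrics(
    ds: GenotypeDataset,
    populations: pd.Series | None = None,
    trios: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Full per-marker metrics table (the QC-score symbol set).

    Columns: ``CR, MAF, Rep_Avg, mean_depth, RD, HWE_dev, MI`` plus one
    ``hwe_p_<population>`` column per designated population.
    """
    primary = primary_sample_indices(ds)
    sub = ds.calls[:, primary]
    metrics = pd.DataFrame(index=ds.marker_ids)
    metrics["CR"] = call_rate(sub)
    metrics["MAF"] = maf(sub)
    metrics["Rep_Avg"] = repeatability(ds)
    if ds.ref_counts is not None and ds.alt_counts is not None:
        metrics["mean_depth"] = mean_depth(ds)
    else:
        metrics["mean_depth"] = np.nan
    metrics["RD"] = (
        standardized_depth(metrics["mean_depth"].to_numpy())
        if metrics["mean_depth"].notna().all()
        else np.nan
    )
    metrics["HWE_dev"] = hwe_deviation_pct(ds, populations)
    pops = populations if populations is not None else ds.populations
    if pops is not None and len(pops):
        pvals = hwe_p_by_pop(ds, pops)
        for pop in pvals.columns:
            metrics[f"hwe_p_{pop}"] = pvals[pop].to_numpy()
    use_trios = ds.trios if trios is None else trios
    if use_trios:
        metrics["MI"], _ = mi_scan(ds, use_trios)
    else:
        metrics["MI"] = 0.0
    return metrics
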