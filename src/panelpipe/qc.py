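"""The staged SNP quality-control cascade.

Stages, in the order they ran for the original assay design:

1. silence genotype calls whose summed allele read depth is below 5;
2. remove markers with MAF < 0.02, call rate <= 0.5, repeatability < 0.9
   (and optionally excessive average depth);
3. keep one SNP per identical RAD-tag (highest MAF);
4. greedy redundancy clustering of tags at 95% identity, one SNP kept
   per cluster;
5. remove markers with > 9% Mendelian-inheritance errors over trios;
6. remove markers out of Hardy-Weinberg equilibrium (exact p < 1e-4) in
   every designated population;
7. silence the individual progeny calls still flagged as MI errors.

Each stage is a scikit-learn style transformer over a
:class:`~panelpipe.dataset.GenotypeDataset`: ``fit`` computes the
decision (masks, counts, fitted attributes with a trailing underscore)
and ``transform`` applies it.  :class:`QCPipeline` chains them and
builds the per-stage removal report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import MISSING, FormatError, GenotypeDataset, primary_sample_indices
from . import stats as ms

__all__ = [
    "QCConfig",
    "LowDepthCallSilencer",
    "BasicMarkerFilter",
    "ExactDuplicateFilter",
    "TagRedundancyClusterer",
    "MendelianErrorFilter",
    "HWEPopulationFilter",
    "MendelianCallSilencer",
    "QCPipeline",
    "run_qc",
    "silence_low_depth",
    "filter_basic",
    "dedup_exact",
    "cluster_tags",
    "filter_hwe",
    "filter_mi",
    "silence_mi_calls",
    "sequence_identity",
]


@dataclass
class QCConfig:
    """Thresholds of the filtering cascade; defaults are the assay-design values."""

    min_call_depth: int = 5  # silence calls with ref+alt reads below this
    min_maf: float = 0.02  # remove MAF strictly below
    min_call_rate: float = 0.5  # remove call rate at or below
    min_repeatability: float = 0.9  # remove repeatability strictly below
    cluster_identity: float = 0.95  # tag redundancy clustering threshold
    hwe_alpha: float = 1e-4  # exact-test significance
    hwe_require_all_pops: bool = True  # deviate in every population to be removed
    max_mi_rate: float = 0.09  # remove MI rate strictly above
    max_avg_depth: float | None = None  # optional; recommended 200 when enabled

    def __post_init__(self) -> None:
        if self.min_call_depth < 0:
            raise ValueError("min_call_depth must be >= 0")
        for name in ("min_maf", "min_call_rate", "min_repeatability", "cluster_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.hwe_alpha <= 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1]")
        if not 0.0 <= self.max_mi_rate <= 1.0:
            raise ValueError("max_mi_rate must lie in [0, 1]")
        if self.max_avg_depth is not None and self.max_avg_depth <= 0:
            raise ValueError("max_avg_depth must be positive when enabled")


def _primary_calls(ds: GenotypeDataset) -> np.ndarray:
    return ds.calls[:, primary_sample_indices(ds)]


# ------------------------------------------------------------------ stages ----
class LowDepthCallSilencer(BaseEstimator, TransformerMixin):
    """Silence calls whose summed per-allele read depth falls below a floor."""

    def __init__(self, min_call_depth: int = 5):
        self.min_call_depth = min_call_depth

    def fit(self, X: GenotypeDataset, y=None):
        if X.ref_counts is None or X.alt_counts is None:
            raise FormatError("low-depth silencing requires read-count matrices")
        mask = (X.total_depth() < self.min_call_depth) & (X.calls != MISSING)
        self.silence_mask_ = mask
        self.n_silenced_ = int(mask.sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        out = X.copy()
        rows, cols = np.nonzero(self.silence_mask_)
        out.silence_calls(rows, cols, "low_depth")
        return out


class BasicMarkerFilter(BaseEstimator, TransformerMixin):
    """Remove markers by MAF, call rate, repeatability and optional depth.

    Criteria are counted in that order: a marker failing several is
    charged to the first.  The call-rate boundary is inclusive (a marker
    at exactly the threshold is removed); MAF and repeatability bounds
    are strict.
    """

    def __init__(
        self,
        min_maf: float = 0.02,
        min_call_rate: float = 0.5,
        min_repeatability: float = 0.9,
        max_avg_depth: float | None = None,
    ):
        self.min_maf = min_maf
        self.min_call_rate = min_call_rate
        self.min_repeatability = min_repeatability
        self.max_avg_depth = max_avg_depth

    def fit(self, X: GenotypeDataset, y=None):
        calls = _primary_calls(X)
        mafs = ms.maf(calls)
        crs = ms.call_rate(calls)
        reps = ms.repeatability(X)
        fail_maf = ~(mafs >= self.min_maf)  # NaN (all-missing) fails too
        fail_cr = crs <= self.min_call_rate
        fail_rep = reps < self.min_repeatability
        fail_depth = np.zeros(X.n_markers, dtype=bool)
        if self.max_avg_depth is not None:
            fail_depth = ms.mean_depth(X) > self.max_avg_depth
        first = np.full(X.n_markers, "", dtype=object)
        for name, fail in (
            ("maf", fail_maf),
            ("call_rate", fail_cr),
            ("repeatability", fail_rep),
            ("max_depth", fail_depth),
        ):
            first[(first == "") & fail] = name
        self.removal_reason_ = first
        self.removed_by_ = {
            name: int((first == name).sum())
            for name in ("maf", "call_rate", "repeatability", "max_depth")
        }
        self.keep_mask_ = first == ""
        self.n_removed_ = int((~self.keep_mask_).sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.keep_mask_)


def _pick_representative(ds: GenotypeDataset, idx: np.ndarray, mafs, crs) -> int:
    """Highest MAF, ties by higher CR, then lowest snp_position, then order."""
    pos = ds.markers["snp_position"].to_numpy()
    best = idx[0]
    for i in idx[1:]:
        key_i = (np.nan_to_num(mafs[i], nan=-1.0), crs[i], -pos[i], -i)
        key_b = (np.nan_to_num(mafs[best], nan=-1.0), crs[best], -pos[best], -best)
        if key_i > key_b:
            best = i
    return int(best)


class ExactDuplicateFilter(BaseEstimator, TransformerMixin):
    """One SNP per identical tag sequence (and per multi-SNP clone).

    Markers sharing a tag sequence or a clone id form one group; the
    highest-MAF SNP of each group is retained.
    """

    def fit(self, X: GenotypeDataset, y=None):
        # union groups keyed by sequence and by clone id
        parent = list(range(X.n_markers))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i, j):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)

        for key_col in ("tag_sequence", "clone_id"):
            firsts: dict[str, int] = {}
            for i, key in enumerate(X.markers[key_col]):
                if key in firsts:
                    union(firsts[key], i)
                else:
                    firsts[key] = i

        calls = _primary_calls(X)
        mafs = ms.maf(calls)
        crs = ms.call_rate(calls)
        groups: dict[int, list[int]] = {}
        for i in range(X.n_markers):
            groups.setdefault(find(i), []).append(i)
        keep = np.zeros(X.n_markers, dtype=bool)
        for members in groups.values():
            keep[_pick_representative(X, np.asarray(members), mafs, crs)] = True
        self.keep_mask_ = keep
        self.n_removed_ = int((~keep).sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.keep_mask_)


def sequence_identity(a: str, b: str) -> float:
    """Ungapped end-to-end identity: matches over the shorter length."""
    n = min(len(a), len(b))
    if n == 0:
        raise ValueError("empty sequence")
    matches = sum(x == y for x, y in zip(a[:n], b[:n]))
    return matches / n


class TagRedundancyClusterer(BaseEstimator, TransformerMixin):
    """Greedy redundancy clustering of tag sequences, one SNP per cluster.

    Emulates the CD-HIT strategy: tags are processed in descending
    (length, MAF) order; each joins the first existing cluster whose
    representative is at least ``cluster_identity`` identical (matching
    positions over the shorter length, ungapped), otherwise it founds a
    new cluster.  Within a cluster the highest-MAF SNP survives.
    """

    def __init__(self, cluster_identity: float = 0.95):
        self.cluster_identity = cluster_identity

    def fit(self, X: GenotypeDataset, y=None):
        calls = _primary_calls(X)
        mafs = ms.maf(calls)
        crs = ms.call_rate(calls)
        seqs = X.markers["tag_sequence"].to_numpy()
        lengths = np.array([len(s) for s in seqs])
        order = sorted(
            range(X.n_markers),
            key=lambda i: (-lengths[i], -np.nan_to_num(mafs[i], nan=-1.0), i),
        )
        encoded = [np.frombuffer(s.encode("ascii"), dtype=np.uint8) for s in seqs]
        rep_indices: list[int] = []
        rep_matrix: np.ndarray | None = None  # representatives padded to max length
        max_len = int(lengths.max()) if X.n_markers else 0
        members: list[list[int]] = []
        cluster_of = np.full(X.n_markers, -1, dtype=np.int64)
        for i in order:
            seq = encoded[i]
            if rep_indices:
                width = np.minimum(lengths[rep_indices], len(seq))
                padded = np.zeros(max_len, dtype=np.uint8)
                padded[: len(seq)] = seq
                matches = (rep_matrix[: len(rep_indices)] == padded).cumsum(axis=1)
                shared = matches[np.arange(len(rep_indices)), width - 1]
                ident = shared / width
                hits = np.nonzero(ident >= self.cluster_identity)[0]
            else:
                hits = np.array([], dtype=np.int64)
            if hits.size:
                c = int(hits[0])
            else:
                c = len(rep_indices)
                rep_indices.append(i)
                members.append([])
                if rep_matrix is None:
                    rep_matrix = np.zeros((256, max_len), dtype=np.uint8)
                elif len(rep_indices) > rep_matrix.shape[0]:
                    rep_matrix = np.vstack(
                        [rep_matrix, np.zeros_like(rep_matrix)]
                    )
                rep_matrix[c, : len(seq)] = seq
            members[c].append(i)
            cluster_of[i] = c
        keep = np.zeros(X.n_markers, dtype=bool)
        for group in members:
            keep[_pick_representative(X, np.asarray(group), mafs, crs)] = True
        self.keep_mask_ = keep
        self.cluster_of_ = cluster_of
        self.n_clusters_ = len(rep_indices)
        self.n_removed_ = int((~keep).sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.keep_mask_)


class MendelianErrorFilter(BaseEstimator, TransformerMixin):
    """Remove markers whose trio MI-error rate exceeds the bound (strict >)."""

    def __init__(self, max_mi_rate: float = 0.09):
        self.max_mi_rate = max_mi_rate

    def fit(self, X: GenotypeDataset, y=None):
        if X.trios:
            rate, _ = ms.mi_scan(X)
        else:
            rate = np.zeros(X.n_markers)
        self.mi_rate_ = rate
        self.keep_mask_ = ~(rate > self.max_mi_rate)
        self.n_removed_ = int((~self.keep_mask_).sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.keep_mask_)


class HWEPopulationFilter(BaseEstimator, TransformerMixin):
    """Remove markers out of HWE in the designated populations.

    With ``require_all_pops`` (the default) a marker must deviate at
    ``alpha`` in every designated population to be removed; otherwise a
    single deviating population suffices.
    """

    def __init__(self, hwe_alpha: float = 1e-4, require_all_pops: bool = True):
        self.hwe_alpha = hwe_alpha
        self.require_all_pops = require_all_pops

    def fit(self, X: GenotypeDataset, y=None):
        if X.populations is None or len(X.populations) == 0:
            raise FormatError("HWE filtering requires a population map")
        pvals = ms.hwe_p_by_pop(X)
        sig = pvals.to_numpy() < self.hwe_alpha
        remove = sig.all(axis=1) if self.require_all_pops else sig.any(axis=1)
        self.hwe_p_ = pvals
        self.keep_mask_ = ~remove
        self.n_removed_ = int(remove.sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        return X.subset_markers(self.keep_mask_)


class MendelianCallSilencer(BaseEstimator, TransformerMixin):
    """Silence the individual progeny calls flagged as MI errors.

    Applied after marker-level MI filtering: the surviving markers may
    still carry isolated inheritance errors (sequencing error, allelic
    dropout); only the offending progeny call is set to missing, parents
    are untouched.
    """

    def fit(self, X: GenotypeDataset, y=None):
        if X.trios:
            _, flags = ms.mi_scan(X)
        else:
            flags = np.zeros((X.n_markers, 0), dtype=bool)
        self.flags_ = flags
        self.n_silenced_ = int(flags.sum())
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        out = X.copy()
        if self.flags_.size == 0:
            return out
        progeny_cols = np.array([out.sample_index(t[0]) for t in out.trios])
        rows, trio_idx = np.nonzero(self.flags_)
        out.silence_calls(rows, progeny_cols[trio_idx], "mendelian_error")
        return out


# ---------------------------------------------------------------- pipeline ----
class QCPipeline(BaseEstimator):
    """Run the full filtering cascade and keep the per-stage report.

    ``fit_transform`` executes the stages in the fixed assay-design
    order, recomputing every statistic on the dataset as it stands at
    each stage.  After fitting, ``report_`` holds the stage-ordered
    removal/silencing counts and ``stages_`` the fitted stage objects.
    """

    STAGE_ORDER = [
        "silence_low_depth",
        "filter_basic",
        "dedup_exact",
        "cluster_tags",
        "filter_mi",
        "filter_hwe",
        "silence_mi_calls",
    ]

    def __init__(self, config: QCConfig | None = None, **overrides):
        if config is None:
            config = QCConfig(**overrides)
        elif overrides:
            config = QCConfig(**{**asdict(config), **overrides})
        self.config = config

    def fit(self, X: GenotypeDataset, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X: GenotypeDataset, y=None) -> GenotypeDataset:
        cfg = self.config
        ds = X
        rows = []
        self.stages_ = {}
        before = self._summary(ds)

        def run_stage(name, stage, current):
            n_in = current.n_markers
            try:
                stage.fit(current)
                nxt = stage.transform(current)
            except Exception as exc:
                raise RuntimeError(f"QC stage {name!r} failed: {exc}") from exc
            removed = getattr(stage, "n_removed_", 0)
            silenced = getattr(stage, "n_silenced_", 0)
            rows.append(
                {
                    "stage": name,
                    "snps_in": n_in,
                    "snps_removed": removed,
                    "snps_out": nxt.n_markers,
                    "calls_silenced": silenced,
                }
            )
            self.stages_[name] = stage
            return nxt

        if ds.ref_counts is not None and cfg.min_call_depth > 0:
            ds = run_stage(
                "silence_low_depth", LowDepthCallSilencer(cfg.min_call_depth), ds
            )
        basic = BasicMarkerFilter(
            cfg.min_maf, cfg.min_call_rate, cfg.min_repeatability, cfg.max_avg_depth
        )
        basic.fit(ds)
        nxt = basic.transform(ds)
        for crit in ("maf", "call_rate", "repeatability", "max_depth"):
            removed = basic.removed_by_[crit]
            if crit == "max_depth" and cfg.max_avg_depth is None:
                continue
            rows.append(
                {
                    "stage": f"filter_{crit}",
                    "snps_in": ds.n_markers if crit == "maf" else rows[-1]["snps_out"],
                    "snps_removed": removed,
                    "snps_out": (ds.n_markers if crit == "maf" else rows[-1]["snps_out"])
                    - removed,
                    "calls_silenced": 0,
                }
            )
        self.stages_["filter_basic"] = basic
        ds = nxt
        ds = run_stage("dedup_exact", ExactDuplicateFilter(), ds)
        ds = run_stage("cluster_tags", TagRedundancyClusterer(cfg.cluster_identity), ds)
        if ds.trios:
            ds = run_stage("filter_mi", MendelianErrorFilter(cfg.max_mi_rate), ds)
        if ds.populations is not None and len(ds.populations):
            ds = run_stage(
                "filter_hwe", HWEPopulationFilter(cfg.hwe_alpha, cfg.hwe_require_all_pops), ds
            )
        if ds.trios:
            ds = run_stage("silence_mi_calls", MendelianCallSilencer(), ds)

        self.report_ = pd.DataFrame(
            rows, columns=["stage", "snps_in", "snps_removed", "snps_out", "calls_silenced"]
        )
        self.summary_before_ = before
        self.summary_after_ = self._summary(ds)
        self.filtered_ = ds
        return ds

    @staticmethod
    def _summary(ds: GenotypeDataset) -> dict[str, float]:
        if ds.n_markers == 0:
            return {"n_markers": 0}
        calls = _primary_calls(ds)
        out = {
            "n_markers": ds.n_markers,
            "mean_call_rate": float(np.mean(ms.call_rate(calls))),
            "mean_maf": float(np.nanmean(ms.maf(calls))),
        }
        if ds.ref_counts is not None:
            depth = ds.total_depth()
            present = ds.calls != MISSING
            out["mean_depth_per_call"] = (
                float(depth[present].mean()) if present.any() else 0.0
            )
        if ds.trios:
            rate, _ = ms.mi_scan(ds)
            out["mean_mi_rate"] = float(rate.mean())
        return out


def run_qc(
    ds: GenotypeDataset, config: QCConfig | None = None
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Run the cascade; returns (filtered dataset, stage report)."""
    pipe = QCPipeline(config)
    filtered = pipe.fit_transform(ds)
    return filtered, pipe.report_


# --------------------------------------------------- thin functional wrappers ----
def silence_low_depth(ds, min_call_depth: int = 5):
    stage = LowDepthCallSilencer(min_call_depth).fit(ds)
    return stage.transform(ds), stage.n_silenced_


def filter_basic(ds, config: QCConfig | None = None):
    cfg = config or QCConfig()
    stage = BasicMarkerFilter(
        cfg.min_maf, cfg.min_call_rate, cfg.min_repeatability, cfg.max_avg_depth
    ).fit(ds)
    return stage.transform(ds), stage.removed_by_


def dedup_exact(ds):
    stage = ExactDuplicateFilter().fit(ds)
    return stage.transform(ds), stage.n_removed_


def cluster_tags(ds, cluster_identity: float = 0.95):
    stage = TagRedundancyClusterer(cluster_identity).fit(ds)
    return stage.transform(ds), stage.n_removed_


def filter_hwe(ds, config: QCConfig | None = None):
    cfg = config or QCConfig()
    stage = HWEPopulationFilter(cfg.hwe_alpha, cfg.hwe_require_all_pops).fit(ds)
    return stage.transform(ds), stage.n_removed_


def filter_mi(ds, config: QCConfig | None = None):
    cfg = config or QCConfig()
    stage = MendelianErrorFilter(cfg.max_mi_rate).fit(ds)
    return stage.transform(ds), stage.n_removed_


def silence_mi_calls(ds):
    stage = MendelianCallSilencer().fit(ds)
    return stage.transform(ds), stage.n_silenced_
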