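"""Core in-memory containers for DArT-style genotype datasets.

A :class:`GenotypeDataset` holds a markers x samples call matrix together
with the paired per-allele read-count matrices and the sample metadata
(population map, pedigree trios, technical-replicate groups) that the QC
pipeline consumes.

Calls are stored as alt-allele dosage: ``0`` hom-ref, ``1`` het, ``2``
hom-alt, ``-1`` missing.  The DArT one-row file coding (0 = hom-ref,
1 = hom-alt, 2 = het, "-" = missing) is translated at the IO boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: columns of the marker metadata frame
MARKER_COLUMNS = [
    "clone_id",
    "snp_position",
    "ref_allele",
    "alt_allele",
    "tag_sequence",
    "rep_avg",
]


class FormatError(ValueError):
    """Raised when input tables disagree in shape, order or coding."""


class PedigreeError(KeyError):
    """Raised when a trio refers to an unknown sample identifier."""


def marker_ids_from(markers: pd.DataFrame) -> pd.Index:
    """Canonical marker identifier: ``<clone_id>:<snp_position>``."""
    return pd.Index(
        markers["clone_id"].astype(str) + ":" + markers["snp_position"].astype(str),
        name="marker_id",
    )


@dataclass
class GenotypeDataset:
    """Markers x samples genotype calls with per-allele read counts.

    Parameters
    ----------
    markers : pandas.DataFrame
        One row per SNP with columns ``clone_id, snp_position, ref_allele,
        alt_allele, tag_sequence, rep_avg``; indexed by marker id.
    samples : list of str
        Ordered unique sample identifiers (matrix columns).
    calls : ndarray of int8, shape (n_markers, n_samples)
        Alt-allele dosage, ``-1`` for missing.
    ref_counts, alt_counts : ndarray of int32 or None
        Per-call read counts for each allele; ``None`` when the provider
        supplied genotypes only.
    populations : pandas.Series or None
        sample -> population label, for the samples that belong to a
        designated (wild) population.
    trios : list of (progeny, sire, dam)
        Pedigree trios used for Mendelian-inheritance scanning.
    replicate_groups : pandas.Series or None
        sample -> replicate-group id for technical replicates.
    silenced : pandas.DataFrame
        Provenance of silenced calls: columns ``marker_id, sample, reason``.
    """

    markers: pd.DataFrame
    samples: list[str]
    calls: np.ndarray
    ref_counts: np.ndarray | None = None
    alt_counts: np.ndarray | None = None
    populations: pd.Series | None = None
    trios: list[tuple[str, str, str]] = field(default_factory=list)
    replicate_groups: pd.Series | None = None
    silenced: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["marker_id", "sample", "reason"])
    )

    def __post_init__(self) -> None:
        self.markers = self.markers.copy()
        if list(self.markers.index.names) != ["marker_id"] or self.markers.index.has_duplicates:
            self.markers.index = marker_ids_from(self.markers)
        self.samples = [str(s) for s in self.samples]
        if len(set(self.samples)) != len(self.samples):
            raise FormatError("sample identifiers are not unique")
        self.calls = np.asarray(self.calls, dtype=np.int8)
        expected = (len(self.markers), len(self.samples))
        if self.calls.shape != expected:
            raise FormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{expected[0]} markers x {expected[1]} samples"
            )
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise FormatError("call matrix contains codes outside {-1, 0, 1, 2}")
        for name in ("ref_counts", "alt_counts"):
            mat = getattr(self, name)
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=np.int32)
            if mat.shape != expected:
                raise FormatError(f"{name} shape {mat.shape} does not match calls {expected}")
            if (mat < 0).any():
                raise FormatError(f"{name} contains negative read counts")
            setattr(self, name, mat)
        if self.populations is not None:
            self.populations = pd.Series(self.populations, dtype=object)
            unknown = set(self.populations.index) - set(self.samples)
            if unknown:
                raise FormatError(f"population map names unknown samples: {sorted(unknown)[:5]}")
        if self.replicate_groups is not None:
            self.replicate_groups = pd.Series(self.replicate_groups, dtype=object)
            unknown = set(self.replicate_groups.index) - set(self.samples)
            if unknown:
                raise FormatError(f"replicate map names unknown samples: {sorted(unknown)[:5]}")
        sample_set = set(self.samples)
        for progeny, sire, dam in self.trios:
            for sid in (progeny, sire, dam):
                if sid not in sample_set:
                    raise PedigreeError(f"trio member {sid!r} is not a sample in the dataset")
            if progeny in (sire, dam):
                raise PedigreeError(f"progeny {progeny!r} listed as its own parent")

    # ------------------------------------------------------------------
    @property
    def marker_ids(self) -> pd.Index:
        return self.markers.index

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise PedigreeError(f"unknown sample {sample_id!r}") from None

    def total_depth(self) -> np.ndarray:
        """Per-call total read count (ref + alt)."""
        if self.ref_counts is None or self.alt_counts is None:
            raise FormatError("dataset carries no read-count matrices")
        return self.ref_counts.astype(np.int64) + self.alt_counts

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            markers=self.markers.copy(),
            samples=list(self.samples),
            calls=self.calls.copy(),
            ref_counts=None if self.ref_counts is None else self.ref_counts.copy(),
            alt_counts=None if self.alt_counts is None else self.alt_counts.copy(),
            populations=None if self.populations is None else self.populations.copy(),
            trios=list(self.trios),
            replicate_groups=(
                None if self.replicate_groups is None else self.replicate_groups.copy()
            ),
            silenced=self.silenced.copy(),
        )

    def subset_markers(self, keep) -> "GenotypeDataset":
        """Return a dataset restricted to ``keep`` (bool mask or id list)."""
        if isinstance(keep, (pd.Index, list, tuple, set)):
            mask = self.marker_ids.isin(list(keep))
        else:
            mask = np.asarray(keep, dtype=bool)
            if mask.shape != (self.n_markers,):
                raise FormatError("marker mask length does not match marker count")
        kept_ids = self.marker_ids[mask]
        return GenotypeDataset(
            markers=self.markers.loc[mask],
            samples=list(self.samples),
            calls=self.calls[mask],
            ref_counts=None if self.ref_counts is None else self.ref_counts[mask],
            alt_counts=None if self.alt_counts is None else self.alt_counts[mask],
            populations=None if self.populations is None else self.populations.copy(),
            trios=list(self.trios),
            replicate_groups=(
                None if self.replicate_groups is None else self.replicate_groups.copy()
            ),
            silenced=self.silenced[self.silenced["marker_id"].isin(kept_ids)].reset_index(
                drop=True
            ),
        )

    def subset_samples(self, keep: Sequence[str]) -> "GenotypeDataset":
        keep = [str(s) for s in keep]
        idx = [self.sample_index(s) for s in keep]
        keep_set = set(keep)
        pops = None
        if self.populations is not None:
            pops = self.populations[self.populations.index.isin(keep_set)]
            pops = pops if len(pops) else None
        reps = None
        if self.replicate_groups is not None:
            reps = self.replicate_groups[self.replicate_groups.index.isin(keep_set)]
            reps = reps if len(reps) else None
        trios = [t for t in self.trios if all(m in keep_set for m in t)]
        return GenotypeDataset(
            markers=self.markers.copy(),
            samples=keep,
            calls=self.calls[:, idx],
            ref_counts=None if self.ref_counts is None else self.ref_counts[:, idx],
            alt_counts=None if self.alt_counts is None else self.alt_counts[:, idx],
            populations=pops,
            trios=trios,
            replicate_groups=reps,
            silenced=self.silenced[self.silenced["sample"].isin(keep_set)].reset_index(drop=True),
        )

    def silence_calls(self, rows: np.ndarray, cols: np.ndarray, reason: str) -> int:
        """Set the (row, col) calls to missing, recording provenance.

        Already-missing calls are left untouched and not recorded.
        Returns the number of calls actually silenced.
        """
        rows = np.asarray(rows, dtype=np.intp)
        cols = np.asarray(cols, dtype=np.intp)
        live = self.calls[rows, cols] != MISSING
        rows, cols = rows[live], cols[live]
        if rows.size == 0:
            return 0
        self.calls[rows, cols] = MISSING
        record = pd.DataFrame(
            {
                "marker_id": self.marker_ids[rows],
                "sample": np.asarray(self.samples, dtype=object)[cols],
                "reason": reason,
            }
        )
        frames = [df for df in (self.silenced, record) if len(df)]
        self.silenced = pd.concat(frames, ignore_index=True) if frames else record
        return int(rows.size)


def primary_sample_indices(ds: GenotypeDataset) -> np.ndarray:
    """Indices of one representative sample per technical-replicate group.

    Within each replicate group the copy with the highest individual call
    rate is retained (ties: first in sample order); samples outside any
    group are their own representatives.  Statistics such as call rate,
    MAF and HWE are computed on these representatives so that replicate
    copies do not pseudo-replicate the data.
    """
    if ds.replicate_groups is None or len(ds.replicate_groups) == 0:
        return np.arange(ds.n_samples)
    non_missing = (ds.calls != MISSING).sum(axis=0)
    group_of = {s: g for s, g in ds.replicate_groups.items()}
    best: dict[object, tuple[int, int]] = {}  # group -> (-callrate, index)
    singles: list[int] = []
    for i, s in enumerate(ds.samples):
        g = group_of.get(s)
        if g is None:
            singles.append(i)
            continue
        cur = best.get(g)
        if cur is None or non_missing[i] > non_missing[cur[1]]:
            best[g] = (non_missing[i], i)
    chosen = sorted(singles + [i for _, i in best.values()])
    return np.asarray(chosen, dtype=np.intp)
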