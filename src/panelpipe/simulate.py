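"""Synthetic DArT-style datasets with known truth.

The generator emulates the statistical structure of a shrimp SNP
discovery cohort: two diverged wild populations plus farm families with
recorded trios, technical replicates re-sequenced with fresh noise,
negative-binomial read depth with a heavy low-depth tail, per-read
allele miscalls that create Mendelian-inheritance errors, and RAD-tags
carrying one to six SNPs including exact and near-duplicate tag
sequences.  Every piece of ground truth (genotypes, per-population
allele frequencies, pedigree, tag duplicate groups) is returned so the
whole QC/selection pipeline can be verified without external data.

Population structure follows the Balding-Nichols model: population
alt-allele frequencies are Beta-distributed around an ancestral
frequency with variance ``Fst * p * (1 - p)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, PedigreeError
from .io import write_dataset

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_allele_freqs",
    "simulate_pedigree_genotypes",
    "simulate_read_counts",
    "simulate_dataset",
    "emit_dataset",
    "DEFAULT_SNPS_PER_TAG",
]

#: observed distribution of SNPs per RAD-tag in the discovery library
#: (1.37 +/- 0.6 SNPs per tag on average)
DEFAULT_SNPS_PER_TAG = {
    1: 0.7814,
    2: 0.1742,
    3: 0.0371,
    4: 0.0063,
    5: 0.0009,
    6: 0.0001,
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror the discovery-cohort scale."""

    n_markers: int = 5000
    tag_length: int = 69
    snps_per_tag_dist: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SNPS_PER_TAG)
    )
    n_pop_A: int = 132  # East Coast-like wild population
    n_pop_B: int = 125  # Northern Territory-like wild population
    fst: float = 0.1
    families: list[tuple[str, str, int]] = field(
        default_factory=lambda: [(f"SIRE{k}", f"DAM{k}", 20) for k in range(1, 7)]
    )
    n_trio_records: int = 81
    replicate_fraction: float = 0.23
    mean_depth: float = 17.0
    depth_dispersion: float = 2.0  # per-call NB size parameter; smaller = heavier tail
    marker_depth_shape: float | None = 1.2  # gamma shape of per-marker depth multipliers
    allele_error_rate: float = 0.001
    missing_rate: float = 0.06  # zero-inflation on top of NB zeros
    freq_interval: tuple[float, float] = (0.05, 0.95)
    dup_tag_fraction: float = 0.02
    near_dup_tag_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.tag_length < 20:
            raise ValueError("tag_length must be >= 20")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must lie in (0, 1)")
        total = sum(self.snps_per_tag_dist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError("snps_per_tag_dist must sum to 1")
        if any(k < 1 or k > 6 for k in self.snps_per_tag_dist):
            raise ValueError("snps per tag must lie in 1..6")
        for name in (
            "replicate_fraction",
            "allele_error_rate",
            "missing_rate",
            "dup_tag_fraction",
            "near_dup_tag_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_depth <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth parameters must be positive")
        if self.marker_depth_shape is not None and self.marker_depth_shape <= 0:
            raise ValueError("marker_depth_shape must be positive (or None to disable)")
        lo, hi = self.freq_interval
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("freq_interval must satisfy 0 < lo < hi < 1")
        if self.n_trio_records > self.n_progeny:
            raise ValueError(
                f"n_trio_records={self.n_trio_records} exceeds total progeny "
                f"{self.n_progeny}"
            )

    @property
    def n_progeny(self) -> int:
        return sum(n for _, _, n in self.families)


@dataclass
class TruthSet:
    """Ground truth behind a simulated dataset."""

    true_genotypes: pd.DataFrame  # markers x samples alt-dosage (0/1/2)
    pop_allele_freqs: pd.DataFrame  # columns: ancestral, pop_A, pop_B
    pedigree: dict[str, tuple[str, str]]  # progeny -> (sire, dam)
    cluster_map: pd.Series  # clone_id -> duplicate-group id
    markers: pd.DataFrame  # marker metadata as emitted
    populations: pd.Series  # wild sample -> population label
    trios: list[tuple[str, str, str]]


# --------------------------------------------------------------- frequencies ----
def simulate_allele_freqs(
    n_markers: int,
    fst: float,
    seed: int | np.random.Generator = 0,
    freq_interval: tuple[float, float] = (0.05, 0.95),
) -> pd.DataFrame:
    """Balding-Nichols ancestral and two population-specific frequencies.

    Ancestral frequencies are uniform on ``freq_interval``; each
    population frequency is Beta-distributed with mean equal to the
    ancestral frequency and variance ``fst * p * (1 - p)``.
    """
    if not 0.0 < fst < 1.0:
        raise ValueError("fst must lie in (0, 1)")
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = freq_interval
    p = rng.uniform(lo, hi, size=n_markers)
    scale = (1.0 - fst) / fst
    a = p * scale
    b = (1.0 - p) * scale
    pop_a = rng.beta(a, b)
    pop_b = rng.beta(a, b)
    return pd.DataFrame({"ancestral": p, "pop_A": pop_a, "pop_B": pop_b})


# ----------------------------------------------------------------- genotypes ----
def _hwe_draw(rng: np.random.Generator, freqs: np.ndarray, n: int) -> np.ndarray:
    """(n_markers, n) founder dosages at HWE for per-marker frequencies."""
    return rng.binomial(2, freqs[:, None], size=(freqs.size, n)).astype(np.int8)


def _gametes(rng: np.random.Generator, parent: np.ndarray) -> np.ndarray:
    """One transmitted allele per marker: hets transmit a fair coin."""
    out = (parent == 2).astype(np.int8)
    het = parent == 1
    if het.any():
        out[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
    return out


def simulate_pedigree_genotypes(
    freqs: pd.DataFrame, config: SimConfig, seed: int | np.random.Generator | None = None
) -> TruthSet:
    """Draw founder and progeny dosages; Mendel-consistent by construction.

    Wild founders are drawn at HWE from their population's frequencies;
    farm parents are founders of the second population (broodstock are
    sourced there); each progeny allele is drawn uniformly from the
    corresponding parent's two alleles, independently per marker.
    Marker metadata (tags, duplicates) is attached by
    :func:`simulate_dataset`; here ``markers`` and ``cluster_map`` are
    left empty.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = len(freqs)
    columns: dict[str, np.ndarray] = {}
    populations: dict[str, str] = {}

    for k in range(config.n_pop_A):
        name = f"EC{k + 1:04d}"
        populations[name] = "EastCoast"
    for k in range(config.n_pop_B):
        name = f"NT{k + 1:04d}"
        populations[name] = "NorthernTerritory"
    if config.n_pop_A:
        pa = _hwe_draw(rng, freqs["pop_A"].to_numpy(), config.n_pop_A)
        for j, name in enumerate(list(populations)[: config.n_pop_A]):
            columns[name] = pa[:, j]
    if config.n_pop_B:
        pb = _hwe_draw(rng, freqs["pop_B"].to_numpy(), config.n_pop_B)
        for j, name in enumerate(list(populations)[config.n_pop_A :]):
            columns[name] = pb[:, j]

    # farm parents: founders drawn from the pop-B gene pool
    parent_names: list[str] = []
    for sire, dam, _ in config.families:
        for pname in (sire, dam):
            if pname not in columns:
                columns[pname] = _hwe_draw(rng, freqs["pop_B"].to_numpy(), 1)[:, 0]
                parent_names.append(pname)

    pedigree: dict[str, tuple[str, str]] = {}
    for sire, dam, n_prog in config.families:
        if sire not in columns or dam not in columns:
            raise PedigreeError(f"family parents {sire!r}/{dam!r} are not founders")
        for k in range(n_prog):
            child = f"{sire}x{dam}_P{k + 1:03d}"
            columns[child] = _gametes(rng, columns[sire]) + _gametes(rng, columns[dam])
            pedigree[child] = (sire, dam)

    progeny = list(pedigree)
    if config.n_trio_records > len(progeny):
        raise ValueError(
            f"n_trio_records={config.n_trio_records} exceeds total progeny {len(progeny)}"
        )
    trios = [(c, *pedigree[c]) for c in progeny[: config.n_trio_records]]

    genotypes = pd.DataFrame(columns, copy=False)
    return TruthSet(
        true_genotypes=genotypes,
        pop_allele_freqs=freqs.copy(),
        pedigree=pedigree,
        cluster_map=pd.Series(dtype=object),
        markers=pd.DataFrame(),
        populations=pd.Series(populations, dtype=object),
        trios=trios,
    )


# --------------------------------------------------------------- read counts ----
def simulate_read_counts(
    genotypes: np.ndarray,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
    depth_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-call read counts and the observed call matrix.

    Total depth per call is negative-binomial with mean ``mean_depth``
    (optionally scaled per marker by ``depth_scale`` to mimic uneven
    RAD-tag amplification) and size ``depth_dispersion`` (variance
    ``mu + mu^2/size``), zero-inflated by ``missing_rate``.  Each read
    carries the wrong allele with probability ``allele_error_rate``.
    The observed call is derived from the counts: both alleles seen ->
    het, one -> that homozygote, none -> missing.
    """
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = np.asarray(genotypes, dtype=np.int8)
    k = config.depth_dispersion
    mu = np.full(g.shape[0], config.mean_depth)
    if depth_scale is not None:
        mu = mu * np.asarray(depth_scale, dtype=float)
    p_nb = k / (k + mu)
    total = rng.negative_binomial(k, p_nb[:, None], size=g.shape)
    if config.missing_rate > 0:
        total[rng.random(g.shape) < config.missing_rate] = 0
    e = config.allele_error_rate
    p_alt = np.choose(g, [e, 0.5, 1.0 - e])
    alt = rng.binomial(total, p_alt)
    ref = total - alt
    calls = np.full(g.shape, MISSING, dtype=np.int8)
    calls[(ref > 0) & (alt > 0)] = 1
    calls[(ref > 0) & (alt == 0)] = 0
    calls[(ref == 0) & (alt > 0)] = 2
    return ref.astype(np.int32), alt.astype(np.int32), calls


# ---------------------------------------------------------------- tag layout ----
def _random_tag(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, n_mut: int, avoid: set[int]) -> str:
    arr = np.array(list(seq))
    candidates = [i for i in range(len(seq)) if i not in avoid]
    pos = rng.choice(len(candidates), size=n_mut, replace=False)
    for p in pos:
        i = candidates[p]
        arr[i] = rng.choice(_BASES[_BASES != arr[i]])
    return "".join(arr)


def _build_tags(config: SimConfig, rng: np.random.Generator):
    """Lay SNPs out on RAD-tags; returns marker metadata + duplicate map.

    Base tags are generated until ``n_markers`` SNPs exist; then a
    fraction of tags is re-emitted as exact duplicates and another as
    near-duplicates (at most ``ceil(0.05 * tag_length) - 1`` mismatches,
    i.e. still within a 95 % identity cluster).  Duplicated tags share
    the true genotypes of their source markers; ``marker_source`` maps
    every emitted marker row to the truth row it mirrors.
    """
    ks = np.array(sorted(config.snps_per_tag_dist))
    ps = np.array([config.snps_per_tag_dist[k] for k in ks], dtype=float)
    ps = ps / ps.sum()

    rows = []  # (clone_id, snp_position, ref, alt, tag_sequence)
    source = []  # index into truth genotype rows
    cluster: dict[str, str] = {}
    tags: list[tuple[str, str, list[tuple[int, str, str]]]] = []
    n_snps = 0
    clone_no = 0
    while n_snps < config.n_markers:
        clone_no += 1
        clone_id = f"CLONE{clone_no:06d}"
        k = int(rng.choice(ks, p=ps))
        k = min(k, config.n_markers - n_snps)
        seq = _random_tag(rng, config.tag_length)
        positions = np.sort(rng.choice(config.tag_length, size=k, replace=False))
        snps = []
        for pos in positions:
            ref = seq[pos]
            alt = str(rng.choice(_BASES[_BASES != ref]))
            rows.append((clone_id, int(pos), ref, alt, seq))
            source.append(n_snps)
            snps.append((int(pos), ref, alt))
            n_snps += 1
        tags.append((clone_id, seq, snps))
        cluster[clone_id] = clone_id

    n_base = len(tags)
    max_mut = max(1, math.ceil(0.05 * config.tag_length) - 1)

    def add_copies(n_copies: int, mutate: bool, label: str):
        nonlocal clone_no
        if n_copies == 0:
            return
        chosen = rng.choice(n_base, size=n_copies, replace=False)
        for t in chosen:
            clone_id, seq, snps = tags[t]
            clone_no += 1
            new_id = f"CLONE{clone_no:06d}{label}"
            new_seq = seq
            if mutate:
                n_mut = int(rng.integers(1, max_mut + 1))
                new_seq = _mutate(rng, seq, n_mut, avoid={p for p, _, _ in snps})
            base_row = next(i for i, r in enumerate(rows) if r[0] == clone_id)
            for off, (pos, ref, alt) in enumerate(snps):
                rows.append((new_id, pos, ref, alt, new_seq))
                source.append(source[base_row + off])
            cluster[new_id] = clone_id

    add_copies(int(round(config.dup_tag_fraction * n_base)), mutate=False, label="D")
    add_copies(int(round(config.near_dup_tag_fraction * n_base)), mutate=True, label="N")

    markers = pd.DataFrame(
        rows, columns=["clone_id", "snp_position", "ref_allele", "alt_allele", "tag_sequence"]
    )
    markers["rep_avg"] = np.nan
    return markers, np.asarray(source), pd.Series(cluster, dtype=object)


# ------------------------------------------------------------------- dataset ----
def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, TruthSet]:
    """Full simulation: truth, tag layout, counts, replicates.

    Deterministic given the config (including its seed).  Technical
    replicates are re-passes of the same true genotypes through the
    read-count sampler with fresh noise, so replicate concordance below
    one is attainable.
    """
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_freq, rng_geno, rng_tags, rng_depth, rng_counts, rng_reps = (
        np.random.default_rng(s) for s in streams
    )

    freqs = simulate_allele_freqs(
        config.n_markers, config.fst, rng_freq, config.freq_interval
    )
    truth = simulate_pedigree_genotypes(freqs, config, rng_geno)
    markers, source, cluster_map = _build_tags(config, rng_tags)
    truth.markers = markers
    truth.cluster_map = cluster_map

    samples = list(truth.true_genotypes.columns)
    base_geno = truth.true_genotypes.to_numpy()[source]  # emitted markers x samples
    # uneven RAD-tag amplification: per-marker depth multiplier, mean 1
    depth_scale = None
    if config.marker_depth_shape is not None:
        a = config.marker_depth_shape
        depth_scale = rng_depth.gamma(a, 1.0 / a, size=len(source))
    ref, alt, calls = simulate_read_counts(base_geno, config, rng_counts, depth_scale)

    # technical replicates: duplicated samples, fresh sequencing noise
    n_rep = int(round(config.replicate_fraction * len(samples)))
    rep_groups: dict[str, str] = {}
    if n_rep:
        chosen = rng_reps.choice(len(samples), size=n_rep, replace=False)
        rep_cols_ref, rep_cols_alt, rep_cols_calls, rep_names = [], [], [], []
        for idx in chosen:
            orig = samples[idx]
            r2, a2, c2 = simulate_read_counts(
                base_geno[:, [idx]], config, rng_reps, depth_scale
            )
            rep_names.append(f"{orig}-rep")
            rep_cols_ref.append(r2[:, 0])
            rep_cols_alt.append(a2[:, 0])
            rep_cols_calls.append(c2[:, 0])
            rep_groups[orig] = orig
            rep_groups[f"{orig}-rep"] = orig
        ref = np.column_stack([ref] + rep_cols_ref)
        alt = np.column_stack([alt] + rep_cols_alt)
        calls = np.column_stack([calls] + rep_cols_calls)
        samples = samples + rep_names

    ds = GenotypeDataset(
        markers=markers,
        samples=samples,
        calls=calls,
        ref_counts=ref,
        alt_counts=alt,
        populations=truth.populations,
        trios=truth.trios,
        replicate_groups=pd.Series(rep_groups, dtype=object) if rep_groups else None,
    )
    return ds, truth


def emit_dataset(
    config: SimConfig, out_dir, prefix: str = "sim"
) -> tuple[GenotypeDataset, TruthSet, dict]:
    """Simulate and write the dataset plus truth sidecars to ``out_dir``."""
    ds, truth = simulate_dataset(config)
    try:
        paths = write_dataset(ds, out_dir, prefix=prefix)
        out = Path(out_dir)
        tg = out / f"{prefix}_truth_genotypes.tsv"
        truth.true_genotypes.to_csv(tg, sep="\t")
        tf = out / f"{prefix}_truth_freqs.tsv"
        truth.pop_allele_freqs.to_csv(tf, sep="\t", index=False)
        cm = out / f"{prefix}_cluster_map.tsv"
        truth.cluster_map.rename_axis("CloneID").rename("Group").to_frame().to_csv(
            cm, sep="\t"
        )
    except OSError as exc:
        raise OSError(f"failed writing simulated dataset under {out_dir}: {exc}") from exc
    paths.update({"truth_genotypes": tg, "truth_freqs": tf, "cluster_map": cm})
    return ds, truth, paths
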