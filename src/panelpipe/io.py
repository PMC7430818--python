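"""Read and write the canonical DArT-style table dialect.

The canonical dialect is the one-row SNP coding: genotype table cells are
``0`` hom-ref, ``1`` hom-alt, ``2`` het, ``-`` missing, with two separate
per-allele read-count matrices aligned on (CloneID, SnpPosition, sample).
Delimiters (tab or comma) are sniffed from the header line.  Tag
sequences travel both as a ``TagSequence`` column of the genotype table
and as a FASTA sidecar.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import MISSING, FormatError, GenotypeDataset

#: metadata columns of the genotype table, in canonical order
GENOTYPE_META_COLUMNS = [
    "CloneID",
    "SnpPosition",
    "RefAllele",
    "AltAllele",
    "TagSequence",
    "RepAvg",
]
COUNT_META_COLUMNS = ["CloneID", "SnpPosition"]

# file cell -> internal dosage (DArT one-row convention)
_CALL_DECODE = {"0": 0, "1": 2, "2": 1, "-": MISSING}
_CALL_ENCODE = {0: "0", 2: "1", 1: "2", MISSING: "-"}


def _sniff_sep(path: Path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    return pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)


def _sample_columns(df: pd.DataFrame, meta: list[str], path) -> list[str]:
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return [c for c in df.columns if c not in meta]


def read_dataset(
    genotype_path,
    ref_count_path=None,
    alt_count_path=None,
    *,
    populations_path=None,
    trios_path=None,
    replicates_path=None,
    silenced_path=None,
) -> GenotypeDataset:
    """Load a dataset from the canonical tables.

    The three matrices must declare identical sample columns in identical
    order; a mismatch raises :class:`FormatError` naming the offending
    column.
    """
    geno = _read_table(genotype_path)
    samples = _sample_columns(geno, GENOTYPE_META_COLUMNS, genotype_path)
    markers = pd.DataFrame(
        {
            "clone_id": geno["CloneID"].astype(str),
            "snp_position": geno["SnpPosition"].astype(int),
            "ref_allele": geno["RefAllele"].astype(str),
            "alt_allele": geno["AltAllele"].astype(str),
            "tag_sequence": geno["TagSequence"].astype(str),
            "rep_avg": pd.to_numeric(geno["RepAvg"].mask(geno["RepAvg"] == "")),
        }
    )
    calls = np.empty((len(geno), len(samples)), dtype=np.int8)
    for j, col in enumerate(samples):
        values = geno[col]
        try:
            calls[:, j] = [_CALL_DECODE[v] for v in values]
        except KeyError:
            for i, v in enumerate(values):
                if v not in _CALL_DECODE:
                    raise FormatError(
                        f"{genotype_path}: unknown genotype code {v!r} "
                        f"at row {i + 2}, column {col!r}"
                    ) from None
            raise

    ref_counts = alt_counts = None
    if (ref_count_path is None) != (alt_count_path is None):
        raise FormatError("ref and alt count tables must be provided together")
    if ref_count_path is not None:
        ref_counts = _read_counts(ref_count_path, samples, geno)
        alt_counts = _read_counts(alt_count_path, samples, geno)

    populations = None
    if populations_path is not None:
        pop = _read_table(populations_path)
        populations = pd.Series(
            pop["Population"].to_numpy(object), index=pop["Sample"].astype(str)
        )
    trios: list[tuple[str, str, str]] = []
    if trios_path is not None:
        tri = _read_table(trios_path)
        trios = list(zip(tri["Progeny"], tri["Sire"], tri["Dam"]))
    replicate_groups = None
    if replicates_path is not None:
        rep = _read_table(replicates_path)
        replicate_groups = pd.Series(
            rep["Group"].to_numpy(object), index=rep["Sample"].astype(str)
        )
    silenced = pd.DataFrame(columns=["marker_id", "sample", "reason"])
    if silenced_path is not None and Path(silenced_path).exists():
        sil = _read_table(silenced_path)
        silenced = sil.rename(
            columns={"MarkerID": "marker_id", "Sample": "sample", "Reason": "reason"}
        )[["marker_id", "sample", "reason"]]

    return GenotypeDataset(
        markers=markers,
        samples=samples,
        calls=calls,
        ref_counts=ref_counts,
        alt_counts=alt_counts,
        populations=populations,
        trios=trios,
        replicate_groups=replicate_groups,
        silenced=silenced,
    )


def _read_counts(path, samples: list[str], geno: pd.DataFrame) -> np.ndarray:
    df = _read_table(path)
    count_samples = _sample_columns(df, COUNT_META_COLUMNS, path)
    if count_samples != samples:
        offending = next(
            (a for a, b in zip(count_samples, samples) if a != b),
            count_samples[-1] if len(count_samples) > len(samples) else samples[-1],
        )
        raise FormatError(
            f"{path}: sample columns disagree with the genotype table "
            f"(first offending column: {offending!r})"
        )
    key_geno = list(zip(geno["CloneID"], geno["SnpPosition"].astype(str)))
    key_cnt = list(zip(df["CloneID"], df["SnpPosition"].astype(str)))
    if key_cnt != key_geno:
        raise FormatError(f"{path}: marker rows are not aligned with the genotype table")
    mat = df[samples].to_numpy(dtype=np.int64)
    if (mat < 0).any():
        raise FormatError(f"{path}: negative read counts")
    return mat.astype(np.int32)


# ------------------------------------------------------------------ write ----
def write_dataset(ds: GenotypeDataset, out_dir, prefix: str = "dataset") -> dict[str, Path]:
    """Write the canonical tables; lossless inverse of :func:`read_dataset`.

    Silenced-call provenance goes to a ``silenced_calls.tsv`` sidecar.
    Returns the mapping of logical name -> written path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    meta = pd.DataFrame(
        {
            "CloneID": ds.markers["clone_id"].to_numpy(),
            "SnpPosition": ds.markers["snp_position"].to_numpy(),
            "RefAllele": ds.markers["ref_allele"].to_numpy(),
            "AltAllele": ds.markers["alt_allele"].to_numpy(),
            "TagSequence": ds.markers["tag_sequence"].to_numpy(),
            "RepAvg": ds.markers["rep_avg"].to_numpy(),
        }
    )
    geno = meta.copy()
    encode = np.vectorize(_CALL_ENCODE.get, otypes=[object])
    geno[ds.samples] = pd.DataFrame(encode(ds.calls), columns=ds.samples)
    paths["genotypes"] = out / f"{prefix}_genotypes.tsv"
    geno.to_csv(paths["genotypes"], sep="\t", index=False)

    if ds.ref_counts is not None and ds.alt_counts is not None:
        for name, mat in (("ref_counts", ds.ref_counts), ("alt_counts", ds.alt_counts)):
            df = meta[COUNT_META_COLUMNS].copy()
            df[ds.samples] = pd.DataFrame(mat, columns=ds.samples)
            paths[name] = out / f"{prefix}_{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)

    paths["tags_fasta"] = out / f"{prefix}_tags.fasta"
    records = []
    seen: set[str] = set()
    for mid, row in ds.markers.iterrows():
        if row["clone_id"] in seen:
            continue
        seen.add(row["clone_id"])
        records.append(
            SeqRecord(Seq(row["tag_sequence"]), id=str(row["clone_id"]), description="")
        )
    SeqIO.write(records, paths["tags_fasta"], "fasta")

    if ds.populations is not None:
        paths["populations"] = out / f"{prefix}_populations.tsv"
        pd.DataFrame(
            {"Sample": ds.populations.index, "Population": ds.populations.to_numpy()}
        ).to_csv(paths["populations"], sep="\t", index=False)
    if ds.trios:
        paths["trios"] = out / f"{prefix}_trios.tsv"
        pd.DataFrame(ds.trios, columns=["Progeny", "Sire", "Dam"]).to_csv(
            paths["trios"], sep="\t", index=False
        )
    if ds.replicate_groups is not None:
        paths["replicates"] = out / f"{prefix}_replicates.tsv"
        pd.DataFrame(
            {"Sample": ds.replicate_groups.index, "Group": ds.replicate_groups.to_numpy()}
        ).to_csv(paths["replicates"], sep="\t", index=False)
    if len(ds.silenced):
        paths["silenced"] = out / f"{prefix}_silenced_calls.tsv"
        ds.silenced.rename(
            columns={"marker_id": "MarkerID", "sample": "Sample", "reason": "Reason"}
        ).to_csv(paths["silenced"], sep="\t", index=False)
    return paths


def read_dataset_dir(out_dir, prefix: str = "dataset") -> GenotypeDataset:
    """Re-load a dataset written by :func:`write_dataset`."""
    out = Path(out_dir)

    def opt(name):
        p = out / f"{prefix}_{name}.tsv"
        return p if p.exists() else None

    ref = opt("ref_counts")
    return read_dataset(
        out / f"{prefix}_genotypes.tsv",
        ref,
        opt("alt_counts") if ref is not None else None,
        populations_path=opt("populations"),
        trios_path=opt("trios"),
        replicates_path=opt("replicates"),
        silenced_path=opt("silenced_calls"),
    )


# ------------------------------------------------------------------ PLINK ----
def export_plink(ds: GenotypeDataset, out_prefix) -> tuple[Path, Path]:
    """Write classic PLINK PED/MAP text files.

    No genome coordinates exist for these markers, so the MAP file uses
    chromosome 0 with dummy positions in input order.  Missing calls
    become the ``0 0`` allele pair.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = out_prefix.with_suffix(".ped")
    map_path = out_prefix.with_suffix(".map")

    ref = ds.markers["ref_allele"].to_numpy()
    alt = ds.markers["alt_allele"].to_numpy()
    with open(ped_path, "w") as fh:
        for j, sample in enumerate(ds.samples):
            fam = "0"
            if ds.populations is not None and sample in ds.populations.index:
                fam = str(ds.populations[sample]).replace(" ", "_")
            fields = [fam, sample, "0", "0", "0", "-9"]
            col = ds.calls[:, j]
            for i in range(ds.n_markers):
                c = col[i]
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [ref[i], ref[i]]
                elif c == 2:
                    fields += [alt[i], alt[i]]
                else:
                    fields += [ref[i], alt[i]]
            fh.write(" ".join(fields) + "\n")
    with open(map_path, "w") as fh:
        for i, mid in enumerate(ds.marker_ids):
            fh.write(f"0 {mid} 0 {i + 1}\n")
    return ped_path, map_path


# ------------------------------------------------------------------ FASTA ----
def export_panel_fasta(ds: GenotypeDataset, selected_ids, path) -> Path:
    """FASTA of tag sequences for the selected markers, order preserved.

    Headers are ``clone_id:snp_position:ref>alt`` so a probe-design
    provider can locate the SNP within each tag.
    """
    path = Path(path)
    records = []
    for mid in selected_ids:
        if mid not in ds.marker_ids:
            raise KeyError(f"unknown marker id {mid!r}")
        row = ds.markers.loc[mid]
        header = (
            f"{row['clone_id']}:{row['snp_position']}:"
            f"{row['ref_allele']}>{row['alt_allele']}"
        )
        records.append(SeqRecord(Seq(row["tag_sequence"]), id=header, description=""))
    path.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, path, "fasta")
    return path
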