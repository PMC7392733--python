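"""Insertion-site tables and the deterministic pre-statistics pipeline.

The quantitative insertion-site sequencing (QI-seq) workflow yields one row
per mapped junction read.  Before any statistics are computed those reads are
(1) collapsed to unique insertion sites (IS) with read counts, (2) optionally
unified across the 5' and 3' transposon-end libraries, (3) trimmed to each
sample's most strongly supported sites, and (4) pooled across samples into the
non-redundant set that the CIS caller consumes.  Every step here is
deterministic; randomness enters only in the Monte-Carlo null of
:mod:`pbscreen.gkc`.

An insertion-site table is a plain :class:`pandas.DataFrame` with columns
``sample_id, tumor_id, region_id, tissue, chrom, pos, orientation,
transposon_end, read_count``.  ``pos`` is the 1-based coordinate of the first
base of the TTAA target site.
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import InputError, MetadataError, ParameterError

INSERTION_COLUMNS = [
    "sample_id", "tumor_id", "region_id", "tissue", "chrom", "pos",
    "orientation", "transposon_end", "read_count",
]

#: key that defines a unique insertion site within a sample
IS_KEY = ["sample_id", "chrom", "pos", "orientation", "transposon_end"]

_META_COLUMNS = ["tumor_id", "region_id", "tissue"]

SAMPLE_COLUMNS = ["sample_id", "mouse_id", "tissue", "region_id", "n_regions"]


def _ensure_meta(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in _META_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    return out


def read_insertions(path: str | os.PathLike) -> pd.DataFrame:
    """Read an insertion TSV (tab-separated, header row)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str,
                                            "tumor_id": str, "region_id": str},
                     keep_default_na=False)
    missing = [c for c in ("sample_id", "chrom", "pos") if c not in df.columns]
    if missing:
        raise InputError(f"insertion table missing columns: {missing}")
    df = _ensure_meta(df)
    if "read_count" not in df.columns:
        df["read_count"] = 1
    df["pos"] = df["pos"].astype(np.int64)
    df["read_count"] = df["read_count"].astype(np.int64)
    return df


def write_insertions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in INSERTION_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def collapse_reads(read_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse mapped reads to unique insertion sites.

    Reads mapping to the same genomic location (same sample, chromosome,
    position, orientation and transposon end) count as a single IS whose
    ``read_count`` is the number of contributing reads.  If the input already
    carries a ``read_count`` column, counts are summed instead, which makes
    the operation idempotent on its own output.

    Returns a table sorted by ``(sample_id, chrom, pos)``.
    """
    df = read_records
    if df.shape[0] == 0:
        return _ensure_meta(pd.DataFrame(columns=[c for c in INSERTION_COLUMNS]))
    for col in IS_KEY:
        if col not in df.columns:
            raise InputError(f"missing key field {col!r}")
        null = df[col].isna()
        if null.any():
            raise InputError(
                f"missing value in key field {col!r} at row {int(np.flatnonzero(null)[0])}"
            )
    df = _ensure_meta(df)
    if "read_count" not in df.columns:
        df = df.assign(read_count=1)
    if (df["read_count"] < 1).any():
        raise InputError("read_count must be >= 1")
    if (df["pos"] < 1).any():
        raise InputError("pos must be >= 1")
    agg = {"read_count": "sum"}
    agg.update({c: "first" for c in _META_COLUMNS})
    out = (df.groupby(IS_KEY, as_index=False, sort=False).agg(agg))
    out = out.sort_values(["sample_id", "chrom", "pos"], kind="mergesort",
                          ignore_index=True)
    return out[[c for c in INSERTION_COLUMNS]]


def merge_ends(sites: pd.DataFrame, tolerance_bp: int = 10) -> pd.DataFrame:
    """Unify 5' and 3' transposon-end records of the same insertion.

    The two junction libraries are sequenced separately, so a single
    integration can appear once per end.  Within each (sample, chromosome,
    orientation) group, 5' and 3' records whose positions differ by at most
    ``tolerance_bp`` are paired greedily in position order and replaced by one
    record at the 5' position with summed read count and
    ``transposon_end == "merged"``.  Unpaired records pass through unchanged.
    """
    if tolerance_bp < 0:
        raise ParameterError("tolerance_bp must be >= 0")
    if sites.shape[0] == 0:
        return sites.copy()
    df = sites.sort_values(["sample_id", "chrom", "pos"], kind="mergesort",
                           ignore_index=True)
    passthrough = df[~df["transposon_end"].isin(["5p", "3p"])]
    paired_rows = []
    keep_idx: list[int] = list(passthrough.index)
    ends = df[df["transposon_end"].isin(["5p", "3p"])]
    for _, grp in ends.groupby(["sample_id", "chrom", "orientation"], sort=False):
        fives = grp[grp["transposon_end"] == "5p"]
        threes = grp[grp["transposon_end"] == "3p"]
        i = j = 0
        fi, ti = list(fives.index), list(threes.index)
        fp, tp = fives["pos"].to_numpy(), threes["pos"].to_numpy()
        while i < len(fi) and j < len(ti):
            d = tp[j] - fp[i]
            if abs(d) <= tolerance_bp:
                row = df.loc[fi[i]].copy()
                row["read_count"] = int(df.loc[fi[i], "read_count"]
                                        + df.loc[ti[j], "read_count"])
                row["transposon_end"] = "merged"
                paired_rows.append(row)
                i += 1
                j += 1
            elif tp[j] < fp[i]:
                keep_idx.append(ti[j])
                j += 1
            else:
                keep_idx.append(fi[i])
                i += 1
        keep_idx.extend(fi[i:])
        keep_idx.extend(ti[j:])
    out = pd.concat([df.loc[sorted(keep_idx)],
                     pd.DataFrame(paired_rows)], ignore_index=True)
    return out.sort_values(["sample_id", "chrom", "pos"], kind="mergesort",
                           ignore_index=True)


def top_n_filter(sites: pd.DataFrame, n: int = 300) -> pd.DataFrame:
    """Keep each sample's top ``n`` insertion sites by read count.

    Ties at the boundary are broken deterministically by (chrom lexicographic,
    pos ascending).  Every retained read count is >= every dropped read count
    within the sample.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    if sites.shape[0] == 0:
        return sites.copy()
    ordered = sites.sort_values(
        ["sample_id", "read_count", "chrom", "pos"],
        ascending=[True, False, True, True], kind="mergesort")
    out = ordered.groupby("sample_id", sort=False).head(n)
    return out.sort_values(["sample_id", "chrom", "pos"], kind="mergesort",
                           ignore_index=True)


def pool_nonredundant(sites: pd.DataFrame, collapse: str = "within-sample") -> pd.DataFrame:
    """Pool per-sample insertion tables into the non-redundant CIS input set.

    ``collapse="within-sample"`` (default) collapses duplicate (chrom, pos)
    rows within each sample (summing read counts) but keeps one record per
    sample at a shared position, so cross-sample recurrence remains visible to
    the CIS caller.  ``collapse="across-samples"`` collapses identical
    positions genome-wide to a single record.  Either way each output row is
    annotated with its contributing sample ids in a ``samples`` column.

    Raises
    ------
    MetadataError
        If one sample_id carries two different tissue labels.
    """
    if collapse not in ("within-sample", "across-samples"):
        raise ParameterError(f"unknown collapse mode {collapse!r}")
    if sites.shape[0] == 0:
        out = sites.copy()
        out["samples"] = pd.Series(dtype=str)
        return out
    df = _ensure_meta(sites)
    tissues = df.groupby("sample_id")["tissue"].nunique()
    if (tissues > 1).any():
        bad = tissues[tissues > 1].index[0]
        raise MetadataError(f"conflicting tissue labels for sample {bad!r}")
    agg = {"read_count": "sum", "orientation": "first", "transposon_end": "first"}
    agg.update({c: "first" for c in _META_COLUMNS})
    pooled = (df.sort_values(["sample_id", "chrom", "pos"], kind="mergesort")
                .groupby(["sample_id", "chrom", "pos"], as_index=False, sort=False)
                .agg(agg))
    pooled["samples"] = pooled["sample_id"]
    if collapse == "across-samples":
        agg2 = {"read_count": "sum", "orientation": "first",
                "transposon_end": "first", "tumor_id": "first",
                "region_id": "first", "tissue": "first",
                "sample_id": "first",
                "samples": lambda s: ",".join(sorted(s))}
        pooled = (pooled.groupby(["chrom", "pos"], as_index=False, sort=False)
                        .agg(agg2))
    return pooled.sort_values(["sample_id", "chrom", "pos"], kind="mergesort",
                              ignore_index=True)


def to_bed(sites: pd.DataFrame, path: str | os.PathLike | None = None) -> pd.DataFrame:
    """Export insertion sites as BED6.

    Internal coordinates are 1-based at the TTAA start; BED intervals are the
    0-based half-open 4-bp target site ``[pos-1, pos+3)``.  Name encodes
    ``sample_id:read_count``; score is the read count; strand the transposon
    orientation.
    """
    bed = pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["pos"] - 1,
        "end": sites["pos"] + 3,
        "name": sites["sample_id"].astype(str) + ":" + sites["read_count"].astype(str),
        "score": sites["read_count"],
        "strand": sites["orientation"],
    })
    if path is not None:
        bed.to_csv(path, sep="\t", header=False, index=False)
    return bed


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Import a BED6 export back into an insertion table.

    Only the exported fields (sample, chrom, pos, orientation, read_count)
    round-trip; cohort metadata columns come back empty.
    """
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str, "name": str})
    sample = bed["name"].str.rsplit(":", n=1).str[0]
    df = pd.DataFrame({
        "sample_id": sample,
        "chrom": bed["chrom"],
        "pos": bed["start"].astype(np.int64) + 1,
        "orientation": bed["strand"],
        "read_count": bed["score"].astype(np.int64),
    })
    return _ensure_meta(df)


def read_samples(path: str | os.PathLike) -> pd.DataFrame:
    """Read a sample-metadata TSV (sample_id, mouse_id, tissue, region_id, n_regions)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    if (df.get("n_regions", pd.Series(dtype=int)) < 1).any():
        raise InputError("n_regions must be >= 1")
    return df
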