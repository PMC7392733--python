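"""Multi-region clonality of transposon insertions.

Lineage relationships between regions of one tumor can be read off shared
insertions: an insertion present (with adequate read support) in every
sampled region is clonal (an early, selected event), one present in a strict
subset of regions but more than one is shared-subclonal, and one seen in a
single region is private.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError

CALL_COLUMNS = ["chrom", "pos", "orientation", "gene", "regions_present",
                "n_regions_present", "n_regions_total", "label"]


@dataclass
class ClonalityParams:
    """``min_reads`` is applied per region: an insertion "exists" in a region
    only when supported by at least that many reads there.  TTAA quantization
    makes coordinates discrete, so the default exact-position matching
    (``match_tolerance_bp = 0``) is safe on clean data."""

    min_reads: int = 2
    match_tolerance_bp: int = 0

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ParameterError("min_reads must be >= 1")
        if self.match_tolerance_bp < 0:
            raise ParameterError("match_tolerance_bp must be >= 0")


def _label(n_present: int, n_total: int) -> str:
    if n_present == n_total:
        return "clonal"
    if n_present == 1:
        return "private"
    return "shared_subclonal"


def match_insertions(regions: Mapping[str, pd.DataFrame],
                     params: ClonalityParams | None = None,
                     cis_genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Match insertions across the regions of one tumor and label clonality.

    ``regions`` maps region_id to that region's collapsed insertion table.
    Insertions below ``min_reads`` in a region are treated as absent from it;
    surviving insertions match across regions when they share chromosome and
    orientation and their positions differ by at most ``match_tolerance_bp``.
    When ``cis_genes`` (a gene table with chrom/start/end/name) is given, only
    insertions inside those genes are analyzed and each call is annotated with
    its gene.
    """
    params = params or ClonalityParams()
    if len(regions) < 2:
        raise ParameterError("clonality analysis needs at least two regions")
    n_total = len(regions)
    pieces = []
    for region_id in sorted(regions):
        df = regions[region_id]
        df = df[df["read_count"] >= params.min_reads]
        if cis_genes is not None and len(df):
            gene = pd.Series("", index=df.index, dtype=object)
            keep = np.zeros(len(df), dtype=bool)
            for g in cis_genes.itertuples(index=False):
                m = ((df["chrom"] == g.chrom) & (df["pos"] >= g.start)
                     & (df["pos"] <= g.end)).to_numpy()
                keep |= m
                gene[m] = g.name
            df = df.assign(gene=gene)[keep]
        elif cis_genes is not None:
            df = df.assign(gene="")
        else:
            df = df.assign(gene="")
        pieces.append(df.assign(_region=region_id))
    allr = pd.concat(pieces, ignore_index=True)
    if len(allr) == 0:
        return pd.DataFrame(columns=CALL_COLUMNS)
    rows = []
    for (chrom, orient), grp in allr.groupby(["chrom", "orientation"], sort=True):
        grp = grp.sort_values("pos", kind="mergesort")
        pos = grp["pos"].to_numpy()
        new = np.ones(len(grp), dtype=bool)
        new[1:] = np.diff(pos) > params.match_tolerance_bp
        for _, cl in grp.groupby(np.cumsum(new), sort=True):
            present = sorted(cl["_region"].unique())
            rows.append({
                "chrom": chrom,
                "pos": int(cl["pos"].iloc[0]),
                "orientation": orient,
                "gene": cl["gene"].iloc[0],
                "regions_present": ",".join(present),
                "n_regions_present": len(present),
                "n_regions_total": n_total,
                "label": _label(len(present), n_total),
            })
    return (pd.DataFrame(rows, columns=CALL_COLUMNS)
            .sort_values(["chrom", "pos"], kind="mergesort", ignore_index=True))


def summarize_clonality(calls: pd.DataFrame,
                        cis_genes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per-gene clonality roll-up: counts per label and the modal label.

    Ties in the modal label break toward the less clonal interpretation
    (private, then shared_subclonal, then clonal).
    """
    if len(calls) == 0:
        return pd.DataFrame(columns=["gene", "n_clonal", "n_shared_subclonal",
                                     "n_private", "modal_label"])
    order = ["private", "shared_subclonal", "clonal"]
    rows = []
    for gene, grp in calls.groupby("gene", sort=True):
        counts = {f"n_{lab}": int((grp["label"] == lab).sum())
                  for lab in ("clonal", "shared_subclonal", "private")}
        modal = max(order, key=lambda lab: (counts[f"n_{lab}"], -order.index(lab)))
        rows.append({"gene": gene, **counts, "modal_label": modal})
    return pd.DataFrame(rows, columns=["gene", "n_clonal", "n_shared_subclonal",
                                       "n_private", "modal_label"])
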