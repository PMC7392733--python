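"""CIS-gene association, ranked CIS-gene tables and insertion-pattern calls.

A transposon carrying a promoter/splice-donor unit activates a gene when it
lands sense-oriented near the 5' end, while its gene-trap cassette (two splice
acceptors and bidirectional polyA) truncates the transcript from anywhere in
the gene body in either orientation.  This module turns significant CIS into
per-gene roll-ups (insertion counts, tumor recurrence) and calls each gene's
insertion pattern as activating or inactivating from orientation bias and
position within the gene.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

#: default upstream window (bp) in which an insertion is still
#: activation-compatible with the downstream gene
UPSTREAM_WINDOW = 10_000


@dataclass
class PatternCall:
    """Orientation/position summary of a gene's insertions.

    ``median_relative_position`` is in gene-body coordinates (0 =
    transcription start, 1 = transcription end, negative = upstream),
    computed strand-aware.
    """

    label: str                      # activating | inactivating | ambiguous
    sense_fraction: float
    orientation_binomial_p: float
    median_relative_position: float
    n: int


def associate_genes(cis: pd.DataFrame, genes: pd.DataFrame,
                    max_distance: int = 0) -> pd.DataFrame:
    """Associate each CIS with the gene(s) it plausibly affects.

    The CIS interval is extended by its best kernel width h on each side
    (kernel support extends beyond the member-insertion span) and every gene
    body overlapping the extended interval is reported, ordered by distance of
    the CIS apex to the gene midpoint, flagged ``overlap``.  If nothing
    overlaps and ``max_distance > 0``, the nearest gene within that distance
    is reported flagged ``nearest``.  CIS without association are absent from
    the output.
    """
    rows = []
    for c in cis.itertuples(index=False):
        ext = int(getattr(c, "best_scale", 0))
        lo, hi = int(c.start) - ext, int(c.end) + ext
        on_chrom = genes[genes["chrom"] == c.chrom]
        overlap = on_chrom[(on_chrom["end"] >= lo) & (on_chrom["start"] <= hi)]
        if len(overlap):
            mid = (overlap["start"] + overlap["end"]) / 2.0
            dist = (mid - int(c.apex_pos)).abs()
            for gi in dist.sort_values(kind="mergesort").index:
                g = overlap.loc[gi]
                rows.append((c.cis_id, g["gene_id"], g["name"], "overlap",
                             float(dist.loc[gi])))
        elif max_distance > 0:
            gap = pd.concat([on_chrom["start"] - hi, lo - on_chrom["end"]],
                            axis=1).max(axis=1).clip(lower=0)
            near = gap[gap <= max_distance]
            if len(near):
                gi = near.sort_values(kind="mergesort").index[0]
                g = on_chrom.loc[gi]
                rows.append((c.cis_id, g["gene_id"], g["name"], "nearest",
                             float(near.loc[gi])))
    return pd.DataFrame(rows, columns=["cis_id", "gene_id", "name", "flag",
                                       "distance"])


def gene_insertions(insertions: pd.DataFrame, gene: Mapping,
                    upstream: int = UPSTREAM_WINDOW) -> pd.DataFrame:
    """Insertions attributable to a gene: its body plus the strand-aware
    upstream activation window."""
    if gene["strand"] == "+":
        lo, hi = gene["start"] - upstream, gene["end"]
    else:
        lo, hi = gene["start"], gene["end"] + upstream
    m = ((insertions["chrom"] == gene["chrom"])
         & (insertions["pos"] >= lo) & (insertions["pos"] <= hi))
    return insertions[m]


def relative_positions(gene: Mapping, positions: np.ndarray) -> np.ndarray:
    """Strand-aware gene-body coordinates: 0 at TSS, 1 at transcription end."""
    length = max(1, int(gene["end"]) - int(gene["start"]))
    pos = np.asarray(positions, dtype=np.float64)
    if gene["strand"] == "+":
        return (pos - gene["start"]) / length
    return (gene["end"] - pos) / length


def classify_pattern(gene: Mapping, member_insertions: pd.DataFrame,
                     min_insertions: int = 3, sense_threshold: float = 0.8,
                     position_threshold: float = 0.2,
                     binom_alpha: float = 0.05) -> PatternCall:
    """Call a gene's insertion pattern as activating, inactivating or ambiguous.

    Activating requires n >= ``min_insertions`` insertions, a sense fraction
    >= ``sense_threshold`` confirmed by a one-sided exact binomial test
    against 0.5, and a median relative position <= ``position_threshold``
    (upstream insertions count as 5').  Inactivating requires the insertions
    to lie in the gene body (majority rule) without the activating signature.
    Anything else -- including every gene with fewer than ``min_insertions``
    insertions -- is ambiguous.
    """
    bad = member_insertions[member_insertions["chrom"] != gene["chrom"]]
    if len(bad):
        raise InputError(
            f"insertions on {bad['chrom'].iloc[0]} cannot belong to gene "
            f"{gene.get('name', gene.get('gene_id'))} on {gene['chrom']}")
    n = int(len(member_insertions))
    if n == 0:
        return PatternCall("ambiguous", 0.0, 1.0, float("nan"), 0)
    rel = relative_positions(gene, member_insertions["pos"].to_numpy())
    sense = (member_insertions["orientation"] == gene["strand"]).to_numpy()
    k = int(sense.sum())
    sense_fraction = k / n
    binom_p = float(stats.binomtest(k, n, 0.5, alternative="greater").pvalue)
    med = float(np.median(rel))
    if n < min_insertions:
        return PatternCall("ambiguous", sense_fraction, binom_p, med, n)
    activating = (sense_fraction >= sense_threshold and binom_p < binom_alpha
                  and med <= position_threshold)
    if activating:
        return PatternCall("activating", sense_fraction, binom_p, med, n)
    in_body = (rel >= 0.0) & (rel <= 1.0)
    if in_body.sum() * 2 > n:
        return PatternCall("inactivating", sense_fraction, binom_p, med, n)
    return PatternCall("ambiguous", sense_fraction, binom_p, med, n)


def build_cis_gene_table(cis: pd.DataFrame, insertions: pd.DataFrame,
                         genes: pd.DataFrame, max_distance: int = 0,
                         upstream: int = UPSTREAM_WINDOW) -> pd.DataFrame:
    """Per-gene roll-up over all associated CIS.

    For every gene associated with at least one CIS: total insertions in the
    gene (body + upstream activation window) across the pooled table, number
    of distinct tumors hit, per-tissue insertion counts, and the insertion
    pattern call.
    """
    assoc = associate_genes(cis, genes, max_distance=max_distance)
    if len(assoc) == 0:
        cols = ["gene_id", "name", "cis_ids", "total_insertions", "n_tumors",
                "pattern", "sense_fraction", "median_relative_position",
                "brain_insertions", "spinal_insertions"]
        return pd.DataFrame(columns=cols)
    tumor_col = "tumor_id" if ("tumor_id" in insertions.columns
                               and insertions["tumor_id"].astype(str).str.len().gt(0).any()) \
        else "sample_id"
    tissues = sorted(set(insertions.get("tissue", pd.Series(dtype=str)).unique())
                     | {"brain", "spinal"})
    rows = []
    for gene_id, grp in assoc.groupby("gene_id", sort=True):
        gene = genes[genes["gene_id"] == gene_id].iloc[0]
        ins = gene_insertions(insertions, gene, upstream=upstream)
        call = classify_pattern(gene, ins)
        rec = {
            "gene_id": gene_id,
            "name": gene["name"],
            "cis_ids": ",".join(sorted(grp["cis_id"].unique())),
            "total_insertions": int(len(ins)),
            "n_tumors": int(ins[tumor_col].nunique()) if len(ins) else 0,
            "pattern": call.label,
            "sense_fraction": call.sense_fraction,
            "median_relative_position": call.median_relative_position,
        }
        for t in tissues:
            rec[f"{t}_insertions"] = int((ins.get("tissue") == t).sum()) if len(ins) else 0
        rows.append(rec)
    return pd.DataFrame(rows)


def rank_cis_genes(cis_genes: pd.DataFrame, cohort: Mapping[str, int]) -> pd.DataFrame:
    """Rank the CIS-gene table by total insertions across all tumors.

    Descending by ``total_insertions``; ties broken by ``n_tumors`` then gene
    name.  ``pct_tumors`` is computed against the full cohort size (the sum of
    the per-tissue tumor counts).
    """
    n_cohort = int(sum(cohort.values()))
    if n_cohort <= 0:
        raise ParameterError("cohort size must be positive")
    out = cis_genes.sort_values(["total_insertions", "n_tumors", "name"],
                                ascending=[False, False, True], kind="mergesort",
                                ignore_index=True)
    out["pct_tumors"] = 100.0 * out["n_tumors"] / n_cohort
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
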