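"""Gene-transposon fusion transcripts and their overlap with CIS genes.

The transposon cargo leaves a characteristic footprint in RNA-seq: fusions
through its promoter/splice-donor (SD) drive the downstream gene (sense
orientation only), while fusions into either splice acceptor (the
carp-beta-actin acceptor CbASA in sense, the Engrailed-2 exon-2 acceptor
En2SA in antisense) terminate the host transcript.  This module classifies
fusion records by those semantics and tests whether fusion-supported genes
are enriched among CIS genes.
"""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Collection

import pandas as pd
from scipy import stats

from .errors import DataConsistencyError, InputError, ParameterError

FUSION_COLUMNS = ["sample_id", "gene", "feature", "orientation",
                  "junction_reads", "spanning_fragments"]

FEATURES = ("SD", "CbASA", "En2SA")


@dataclass
class EnrichmentResult:
    n_cis_with_fusion: int
    n_cis: int
    n_fusion_genes: int
    universe_size: int
    odds_ratio: float
    p_two_sided: float


def classify_fusion(feature: str, orientation: str) -> str:
    """Effect of one fusion transcript: ``activating`` or ``truncating``.

    SD fusions are activating and only consistent with sense orientation;
    splice-acceptor fusions (CbASA, En2SA) truncate the transcript in either
    orientation.

    Raises
    ------
    DataConsistencyError
        For an SD fusion reported antisense (the splice donor cannot join the
        downstream exon in that orientation).
    """
    if feature not in FEATURES:
        raise InputError(f"unknown transposon feature {feature!r}")
    if orientation not in ("sense", "antisense"):
        raise InputError(f"unknown orientation {orientation!r}")
    if feature == "SD":
        if orientation != "sense":
            raise DataConsistencyError(
                "SD fusion reported in antisense orientation; the splice donor "
                "can only drive transcription in sense")
        return "activating"
    return "truncating"


def classify_fusion_table(fusions: pd.DataFrame) -> pd.DataFrame:
    """Add an ``effect`` column to a fusion table, validating each record."""
    effects = []
    for i, rec in enumerate(fusions.itertuples(index=False)):
        if rec.junction_reads + rec.spanning_fragments < 1:
            raise InputError(f"fusion record {i} has no supporting evidence")
        try:
            effects.append(classify_fusion(rec.feature, rec.orientation))
        except DataConsistencyError as err:
            raise DataConsistencyError(
                f"record {i} ({rec.sample_id}, {rec.gene}): {err}") from None
    out = fusions.copy()
    out["effect"] = effects
    return out


def overlap_enrichment(cis_genes: Collection[str], fusion_genes: Collection[str],
                       universe: Collection[str]) -> EnrichmentResult:
    """Two-sided Fisher's exact test of CIS/fusion gene-set overlap.

    2x2 table over the gene universe: ``[[overlap, cis-only],
    [fusion-only, neither]]``.
    """
    uni = set(universe)
    if not uni:
        raise ParameterError("gene universe must be non-empty")
    cis = set(cis_genes)
    fus = set(fusion_genes)
    stray = (cis | fus) - uni
    if stray:
        raise InputError(f"genes outside the universe: {sorted(stray)[:5]}")
    both = len(cis & fus)
    cis_only = len(cis - fus)
    fus_only = len(fus - cis)
    neither = len(uni) - both - cis_only - fus_only
    table = [[both, cis_only], [fus_only, neither]]
    orr, p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(both, len(cis), len(fus), len(uni),
                            float(orr), float(p))


def read_fusions(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"fusion table missing columns: {missing}")
    return df


def write_fusions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=FUSION_COLUMNS)
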