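"""Brain-vs-spinal cohort comparison of CIS genes.

Two questions: which CIS genes are shared between the tumor types (at least
one insertion in each) versus tissue-specific, and for shared genes whether
the insertion frequency differs between cohorts (two-sided Fisher's exact
test on insertions vs tumors-without, per tissue).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

KNOWN_TISSUES = ("brain", "spinal")


@dataclass
class VennSummary:
    shared_genes: list = field(default_factory=list)
    brain_specific: list = field(default_factory=list)
    spinal_specific: list = field(default_factory=list)

    @property
    def n_shared(self) -> int:
        return len(self.shared_genes)

    @property
    def n_brain_specific(self) -> int:
        return len(self.brain_specific)

    @property
    def n_spinal_specific(self) -> int:
        return len(self.spinal_specific)


@dataclass
class GeneCohortTest:
    gene: str
    count_brain: int
    count_spinal: int
    n_brain: int
    n_spinal: int
    odds_ratio: float
    p_two_sided: float


def shared_specific(cis_genes: pd.DataFrame,
                    tissues: tuple[str, str] = KNOWN_TISSUES) -> VennSummary:
    """Partition CIS genes into shared and tissue-specific sets.

    Expects per-tissue insertion-count columns (``brain_insertions``,
    ``spinal_insertions``) as produced by
    :func:`pbscreen.annotate.build_cis_gene_table`.  A gene is shared when it
    has at least one insertion in each tumor type, tissue-specific when all of
    its insertions come from one tissue.
    """
    t1, t2 = tissues
    c1, c2 = f"{t1}_insertions", f"{t2}_insertions"
    for c in (c1, c2):
        if c not in cis_genes.columns:
            raise InputError(f"missing per-tissue count column {c!r}")
    extra = [c for c in cis_genes.columns
             if c.endswith("_insertions")
             and c not in (c1, c2, "total_insertions")]
    for c in extra:
        bad = cis_genes[cis_genes[c] > 0]
        if len(bad):
            raise InputError(
                f"unknown tissue label {c.removesuffix('_insertions')!r} with "
                f"insertions in gene {bad['name'].iloc[0]!r}")
    out = VennSummary()
    for g in cis_genes.itertuples(index=False):
        a, b = getattr(g, c1), getattr(g, c2)
        if a > 0 and b > 0:
            out.shared_genes.append(g.name)
        elif a > 0:
            out.brain_specific.append(g.name)
        elif b > 0:
            out.spinal_specific.append(g.name)
    return out


def per_gene_fisher(gene: str, count_brain: int, count_spinal: int,
                    n_brain: int, n_spinal: int) -> GeneCohortTest:
    """Two-sided Fisher's exact test of per-tissue insertion frequency.

    The 2x2 table is ``[[count_brain, n_brain - count_brain],
    [count_spinal, n_spinal - count_spinal]]`` -- insertion counts normalized
    for the number of tumors analyzed per tissue.  Two-sided by the
    point-probability rule (sum over tables at most as probable as observed);
    the odds ratio is the conditional maximum-likelihood estimate.  Counts
    exceeding the cohort size are clamped with a warning (insertion counts are
    treated as tumor-level events).
    """
    if n_brain <= 0 or n_spinal <= 0:
        raise ParameterError("cohort sizes must be positive")
    cb, cs = int(count_brain), int(count_spinal)
    if cb > n_brain or cs > n_spinal:
        warnings.warn("insertion count exceeds cohort size; clamping for the "
                      "2x2 construction", stacklevel=2)
        cb, cs = min(cb, n_brain), min(cs, n_spinal)
    table = [[cb, n_brain - cb], [cs, n_spinal - cs]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    orr = float(stats.contingency.odds_ratio(table, kind="conditional").statistic)
    return GeneCohortTest(gene, cb, cs, int(n_brain), int(n_spinal), orr,
                          min(1.0, p))


def compare_all(cis_genes: pd.DataFrame, cohort: Mapping[str, int],
                adjust: str = "none") -> pd.DataFrame:
    """Per-gene cohort tests over a ranked CIS-gene table.

    One Fisher test per gene using its ``brain_insertions`` /
    ``spinal_insertions`` counts against the cohort tumor counts; ``adjust``
    may be ``benjamini-hochberg`` to add an FDR-adjusted column.  Ordering is
    deterministic (input order preserved).
    """
    if adjust not in ("none", "benjamini-hochberg"):
        raise ParameterError(f"unknown adjust mode {adjust!r}")
    n_brain, n_spinal = int(cohort.get("brain", 0)), int(cohort.get("spinal", 0))
    rows = []
    for g in cis_genes.itertuples(index=False):
        t = per_gene_fisher(g.name, getattr(g, "brain_insertions"),
                            getattr(g, "spinal_insertions"), n_brain, n_spinal)
        rows.append({"gene": t.gene, "count_brain": t.count_brain,
                     "count_spinal": t.count_spinal, "n_brain": t.n_brain,
                     "n_spinal": t.n_spinal, "odds_ratio": t.odds_ratio,
                     "p_two_sided": t.p_two_sided})
    out = pd.DataFrame(rows, columns=["gene", "count_brain", "count_spinal",
                                      "n_brain", "n_spinal", "odds_ratio",
                                      "p_two_sided"])
    if adjust == "benjamini-hochberg" and len(out):
        out["p_bh"] = stats.false_discovery_control(out["p_two_sided"], method="bh")
    return out
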