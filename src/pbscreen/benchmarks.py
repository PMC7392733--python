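"""Seeded whole-pipeline benchmarks on synthetic screens.

These routines measure the statistical behaviour of the CIS caller under
controlled, scaled-down study conditions: the convolution engine against a
brute-force oracle, Monte-Carlo null calibration (family-wise error on
driver-free cohorts), exact-enumeration equivalence on a toy chromosome, and
end-to-end driver recovery.  They are used by the test suite and the
reproduction script; problem sizes are deliberately modest so a full run
stays in the minutes range on one CPU.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotate import build_cis_gene_table, rank_cis_genes
from .genome import TTAAIndex
from .gkc import CommonInsertionSiteModel, GkcParams, _child_seeds, sample_null
from .io import collapse_reads, pool_nonredundant, top_n_filter
from .kernel_oracle import brute_force_density
from .simulate import SimConfig, choose_drivers, simulate_cohort, simulate_genome


def kernel_oracle_check(n_configs: int = 1000, seed: int = 0) -> float:
    """Maximum relative error of the convolution engine vs the brute-force
    oracle over random insertion/eval-point configurations."""
    from .gkc import kernel_density

    rng = np.random.default_rng(int(seed))
    worst = 0.0
    for _ in range(n_configs):
        n = int(rng.integers(1, 60))
        m = int(rng.integers(2, 40))
        h = float(rng.uniform(50.0, 50_000.0))
        span = h * float(rng.uniform(1.0, 8.0))
        pos = np.sort(rng.uniform(0.0, span, n))
        ev = np.sort(rng.uniform(pos.min() - h, pos.max() + h, m))
        engine = kernel_density(pos, h, ev)
        oracle = brute_force_density(pos, h, ev)
        rel = np.max(np.abs(engine - oracle) / np.maximum(np.abs(oracle), 1e-300))
        worst = max(worst, float(rel))
    return worst


def fwer_calibration(n_cohorts: int = 100, tumors_per_cohort: int = 10,
                     n_perm: int = 200, alpha: float = 0.001,
                     min_scales: int = 2, seed: int = 0) -> float:
    """Fraction of driver-free cohorts yielding at least one CIS.

    One 3 x 10 Mb genome is shared across cohorts; each cohort draws
    ``tumors_per_cohort`` tumors with the default background insertion rate
    and no drivers, and the CIS caller runs with the full default scale
    ladder.  Under a calibrated null this fraction is the empirical
    family-wise error rate.
    """
    half = max(1, tumors_per_cohort // 2)
    conf = SimConfig(cohort_sizes={"brain": half, "spinal": tumors_per_cohort - half})
    seeds = _child_seeds(seed, n_cohorts + 1)
    ttaa, genes, _ = simulate_genome(conf, seed=int(seeds[0]))
    params = GkcParams(n_perm=n_perm, alpha=alpha,
                       min_scales_significant=min_scales)
    n_positive = 0
    for i in range(n_cohorts):
        screen = simulate_cohort(ttaa, genes, conf, seed=int(seeds[i + 1]))
        pooled = pool_nonredundant(collapse_reads(screen.insertions))
        res = CommonInsertionSiteModel(pooled, ttaa, params=params).fit(
            seed=int(seeds[i + 1]))
        n_positive += res.n_cis > 0
    return n_positive / n_cohorts


@dataclass
class ToyNullComparison:
    """Monte-Carlo vs exhaustive-enumeration tail probabilities on a toy
    chromosome where peak heights equal insertion multiplicities."""

    mc_tail_ge3: float
    exact_tail_ge3: float
    mc_peaks_per_rep: float
    exact_peaks_per_rep: float
    n_pooled: int

    @property
    def binomial_se(self) -> float:
        p = self.exact_tail_ge3
        return float(np.sqrt(p * (1 - p) / max(1, self.n_pooled)))


def exact_null_equivalence(n_sites: int = 20, n_insertions: int = 3,
                           n_perm: int = 2000, seed: int = 0) -> ToyNullComparison:
    """Compare the Monte-Carlo null to exact enumeration of all placements.

    A toy chromosome carries ``n_sites`` TTAA positions spaced far apart
    relative to a tiny kernel width, so every peak height equals a site's
    insertion multiplicity.  The exact null enumerates all
    ``n_sites**n_insertions`` equally likely placements combinatorially; the
    Monte-Carlo null runs :func:`pbscreen.gkc.sample_null` on the same space.
    """
    spacing = 50
    sites = np.arange(1, n_sites + 1, dtype=np.int64) * spacing
    ttaa = TTAAIndex({"toy": sites}, {"toy": int(sites[-1]) + 10})
    h = 5
    params = GkcParams(scales=(h,), n_perm=n_perm, min_scales_significant=1)
    null = sample_null({"toy": n_insertions}, ttaa, h, params, seed=int(seed))
    mc_tail = float((null.heights >= 2.5).sum() / max(1, null.heights.size))
    mc_rate = float(null.heights.size / n_perm)

    # exhaustive enumeration over multiplicity patterns of 3 insertions on
    # n_sites equally likely sites: a site with multiplicity >= 2 is a peak
    # of that height; all-distinct placements have no qualifying peak.
    s = n_sites
    n_triple = s                                  # all three on one site -> height 3
    n_pair = 3 * s * (s - 1)                      # exactly one pair -> height 2
    total_placements = s ** n_insertions
    total_peaks = n_triple + n_pair               # one qualifying peak each
    exact_tail = n_triple / total_peaks
    exact_rate = total_peaks / total_placements
    return ToyNullComparison(mc_tail, exact_tail, mc_rate, exact_rate,
                             int(null.heights.size))


@dataclass
class RecoverySummary:
    per_seed: pd.DataFrame
    n_seeds: int

    @property
    def n_all_recovered(self) -> int:
        return int(self.per_seed["all_recovered"].sum())

    @property
    def n_top_ranked_first(self) -> int:
        return int(self.per_seed["top_ranked_first"].sum())


def driver_recovery(n_seeds: int = 20, n_drivers: int = 5, pi: float = 0.4,
                    tumors_per_tissue: int = 25, n_perm: int = 200,
                    alpha: float = 0.01, seed: int = 0) -> RecoverySummary:
    """End-to-end driver recovery on seeded scaled-down screens.

    Per seed: simulate a fresh genome and a 50-tumor two-tissue cohort with
    ``n_drivers`` well-separated drivers at per-tumor insertion probability
    ``pi`` over the default background rate; run the full pipeline (collapse,
    top-300 filter, pooling, CIS calling, gene association, ranking); record
    how many drivers appear among the CIS genes and whether the
    most-frequently-hit simulated driver ranks first by insertion count.

    ``alpha`` defaults to 0.01 here: with reduced Monte-Carlo replicates the
    attainable Bonferroni-adjusted p is floored near ``1/n_perm``, so the
    stricter screening threshold of 0.001 cannot be reached by construction
    at this n_perm (see the methods notes).
    """
    rows = []
    master = _child_seeds(seed if seed else 12345, n_seeds * 2).reshape(n_seeds, 2)
    for i in range(n_seeds):
        conf = SimConfig(cohort_sizes={"brain": tumors_per_tissue,
                                       "spinal": tumors_per_tissue})
        ttaa, genes, _ = simulate_genome(conf, seed=int(master[i, 0]))
        conf.drivers = choose_drivers(genes, n=n_drivers, pi=pi)
        screen = simulate_cohort(ttaa, genes, conf, seed=int(master[i, 1]))
        pooled = pool_nonredundant(collapse_reads(top_n_filter(screen.insertions)))
        params = GkcParams(n_perm=n_perm, alpha=alpha)
        res = CommonInsertionSiteModel(pooled, ttaa, params=params).fit(
            seed=int(master[i, 1]))
        table = build_cis_gene_table(res.cis, pooled, genes)
        drivers = [d.gene for d in conf.drivers]
        if len(table):
            ranked = rank_cis_genes(table, conf.cohort_sizes)
            recovered = sorted(set(ranked["name"]) & set(drivers))
            top_first = bool(ranked["name"].iloc[0] == screen.truth.driver_ranking[0])
        else:
            recovered, top_first = [], False
        rows.append({"seed": i, "n_cis": res.n_cis,
                     "n_recovered": len(recovered),
                     "all_recovered": len(recovered) == n_drivers,
                     "top_ranked_first": top_first})
    return RecoverySummary(pd.DataFrame(rows), n_seeds)
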