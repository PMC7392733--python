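"""Seeded synthetic piggyBac screens for end-to-end pipeline testing.

The generator emulates the structure of a two-tissue (brain/spinal) QI-seq
screen: a toy genome with TTAA motif positions, non-overlapping gene models,
tumors whose background insertions fall uniformly on TTAA sites, driver genes
hit at elevated per-tumor probabilities with pattern-appropriate placement
(gene-trap insertions anywhere in the body, activating insertions sense near
the 5' end), a clonal/subclonal read-count mixture, optional multi-region
sampling, and matched fusion-transcript records.  A ground-truth object
records every driver insertion for recovery testing.

What it deliberately does not model: sequencing error, mappability, local
hopping from the donor locus (off by default), chromatin-driven insertion
bias, or read-level data.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParameterError
from .genome import TTAAIndex, scan_ttaa

DEFAULT_CHROMS = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}


@dataclass
class DriverSpec:
    """One simulated driver gene.

    ``pi`` is the per-tumor insertion probability, either one number or a
    tissue -> probability mapping (to emulate tissue-biased drivers).
    """

    gene: str
    pi: float | Mapping[str, float] = 0.4
    pattern: str = "inactivating"           # or "activating"
    clonal: bool = True

    def pi_for(self, tissue: str) -> float:
        p = self.pi[tissue] if isinstance(self.pi, Mapping) else float(self.pi)
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"driver {self.gene}: pi must be in [0, 1]")
        return p


@dataclass
class SimConfig:
    """Study conditions of the synthetic screen.

    Defaults mirror the screen being emulated where it states them (46 brain
    and 50 spinal tumors; TTAA motif density 1/256 bp as for uniform base
    composition) and order-of-magnitude realistic values elsewhere
    (λ_bg = 200 detectable background insertions per bulk tumor sample --
    the transposon line carries ~20 copies per cell but bulk sequencing sees
    many subclones; read-count mixture tuned so clonal events dominate a
    top-300 read-count filter).
    """

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CHROMS))
    ttaa_mode: str = "position-process"     # or "from-sequence"
    ttaa_rate: float = 1.0 / 256.0
    n_genes: int = 200
    gene_length_median: int = 20_000
    gene_length_sigma: float = 0.6
    gene_min_length: int = 5_000
    gene_max_length: int = 120_000
    cohort_sizes: dict[str, int] = field(default_factory=lambda: {"brain": 46,
                                                                  "spinal": 50})
    lambda_bg: float = 200.0
    bg_dispersion: float = 10.0
    f_clonal: float = 0.1
    mu_clonal: float = 100.0
    mu_subclonal: float = 3.0
    read_dispersion: float = 1.0
    regions_per_tumor: int = 1
    p_fusion: float = 0.5
    upstream_window: int = 10_000
    activating_fraction: float = 0.2
    donor_chrom: str | None = None
    donor_multiplier: float = 1.0
    drivers: list[DriverSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.chrom_lengths.values()):
            raise ParameterError("chromosome lengths must be positive")
        if self.ttaa_mode not in ("position-process", "from-sequence"):
            raise ParameterError(f"unknown ttaa_mode {self.ttaa_mode!r}")
        if not 0 < self.ttaa_rate < 1:
            raise ParameterError("ttaa_rate must be in (0, 1)")
        if self.lambda_bg < 0 or self.regions_per_tumor < 1:
            raise ParameterError("rates and sizes must be positive")
        self.drivers = [d if isinstance(d, DriverSpec) else DriverSpec(**d)
                        for d in self.drivers]


@dataclass
class SimTruth:
    """Ground truth emitted alongside a synthetic cohort.

    ``insertions`` has one row per realized driver insertion (tumor, gene,
    position, orientation, clonal flag, pattern); ``driver_ranking`` lists
    driver genes by realized insertion count, descending.
    """

    insertions: pd.DataFrame
    driver_ranking: list[str]

    def count_for(self, gene: str) -> int:
        return int((self.insertions["gene"] == gene).sum())


@dataclass
class SimScreen:
    insertions: pd.DataFrame
    samples: pd.DataFrame
    truth: SimTruth
    fusions: pd.DataFrame


def simulate_genome(config: SimConfig, seed: int = 0):
    """Generate the toy genome: TTAA index, gene models, optional sequences.

    In ``position-process`` mode TTAA starts are drawn as a discrete uniform
    process at ``ttaa_rate`` per bp; in ``from-sequence`` mode iid-uniform
    ACGT sequences are generated (which realize the same 1/256 motif rate) and
    scanned, so the emitted index is exactly what
    :func:`pbscreen.genome.scan_ttaa` reports on the emitted FASTA.

    Returns ``(ttaa, genes, sequences)``; sequences is None in
    position-process mode.
    """
    rng = np.random.default_rng(int(seed))
    sequences = None
    if config.ttaa_mode == "from-sequence":
        sequences = {}
        for chrom in sorted(config.chrom_lengths):
            n = config.chrom_lengths[chrom]
            seq = rng.integers(0, 4, size=n, dtype=np.uint8)
            sequences[chrom] = (np.frombuffer(b"ACGT", dtype=np.uint8)[seq]
                                .tobytes().decode("ascii"))
        ttaa = scan_ttaa(sequences)
    else:
        positions = {}
        for chrom in sorted(config.chrom_lengths):
            length = config.chrom_lengths[chrom]
            count = rng.binomial(max(0, length - 3), config.ttaa_rate)
            draws = rng.integers(1, max(2, length - 2), size=count)
            positions[chrom] = np.unique(draws)
        ttaa = TTAAIndex(positions, config.chrom_lengths)

    lengths = np.exp(rng.normal(np.log(config.gene_length_median),
                                config.gene_length_sigma, size=config.n_genes))
    lengths = np.clip(lengths, config.gene_min_length,
                      config.gene_max_length).astype(np.int64)
    chroms = sorted(config.chrom_lengths)
    genome_len = sum(config.chrom_lengths.values())
    if lengths.sum() > 0.7 * genome_len:
        raise ConfigurationError("gene demand exceeds genome capacity")
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    rows = []
    for i, glen in enumerate(lengths):
        for _ in range(1000):
            chrom = chroms[rng.integers(0, len(chroms))]
            clen = config.chrom_lengths[chrom]
            if glen + 2 >= clen:
                continue
            start = int(rng.integers(1, clen - glen - 1))
            end = start + int(glen) - 1
            if all(end < s - 1000 or start > e + 1000 for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                rows.append((f"g{i + 1:04d}", f"Gene{i + 1:04d}", chrom,
                             start, end, strand))
                break
        else:
            raise ConfigurationError("gene demand exceeds genome capacity")
    genes = (pd.DataFrame(rows, columns=["gene_id", "name", "chrom", "start",
                                         "end", "strand"])
             .sort_values(["chrom", "start"], ignore_index=True))
    return ttaa, genes, sequences


def choose_drivers(genes: pd.DataFrame, n: int = 5, pi: float = 0.4,
                   patterns: tuple[str, ...] = ("inactivating", "activating"),
                   min_separation: int = 1_000_000) -> list[DriverSpec]:
    """Pick n well-separated driver genes (>= min_separation apart or on
    different chromosomes) with alternating insertion patterns.

    If the genome cannot host n genes at the requested separation, the
    separation is relaxed (quartered) until it can; separation 0 degenerates
    to the first n genes.
    """
    if n > len(genes):
        raise ConfigurationError("fewer genes than requested drivers")
    sep = int(min_separation)
    while True:
        chosen: list[pd.Series] = []
        for _, g in genes.sort_values(["chrom", "start"]).iterrows():
            ok = all(g["chrom"] != c["chrom"]
                     or abs(int(g["start"]) - int(c["start"])) >= sep
                     for c in chosen)
            if ok:
                chosen.append(g)
            if len(chosen) == n:
                break
        if len(chosen) == n:
            break
        if sep == 0:
            raise ConfigurationError("not enough well-separated genes for drivers")
        sep //= 4
    return [DriverSpec(gene=g["name"], pi=pi, pattern=patterns[i % len(patterns)],
                       clonal=True)
            for i, g in enumerate(chosen)]


def _read_count(rng: np.random.Generator, mu: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mu)
    return int(max(1, rng.negative_binomial(dispersion, p)))


def _driver_window(gene: pd.Series, pattern: str, config: SimConfig) -> tuple[int, int]:
    if pattern == "inactivating":
        return int(gene["start"]), int(gene["end"])
    glen = int(gene["end"]) - int(gene["start"]) + 1
    body = int(round(config.activating_fraction * glen))
    if gene["strand"] == "+":
        return int(gene["start"]) - config.upstream_window, int(gene["start"]) + body
    return int(gene["end"]) - body, int(gene["end"]) + config.upstream_window


def simulate_cohort(ttaa: TTAAIndex, genes: pd.DataFrame, config: SimConfig,
                    seed: int = 0) -> SimScreen:
    """Simulate the two-tissue tumor cohort over a generated genome.

    Per tumor: a negative-binomial number of background insertions placed
    uniformly over TTAA sites with fair-coin orientation; each driver inserted
    with its per-tissue probability, positioned according to its pattern
    (gene-trap: uniform over TTAA in the gene body, random orientation;
    activating: TTAA in the 5' window, sense orientation); read counts from
    the clonal/subclonal mixture, with driver insertions forced clonal when
    their DriverSpec marks them clonal; multi-region tumors replicate clonal insertions across all
    regions and draw subclonal ones per region; each driver insertion emits a
    fusion record with probability ``p_fusion`` whose feature/orientation is
    consistent with its pattern.
    """
    rng = np.random.default_rng(int(seed))
    gene_by_name = {g["name"]: g for _, g in genes.iterrows()}
    for spec in config.drivers:
        if spec.gene not in gene_by_name:
            raise ConfigurationError(f"driver gene {spec.gene!r} not in annotation")
        if spec.pattern not in ("activating", "inactivating"):
            raise ParameterError(f"unknown driver pattern {spec.pattern!r}")
    chroms = [c for c in sorted(ttaa.chroms) if ttaa[c].size > 0]
    site_weights = np.array([ttaa[c].size for c in chroms], dtype=np.float64)
    if config.donor_chrom in chroms:
        site_weights[chroms.index(config.donor_chrom)] *= config.donor_multiplier
    chrom_probs = site_weights / site_weights.sum()

    region_ids = ([""] if config.regions_per_tumor == 1
                  else [f"R{k + 1}" for k in range(config.regions_per_tumor)])

    ins_rows: list[dict] = []
    truth_rows: list[dict] = []
    fusion_rows: list[dict] = []
    sample_rows: list[dict] = []

    def emit(tumor, tissue, region, chrom, pos, orient, clonal):
        sample = tumor if region == "" else f"{tumor}_{region}"
        mu = config.mu_clonal if clonal else config.mu_subclonal
        ins_rows.append({
            "sample_id": sample, "tumor_id": tumor, "region_id": region,
            "tissue": tissue, "chrom": chrom, "pos": int(pos),
            "orientation": orient, "transposon_end": "merged",
            "read_count": _read_count(rng, mu, config.read_dispersion),
        })

    def random_site() -> tuple[str, int]:
        chrom = chroms[rng.choice(len(chroms), p=chrom_probs)]
        sites = ttaa[chrom]
        return chrom, int(sites[rng.integers(0, sites.size)])

    for tissue in sorted(config.cohort_sizes):
        for t in range(int(config.cohort_sizes[tissue])):
            tumor = f"{tissue[0].upper()}{t + 1:03d}"
            for region in region_ids:
                sample_rows.append({
                    "sample_id": tumor if region == "" else f"{tumor}_{region}",
                    "mouse_id": tumor, "tissue": tissue, "region_id": region,
                    "n_regions": config.regions_per_tumor,
                })
            p_nb = config.bg_dispersion / (config.bg_dispersion + config.lambda_bg)
            n_bg = int(rng.negative_binomial(config.bg_dispersion, p_nb))
            n_clonal = int(rng.binomial(n_bg, config.f_clonal))
            # clonal background: one draw, present in every region
            for _ in range(n_clonal):
                chrom, pos = random_site()
                orient = "+" if rng.random() < 0.5 else "-"
                for region in region_ids:
                    emit(tumor, tissue, region, chrom, pos, orient, clonal=True)
            # subclonal background: fresh draws per region
            for region in region_ids:
                for _ in range(n_bg - n_clonal):
                    chrom, pos = random_site()
                    orient = "+" if rng.random() < 0.5 else "-"
                    emit(tumor, tissue, region, chrom, pos, orient, clonal=False)
            # drivers
            for spec in config.drivers:
                if rng.random() >= spec.pi_for(tissue):
                    continue
                gene = gene_by_name[spec.gene]
                lo, hi = _driver_window(gene, spec.pattern, config)
                sites = ttaa[gene["chrom"]]
                sel = sites[(sites >= lo) & (sites <= hi)]
                if sel.size == 0:
                    mid = (lo + hi) // 2
                    sel = sites[[int(np.argmin(np.abs(sites - mid)))]]
                pos = int(sel[rng.integers(0, sel.size)])
                if spec.pattern == "activating":
                    orient = gene["strand"]
                else:
                    orient = "+" if rng.random() < 0.5 else "-"
                regions = region_ids if spec.clonal else [
                    region_ids[rng.integers(0, len(region_ids))]]
                for region in regions:
                    emit(tumor, tissue, region, gene["chrom"], pos, orient,
                         clonal=spec.clonal)
                truth_rows.append({
                    "tumor_id": tumor, "tissue": tissue, "gene": spec.gene,
                    "chrom": gene["chrom"], "pos": pos, "orientation": orient,
                    "clonal": spec.clonal, "pattern": spec.pattern,
                })
                if rng.random() < config.p_fusion:
                    if spec.pattern == "activating":
                        feature, f_orient = "SD", "sense"
                    elif orient == gene["strand"]:
                        feature, f_orient = "CbASA", "sense"
                    else:
                        feature, f_orient = "En2SA", "antisense"
                    fusion_rows.append({
                        "sample_id": tumor if region_ids[0] == "" else f"{tumor}_{region_ids[0]}",
                        "gene": spec.gene, "feature": feature,
                        "orientation": f_orient,
                        "junction_reads": 1 + int(rng.poisson(5.0)),
                        "spanning_fragments": int(rng.poisson(3.0)),
                    })

    insertions = pd.DataFrame(ins_rows, columns=[
        "sample_id", "tumor_id", "region_id", "tissue", "chrom", "pos",
        "orientation", "transposon_end", "read_count"])
    samples = pd.DataFrame(sample_rows)
    truth_df = pd.DataFrame(truth_rows, columns=[
        "tumor_id", "tissue", "gene", "chrom", "pos", "orientation", "clonal",
        "pattern"])
    counts = truth_df.groupby("gene").size() if len(truth_df) else pd.Series(dtype=int)
    ranking = sorted((spec.gene for spec in config.drivers),
                     key=lambda g: (-int(counts.get(g, 0)), g))
    fusions = pd.DataFrame(fusion_rows, columns=[
        "sample_id", "gene", "feature", "orientation", "junction_reads",
        "spanning_fragments"])
    return SimScreen(insertions, samples, SimTruth(truth_df, ranking), fusions)


def simulate_screen(config: SimConfig, seed: int = 0):
    """Genome + cohort in one call; returns ``(ttaa, genes, screen)``."""
    genome_seed, cohort_seed = (np.random.SeedSequence(int(seed))
                                .generate_state(2, dtype=np.uint32) % (2 ** 31))
    ttaa, genes, _ = simulate_genome(config, seed=int(genome_seed))
    screen = simulate_cohort(ttaa, genes, config, seed=int(cohort_seed))
    return ttaa, genes, screen


def config_from_dict(d: Mapping) -> SimConfig:
    kwargs = {k: v for k, v in d.items() if k in SimConfig.__dataclass_fields__}
    return SimConfig(**kwargs)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
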