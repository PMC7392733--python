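# pbscreen

Statistical analysis of *piggyBac* transposon insertional-mutagenesis tumor
screens: from per-sample insertion-site evidence to significant **common
insertion sites (CIS)**, driver-gene annotation with activating/disrupting
pattern calls, brain-vs-spinal cohort comparison, multi-region clonality, and
gene–transposon fusion-transcript integration. A seeded synthetic-screen
generator makes every stage testable without sequencing data.

## Who this is for

Forward-genetics screens mobilize a transposon (here *piggyBac*, which
integrates exclusively at TTAA tetranucleotides) across a tumor cohort and
sequence the transposon–genome junctions (QI-seq). Genes that the transposon
hits in many independent tumors are under positive selection — candidate
cancer drivers. The statistical problem is to find the genomic regions hit
more often than chance, given that "chance" is shaped by the discrete TTAA
target space and the background insertion rate.

## The model

Insertion positions pooled across tumors are smoothed with an unnormalized
Gaussian kernel at width *h* (the "window size"):

    f(x) = Σᵢ exp( −(x − xᵢ)² / 2h² ),   h ∈ {10, 20, …, 100} kb

so that `f` at a peak is directly comparable to a local insertion count.
Peaks of `f` are candidate CIS. Significance comes from a Monte-Carlo null
that redraws the same number of insertions **uniformly over the TTAA motif
positions** of each chromosome and collects the null peak heights; the raw
peak p-value is the add-one tail frequency and is Bonferroni-corrected over
the candidate peaks at that scale. A CIS is reported when its corrected
p-value beats the threshold at a minimum number of kernel widths (≥ 2 by
default). Per-gene roll-ups are then ranked by insertion count; orientation
bias and position within the gene body classify each gene's pattern as
**activating** (sense-oriented, 5′-biased insertions — the transposon's
promoter/splice-donor drives the gene) or **inactivating** (gene-trap
insertions scattered through the body in either orientation). Cohort
contrasts use two-sided Fisher's exact tests on insertions vs tumors per
tissue.

## Worked example

Simulate a small two-tissue screen with two certain drivers, run the
pipeline, and rank the CIS genes:

```python
import pbscreen as pb

conf = pb.SimConfig(chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
                    n_genes=30, cohort_sizes={"brain": 6, "spinal": 6},
                    lambda_bg=20)
ttaa, genes, _ = pb.simulate_genome(conf, seed=11)
conf.drivers = pb.choose_drivers(genes, n=2, pi=1.0, min_separation=400_000)
screen = pb.simulate_cohort(ttaa, genes, conf, seed=12)

pooled = pb.pool_nonredundant(pb.collapse_reads(pb.top_n_filter(screen.insertions)))
params = pb.GkcParams(scales=(10_000, 20_000, 30_000), alpha=0.05, n_perm=200)
res = pb.CommonInsertionSiteModel(pooled, ttaa, params=params).fit(seed=1)
print(res.summary())

table = pb.rank_cis_genes(pb.build_cis_gene_table(res.cis, pooled, genes),
                          conf.cohort_sizes)
print(table[["rank", "name", "total_insertions", "n_tumors", "pct_tumors",
             "pattern"]].to_string(index=False))
```

prints

```
Common insertion site analysis (Gaussian kernel convolution)
================================================================
Insertions:      224    Tumors: 12
Chromosomes:       2    Scales: 10-30 kb (n=3)
Null replicates: 200    alpha: 0.05    min scales: 2
Seed: 1    null mode: chromosome-matched
Significant CIS: 2
----------------------------------------------------------------
         cis_id chrom  apex_pos  best_scale  n_insertions  n_tumors  adjusted_p
CIS_chr1_109336  chr1    109336       10000            12        12    0.004272
CIS_chr1_622000  chr1    622000       10000            12        12    0.004272

 rank     name  total_insertions  n_tumors  pct_tumors      pattern
    1 Gene0002                12        12  100.000000 inactivating
    2 Gene0010                12        12  100.000000   activating
    3 Gene0003                 5         5   41.666667    ambiguous
```

Both CIS are genome-wide significant density peaks hit in all 12 tumors;
they land exactly on the two simulated drivers, whose insertion geometry
(scattered/mixed-orientation vs sense/5′-clustered) drives the pattern call.
Cohort contrasts work the same way on real counts — e.g. 8/46 brain vs 22/50
spinal insertions in one gene:

```python
t = pb.per_gene_fisher("Pten", 8, 22, 46, 50)
print(f"p = {t.p_two_sided:.4f}")     # p = 0.0077
```

The same pipeline is scriptable from the shell (`pbscreen simulate`,
`collapse`, `filter`, `pool`, `scan-ttaa`, `call-cis`, `annotate`,
`compare`, `clonality`, `fusion-enrich`); see `pbscreen --help`.

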