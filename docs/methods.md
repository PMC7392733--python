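# Methods

## The screen and its statistical problem

A *piggyBac* insertional-mutagenesis screen mobilizes ~20 transposon copies
per cell across a tumor cohort and sequences transposon–genome junctions
(QI-seq), yielding per-sample insertion sites (IS) with read counts.
Because selection acts on tumors independently, genes that cooperate with
the initiating lesion accumulate insertions across tumors — common insertion
sites (CIS). Two facts shape the null model: *piggyBac* integrates only at
TTAA tetranucleotides (a palindromic 4-bp motif, so the target space is
strand-free and discrete), and the background insertion rate varies with
how many insertions a tumor carries. The caller therefore conditions on
both: nulls redraw the observed number of insertions uniformly over the
actual TTAA positions.

## Pipeline

1. **Read collapsing** — reads mapping to the same (sample, chromosome,
   position, orientation, transposon end) count as a single IS with a read
   count. Idempotent; total reads conserved.
2. **End merging** (optional) — the 3′ and 5′ junction libraries are
   sequenced separately; records from opposite ends within 10 bp (default,
   configurable) at consistent orientation are unified at the 5′ position
   with summed reads. The merge is a greedy in-order pairing, chosen for
   determinism; the protocol itself does not dictate a rule.
3. **Top-N filter** — each sample keeps its 300 highest-read IS (clonally
   expanded insertions dominate read counts, so this enriches for selected
   events). Boundary ties break by (chromosome, position) so reruns are
   byte-identical.
4. **Pooling** — per-sample tables form the non-redundant analysis set. By
   default duplicates are collapsed within a sample only, so a position
   recurring in k samples contributes k entries (recurrence is the signal);
   `collapse=across-samples` collapses genome-wide instead, since the
   protocol description admits either reading.
5. **CIS calling** — below.
6. **Annotation, cohort comparison, clonality, fusions** — below.

## CIS detection (Gaussian kernel convolution)

Pooled positions on each chromosome are smoothed with the unnormalized
kernel `K_h(u) = exp(−u²/2h²)` over the scale ladder h = 10…100 kb in 10 kb
steps. Peak height at an apex then reads as "effective local insertion
count", directly comparable to the enumeration oracle on toy data. Design
choices, in the order they matter:

- **Evaluation grid.** Regular spacing of `0.2·h` per chromosome, plus every
  insertion position. Including the data points guarantees the reported apex
  is never below a true peak by more than a bounded interpolation error.
- **Peaks.** Strict local maxima (plateaus yield their leftmost point;
  an end point qualifies against its single neighbour). Observed candidates
  must have ≥ 2 member insertions and ≥ 2 distinct tumors within ±h
  (`min_tumors`, default 2 — one tumor is not recurrence).
- **Null.** For each scale, `n_perm` replicates place the matched number of
  insertions uniformly (with replacement) on the TTAA positions — per
  chromosome by default (`chromosome-matched`, absorbing chromosome-level
  rate biases such as donor-locus proximity), or genome-wide proportional to
  TTAA counts. Null profiles run through the identical grid/peak machinery
  with the tumor filter disabled; all qualifying null peak heights are
  pooled, and each replicate's genome-wide maximum is kept as a diagnostic.
- **Significance.** `raw_p = (1 + #{null peaks ≥ height}) / (1 + #null
  peaks)` (add-one, so the attainable minimum is set by the Monte-Carlo
  resolution), then `adjusted_p = raw_p × n_candidate_peaks` at that scale
  (Bonferroni over the tests actually performed; a genome-length/h
  effective-test count is available as an alternative). Peaks across scales
  within `max(scales)` of each other cluster into one CIS, reported iff
  `adjusted_p < α` at ≥ `min_scales_significant` scales (default 2,
  operationalizing "significant for multiple window sizes"); the
  representative scale is the one with the smallest adjusted p, ties to the
  sharper (smaller) h. The default α is 0.001; the screening literature for
  this construct also uses 0.01, and both are one flag apart.
- **Monte-Carlo resolution.** Because of the add-one bound, the smallest
  attainable adjusted p is ≈ `n_candidates / (1 + n_perm × null peaks per
  replicate)` ≈ `1/n_perm` whenever observed and null candidate counts are
  similar. Consequently α = 0.001 requires n_perm > 1000; the scaled-down
  benchmarks in this repository run at n_perm = 200 with α = 0.01, the only
  operative threshold at that replicate count.

### Numerical engine

The reference kernel (`kernel_density`) is exact float64 and is what the
brute-force oracle test checks to 1e-9 relative error. The screening engine
used inside the model windows the sum at `6h` (absolute error ≤ n·e⁻¹⁸,
documented bound, tested), evaluates in float32, and replaces `exp` by
linear interpolation of an 8192-bin table (relative error < 1e-6). Observed
and null profiles go through the same routine, so peak-height comparisons
are internally consistent; the approximation error is orders of magnitude
below the Monte-Carlo noise floor. Positions up to 2²⁴ are exact in
float32; larger coordinates round by up to 16 bp, negligible against
h ≥ 10 kb. All randomness derives from a single seed via spawned seed
sequences (per scale, per chromosome); identical inputs and seed give
byte-identical CIS tables.

## Gene annotation and pattern calls

A CIS associates with every gene whose body overlaps the CIS interval
extended by the representative h on each side (kernel support exceeds the
member-insertion span); intergenic CIS can optionally take the nearest gene
within a cap, flagged as such. Per-gene roll-ups count insertions in the
gene body plus a 10 kb strand-aware upstream window (the
activation-compatible 5′ region), rank genes by total insertions (ties by
tumor count, then name) and compute percent-of-cohort recurrence.

The construct can activate a gene (promoter + splice donor, requires sense
orientation, usually 5′) or truncate it (two splice acceptors +
bidirectional polyA, either orientation, anywhere in the body). The
quantitative operationalization here: **activating** iff n ≥ 3, sense
fraction ≥ 0.8 confirmed by a one-sided exact binomial test against 0.5 at
p < 0.05, and median strand-aware relative position ≤ 0.2 (upstream counts
as 5′); **inactivating** iff n ≥ 3, a majority of insertions lie inside the
gene body, and the activating signature is absent; anything else (including
every gene with n < 3) is **ambiguous**. The thresholds are this package's
choices — the construct biology is qualitative — and are exposed as
arguments. A one-sided binomial test is used because the activating
hypothesis is directional; with the two-sided variant no gene below n = 8
could ever be called activating.

## Cohort comparison

Shared CIS genes have ≥ 1 insertion in each tumor type; tissue-specific
genes draw all insertions from one type. Per-gene frequency contrasts use a
two-sided Fisher's exact test (point-probability rule: sum over tables at
most as probable as observed) on `[[insertions_brain, tumors_brain −
insertions_brain], [insertions_spinal, tumors_spinal − insertions_spinal]]`
— insertion counts normalized by cohort size. This construction reproduces
the published Pten contrast (8/46 vs 22/50 → p = 0.0077 ≈ 0.008) and Sox6
(26/46 vs 3/50 → p < 1e-4); those two printed values are its only external
validation, and a tumors-with-insertion variant is available by supplying
those counts instead. Insertion counts above the cohort size clamp with a
warning (they are treated as tumor-level events). The odds ratio is the
conditional maximum-likelihood estimate. No multiplicity correction by
default (matching raw reporting); Benjamini-Hochberg is an option.

## Multi-region clonality

Within one tumor sampled at ≥ 2 regions, an insertion "exists" in a region
only with ≥ 2 supporting reads there (per-region application is the
stricter reading of the protocol and the default). Surviving insertions
match across regions at identical position and orientation (TTAA
quantization makes exact matching safe; a bp tolerance is available).
Present in all regions → clonal; exactly one → private; otherwise
shared-subclonal. Per-gene summaries report label counts and the modal
label, ties breaking toward the less clonal interpretation.

## Fusion transcripts

Fusion callers report, per transcript, which transposon feature is joined
(splice donor SD, carp-β-actin acceptor CbASA, Engrailed-2 exon-2 acceptor
En2SA) and the orientation relative to the gene. SD fusions are activating
and only exist in sense — an antisense SD record is a data-consistency
error; either acceptor truncates in either orientation. Enrichment of
fusion-supported genes among CIS genes is a two-sided Fisher test on the
2×2 over an explicit gene universe; no default universe is baked in because
the choice (all annotated genes vs all expressed genes) changes the answer
and must be the analyst's.

## Synthetic screens

The generator emulates the structure of the study conditions: a 3 × 10 Mb
toy genome; TTAA positions either as a discrete uniform process at 1/256
per bp (the iid-sequence motif rate) or scanned from emitted iid ACGT
sequence (both modes agree with the scanner by construction); ~200
non-overlapping genes with log-normal lengths (median 20 kb); cohorts of 46
brain and 50 spinal tumors by default; background insertions per tumor
negative-binomial with mean λ_bg = 200 (the transposon line carries ~20
copies per cell, but bulk sequencing of many subclones yields hundreds of
detectable IS per sample — order-of-magnitude choice, configurable) and
dispersion 10; read counts from a clonal/subclonal mixture (10% clonal at
mean 100 reads, else mean 3, dispersion 1) so a top-300 filter retains
clonal events preferentially; drivers hit each tumor with per-tissue
probability π, placed on TTAA sites uniformly over the gene body
(inactivating, random orientation) or over [TSS − 10 kb, TSS + 0.2·length]
in sense (activating), forced clonal by default; multi-region tumors
replicate clonal insertions across regions and draw subclonal ones per
region; each driver insertion emits a pattern-consistent fusion record with
probability 0.5. A truth object records every driver insertion.

Not modeled: sequencing error, mappability, chromatin insertion bias,
local hopping (an optional donor-chromosome multiplier exists to stress the
donor-exclusion flag), and read-level data. Passing tests on synthetic
screens therefore demonstrate the statistics under the stated generative
model, not robustness to alignment artifacts.

## Benchmark problem sizes and what they show

The repository's heavy checks (test suite and `scripts/acceptance.py`) use
deliberately scaled-down conditions chosen once:

- **Null calibration**: 100 driver-free cohorts of 10 tumors each on one
  shared 3 × 10 Mb genome, n_perm = 200, α = 0.001, min scales 2. At this
  replicate count the Monte-Carlo floor alone keeps the family-wise error
  at zero (see *Monte-Carlo resolution* above), so the ≤ 5% check passes
  conservatively.
- **Driver recovery**: 20 seeds × (50 tumors, 5 drivers at π = 0.4,
  λ_bg = 200, fresh genome per seed), n_perm = 200, α = 0.01. Note the
  scaled-down geometry is much harsher than a real screen: 200 background
  insertions per tumor on 30 Mb is ~1 pooled insertion per 3 kb, roughly
  50× the per-bp background of a real 96-tumor screen on a 2.5 Gb genome,
  while the driver signal (≈ 20 insertions) is unchanged. Driver peaks must
  beat the maximum of ~10⁵ pooled null peaks at two scales, so only the
  strongest realized drivers clear the bar and recovery is partial by
  construction at these settings. The benchmark reports exactly what it
  measures (drivers recovered per seed, whether the most-hit driver ranks
  first); it demonstrates the machinery end to end, not full sensitivity at
  this signal-to-noise.
- **Exact-null equivalence**: 20 TTAA sites, 3 insertions, h = 5 bp, 2000
  replicates against exhaustive enumeration of all 8000 placements.
- **Kernel oracle**: 1000 random configurations against the exact double
  loop.

## Known limitations

- The Bonferroni-by-candidate-count correction is the literal reading of
  "Bonferroni-corrected"; correcting across scales as well would be
  stricter and is not implemented beyond the ≥ 2-scales rule.
- Read-count weighting of the kernel (and of the null via resampled
  weights) is available but unvalidated against any published number.
- Pattern calls use gene bodies only; exon/intron structure, promoters and
  enhancers are out of scope.
- The clonality module labels insertions; it does not reconstruct trees or
  cancer-cell fractions.
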