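# Methods

## Simulation model (`gcatbench.simkit`)

**Reference.** `generate_reference` draws bases i.i.d. with
P(G)=P(C)=gc/2, P(A)=P(T)=(1−gc)/2. Default GC in the CLI and examples is
0.41, the genome-wide human value; the composition is otherwise structureless
(no repeats, no N-runs) — see *Limitations*.

**Mutation.** Each reference base mutates independently with probability
`mutation_rate` (default 0.001 per base). A mutation is an indel with
probability `indel_fraction` (default 0.10), split evenly between
insertions and deletions; indel length is drawn uniformly from the large
range 10–24 bp with probability `large_indel_fraction` (default 0.1) and
from the small range 1–10 bp otherwise. The large-class mix is a package
choice: the two length classes are standard, their relative frequency is
not, so it is a configurable parameter with a deliberately small default
(large indels are rarer in germline data). A mutation is heterozygous with
probability `het_probability` (default 0.5 — zygosity of simulated
germline variation is a free choice; 0.5 keeps both classes well
represented), landing on one uniformly chosen haplotype; hom-alt mutations
apply to both. A proposed mutation whose reference footprint overlaps an
earlier mutation on a shared haplotype, or whose deletion would run past
the contig end, is rejected *without resampling*: this keeps per-base
independence approximately intact and guarantees non-overlapping truth per
haplotype. At the default rate the rejection probability is O(10⁻³), far
inside the binomial sampling tolerance used everywhere.

Truth records use the VCF anchor-base convention (deletion removes bases
after the anchor, insertion inserts after it) at the sampled position; in
repetitive sequence an indel may admit a left-shifted equivalent
representation, so all comparisons normalize both call sets first rather
than assuming the simulator's representation is canonical.

**Truth VCF.** Heterozygous genotypes are written phased (`1|0` = variant
on haplotype 0, `0|1` = haplotype 1) so the haplotype assignment — needed
to reconstruct the haplotypes exactly from reference + VCF — survives a
write/read round trip. Hets of unknown phase write `0/1`; hom-alt `1/1`.

**Library.** Defaults: paired 100-bp reads, fragment length ~ N(500, 50²)
interpreted as the *outer* fragment length (the usual simulator
convention; the alternative inner-gap reading would shift the mean by two
read lengths and is not used), 20× coverage, per-base substitution error
0.01 with a flat base-quality string at the matching Phred value (Q20);
`base_error_rate=0` writes Q40. The error model is substitution-only —
no indel errors, no quality decay along the read, no platform-specific
artifacts. The pair count is deterministic:
`round(coverage × reference_length / (2 × read_length))`. Fragments pick a
haplotype uniformly, resample length until it fits in
[read_length, haplotype_length], place uniformly, and orient as a standard
FR pair with mate 1 forward with probability 0.5.

**Truth channel.** Read names encode
`chrom_start1_strand_start2_strand_haplotype_serial` (strands F/R, split
from the right so contig names may contain underscores). Starts are the
1-based leftmost *reference* coordinates of each mate — what a perfect
mapper reports as POS — computed through a haplotype→reference coordinate
map in which inserted bases inherit their anchor's coordinate.

**Random streams.** One seeded generator per stage (mutation;
fragmentation; base errors) derived from a single user seed via
`numpy.random.SeedSequence.spawn`, so changing, say, the error rate leaves
fragment placement untouched. Identical seed + parameters reproduce FASTQ
and VCF outputs byte-for-byte (gzip members are written with fixed mtime
and no embedded filename).

## Alignment scoring (`gcatbench.alneval`)

Only primary, non-supplementary SAM/BAM records are admitted (mappers are
expected to be run in a mode that emits primary alignments only; secondary
and supplementary records are skipped rather than scored twice). A mapped
read is **correct** iff contig and strand match its origin and
|POS − true POS| ≤ tolerance. The default tolerance is 20 bp: indels up to
24 bp inside a fragment shift leftmost coordinates of overlapping reads,
so exact equality would misclassify correctly placed reads; the flag is
exposed because there is no single field-wide definition of "incorrectly
mapped". Both mates are judged independently (all percentages are
per-read, not per-pair). A read name that fails to decode, or a duplicated
(name, mate) pair, aborts the evaluation — silent drops would bias the
reported percentages.

The ROC-like curve has one point per distinct MAPQ, descending; the point
at threshold t counts correct/incorrect reads with MAPQ ≥ t, so both
coordinates are non-decreasing and the final point equals the totals over
mapped reads. The calibration histogram assigns each mapped read a
percentile = rank of its MAPQ among all mapped reads (mean rank on ties,
via `scipy.stats.rankdata`) scaled to [0, 100], then counts incorrect
reads in ten equal-width bins (last bin closed). Mean-rank ties make the
binning well defined when a mapper emits few distinct MAPQ values.

## Variant benchmarking (`gcatbench.vareval`)

**Normalization.** Multi-allelic records are decomposed at load; each
record is then canonicalized against the reference by the standard
algorithm: repeatedly trim a shared terminal base, left-extending with the
previous reference base whenever an allele empties, then trim shared
leading bases beyond the anchor. The result is minimal and left-aligned;
the operation is idempotent, and `compare` rejects inputs that fail cheap
minimality/sortedness checks rather than silently comparing mismatched
representations.

**Evaluability.** A record is evaluable iff its full reference footprint
lies inside one high-confidence interval and touches no excluded interval.
Non-evaluable test and truth records are tallied (`excluded_*`) but never
counted as TP/FP/FN.

**Complex-region exclusion.** For every truth indel, any other truth
variant starting within `window − 1` bases (default window 10 bp)
triggers exclusion of the interval spanning both variants' reference
footprints; intervals are merged. Nearby indel+variant combinations are
representation-ambiguous across pipelines, so no method is rewarded or
punished for its choice there. The window is configurable.

**Matching.** A test call matching an evaluable truth record on
(chrom, pos, ref, alt) — and genotype, by default — is a TP; each truth
record absorbs at most one call. Genotype-aware mode is the default
because a genotype truth set asserts genotypes, not just alleles; an
allele match with the wrong genotype therefore counts as one FP *and* one
FN (the asserted genotype was not produced). `--no-genotype` gives
allele-only matching. Calls with FILTER other than PASS/'.' are dropped by
default (`--include-filtered` reverses).

**True negatives** are counted per base: TN = confident bases − bases
covered by the union of truth and test reference footprints (intersected
with the confident regions). Because almost every confident base is
homozygous reference, specificity TN/(TN+FP) is near-saturated and the
reports flag precision as the more informative statistic.

**Quality ROC.** One point per distinct QUAL, descending: at threshold t,
calls with quality ≥ t keep their TP/FP status; a demoted TP becomes a FN
and a demoted FP joins the TN pool, so TPR = TP/(TP+FN) and
FPR = FP/(FP+TN) at every point. Calls without a QUAL sit below every
explicit threshold rather than being dropped; consequently the final point
reproduces the unthresholded counts exactly.

**Depth stratification** bins TP/FP records by the per-sample DP (INFO/DP
fallback) into half-open `[lo, hi)` bins; records without a usable depth
go to a trailing "unknown" stratum. FN records carry no caller depth and
are not binned — the strata support precision only.

## What the synthetic data does and does not show

The generator reproduces the *bookkeeping* conditions of a mapper/caller
benchmark: known truth at every site, exact read provenance, configurable
mutation and library parameters. It does not reproduce genomic repeat
structure, GC-dependent coverage bias, indel sequencing errors, quality
miscalibration or platform artifacts. Passing tests therefore demonstrate
that the *accounting* — judgments, counts, curves, exclusions — is exact,
and that simulation parameters are recovered at sampling precision; they
do not certify any particular mapper or caller's real-genome accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script use 1-Mb contigs for mutation-rate
recovery (≈1,000 truth variants; binomial 4-s.d. windows), 100-kb contigs
with 10,000 read pairs for library statistics (mean within 4 standard
errors, s.d. within 10%), a 5-Mb contig (≈500 indels) for the indel-length
bound, and ≤10-kb instances for the randomized oracle suites (200–1,000
cases per operation against per-base/brute-force re-implementations).
These sizes put every sampling check well inside its tolerance while the
whole suite runs in seconds. Percentages are reported to 2 decimals.
Degenerate inputs are explicit: 0/0 ratios are absent (never 0 or 1), an
empty comparison yields empty strata, zero mapped reads make percentiles
an error rather than NaN.

## Known limitations

- Matching is exact per-record after normalization; haplotype-path
  equivalence (vcfeval-style) is out of scope, which can over-count
  FP+FN in complex regions — the exclusion window exists precisely to
  remove most such sites.
- Structural variants, phasing, somatic allele fractions and trio designs
  are not modeled.
- The alignment judgment is positional only; CIGAR-level (per-base)
  accuracy is not assessed.
- `write_perfect_sam` emits ungapped alignments at true origins; it is a
  closed-loop fixture, not a mapper.
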