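# Methods

## Coordinates and counting

All internal coordinates are 0-based half-open (the BED convention); SAM and
GTF are converted at the parsing boundary. A "tag" is one aligned mate; both
mates of a pair contribute coverage over their aligned spans only, and the
library size used for all scaling is the number of aligned tags. Coverage is
built by difference arrays, so total depth mass always equals total aligned
bases.

## Input normalization

Every comparative score is a fold enrichment over the genomic input:

    FE = (stat_sample · 10⁶/N_sample + ε) / (stat_input · 10⁶/N_input + ε)

with `stat` the max depth for window/gene scores (mean where an average is
wanted) and pseudocount `ε = 1` in tags-per-million depth units. The
per-million scaling makes FE invariant to sequencing depth (doubling both
libraries changes nothing); `ε = 1` bounds scores, keeps all-zero regions at
exactly 1.0, and pulls weakly covered regions toward neutrality instead of
letting a near-zero denominator explode. The same `ε` is reused when
quantifying lncRNA candidate ratios, which is what stops sparse background
contigs (a few stray tags, zero RNAPII) from acquiring spuriously extreme
"stability" ratios.

The input library corrects mapping artifacts: a repeat-like locus attracts
reads from every library in proportion to that library's size, so its raw
depth is far above background while its FE stays near 1. The generator
plants exactly such a region (2% of each library's tags over 5 kb) to
exercise this correction.

## Transcriptional classes

Windows (10 kb, tiled from 0, trailing partial window kept and flagged) and
gene spans are scored on both axes; outlier fences are `Q3 + 1.5·IQR` with
linear-interpolation (type-7) quantiles. A region must *strictly* exceed a
fence to count as enriched (ties fall low); genes ≤ 300 bp are removed
before the fences are computed. The fence logic implies planted enriched
classes must be a minority — a fence computed on a distribution whose upper
quartile already sits in the enriched group detects nothing. Per-class
transcription efficiency is the trimmed mean (removing `ceil(trim·n)` per
tail; plain mean for classes of ≤ 2 members, which cannot be trimmed) of
per-region nucRNA:RNAPII score ratios.

## Stalling indices

For each gene, the promoter index is `max FE(TSS ± 300 bp) / mean FE(body)`
and the 3′ index the same at the TES. The body excludes *both* anchor
windows, so a large peak at one end cannot inflate the other index's
denominator; anchors are strand-aware and the definition is exactly
mirror-invariant. Genes ≤ 300 bp or too short to leave a non-empty body
(≤ 2·flank + 300) become reason-coded exclusion records. Categories
(promoter / 3′ / double / none) come from strict exceedance of the 95th
percentile of each index over defined records. A flat signal returns an
index of exactly 1.0 (special-cased: the floating-point mean of a constant
array can differ from the constant in the last ulp).

Two statistics accompany the records: tie-corrected Kruskal–Wallis on the
body nucRNA:RNAPII ratio across categories, and a Jonckheere–Terpstra trend
test of coverage across index quintiles. JT uses the tie-adjusted normal
approximation with a 0.5 continuity correction (the statistic is
half-integer valued); type-I error at α = 0.05 is 0.048–0.058 over 2000
null replicates, and the test suite checks small-sample agreement against
exhaustive permutation. The default alternative is one-sided decreasing
(high stalling, lower coverage).

## Regulatory-region nomination

The peak caller reimplements the strand-imbalance idea minimally: forward
tag 5′ ends and reverse tag 5′ ends are binned at 20 bp; a candidate summit
sits at each + → − sign change of the net count *between consecutive
non-empty bins* (the forward and reverse clusters of a real binding site
are separated by empty bins); summits closer than 40 bp merge, and a summit
survives only if the tag count in ± 100 bp beats a Poisson background at
the genome-average rate with p < 0.001. Externally-called peaks can be
supplied as BED and bypass the caller.

Subtraction removes any peak overlapping (≥ 1 bp) a merged nucRNA region
(gap ≤ 100 bp, ≥ 1 kb). Positional classification uses the peak midpoint
with fixed precedence TSS > gene body > upstream > downstream > intergenic;
up/downstream are strand-aware relative to the nearest gene and capped at
10 kb, so fractions always sum to 1.

Conservation enrichment counts bases > 0.8 in 1 kb around candidate
midpoints against matched random regions (same count and width, sampled
uniformly outside candidate footprints, seeded); TF enrichment tiles the
genome into 1 kb bins and crosses candidate-overlap with TF-overlap. Both
use natural-log odds with Haldane 0.5 correction applied only when a cell
is zero, and a Wald z p-value.

## lncRNA discovery

Strict pass: merge nucRNA tags at gap ≤ 2 kb, keep contigs ≥ 4.5 kb.
Sensitive pass: gap ≤ 1 kb, then merge surviving contigs separated by
< 5 kb, then keep ≥ 2.5 kb (merging precedes the size filter). Sensitive
contigs are added only when < 50% of their length is already covered by a
strict contig. Any candidate touching an excluded annotation (gene spans,
plus whatever pseudogene/rRNA/miRNA sets are supplied) by 1 bp is removed —
which also makes gene-overlapping (antisense/intronic) transcripts
structurally invisible to this method, a limitation asserted by a test
rather than hidden. Selection of stable nuclear transcripts defaults to a
boxplot fence on the candidates' nucRNA:RNAPII normalized-depth ratios
(mirroring the T-class logic); `top_n` and `min_ratio` rules are available,
and the rule plus threshold are recorded in every output.

## The synthetic-data generator

The generator is the package's study design, not a test convenience. Tag
starts are Poisson with per-base rate `rate · depth/10⁶` (rates in tags per
eligible start position per million nominal tags; tag length 36 bp), which
gives every expectation in closed form for the tests. Defaults, chosen once
as the conditions the pipeline is demonstrated under:

* **Genome:** 2 chromosomes × 1.2 Mb; features laid out 12–22 kb apart.
* **Genes:** 40 across classes BT/B/T/loBT = 4/4/4/28 with rate pairs
  (nucRNA, RNAPII) of (4, 4), (0.1, 4), (4, 0.1), (0.1, 0.15); enriched
  classes are a minority because boxplot fences can only flag minorities.
  Each gene carries a lognormal(σ = 0.4) expression multiplier on both
  rates — this models biological dispersion and is what makes replicate
  RPKM rank correlations (> 0.9 across seeds) meaningful. 3–5 exons of
  200–400 bp, introns 300–800 bp; nucRNA tags stay on exons always and on
  introns with probability 1 − splicing_fraction (default 0.5); RNAPII
  covers the whole unit, strand-balanced.
* **Stalling:** planted promoter/3′/double genes (1/1/1 by default, on B/BT
  genes) multiply the RNAPII rate ×10 in the TSS/TES ± 300 bp window;
  double genes carry 2× body nucRNA. The acceptance cohort for stalling
  recovery is 160 RNAPII-bound genes (B/BT 140/20) with 4/4/2 planted
  stalls: planted genes must stay under the ≤ 5% tail the 95th-percentile
  rule can flag, and the max/mean index is ill-behaved on the near-zero
  coverage of loBT genes — stalling is only a meaningful statistic where
  polymerase is present.
* **Enhancer-like elements:** 8 intergenic 300 bp elements at a B-gene
  RNAPII rate with TF-binding-style tag arrangement (forward tags upstream,
  reverse downstream of the summit), no nucRNA, a ≥ 200 bp conserved core
  (> 0.8) and 1–3 TF peaks; every TF also gets 30 random background peaks.
* **lncRNA units:** 4 stable (nucRNA 2.0, RNAPII 0.05) and 16 decoys
  (2.0, 2.0), 7–11 kb — the scale of Malat1/Xist-class stable nuclear
  transcripts; stable units are the minority so the boxplot selection fence
  applies, matching a world where most discovered contigs are not
  preferentially retained.
* **Background and input:** sample libraries have sparse intergenic
  background (10⁻⁴ tags/bp/Mtag, mean tag gap ~20 kb — dense backgrounds
  would fuse the whole genome under 1–2 kb gap merging); the input is
  uniform at 0.3 and deep. Nominal depth 5 × 10⁵ per library
  (~10⁵–4 × 10⁵ realized tags each), which keeps every full simulation
  around a second.

What the generator does **not** model: sequence (no FASTA, mismatches or
mappability beyond the planted artifact), fragment-length variation,
isoforms, antisense transcription, GC bias, or any coupling between
stalling and expression level. Passing tests therefore demonstrate that the
pipeline's inferences are correct *under its own stated model of the data*,
not that real libraries satisfy that model.

## Problem sizes and numerical choices

Acceptance-style checks run at: 10 seeds × 40 genes for class recovery,
3 seeds × 160 genes for stalling, 2000 replicates for type-I calibration,
20 seeds for null enrichment, 3 seeds × 20 units for lncRNA recovery, and
≥ 1000 random instances per brute-force oracle — the whole suite completes
in well under a minute of simulation time. Quantiles are type-7 everywhere;
average ranks break ties in all rank statistics; all randomness flows from
a single integer seed through named substreams, so every table and file the
pipeline writes is byte-reproducible.

## Known limitations

Contig boundaries from gap-merging extend past a transcription unit when a
stray background tag falls within the gap threshold — boundary precision
degrades as background density rises. The sensitive pass (merging before
its size filter, as specified) admits sparse background chains as
candidates; they are neutralized at selection by the shared pseudocount but
still appear in candidate counts. The 95th-percentile stalling rule fixes
its discovery fraction by construction (~5% per index) regardless of how
many genes are truly stalled. The peak caller is deliberately minimal and
is not a general-purpose replacement for a production ChIP-seq caller.
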