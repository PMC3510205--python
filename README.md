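# nucstate

Comparative analysis of **nuclear RNA output** (nucRNA-Seq) versus **RNA
polymerase II occupancy** (RNAPII-S5P ChIP-Seq), normalized against a genomic
input library — for epigenomics groups who want the classic three-library
erythroid design as a reusable, tested pipeline rather than a pile of
one-off scripts.

Given aligned tags for the three libraries, a gene annotation, a per-base
conservation track and TF peak sets, `nucstate`:

1. **Scores coverage.** Per-base depth per library; region scores as
   *fold enrichment over input*,
   `FE = (s·10⁶/N_s + ε) / (i·10⁶/N_i + ε)` with `ε = 1`, where `s`, `i` are
   the max (or mean) depth of sample and input in the region and `N` the
   library sizes. RPKM per gene, 10 kb window scores, exon/intron coverage by
   gene thirds.
2. **Assigns transcriptional classes.** Boxplot outlier fences
   `Q3 + 1.5·IQR` on the nucRNA and RNAPII score distributions partition
   windows/genes into **BT** (bound + transcribed), **B** (bound only),
   **T** (transcribed only) and **loBT**, plus per-class transcription
   efficiency (5% trimmed mean of nucRNA:RNAPII ratios).
3. **Computes stalling indices.** Per gene,
   `max FE(TSS ± 300 bp) / mean FE(gene body)` (and the mirrored 3′-end
   index); genes exceeding the 95th percentile of either index are
   categorized promoter / 3′ / double; Kruskal–Wallis on body RNA:polymerase
   ratios and Jonckheere–Terpstra trend tests across index quintiles.
4. **Nominates regulatory regions.** A minimal SISSRs-style strand-imbalance
   peak caller (p < 0.001 Poisson background) finds RNAPII peaks; peaks
   overlapping merged nucRNA regions (gap ≤ 100 bp, ≥ 1 kb) are subtracted,
   leaving **RNAPII+/nucRNA−** candidates, which are positionally classified
   (TSS ± 500 bp / gene body / ± 10 kb / intergenic) and tested for
   conservation (> 0.8 in 1 kb around midpoints vs matched random regions)
   and TF-peak overlap (1 kb genome bins) by log-odds ratios.
5. **Discovers lncRNA candidates.** Contig building over nucRNA tags in a
   strict pass (2 kb gap, ≥ 4.5 kb) plus a sensitive pass (1 kb gap,
   ≥ 2.5 kb, merging within 5 kb), exclusion of anything touching annotated
   genes, and selection of stable nuclear transcripts by outlying
   nucRNA:RNAPII depth ratios.

A first-class synthetic-data generator (`nucstate.synthetic_data`) emulates
all three libraries over a toy genome with planted gene classes, stalling
configurations, enhancer-like elements, lncRNA units and a mapping-artifact
region, so the whole pipeline is testable end-to-end with known ground truth.

## Worked example

```
$ nucstate simulate --seed 1 --outdir demo/data
dataset written to demo/data (seed=1)
$ nucstate run-all --data demo/data --outdir demo/report
report in demo/report: 40 genes classified, 102 RNAPII+/nucRNA- candidates, 4 stable lncRNA candidates
```

`demo/report/summary.json` from that run contains (abridged):

```
class_counts  {'B': 4, 'BT': 4, 'T': 4, 'loBT': 28}
efficiency    {'B': 0.038, 'BT': 1.148, 'T': 12.613, 'loBT': 0.811}
conservation_log_odds  8.09      tf_combined_log_odds  2.49
n_selected_lncrna      4
```

Reading this: the boxplot fences recover exactly the planted 4/4/4/28 class
structure; T-class genes produce ~12.6× more RNA per unit polymerase than
BT genes (high nucRNA with little RNAPII — the signature of stable nuclear
transcripts); the RNAPII+/nucRNA− candidates are strongly enriched for the
planted conserved, TF-bound enhancer-like elements; and ratio selection
flags exactly the 4 planted stable lncRNA units (none of the 16 low-ratio
decoys).

The library API mirrors the CLI — see `nucstate.pipeline.analyze` for the
in-memory entry point and the module docstrings (`coverage`,
`expression_classes`, `stalling`, `regulatory`, `lncrna`, `stats`) for each
stage.

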