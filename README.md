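# k4balance

Statistical toolkit for quantitative chromatin experiments in which
absolute signal levels matter: permutation-based overlap-enrichment
testing of peak sets, spike-in-normalized ChIP-seq and ChIP-qPCR
quantification, TMT IP-MS hit calling, and per-nucleus quantitative
immunofluorescence. It was built for the kind of study that asks whether a
chromatin reader's binding sites coincide with particular histone marks
(e.g. H3K4me1/me2/me3) and whether depleting a regulator changes those
marks *globally* — a question ordinary read-depth normalization cannot
answer, because it silently rescales away genome-wide losses.

## What it computes

**Overlap enrichment (permutation null).** For a query peak set *Q* and an
annotation peak set *A* on a genome with exclusion regions (gaps,
blacklist), the observed statistic is the base-pair overlap
`obs = |Q ∩ A|`. A null distribution is built from *N* genome-wide
shuffles of *A* that conserve each peak's exact length, avoid the excluded
regions entirely, and (for tiling-array annotations) preserve each peak's
microarray probe density within ±0.1 probes/bp for ≥99% of peaks. With
`null₁…null_N` the shuffled overlaps,

    expected = mean(null),   log2E = log2((obs + 1)/(expected + 1)),
    p = (1 + #{nullᵢ at least as extreme as obs}) / (N + 1)

so the smallest attainable p at N = 1000 is 1/1001 ≈ 0.001. Across a panel
of annotations, p-values are Benjamini–Hochberg corrected. An
interval-level Fisher's exact test on co-occurrence of two peak sets is
also provided.

**Spike-in ChIP-seq.** Barcoded synthetic nucleosomes are spiked into
chromatin before IP; within each biological replicate the scale factor is
`reference barcode reads / test barcode reads`, applied to 50-bp binned
mean-depth coverage. Peak-centered metaprofile matrices (sorted by mean
occupancy) quantify signal around region centers.

**Spike-in ChIP-qPCR.** `%Enrichment = 2^(CtInput − CtIP)/input% × 100`,
divided by the spike amplicon's percent input, then rescaled within each
replicate so the reference target amplicon in the reference condition is
exactly 1.

**TMT IP-MS.** Peptides with >25% coisolation interference are removed;
channels are normalized to equal totals then equal medians; unique/razor
peptides are summed per protein; bait vs. control is tested with an
equal-variance Student t-test on log2 abundances (hit: p < 0.05 and
positive log2 fold change).

**Quantitative IF.** Per-nucleus marker intensity is divided by DAPI
intensity (DNA content), replicates are pooled, 1,000 nuclei are sampled
per condition, and groups are compared with a tie-corrected
Kruskal–Wallis test (Holm-corrected pairwise rank tests as post-hoc; a
one-way ANOVA + Tukey path is available).

Every stage has a seeded synthetic-data generator with planted ground
truth (`k4balance.synthetic_data`), so the full pipeline runs and is
testable with no external downloads.

## Worked example

Simulate a toy genome (2 × 500 kb, 5% gaps) with an annotation set and a
query set planted to overlap it 4× more than uniform placement, then run
the permutation test with 1,000 shuffles:

```sh
k4balance simulate enrichment --seed 7 --out demo
k4balance enrich --query demo/query.bed --annotations demo/annotation.bed \
    --genome demo/genome.chrom.sizes --exclude demo/excluded.bed \
    --n 1000 --seed 7 --out demo/enrichment.tsv
```

which prints:

```
annotation  observed_bp  expected_bp  log2_enrichment direction  p_empirical  q_value  n_permutations  matched_fraction
annotation         6134     1788.003         1.777908  enriched     0.000999 0.000999            1000               1.0
```

Reading this: the query overlaps the annotation by 6,134 bp where random
length-matched placement of the annotation yields 1,788 bp on average — a
2^1.78 ≈ 3.4-fold enrichment, matching the realized planted ratio recorded
in `demo/truth.json` (3.43; the realized ratio fluctuates around the
planted 4× at this peak count). The observed overlap exceeded all 1,000
null values, so the empirical p is at its floor 1/1001 ≈ 0.001, the
smallest p a 1,000-permutation test can report.

The same `simulate` command generates inputs for the other subcommands
(`spikein-scale`, `coverage`, `metaprofile`, `qpcr`, `tmt`, `ifquant`);
each is a thin wrapper over the library functions in
`k4balance.<module>`.

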