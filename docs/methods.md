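# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions a maintainer would otherwise have to
reverse-engineer.

## Interval model

Coordinates are 0-based half-open (BED convention) throughout. Book-ended
intervals merge into one interval but share zero overlapping bases.
`overlap_bp`, `subtract` and `merge` operate on the union of covered
bases, so duplicated or overlapping records never double-count; all three
are verified against a per-base boolean-array oracle in the test suite.
Records on unknown chromosomes or out of bounds raise instead of being
dropped: a silently dropped record biases every downstream overlap
statistic, and the error surfaces the mismatch (usually a genome-build
mixup) immediately.

The interval-level Fisher test needs a finite universe of "trials" that
the data do not define. We count intervals of each merged set that touch
the other, and approximate the "neither" cell as
`floor(uncovered_genome_bp / mean_interval_length(a ∪ b))` — the number of
interval-sized slots in the untouched genome. This matches common practice
for genome-scale 2×2 co-occurrence tests; the resulting p-value should be
read as an association screen, not an exact probability model.

## Shuffle null

The null hypothesis is that the annotation's peaks are positioned at
random with respect to the query, subject to what is physically knowable:
peak lengths, inaccessible genome (gaps/blacklist), and — for tiling-array
data — local probe availability.

* **Length matching** is exact: the multiset of peak lengths is conserved
  in every shuffle.
* **Exclusion regions** may not be touched at all (no partial overlap).
  Placement is sampled *exactly* uniformly over all valid start positions
  genome-wide: the complement of the exclusion set is decomposed into
  allowed regions, the number of valid starts for the peak's length is
  counted per region, and a single uniform integer indexes into that
  space. Chromosome choice is therefore implicitly weighted by valid
  starts, and no rejection sampling is needed for this constraint.
* **Probe-density matching** (tiling-array annotations) is rejection
  sampling: a placement is redrawn until the probe density of the
  shuffled peak (probe midpoints per bp) is within `density_tolerance`
  (default 0.1) of the original, up to `max_attempts_per_peak` (default
  1000) draws. Once at least `min_matched_fraction` (default 0.99) of
  peaks match, remaining peaks keep their final draw; below the quota the
  shuffle fails loudly with diagnostics. Midpoints rather than any-overlap
  are counted so a probe straddling a peak edge is not credited to both
  sides.
* Peaks are placed independently and may overlap each other; the
  procedure models random positioning, not a physical non-overlapping
  packing, and independent placement keeps the null exchangeable.
* Permutation *i* uses seed `seed_base + i`, so each permutation is
  individually reproducible and shuffles are embarrassingly parallel.
  Within a panel, annotation *j* offsets its seed block by
  `j × (n_permutations + 1)` so no two permutations anywhere share a seed.

Shuffling moves peaks across chromosomes by default. Confining shuffles
to the source chromosome is a stricter null (preserving chromosome-level
composition) that the `excluded` mechanism can emulate by masking all
other chromosomes.

## Enrichment statistic

`observed_bp` is compared to the null overlaps of `n_permutations`
(default 1000) shuffles **of the annotation** — the annotation is what
the null randomizes; the query stays fixed. The expected overlap is the
arithmetic mean of the null (median available via `expected_summary`).
Enrichment is `log2((obs + ε)/(expected + ε))` with ε = 1 bp, which keeps
zero-overlap cases finite; a result with `obs = expected = 0` is flagged
`untestable` rather than reported as a log-ratio of pseudocounts.

The empirical p uses the add-one estimator `(1 + k)/(N + 1)` with ties
counted as extreme, so p is never 0 and its floor at N = 1000 is
1/1001 ≈ 0.001. By default the tested tail follows the observed direction
(enrichment if `obs ≥ expected`, depletion otherwise), which is the
natural screen when either effect is of interest; note that this adaptive
p is distributed on (0, ½] under the null (it is the smaller of two
one-sided tails), so for calibration studies or strictly one-sided
hypotheses the `alternative="enriched"` / `"depleted"` option fixes the
tail, making the null p exactly uniform by rank exchangeability. Panel
q-values are standard step-up Benjamini–Hochberg (via statsmodels),
applied across the annotations tested against one query.

## Spike-in ChIP-seq

The scale factor is `reference barcode reads / test barcode reads` within
a biological replicate; the reference sample's own factor is 1. Coverage
bins hold *scaled mean per-base depth*, not raw counts: the mean is
well-defined for the final partial bin and makes the track exactly linear
in the scale factor (the scale is applied after the depth/width
division). The divergence from count-per-bin conventions is a constant
factor `1/bin_size` on full bins. Tracks are written as text bedGraph
(run-length merged), which round-trips bit-exactly and diffs cleanly.
Metaprofile windows are centered on interval midpoints (floor division
for odd lengths), zero-padded and flagged where they run off a
chromosome, and rows are sorted by descending mean for occupancy
heatmaps.

## ChIP-qPCR

`%Enrichment = 2^(CtInput − CtIP) / input_percent × 100` — the standard
ΔCt reading of the percent-input formula. Technical triplicates are
averaged as mean Ct before the ΔCt (averaging after exponentiation would
weight outlier wells geometrically; either choice is defensible, this one
is documented). No dilution-factor Ct adjustment is applied beyond the
input-percent divisor. Spike normalization divides each amplicon's
percent input by the spike amplicon's percent input in the same sample,
cancelling per-sample IP efficiency; reference rescaling then divides
every value within a replicate by the (reference amplicon, reference
condition) value, which is therefore exactly 1 in every replicate. The
chain is invariant to any per-replicate multiplicative factor.

## TMT hit calling

Peptides with coisolation interference **strictly greater than** 25% are
removed (a peptide at exactly 25% survives). Channel normalization is two
steps: (1) each channel is scaled so its total equals the across-channel
mean total (assumes comparable background across IPs); (2) each channel
is divided by its median peptide abundance, equalizing channel medians.
Step 2 deliberately does not re-inflate by a global constant: written
this way the composed map is exactly idempotent (normalizing twice is a
no-op), which makes accidental double normalization harmless, and any
global constant cancels in the downstream log-ratio test anyway.
"Unique or razor" peptides are summed per protein; proteins with no
qualifying peptide are dropped. The test is an equal-variance two-sample
Student t-test on log2 abundances (log transform stabilizes the
multiplicative error of reporter-ion data; whether to log-transform is a
genuine choice and is documented here as ours). Zero abundances are
floored at the smallest positive value in the matrix before log2. A hit
requires p < 0.05 *and* positive log2 fold change toward the bait.

## Quantitative IF

Each nucleus contributes `marker / DAPI`, removing DNA-content (ploidy /
cell-cycle) variation. Replicates of a condition are pooled before
sampling (per-replicate stratified sampling is available), 1,000 nuclei
are drawn without replacement per condition with a per-condition seed,
and the omnibus test is Kruskal–Wallis with tie correction and the
chi-square approximation (k − 1 df). The degenerate all-values-identical
case returns H = 0, p = 1. Post-hoc comparisons are pairwise two-sided
Mann–Whitney tests with Holm correction. A parametric one-way ANOVA +
Tukey HSD path is provided as an alternative because practice in the
field uses both families of tests for this design; the rank-based path is
the default since per-nucleus intensity distributions are right-skewed
and heavy-tailed.

## Synthetic data

Defaults were chosen once to mirror the experimental designs the package
serves, at a scale where every stage runs in seconds:

* **Genome**: 2 chromosomes × 500 kb, 5% exclusion (2-kb gaps). Large
  enough that 1,000-permutation nulls are stable; small enough for
  seconds-scale tests.
* **Enriched query**: each query peak is placed fully inside the
  annotation with probability `p_in = f(r − 1)/(1 − f)` (planted ratio
  r ≥ 1; `f` = annotation fraction of the placeable genome), fully outside
  with probability `1 − r` (r < 1), uniformly otherwise — giving expected
  overlap `r × f × length` per peak. The truth records both the planted
  and the realized ratio; recovery tests compare against the planted
  value, so finite-sample fluctuation of the realized ratio is part of
  the measured error.
* **Spike-in reads**: genomic reads Poisson at `n_reads × g` per
  condition (g the planted global scale, default test g = 0.5), placed
  uniformly within signal regions; barcode reads Poisson at a constant
  rate (default 2,000) on 6 barcode contigs. 20,000 genomic reads keep the
  Poisson error of the recovered scale under a few percent.
* **Ct tables**: 3 replicates × 2 conditions × 4 amplicons (reference
  target, second target, negative locus, spike), per-replicate IP
  efficiency drawn from U(0.5, 1.5), planted fold change on targets only,
  N(0, sd) noise on every Ct (default 0.1 cycles, the scale of averaged
  technical triplicates).
* **Peptide matrices**: 500 proteins × 5 peptides, lognormal base
  abundance, 5 proteins 8-fold enriched in 3 bait vs. 3 control channels,
  10% channel CV, exponential(10%) coisolation so a realistic minority of
  peptides is filtered, 95% unique/razor.
* **Nucleus tables**: lognormal marker (σ = 0.4) and DAPI (σ = 0.2)
  intensities, 3 replicates × 400 nuclei per condition, planted 1.5×
  marker shift in the treated condition.

What the generators do **not** emulate: mappability and GC structure,
correlated placement of peaks (clustering along chromosomes), read-depth
overdispersion beyond Poisson, amplification-efficiency differences
between qPCR primers, peptide-level missingness in MS data, and
segmentation errors in IF. Passing tests therefore demonstrate that the
estimators recover planted effects under clean sampling noise — they
validate the statistical machinery, not robustness to those artifacts.

## Problem sizes in the validation suite

The test suite runs the calibration and recovery studies at reduced but
statistically sufficient sizes: null calibration uses 200 simulated
datasets at 99 permutations each (the uniformity of a rank-based p does
not depend on the permutation count); planted-enrichment recovery uses 50
datasets at 100 permutations; the p-floor check uses the full default
1,000 permutations. These sizes were fixed when the suite was written.

## Known limitations

* The shuffle null conditions on lengths and probe density only; peak
  sets with strong sequence-composition biases would need a GC- or
  mappability-matched null, which is out of scope.
* The Fisher "neither" cell is an approximation (see above); treat its p
  as a screen.
* The empirical p's resolution is 1/(N + 1); claims below 0.001 require
  more than 1,000 permutations.
* qPCR quantification assumes perfect (2×/cycle) amplification
  efficiency for all primers.
* The TMT test assumes equal variances between groups (the Student form);
  with ≥3 channels per group a Welch variant would be a small change but
  is not currently exposed.
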