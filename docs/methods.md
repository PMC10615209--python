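# Methods

## Coordinate conventions

Printed genome positions (e.g. `ch11:47,124,456` on an SL4.0-style frame) are
1-based and live in `Locus`; all internal intervals are 0-based half-open
(BED semantics), so `length = end - start`. Printed ranges are read with an
exclusive end — the convention under which the 17,396-bp deleted fragment
`ch11:47,301,154-47,318,550` has length exactly `end - start`. "Proximal"
and "distal" are defined relative to the centromere recorded in the
`GenomeMap`: proximal = centromere side of the break, distal = telomere side.
Only chromosomes listed in the `GenomeMap` participate in window tiling and
normalization baselines, which is how organelle and scaffold contigs are kept
out.

## Dosage estimation

Window counts are normalized within-sample. Baseline windows (unmasked, and
optionally restricted to chromosomes believed unrearranged) are stratified
into deciles of GC fraction; the decile mean raw count is the diploid
expectation μ_g, and dosage is `2·n(w)/μ_g(w)`. Choices:

* **Mask first, stratify second.** Masked windows (centromeres by default,
  where repeat-driven mapping artifacts distort counts) never enter the
  decile fit.
* **Ties at a decile edge go to the lower decile** (searchsorted on the
  empirical quantile edges); GC values outside the fitted range are clamped
  into the terminal strata with a warning.
* **Empty strata are merged with a neighbour** (possible when GC is highly
  discrete); all-identical GC degenerates to a single stratum equal to global
  mean normalization.
* The baseline assumes rearrangements affect a small genome fraction. When a
  specific chromosome is under suspicion (the pipeline's default for the
  break chromosome), it is excluded from the baseline; the estimate is then
  unbiased even for chromosome-scale events such as monosomy.

By construction the mean dosage of baseline windows is 2; scale invariance
(multiplying all counts by a constant leaves dosage unchanged) and GC-bias
removal (|r(dosage, GC)| < 0.05 on diploid simulations where raw counts
correlate strongly) are enforced by tests.

## Break classification

Each 1-Mbp flank is measured from the edges of the window containing the
break coordinate, so the break-overlapping window belongs to neither flank
and an aligned break yields exactly 200 five-kb windows per side. Four
simple hypotheses with fixed dosages are evaluated per flank — 2× (no
rearrangement), 0.01× (full deletion; kept slightly above zero so the
Poisson mean never degenerates), 1× (arm deletion), 3× (duplication) — with
window counts Poisson(μ_g·d/2). The reported statistic is
Λ = 2(lnL_best − lnL_2×) against χ²₁, with p = 1 when the null itself wins.
The χ²₁ reference is a convention (the hypotheses are simple, not nested
families); it is validated empirically: under 2,000 diploid replicates at
depth 10/copy the fraction of flanks reaching p < 0.001 is ≤ 0.005, because
the fixed alternatives sit far from the null. A permutation option
(shuffling window-to-flank labels) is available for exactness. Flanks are
tested independently; there is no joint two-flank model, matching how
per-side dosages are reported.

`scan_chromosome` extends the per-site test to a grid of candidate breaks.
Candidates are ranked by a *changepoint* likelihood ratio — independent
per-flank best hypotheses versus one hypothesis shared by both flanks —
because the per-flank statistic alone peaks anywhere inside a uniformly
deleted arm rather than at its boundary. Ties break deterministically to the
lower coordinate.

## LOH genotyping and mechanism

Genotypes are two-state calls from biparental allele depths: heterozygous
when the minor-parent fraction is ≥ `het_fraction` (default 0.2) at total
depth ≥ `min_depth` (default 8); below that depth the call is missing. At
depth 30 and balanced alleles the analytic heterozygote miscall probability
(binomial tail below 6 or above 24 of 30) is ~3·10⁻⁴. The defaults are the
package's own conservative choices; raw allele fractions are kept in the
output so unusual ratios (e.g. 2:1 in a trisomic flank) remain visible
rather than being flattened by the two-state call.

The het→hom transition is a single changepoint minimizing call
misclassification over a two-run model, with ties resolved toward the break;
all-het chromosomes report no event and single-parent chromosomes report
whole-chromosome homozygosity. Mechanism resolution combines the transition
with the dosage evidence:

* **crossover** — transition brackets the break and both flanks classify as
  no-rearrangement (the unchanged read counts are what rules out a loss);
* **segmental loss** — homozygous extent is distal and that flank classifies
  as arm deletion (1×);
* **chromosome loss** — chromosome-wide homozygosity with chromosome-wide
  median dosage ≈ 1 (tolerance 0.25);
* anything conflicting is **undetermined**, with diagnostics.

A crossover cannot be distinguished from a long gene-conversion tract from a
single sample (that needs the reciprocal product); marker presence
(`present`/`partial`/`absent`) is read from the dosage over the marker
interval with a ~0 threshold of 0.3×, and transgene silencing is outside the
model (a silenced marker is simply `present`).

## Junction detection

Evidence records are BEDPE read pairs; the junction-proximal end of a read
('+': high coordinate, '−': low) estimates the breakpoint. Records sharing
chromosomes and strand configuration cluster when their positions co-locate
within `max_gap` (default 500 bp, the short-read insert scale) on both sides;
clusters are exactly the connected components of that proximity relation
(verified against a brute-force all-pairs oracle), breakpoints are medians,
and clusters under `min_support` (default 3) are discarded. Orientation
classes: strands agree → forward adjacency, disagree → inverted; reversing
both strands (reading the junction from the other side) leaves the class
unchanged. An inverted-duplication fragment inserted into another chromosome
produces one forward and one inverted junction at the insertion site plus a
fold-back (+/−) junction at the original cut — the full diagnostic
signature. No split-read base-level refinement is attempted (the simulator
emits pair-level evidence only), and insertion sites are treated as
arbitrary: no sequence-motif model is applied.

## Simulator

The generator is first-class, tested code and defines the benchmark
conditions:

* **Events.** Karyotypes are ordered oriented segment lists per chromosome
  copy with per-segment parental haplotype. `cut` splits at a source
  coordinate; `fuse_sisters` concatenates a broken chromatid with its
  reversed, orientation-flipped image (palindromic dicentric);
  `bridge_break` draws the anaphase break uniformly between the two
  centromeres, leaving one derivative with an inverted duplication;
  `reintegrate` splices a micronuclear fragment elsewhere. Base-pair content
  is conserved exactly at every step (what leaves a chromosome goes to
  `lost_fragments` or the micronucleus pool); the micronucleus pool and lost
  fragments do not contribute to expected dosage, i.e. micronuclear DNA is
  treated as unsequenced until reintegration.
* **BFBC builder.** Bridge breaks are redrawn until the inverted duplication
  spans at least `min_duplication_bp` (default 2 Mb), reflecting the
  megabase-to-~20-Mb scale of observed BFBC duplications and guaranteeing the
  1-Mbp analysis flank sits inside the duplicated region.
* **Counts.** Poisson with mean `per_copy_depth × copies × bias(GC)`.
  Window GC is Beta(6, 8) scaled to [0.15, 0.60] (typical plant-genome
  window GC); the default bias curve is a smooth unimodal multiplier peaking
  near 38 % GC with a floor of 0.25. An optional gamma–Poisson
  overdispersion knob inflates variance (default off: plain read counting is
  the minimal model). Chimeric tissue is a two-karyotype mixture with one
  mixing fraction; arbitrary mosaics are out of scope.
* **SNPs.** Total depth Poisson(depth × copies/2), split binomially by
  haplotype copy number — so a crossover keeps full depth while
  homozygosing, and an arm loss halves depth distal to the break.
* **Junctions.** Poisson support per novel adjacency; junction-side read
  ends sit within a configurable jitter of the true breakpoint (0 = exact).
* **Seeding.** One root seed; every observation channel uses an independent
  `SeedSequence` substream, so a fixed seed is byte-reproducible and the GC
  landscape is shared between samples simulated under the same seed.

What the simulator does **not** emulate: alignment and mappability artifacts
(beyond a static mask), repeat-driven coverage spikes at centromeres,
library-preparation waves, split reads, or sequencing error in SNP alleles.
Passing tests therefore demonstrate correctness of the inference given the
count/multinomial observation model, not robustness to every artifact of
real short-read data.

## Benchmark problem sizes

The bundled demo genome has three chromosomes (98.5, 68.5, 55.4 Mb; the
last mirrors a real 55.4-Mb chromosome with its centromere at 23.24 Mb and
carries the real break and marker coordinates), with ±1.5-Mb centromeric
masks. Benchmarks use 5-kb windows around the break (44,480 windows
genome-wide) at 25 reads/window/copy, 250-kb windows for genome-wide
summaries, 2,000 replicates for null calibration on a single 4.2-Mb toy
chromosome, and 100 replicates per condition for power and LOH-recovery
rates on a two-chromosome toy genome — sizes chosen so the whole suite runs
in well under a minute per criterion while keeping Monte-Carlo error far
inside the acceptance bands. The minimum-coverage power check uses 5
reads/window/copy, the package's conservative reading of ×5 minimum
coverage.

## Known limitations

* The χ²₁ p-value is a calibrated convention, not an exact null (see above).
* Dosage hypotheses are the four fixed levels; continuous dosage lives in
  the estimator, not the test, and intermediate chimera levels (e.g. 1.5×)
  are classified to the nearest supported hypothesis.
* `detect_transition` fits one changepoint per chromosome; multiple LOH
  tracts on one chromosome would need segmentation beyond scope.
* Whether a retained centromeric minichromosome underlies an apparent
  whole-chromosome loss cannot be resolved from coverage alone; the
  simulator supports both scenarios but the classifier reports
  chromosome-scale loss either way.
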