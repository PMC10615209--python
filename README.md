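# lohscan

Analysis of what happens to a diploid genome after a CRISPR–Cas9
double-strand break (DSB) that is *not* cleanly repaired: loss of the distal
chromosome arm, whole-chromosome loss, breakage–fusion–bridge cycles (BFBC)
that leave inverted megabase-scale duplications, chromothripsis-like
translocations of shattered fragments — or a copy-neutral somatic crossover.
`lohscan` implements the whole read-depth / SNP / junction workflow needed to
tell these outcomes apart from whole-genome sequencing of a single plant (or
any diploid sample), together with a ground-truth karyotype simulator that
generates all of these events for testing and benchmarking.

It is aimed at people analysing CRISPR loss-of-heterozygosity (LOH) screens
in plants or other diploids: given windowed read counts, biparental SNP
allele depths and discordant read-pair evidence, it answers "what happened at
the break?"

## The model

**Dosage.** The genome is tiled into windows (250 kb genome-wide, 5 kb around
the break). Window read counts are normalized within-sample for GC bias:
unmasked baseline windows are split into deciles of GC fraction, and the
decile mean count μ<sub>g</sub> is the diploid expectation. The dosage of
window *w* in GC decile *g* is

&nbsp;&nbsp;&nbsp;&nbsp;D(w) = 2 · n(w) / μ<sub>g(w)</sub>,

so a diploid region reads 2×, a hemizygous region 1×, an extra copy 3×, and a
region deleted in half the cells of a chimeric tissue 1.5×.

**Break classification.** Each 1-Mbp flank of the declared cut site is tested
against four fixed-dosage hypotheses — no rearrangement (2×), full deletion
of both homologs (0.01×), single arm deletion (1×), duplication (3×) — with
window counts modelled as Poisson(μ<sub>g(w)</sub>·d/2). The best alternative
is compared with the 2× null through Λ = 2(ln L<sub>best</sub> −
ln L<sub>2×</sub>) referred to χ²₁; flanks with p < 0.001 are called
rearranged. A BFBC derivative shows the diagnostic 3×→1× transition at the
break (duplication proximal, arm deletion distal).

**LOH mechanism.** Biparental SNP depths give heterozygous/homozygous calls;
the het→hom transition is located by a single-changepoint fit. Combining it
with the dosage evidence separates a crossover (transition at the break,
dosage 2× on both sides — read counts unchanged), a segmental loss
(homozygous extent at 1×) and whole-chromosome loss (chromosome-wide
homozygosity at 1×).

**Junctions.** Discordant read pairs are clustered into junction calls
(median breakpoint, strand-configuration orientation). A fragment inserted
with one inverted and one forward copy — the signature of an
inverted-duplication translocation after a second BFBC round — yields one
inverted and one forward junction at the insertion site.

**Simulator.** Karyotypes are ordered, oriented segment lists manipulated by
the BFBC event algebra (cut, sister fusion into a palindromic dicentric,
uniform bridge break between centromeres, micronuclear reintegration), with
exact base-pair accounting. Observations are Poisson counts with a
configurable GC-bias curve, multinomial SNP allele depths, and BEDPE read
pairs over every novel adjacency.

## Worked example

```sh
lohscan demo --scenario bfbc --seed 7 --outdir demo_bfbc
```

```
ch01: median dosage 1.99
ch09: median dosage 1.99
ch11: median dosage 2.03
break classification: duplication/arm_deletion
LOH mechanism: segmental_loss
```

The simulated plant carries one BFBC derivative of chromosome 11: reading
along the chromosome, the genome-wide median dosage still looks diploid
(2.03×, because the duplicated and deleted regions balance in the median),
but the 5-kb zoom at the cut site (ch11:47,124,456) shows the 3×→1×
transition: the proximal flank was duplicated in inverted orientation by the
bridge break and the distal arm was lost, so the break is classified
`duplication/arm_deletion` (both flanks p < 0.001), and the SNP track shows
heterozygosity giving way to one parent distal to the break — a segmental
loss, not a crossover. All intermediates (window counts, GC track, dosage
bedGraph, SNP calls, junction BEDPE, classification TSV, JSON report) are in
`demo_bfbc/`.

The same stages are available as composable subcommands over files:
`lohscan simulate | dosage | classify | loh | junctions | report`, or as the
Python API (`lohscan.simulate`, `lohscan.dosage`, `lohscan.lrt`,
`lohscan.loh`, `lohscan.junctions`).

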