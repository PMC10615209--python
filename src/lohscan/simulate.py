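"""Observation models and rearrangement scenarios for synthetic WGS data.

This module turns a ground-truth :class:`~lohscan.events.Karyotype` into the
three observation tables the analysis stages consume:

* windowed read counts with per-window GC fraction — Poisson counts whose
  expectation is proportional to local copy number times a GC-bias curve;
* biparental SNP allele depths — Poisson total depth split binomially over
  the parental alleles actually present at the locus;
* chimeric junction read pairs — BEDPE-like records spanning every
  non-reference adjacency of the karyotype.

Scenario builders compose the BFBC event algebra into the rearrangement
classes observed after an unrepaired CRISPR break: distal arm loss, whole
chromosome loss, BFBC inverted duplication, interstitial deletion (optionally
as a chimeric cell mixture), somatic crossover, and translocation of an
inverted-duplicated fragment into another chromosome.

Seeding: each simulation derives independent substreams from one root seed
via ``numpy.random.SeedSequence``, so a fixed seed gives byte-identical
output and the GC landscape is shared between samples simulated from the
same seed.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .events import (FORWARD, INVERTED, DerivedChromosome, EventError, Karyotype,
                     Segment, bridge_break, cut, fuse_sisters,
                     inverted_duplication, project_dosage, reintegrate,
                     _split_segments_at_source, _split_at_derived)
from .genome import GenomeMap, Interval, Locus

# ---------------------------------------------------------------------------
# demo genome: a reduced three-chromosome frame in SL4.0-like coordinates.
# ch11 carries the real break/marker coordinates used throughout the package.

DEMO_BREAK = Locus("ch11", 47_124_456, "gRNA2")
DEMO_MARKER = Interval("ch11", 47_301_154, 47_318_550)
DEMO_MARKER_INSERTION = Locus("ch11", 47_305_369, "pX11")
DEMO_CLV3 = Locus("ch11", 52_945_095, "CLV3")


def demo_genome(mask_radius: int = 1_500_000) -> GenomeMap:
    """Three-chromosome demo frame; ch11 mirrors the tomato SL4.0 chromosome
    (55.4 Mb, centromere at 23.24 Mb); centromeric windows are masked."""
    chromosomes = [("ch01", 98_500_000), ("ch09", 68_500_000),
                   ("ch11", 55_400_000)]
    centromeres = {"ch01": 49_200_000, "ch09": 34_200_000, "ch11": 23_240_000}
    masks = [Interval(c, max(0, p - 1 - mask_radius), p - 1 + mask_radius)
             for c, p in centromeres.items()]
    return GenomeMap(chromosomes, centromeres, masks)


# ---------------------------------------------------------------------------
# observation config

def default_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Smooth unimodal coverage multiplier peaking near 38% GC."""
    gc = np.asarray(gc, dtype=float)
    return 0.25 + 0.75 * np.exp(-0.5 * ((gc - 0.38) / 0.10) ** 2)


def flat_gc_bias(gc: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(gc, dtype=float))


@dataclass
class ObservationConfig:
    """Knobs of the window-count observation model.

    per_copy_depth is the expected number of reads per window contributed by
    one chromosome copy (a diploid window averages twice that).
    chimera_fraction is the proportion of cells carrying the rearranged
    karyotype; the remainder carry a companion karyotype (default: intact
    diploid).  gc_bias may be a callable on GC fraction or a sequence of 10
    per-decile multipliers; overdispersion > 0 inflates the count variance
    gamma-Poisson style (variance multiplier 1 + overdispersion * mean).
    """

    window_size: int = 5_000
    per_copy_depth: float = 25.0
    seed: int = 0
    chimera_fraction: float = 1.0
    gc_bias: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None
    gc_range: tuple[float, float] = (0.15, 0.60)
    gc_beta: tuple[float, float] = (6.0, 8.0)
    overdispersion: float = 0.0

    def __post_init__(self):
        if self.window_size <= 0 or self.per_copy_depth <= 0:
            raise ValueError("window_size and per_copy_depth must be positive")
        if not 0.0 <= self.chimera_fraction <= 1.0:
            raise ValueError("chimera_fraction must be in [0, 1]")

    def bias_values(self, gc: np.ndarray) -> np.ndarray:
        if self.gc_bias is None:
            mult = default_gc_bias(gc)
        elif callable(self.gc_bias):
            mult = np.asarray(self.gc_bias(gc), dtype=float)
        else:
            mult = np.asarray(self.gc_bias, dtype=float)[_empirical_decile(gc)]
        if np.any(mult <= 0):
            raise ValueError("GC bias multipliers must be positive")
        return mult


def _empirical_decile(gc: np.ndarray) -> np.ndarray:
    edges = np.quantile(gc, np.linspace(0.1, 0.9, 9))
    return np.searchsorted(edges, gc, side="left")


def window_gc(n: int, config: ObservationConfig) -> np.ndarray:
    """Per-window GC fractions, a function of the root seed only."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    lo, hi = config.gc_range
    a, b = config.gc_beta
    return lo + (hi - lo) * rng.beta(a, b, size=n)


def simulate_window_counts(karyotype: Karyotype, config: ObservationConfig,
                           companion: Karyotype | None = None) -> pd.DataFrame:
    """Windowed read counts: Poisson(per_copy_depth x copies x gc_bias).

    Returns a WindowTrack DataFrame (chrom, start, end, gc, count) tiling the
    karyotype's genome at ``config.window_size``.
    """
    genome = karyotype.genome
    windows = genome.windows(config.window_size)
    ss = np.random.SeedSequence(config.seed).spawn(3)
    count_rng = np.random.default_rng(ss[1])
    od_rng = np.random.default_rng(ss[2])
    gc = window_gc(len(windows), config)
    dos = project_dosage(karyotype, windows, companion=companion,
                         fraction=config.chimera_fraction)
    mean = config.per_copy_depth * dos * config.bias_values(gc)
    if config.overdispersion > 0:
        shape = 1.0 / config.overdispersion
        mean = mean * od_rng.gamma(shape, 1.0 / shape, size=len(mean))
    counts = count_rng.poisson(mean)
    return windows.assign(gc=gc, count=counts)


# ---------------------------------------------------------------------------
# SNP panel and allele depths

_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]


@dataclass
class SnpPanel:
    """Biparental marker grid: chrom, pos (1-based), allele_a, allele_b."""

    table: pd.DataFrame

    def __post_init__(self):
        for chrom, sub in self.table.groupby("chrom"):
            if not sub["pos"].is_monotonic_increasing:
                raise ValueError(f"SNP positions not sorted on {chrom}")
        if (self.table["allele_a"] == self.table["allele_b"]).any():
            raise ValueError("parental alleles must differ")

    @classmethod
    def regular(cls, genome: GenomeMap, spacing: int,
                chromosomes: Sequence[str] | None = None) -> "SnpPanel":
        """Evenly spaced panel, one marker every ``spacing`` bp."""
        rows = []
        pairs = itertools.cycle(_ALLELE_PAIRS)
        for name, length in genome.chromosomes:
            if chromosomes is not None and name not in chromosomes:
                continue
            for pos in range(spacing // 2, length, spacing):
                a, b = next(pairs)
                rows.append((name, pos + 1, a, b))
        return cls(pd.DataFrame(rows, columns=["chrom", "pos", "allele_a",
                                               "allele_b"]))


def haplotype_copy_numbers(karyotype: Karyotype, chrom: str,
                           positions0: np.ndarray,
                           haplotypes: tuple[str, str] = ("A", "B")
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Copies of each parental haplotype covering the given 0-based positions."""
    nA = np.zeros(len(positions0), dtype=np.int32)
    nB = np.zeros(len(positions0), dtype=np.int32)
    for c in karyotype.copies:
        for seg in c.segments:
            if seg.chrom != chrom:
                continue
            hit = (positions0 >= seg.start) & (positions0 < seg.end)
            if seg.haplotype == haplotypes[0]:
                nA += hit
            elif seg.haplotype == haplotypes[1]:
                nB += hit
    return nA, nB


def simulate_snp_depths(karyotype: Karyotype, panel: SnpPanel,
                        mean_depth: float = 30.0, seed: int = 0) -> pd.DataFrame:
    """Allele depths at panel loci given the karyotype's haplotype content.

    Total depth at a locus is Poisson(mean_depth x copies / 2) — a locus
    hemizygous through arm loss gets half depth — and reads split binomially
    between the two parental alleles in proportion to haplotype copy number.
    Loci covered by no copy get zero depth.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    out = []
    for chrom, sub in panel.table.groupby("chrom", sort=False):
        pos0 = sub["pos"].to_numpy() - 1
        nA, nB = haplotype_copy_numbers(karyotype, chrom, pos0)
        ncop = nA + nB
        total = rng.poisson(mean_depth * ncop / 2.0)
        frac = np.divide(nA, ncop, out=np.zeros(len(ncop)), where=ncop > 0)
        da = rng.binomial(total, frac)
        out.append(sub.assign(depth_a=da, depth_b=total - da))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# junction read pairs

def _is_reference_adjacent(s1: Segment, s2: Segment) -> bool:
    if s1.chrom != s2.chrom or s1.orientation != s2.orientation:
        return False
    if s1.orientation == FORWARD:
        return s1.end == s2.start
    return s2.end == s1.start


def _junction_end(seg: Segment, upstream: bool) -> tuple[int, str]:
    """(source position, strand) of the junction-facing end of a segment.

    Strand records the reference direction of reading through the junction:
    '+' when the read enters (upstream) or leaves (downstream) the junction
    with increasing reference coordinate.
    """
    if upstream:
        return (seg.end, "+") if seg.orientation == FORWARD else (seg.start, "-")
    return (seg.start, "+") if seg.orientation == FORWARD else (seg.end, "-")


def novel_adjacencies(karyotype: Karyotype) -> pd.DataFrame:
    """Non-reference segment adjacencies across all derived chromosomes.

    Haplotype is ignored: a crossover joint between homologous segments at
    the same coordinate is reference-adjacent and produces no junction.
    """
    rows = []
    for c in karyotype.copies:
        for s1, s2 in zip(c.segments[:-1], c.segments[1:]):
            if _is_reference_adjacent(s1, s2):
                continue
            pa, sa = _junction_end(s1, upstream=True)
            pb, sb = _junction_end(s2, upstream=False)
            rows.append((s1.chrom, pa, sa, s2.chrom, pb, sb, c.name))
    return pd.DataFrame(rows, columns=["chromA", "posA", "strandA", "chromB",
                                       "posB", "strandB", "source"])


def simulate_junction_reads(karyotype: Karyotype, pairs_per_junction: float = 20,
                            read_len: int = 150, insert_size: int = 400,
                            seed: int = 0, jitter: int | None = None
                            ) -> pd.DataFrame:
    """BEDPE-like chimeric read pairs spanning every novel adjacency.

    Support per junction is Poisson(pairs_per_junction), so doubling the rate
    doubles expected support.  ``jitter`` bounds how far the junction-facing
    read end may sit from the true breakpoint (default: the slack left by the
    insert size); jitter=0 yields noise-free evidence whose junction-side
    coordinates equal the ground truth exactly.
    """
    adj = novel_adjacencies(karyotype)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[3])
    if jitter is None:
        jitter = max(0, insert_size - 2 * read_len)
    rows = []
    for j, rec in adj.iterrows():
        n = rng.poisson(pairs_per_junction)
        for k in range(n):
            da = int(rng.integers(0, jitter + 1)) if jitter > 0 else 0
            db = int(rng.integers(0, jitter + 1)) if jitter > 0 else 0
            sa, ea = _read_interval(rec.posA, rec.strandA, read_len, da)
            sb, eb = _read_interval(rec.posB, rec.strandB, read_len, db)
            rows.append((rec.chromA, sa, ea, rec.chromB, sb, eb,
                         f"jp{j}_{k}", 0, rec.strandA, rec.strandB))
    return pd.DataFrame(rows, columns=["chromA", "startA", "endA", "chromB",
                                       "startB", "endB", "name", "score",
                                       "strandA", "strandB"])


def _read_interval(pos: int, strand: str, read_len: int, offset: int
                   ) -> tuple[int, int]:
    if strand == "+":
        end = pos - offset
        return max(0, end - read_len), end
    start = pos + offset
    return start, start + read_len


# ---------------------------------------------------------------------------
# scenario builders

def diploid(genome: GenomeMap) -> Karyotype:
    return Karyotype.f1(genome)


def monosomy(genome: GenomeMap, chromosome: str, lost_haplotype: str = "B"
             ) -> Karyotype:
    """Whole-chromosome loss of one haplotype."""
    k = Karyotype.f1(genome)
    name = f"{chromosome}_{lost_haplotype}"
    lost = k.find_copy(name)
    k.copies = [c for c in k.copies if c.name != name]
    k.lost_fragments.append(list(lost.segments))
    return k


def arm_loss(genome: GenomeMap, break_site: Locus, haplotype: str = "B"
             ) -> Karyotype:
    """Loss of the acentric fragment distal to an unrepaired break."""
    k = Karyotype.f1(genome)
    name = f"{break_site.chromosome}_{haplotype}"
    cent, acentric = cut(k.find_copy(name), break_site, genome)
    k.replace_copy(name, cent)
    k.lost_fragments.append(acentric)
    return k


def segmental_deletion(genome: GenomeMap, region: Interval, haplotype: str = "B"
                       ) -> Karyotype:
    """Interstitial deletion of ``region`` on one haplotype."""
    k = Karyotype.f1(genome)
    name = f"{region.chromosome}_{haplotype}"
    copy = k.find_copy(name)
    before, rest = _split_segments_at_source(copy.segments, region.chromosome,
                                             region.start)
    mid, after = _split_segments_at_source(rest, region.chromosome, region.end)
    k.replace_copy(name, DerivedChromosome(name, before + after))
    k.lost_fragments.append(mid)
    return k


def crossover_sector(genome: GenomeMap, break_site: Locus,
                     retained: str = "A") -> Karyotype:
    """Copy-neutral somatic crossover sector: heterozygous proximal to the
    break, homozygous for ``retained`` distal to it, read depth unchanged."""
    k = Karyotype.f1(genome)
    chrom = break_site.chromosome
    other = "B" if retained == "A" else "A"
    cen0 = genome.centromere(chrom).pos0
    ret = k.find_copy(f"{chrom}_{retained}")
    oth = k.find_copy(f"{chrom}_{other}")
    ret_prox, ret_dist = _split_segments_at_source(ret.segments, chrom,
                                                   break_site.pos0)
    oth_prox, oth_dist = _split_segments_at_source(oth.segments, chrom,
                                                   break_site.pos0)
    if cen0 <= break_site.pos0:
        # distal side = high coordinates: the other homolog's distal part is
        # replaced by a copy of the retained homolog's distal part
        new_oth = oth_prox + [Segment(s.chrom, s.start, s.end, s.orientation,
                                      retained) for s in ret_dist]
    else:
        new_oth = [Segment(s.chrom, s.start, s.end, s.orientation, retained)
                   for s in ret_prox] + oth_dist
    k.replace_copy(oth.name, DerivedChromosome(oth.name, new_oth))
    return k


def bfbc_derivative(genome: GenomeMap, break_site: Locus,
                    rng: np.random.Generator, haplotype: str = "B",
                    min_duplication_bp: int = 2_000_000,
                    max_tries: int = 200) -> tuple[Karyotype, Interval]:
    """One breakage-fusion-bridge cycle at an unrepaired break.

    The acentric distal fragment is lost, the broken centromeric chromatid
    fuses with its sister, and the dicentric bridge re-breaks uniformly
    between the centromeres.  The daughter carrying the inverted duplication
    is kept.  Bridge breaks are redrawn until the duplicated region spans at
    least ``min_duplication_bp`` (the duplications observed after such cycles
    are megabase-scale; ~20 Mb in the motivating data).

    Returns the karyotype and the duplicated source interval.
    """
    k = Karyotype.f1(genome)
    name = f"{break_site.chromosome}_{haplotype}"
    cent, acentric = cut(k.find_copy(name), break_site, genome)
    k.lost_fragments.append(acentric)
    dic = fuse_sisters(cent)
    for _ in range(max_tries):
        d1, d2 = bridge_break(dic, genome, rng)
        for deriv in (d1, d2):
            dup = inverted_duplication(deriv)
            if dup is not None and dup.length >= min_duplication_bp:
                deriv = DerivedChromosome(name, deriv.segments,
                                          deriv.broken_left, deriv.broken_right)
                k.replace_copy(name, deriv)
                return k, dup
    raise EventError(f"no bridge break gave a duplication >= "
                     f"{min_duplication_bp} bp in {max_tries} tries")


def translocation_insertion(genome: GenomeMap, break_site: Locus,
                            target: Locus, rng: np.random.Generator,
                            haplotype: str = "B",
                            min_duplication_bp: int = 2_000_000
                            ) -> tuple[Karyotype, Interval]:
    """Chromothripsis-like follow-up of a BFBC: the inverted-duplicated
    fold-back unit shatters off into a micronucleus and reintegrates into
    another chromosome at ``target``.

    The two outer junctions of the insertion carry the diagnostic orientation
    signature: one inverted and one forward, both anchored at the same source
    coordinate of the donor chromosome.  Returns the karyotype and the
    duplicated (translocated) source interval.
    """
    k, dup = bfbc_derivative(genome, break_site, rng, haplotype,
                             min_duplication_bp)
    name = f"{break_site.chromosome}_{haplotype}"
    deriv = k.find_copy(name)
    # excise the palindromic fold-back unit (the duplicated interval read once
    # forward and once inverted) from the derivative's reading order; it sits
    # at whichever end of the derivative contains the fusion point
    unit_len = 2 * dup.length
    head = deriv.segments[0]
    at_head = (head.chrom == dup.chromosome
               and (head.start, head.end) == (dup.start, dup.end))
    if at_head:
        frag, keep = _split_at_derived(deriv.segments, unit_len)
        remaining = DerivedChromosome(name, list(keep), broken_left=True)
    else:
        keep, frag = _split_at_derived(deriv.segments, deriv.length - unit_len)
        remaining = DerivedChromosome(name, list(keep), broken_right=True)
    frag = list(frag)
    k.replace_copy(name, remaining)
    k.micronucleus_pool.append(frag)
    reintegrate(k, frag, target, copy_name=f"{target.chromosome}_A")
    return k, dup
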