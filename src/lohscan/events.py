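"""Karyotype event algebra for breakage-fusion-bridge cycles (BFBC).

A karyotype is a set of derived chromosomes, each an ordered list of oriented
:class:`Segment` pieces of the reference genome.  The event operations — cut
at a break site, sister-chromatid fusion into a dicentric, anaphase bridge
break, and reintegration of a micronuclear fragment — implement the algebra
behind BFBC and chromothripsis-like rearrangements: an unrepaired double
strand break loses its acentric distal fragment; the two broken sister
centromere-bearing chromatids fuse into a palindromic dicentric; pulling the
two centromeres apart re-breaks the bridge at a random point, leaving one
daughter with an inverted duplication (the 3x dosage signature) and the other
with a terminal deletion; shattered fragments in micronuclei can later
reintegrate elsewhere, creating translocation junctions.

Base-pair content is conserved exactly through every operation: what leaves a
chromosome goes to ``lost_fragments`` or ``micronucleus_pool``, never
vanishes.
"""
from __future__ import annotations

import copy as _copy
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import GenomeMap, Interval, Locus

FORWARD = 1
INVERTED = -1


class EventError(ValueError):
    """Base class for karyotype event errors."""


class SiteNotPresentError(EventError):
    pass


class AmbiguousSiteError(EventError):
    pass


class NothingToFuseError(EventError):
    pass


class NotDicentricError(EventError):
    pass


class UnknownFragmentError(EventError):
    pass


@dataclass(frozen=True)
class Segment:
    """Oriented piece [start, end) of a reference chromosome on one haplotype."""

    chrom: str
    start: int
    end: int
    orientation: int = FORWARD
    haplotype: str = "A"

    def __post_init__(self):
        if self.start >= self.end:
            raise EventError(f"invalid segment {self.chrom}:{self.start}-{self.end}")
        if self.orientation not in (FORWARD, INVERTED):
            raise EventError("orientation must be +1 or -1")

    @property
    def length(self) -> int:
        return self.end - self.start

    def flipped(self) -> "Segment":
        return replace(self, orientation=-self.orientation)

    def covers(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end


def segment_carries_centromere(seg: Segment, genome: GenomeMap) -> bool:
    cen = genome.centromeres.get(seg.chrom)
    return cen is not None and seg.start <= cen - 1 < seg.end


@dataclass
class DerivedChromosome:
    """An ordered, oriented segment list; may carry broken (non-telomeric) ends."""

    name: str
    segments: list[Segment]
    broken_left: bool = False
    broken_right: bool = False

    @property
    def length(self) -> int:
        return sum(s.length for s in self.segments)

    def n_centromeres(self, genome: GenomeMap) -> int:
        return sum(segment_carries_centromere(s, genome) for s in self.segments)

    def normalized(self) -> "DerivedChromosome":
        """Merge adjacent segments that are contiguous in the reference."""
        merged: list[Segment] = []
        for seg in self.segments:
            if merged:
                prev = merged[-1]
                if (prev.chrom == seg.chrom and prev.haplotype == seg.haplotype
                        and prev.orientation == seg.orientation):
                    if seg.orientation == FORWARD and prev.end == seg.start:
                        merged[-1] = replace(prev, end=seg.end)
                        continue
                    if seg.orientation == INVERTED and seg.end == prev.start:
                        merged[-1] = replace(prev, start=seg.start)
                        continue
            merged.append(seg)
        return DerivedChromosome(self.name, merged, self.broken_left,
                                 self.broken_right)


# ---------------------------------------------------------------------------
# splitting helpers

def _split_segment_at_source(seg: Segment, pos0: int) -> tuple[Segment, Segment]:
    """Split at a source coordinate strictly inside the segment.

    Returns the two pieces in derived reading order: for an inverted segment
    the piece covering the larger source coordinates is read first.
    """
    low = replace(seg, end=pos0)
    high = replace(seg, start=pos0)
    return (low, high) if seg.orientation == FORWARD else (high, low)


def _split_segments_at_source(segments: list[Segment], chrom: str,
                              pos0: int) -> tuple[list[Segment], list[Segment]]:
    interior = [i for i, s in enumerate(segments)
                if s.covers(chrom, pos0) and s.start < pos0]
    interior = [i for i in interior if pos0 > segments[i].start and pos0 < segments[i].end]
    if len(interior) > 1:
        raise AmbiguousSiteError(
            f"{chrom}:{pos0} present in {len(interior)} segments")
    if len(interior) == 1:
        i = interior[0]
        first, second = _split_segment_at_source(segments[i], pos0)
        return segments[:i] + [first], [second] + segments[i + 1:]
    # boundary case: the site coincides with an existing segment edge
    for i in range(len(segments) + 1):
        left_ok = i > 0 and _edge_source(segments[i - 1], "right") == (chrom, pos0)
        right_ok = i < len(segments) and _edge_source(segments[i], "left") == (chrom, pos0)
        if left_ok or right_ok:
            return list(segments[:i]), list(segments[i:])
    raise SiteNotPresentError(f"{chrom}:{pos0} not covered by this chromosome copy")


def _edge_source(seg: Segment, side: str) -> tuple[str, int]:
    """Source coordinate of a derived-reading-order edge of a segment."""
    if side == "left":
        return (seg.chrom, seg.start if seg.orientation == FORWARD else seg.end)
    return (seg.chrom, seg.end if seg.orientation == FORWARD else seg.start)


def _split_at_derived(segments: list[Segment], offset: int
                      ) -> tuple[list[Segment], list[Segment]]:
    """Split a segment list at a derived (reading-order) coordinate."""
    total = sum(s.length for s in segments)
    if not 0 < offset < total:
        raise EventError(f"derived offset {offset} outside (0, {total})")
    acc = 0
    for i, seg in enumerate(segments):
        if offset == acc:
            return list(segments[:i]), list(segments[i:])
        if acc < offset < acc + seg.length:
            k = offset - acc
            if seg.orientation == FORWARD:
                first, second = replace(seg, end=seg.start + k), replace(seg, start=seg.start + k)
            else:
                first, second = replace(seg, start=seg.end - k), replace(seg, end=seg.end - k)
            return segments[:i] + [first], [second] + segments[i + 1:]
        acc += seg.length
    raise EventError("unreachable")  # pragma: no cover


# ---------------------------------------------------------------------------
# event operations

def cut(copy: DerivedChromosome, site: Locus, genome: GenomeMap
        ) -> tuple[DerivedChromosome, list[Segment]]:
    """Cut a chromosome copy at a break site.

    Returns ``(centromeric_fragment, acentric_segments)``.  The centromeric
    fragment records which end is broken; the acentric piece is returned as a
    bare segment list destined for ``lost_fragments`` or the micronucleus
    pool.
    """
    before, after = _split_segments_at_source(copy.segments, site.chromosome,
                                              site.pos0)
    if not before or not after:
        raise SiteNotPresentError(
            f"cut at {site.chromosome}:{site.position} does not split {copy.name}")
    nc_before = sum(segment_carries_centromere(s, genome) for s in before)
    nc_after = sum(segment_carries_centromere(s, genome) for s in after)
    if nc_before and nc_after:
        raise EventError("cut would leave centromeres on both fragments")
    if not nc_before and not nc_after:
        raise EventError("no centromere on either fragment")
    if nc_before:
        cent = DerivedChromosome(copy.name, before, broken_right=True,
                                 broken_left=copy.broken_left)
        return cent, after
    cent = DerivedChromosome(copy.name, after, broken_left=True,
                             broken_right=copy.broken_right)
    return cent, before


def fuse_sisters(broken: DerivedChromosome) -> DerivedChromosome:
    """Fuse a broken chromatid with its own sister at the broken end.

    The product is a dicentric chromosome, palindromic about the fusion
    point: the segment list concatenated with its reversed,
    orientation-flipped image.
    """
    if broken.broken_right:
        segs = list(broken.segments) + [s.flipped() for s in reversed(broken.segments)]
    elif broken.broken_left:
        segs = [s.flipped() for s in reversed(broken.segments)] + list(broken.segments)
    else:
        raise NothingToFuseError(f"{broken.name} has no broken end")
    return DerivedChromosome(broken.name + "_dic", segs)


def centromere_positions(chromosome: DerivedChromosome, genome: GenomeMap
                         ) -> list[int]:
    """Derived coordinates of every centromere base on the chromosome."""
    out = []
    acc = 0
    for seg in chromosome.segments:
        if segment_carries_centromere(seg, genome):
            c0 = genome.centromeres[seg.chrom] - 1
            if seg.orientation == FORWARD:
                out.append(acc + (c0 - seg.start))
            else:
                out.append(acc + (seg.end - 1 - c0))
        acc += seg.length
    return out


def bridge_break(dicentric: DerivedChromosome, genome: GenomeMap,
                 rng: np.random.Generator
                 ) -> tuple[DerivedChromosome, DerivedChromosome]:
    """Break an anaphase bridge at a uniform random point between centromeres.

    Each derivative retains exactly one centromere.  Unless the break falls
    exactly at the fusion point, one derivative carries an inverted
    duplication of the region between the break and the fusion point.
    """
    cens = sorted(centromere_positions(dicentric, genome))
    if len(cens) != 2:
        raise NotDicentricError(
            f"{dicentric.name} has {len(cens)} centromeres, need 2")
    u = int(rng.integers(cens[0] + 1, cens[1] + 1))
    before, after = _split_at_derived(dicentric.segments, u)
    d1 = DerivedChromosome(dicentric.name + "_d1", before, broken_right=True)
    d2 = DerivedChromosome(dicentric.name + "_d2", after, broken_left=True)
    return d1, d2


def inverted_duplication(chromosome: DerivedChromosome) -> Interval | None:
    """Largest source interval present more than once on the chromosome.

    Returns None when every base occurs once (no duplication).
    """
    events: dict[str, list[tuple[int, int]]] = {}
    for seg in chromosome.segments:
        events.setdefault(seg.chrom, []).append((seg.start, seg.end))
    best: Interval | None = None
    for chrom, ivs in events.items():
        edges = sorted({e for iv in ivs for e in iv})
        run_start = None
        for a, b in zip(edges[:-1], edges[1:]):
            depth = sum(1 for s, e in ivs if s <= a and b <= e)
            if depth >= 2:
                if run_start is None:
                    run_start = a
                run_end = b
            elif run_start is not None:
                cand = Interval(chrom, run_start, run_end)
                if best is None or cand.length > best.length:
                    best = cand
                run_start = None
        if run_start is not None:
            cand = Interval(chrom, run_start, run_end)
            if best is None or cand.length > best.length:
                best = cand
    return best


# ---------------------------------------------------------------------------
# karyotype container

@dataclass
class Karyotype:
    """Derived chromosomes plus lost (acentric) and micronuclear material."""

    genome: GenomeMap
    copies: list[DerivedChromosome]
    lost_fragments: list[list[Segment]] = field(default_factory=list)
    micronucleus_pool: list[list[Segment]] = field(default_factory=list)

    @classmethod
    def f1(cls, genome: GenomeMap, haplotypes: tuple[str, str] = ("A", "B")
           ) -> "Karyotype":
        """Intact diploid F1: one copy of every chromosome per haplotype."""
        copies = [
            DerivedChromosome(f"{name}_{h}", [Segment(name, 0, length, FORWARD, h)])
            for name, length in genome.chromosomes for h in haplotypes
        ]
        return cls(genome, copies)

    def clone(self) -> "Karyotype":
        return _copy.deepcopy(self)

    def find_copy(self, name: str) -> DerivedChromosome:
        for c in self.copies:
            if c.name == name:
                return c
        raise EventError(f"no chromosome copy named {name!r}")

    def replace_copy(self, name: str, new: DerivedChromosome) -> None:
        for i, c in enumerate(self.copies):
            if c.name == name:
                self.copies[i] = new
                return
        raise EventError(f"no chromosome copy named {name!r}")

    def total_bp(self, include_pools: bool = True) -> dict[tuple[str, str], int]:
        """Base pairs per (reference chromosome, haplotype), everywhere."""
        out: dict[tuple[str, str], int] = {}
        pools: list[list[Segment]] = [c.segments for c in self.copies]
        if include_pools:
            pools += list(self.lost_fragments) + list(self.micronucleus_pool)
        for segs in pools:
            for s in segs:
                key = (s.chrom, s.haplotype)
                out[key] = out.get(key, 0) + s.length
        return out

    def base_coverage(self, chromosome: str, include_pools: bool = False
                      ) -> np.ndarray:
        """Per-base copy count along a reference chromosome (oracle-grade)."""
        arr = np.zeros(self.genome.length(chromosome), dtype=np.int32)
        pools: list[list[Segment]] = [c.segments for c in self.copies]
        if include_pools:
            pools += list(self.lost_fragments) + list(self.micronucleus_pool)
        for segs in pools:
            for s in segs:
                if s.chrom == chromosome:
                    arr[s.start:s.end] += 1
        return arr

    # -- event log ---------------------------------------------------------
    def to_dict(self) -> dict:
        def seglist(segs):
            return [{"chrom": s.chrom, "start": int(s.start), "end": int(s.end),
                     "orientation": "forward" if s.orientation == FORWARD else "inverted",
                     "haplotype": s.haplotype} for s in segs]
        return {
            "copies": [{"name": c.name, "segments": seglist(c.segments)}
                       for c in self.copies],
            "lost_fragments": [seglist(f) for f in self.lost_fragments],
            "micronucleus_pool": [seglist(f) for f in self.micronucleus_pool],
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def reintegrate(karyotype: Karyotype, fragment: list[Segment], target: Locus,
                copy_name: str | None = None) -> Karyotype:
    """Splice a micronuclear fragment into a chromosome copy at ``target``.

    The fragment must be an element of ``micronucleus_pool`` (by identity);
    its per-segment orientations are preserved.  Mutates and returns the
    karyotype.
    """
    if not any(fragment is f for f in karyotype.micronucleus_pool):
        raise UnknownFragmentError("fragment is not in the micronucleus pool")
    if copy_name is None:
        candidates = [c for c in karyotype.copies
                      if sum(s.covers(target.chromosome, target.pos0)
                             for s in c.segments) == 1]
        if not candidates:
            raise SiteNotPresentError(
                f"no copy uniquely covers {target.chromosome}:{target.position}")
        target_copy = candidates[0]
    else:
        target_copy = karyotype.find_copy(copy_name)
    before, after = _split_segments_at_source(target_copy.segments,
                                              target.chromosome, target.pos0)
    new = DerivedChromosome(target_copy.name, before + list(fragment) + after,
                            target_copy.broken_left, target_copy.broken_right)
    karyotype.replace_copy(target_copy.name, new)
    karyotype.micronucleus_pool = [f for f in karyotype.micronucleus_pool
                                   if f is not fragment]
    return karyotype


def excise_fragment(karyotype: Karyotype, fragment: list[Segment]) -> Karyotype:
    """Inverse of :func:`reintegrate`: remove the fragment's segment objects
    from whichever copy holds them and return them to the micronucleus pool."""
    ids = {id(s) for s in fragment}
    for i, c in enumerate(karyotype.copies):
        if any(id(s) in ids for s in c.segments):
            kept = [s for s in c.segments if id(s) not in ids]
            karyotype.copies[i] = DerivedChromosome(
                c.name, kept, c.broken_left, c.broken_right).normalized()
            karyotype.micronucleus_pool.append(list(fragment))
            return karyotype
    raise UnknownFragmentError("fragment segments not found in any copy")


def project_dosage(karyotype: Karyotype, windows: pd.DataFrame,
                   companion: Karyotype | None = None,
                   fraction: float = 1.0) -> np.ndarray:
    """Expected copy number per window on the diploid "x" scale.

    Each window's value is the overlap-weighted number of times its source
    interval occurs across all derived chromosomes (an intact diploid gives 2
    everywhere).  With ``fraction < 1`` the result is a cell-mixture average:
    ``fraction`` of cells carry ``karyotype`` and the rest carry
    ``companion`` (default: intact diploid), modelling chimeric tissue.
    Micronuclear and lost material does not contribute.
    """
    if not 0.0 <= fraction <= 1.0:
        raise EventError("fraction must be in [0, 1]")
    dos = _project_one(karyotype, windows)
    if fraction < 1.0:
        comp = companion if companion is not None else Karyotype.f1(karyotype.genome)
        dos = fraction * dos + (1.0 - fraction) * _project_one(comp, windows)
    return dos


def _project_one(karyotype: Karyotype, windows: pd.DataFrame) -> np.ndarray:
    chrom = windows["chrom"].to_numpy()
    start = windows["start"].to_numpy()
    end = windows["end"].to_numpy()
    width = (end - start).astype(float)
    dos = np.zeros(len(windows))
    index: dict[str, np.ndarray] = {}
    for name in np.unique(chrom):
        index[name] = np.flatnonzero(chrom == name)
    for c in karyotype.copies:
        for seg in c.segments:
            rows = index.get(seg.chrom)
            if rows is None:
                continue
            s, e = start[rows], end[rows]
            lo = np.searchsorted(e, seg.start, side="right")
            hi = np.searchsorted(s, seg.end, side="left")
            if hi <= lo:
                continue
            sel = rows[lo:hi]
            overlap = (np.minimum(e[lo:hi], seg.end)
                       - np.maximum(s[lo:hi], seg.start)).clip(min=0)
            dos[sel] += overlap / width[sel]
    return dos
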