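"""Genomic coordinate frame: chromosomes, centromeres, masks, loci and intervals.

Conventions
-----------
Printed genome coordinates (e.g. ``ch11:47,124,456`` on the SL4.0 tomato
assembly) are 1-based inclusive and live in :class:`Locus.position`.  Every
internal interval is half-open and 0-based, matching BED semantics, so that
``length == end - start``.  Printed coordinate ranges such as
``ch11:47,301,154-47,318,550`` are read with an exclusive end, which is the
interpretation under which the printed fragment length (17,396 bp) equals
``end - start`` exactly.  Conversion between the two happens only at the I/O
boundary.

"Proximal" and "distal" are always relative to the centromere of the
chromosome carrying a break: proximal = centromere side, distal = telomere
side.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GenomeError(ValueError):
    """Base class for coordinate-frame errors."""


class DifferentChromosomesError(GenomeError):
    """Distance between loci on different chromosomes is undefined."""


class InvalidIntervalError(GenomeError):
    """Interval with start >= end."""


class UnknownChromosomeError(GenomeError):
    """Chromosome name not present in the genome map."""


class EmptyFlankError(GenomeError):
    """A break flank contains no usable windows."""


@dataclass(frozen=True)
class Locus:
    """A single 1-based genomic position (marker, break site, gene...)."""

    chromosome: str
    position: int
    label: str = ""

    def __post_init__(self):
        if self.position < 1:
            raise GenomeError(f"position must be >= 1, got {self.position}")

    @property
    def pos0(self) -> int:
        """0-based coordinate of this locus."""
        return self.position - 1


@dataclass(frozen=True)
class Interval:
    """Half-open 0-based interval [start, end)."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self):
        if self.start >= self.end:
            raise InvalidIntervalError(
                f"invalid interval {self.chromosome}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end

    def overlaps(self, chromosome: str, start: int, end: int) -> bool:
        return chromosome == self.chromosome and self.start < end and start < self.end


def locus_distance(a: Locus, b: Locus) -> int:
    """Distance in bp between two loci on the same chromosome (symmetric)."""
    if a.chromosome != b.chromosome:
        raise DifferentChromosomesError(
            f"distance undefined between {a.chromosome} and {b.chromosome}"
        )
    return abs(a.position - b.position)


def interval_length(iv: Interval) -> int:
    """Length of a half-open interval in bp."""
    return iv.length


@dataclass
class GenomeMap:
    """Chromosome sizes, centromere positions and masked regions.

    ``chromosomes`` is an ordered list of (name, length-in-bp); only the
    chromosomes listed here participate in window tiling and normalization
    baselines, which is how organelle/scaffold contigs are excluded.
    ``centromeres`` maps chromosome name to a 1-based position.
    """

    chromosomes: list[tuple[str, int]]
    centromeres: dict[str, int] = field(default_factory=dict)
    masked_regions: list[Interval] = field(default_factory=list)

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise GenomeError("duplicate chromosome names")
        for name, length in self.chromosomes:
            if length <= 0:
                raise GenomeError(f"non-positive length for {name}")
        for name, pos in self.centromeres.items():
            if not 1 <= pos <= self.length(name):
                raise GenomeError(f"centromere of {name} outside [1, length]")
        for iv in self.masked_regions:
            if not (0 <= iv.start and iv.end <= self.length(iv.chromosome)):
                raise GenomeError(f"masked interval {iv} outside chromosome bounds")

    # -- basic lookups -----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    def length(self, chromosome: str) -> int:
        for name, length in self.chromosomes:
            if name == chromosome:
                return length
        raise UnknownChromosomeError(chromosome)

    def centromere(self, chromosome: str) -> Locus:
        if chromosome not in self.centromeres:
            raise GenomeError(f"no centromere recorded for {chromosome}")
        return Locus(chromosome, self.centromeres[chromosome], "centromere")

    # -- window grid -------------------------------------------------------
    def windows(self, window_size: int) -> pd.DataFrame:
        """Tile every chromosome into half-open windows of ``window_size`` bp.

        Terminal windows are truncated at the chromosome end.  Returns a
        DataFrame with columns chrom/start/end, ordered as in
        ``self.chromosomes``.
        """
        if window_size <= 0:
            raise GenomeError("window_size must be positive")
        frames = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, window_size, dtype=np.int64)
            ends = np.minimum(starts + window_size, length)
            frames.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)

    def mask_array(self, windows: pd.DataFrame) -> np.ndarray:
        """Boolean array: True for windows overlapping any masked region."""
        masked = np.zeros(len(windows), dtype=bool)
        chrom = windows["chrom"].to_numpy()
        start = windows["start"].to_numpy()
        end = windows["end"].to_numpy()
        for iv in self.masked_regions:
            masked |= (chrom == iv.chromosome) & (start < iv.end) & (iv.start < end)
        return masked

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_files(cls, chrom_sizes: str, centromeres_bed: str | None = None,
                   mask_bed: str | None = None) -> "GenomeMap":
        """Load from a 2/3-column chrom-sizes TSV plus optional BED files.

        The centromere BED uses the midpoint of each record; masks are taken
        verbatim as half-open BED intervals.
        """
        sizes = pd.read_csv(chrom_sizes, sep="\t", header=None, comment="#")
        chromosomes = [(str(r[0]), int(r[1])) for r in sizes.itertuples(index=False)]
        centromeres: dict[str, int] = {}
        if centromeres_bed is not None:
            cen = pd.read_csv(centromeres_bed, sep="\t", header=None, comment="#")
            for r in cen.itertuples(index=False):
                centromeres[str(r[0])] = (int(r[1]) + int(r[2])) // 2 + 1
        masks: list[Interval] = []
        if mask_bed is not None:
            bed = pd.read_csv(mask_bed, sep="\t", header=None, comment="#")
            for r in bed.itertuples(index=False):
                masks.append(Interval(str(r[0]), int(r[1]), int(r[2])))
        return cls(chromosomes, centromeres, masks)

    def to_files(self, chrom_sizes: str, centromeres_bed: str, mask_bed: str) -> None:
        pd.DataFrame(self.chromosomes).to_csv(chrom_sizes, sep="\t", header=False,
                                              index=False)
        rows = [(c, p - 1, p) for c, p in self.centromeres.items()]
        pd.DataFrame(rows).to_csv(centromeres_bed, sep="\t", header=False, index=False)
        rows = [(iv.chromosome, iv.start, iv.end) for iv in self.masked_regions]
        pd.DataFrame(rows, columns=["c", "s", "e"]).to_csv(
            mask_bed, sep="\t", header=False, index=False)


def flank_intervals(windows: pd.DataFrame, break_site: Locus, flank_bp: int,
                    genome: GenomeMap) -> dict[str, Interval]:
    """Proximal/distal 1-sided flank intervals around a break.

    Flanks are measured from the edges of the window containing the break
    coordinate, so the break-overlapping window belongs to neither side and
    an aligned break with a 1-Mbp flank yields exactly 200 five-kb windows
    per side.  Flanks running past a chromosome end are truncated with a
    warning.
    """
    if flank_bp <= 0:
        raise GenomeError("flank_bp must be positive")
    chrom = break_site.chromosome
    length = genome.length(chrom)
    p0 = break_site.pos0
    sub = windows[windows["chrom"] == chrom]
    hit = sub[(sub["start"] <= p0) & (p0 < sub["end"])]
    if len(hit):
        bw_start = int(hit["start"].iloc[0])
        bw_end = int(hit["end"].iloc[0])
    else:  # break beyond the tiled region: fall back to a zero-width pivot
        bw_start = bw_end = p0
    cen0 = genome.centromere(chrom).pos0
    lower = (max(0, bw_start - flank_bp), bw_start)
    upper = (bw_end, min(length, bw_end + flank_bp))
    if bw_start - flank_bp < 0 or bw_end + flank_bp > length:
        warnings.warn(f"flank around {chrom}:{break_site.position} truncated at "
                      "chromosome end", stacklevel=2)
    if cen0 <= p0:
        prox, dist = lower, upper
    else:
        prox, dist = upper, lower
    out = {}
    for side, (s, e) in (("proximal", prox), ("distal", dist)):
        out[side] = None if s >= e else Interval(chrom, s, e)
    return out


def windows_in_flank(windows: pd.DataFrame, break_site: Locus, flank_bp: int,
                     side: str, genome: GenomeMap,
                     masked: np.ndarray | None = None) -> np.ndarray:
    """Boolean selector for windows fully inside a 1-sided break flank.

    Masked windows (from ``masked`` or the genome's masked regions) and the
    window overlapping the break coordinate are excluded.  Raises
    :class:`EmptyFlankError` when no usable window remains.
    """
    if side not in ("proximal", "distal"):
        raise GenomeError(f"side must be proximal or distal, got {side!r}")
    iv = flank_intervals(windows, break_site, flank_bp, genome)[side]
    if iv is None:
        raise EmptyFlankError(f"{side} flank of {break_site.chromosome}:"
                              f"{break_site.position} is empty")
    if masked is None:
        masked = genome.mask_array(windows)
    sel = ((windows["chrom"].to_numpy() == iv.chromosome)
           & (windows["start"].to_numpy() >= iv.start)
           & (windows["end"].to_numpy() <= iv.end)
           & ~masked)
    if not sel.any():
        raise EmptyFlankError(f"no usable windows in {side} flank of "
                              f"{break_site.chromosome}:{break_site.position}")
    return sel
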