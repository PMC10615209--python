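"""Loss-of-heterozygosity genotyping and mechanism classification.

Biparental SNP allele depths are called heterozygous/homozygous, the
heterozygous-to-homozygous transition along the chromosome is located, and
the mechanism is resolved by combining the genotype pattern with the
read-depth evidence: a copy-neutral crossover leaves the dosage at 2x on both
sides of the break, a segmental (arm) loss drops the homozygous extent to 1x,
and whole-chromosome loss shows chromosome-wide homozygosity at 1x.  The
marker-presence call reads a dosage interval (e.g. a hemizygous T-DNA
insertion region) as present / partially deleted / absent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeError, GenomeMap, Interval, Locus
from .lrt import NULL_LABEL, BreakClassification

CALL_CATEGORIES = ("heterozygous", "homozygous_A", "homozygous_B", "missing")


def call_genotypes(snps: pd.DataFrame, min_depth: int = 8,
                   het_fraction: float = 0.2) -> pd.DataFrame:
    """Two-state genotype calls from biparental allele depths.

    A locus is heterozygous when the minor-parent fraction
    min(depth_a, depth_b) / total is at least ``het_fraction`` and total
    depth reaches ``min_depth``; otherwise homozygous toward the majority
    allele.  Below ``min_depth`` the call is missing.  The raw allele
    fraction is kept alongside the two-state call so unusual allele ratios
    (e.g. a trisomic 2:1 flank) stay visible.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be >= 0")
    if not 0 < het_fraction <= 0.5:
        raise ValueError("het_fraction must be in (0, 0.5]")
    da = snps["depth_a"].to_numpy(dtype=float)
    db = snps["depth_b"].to_numpy(dtype=float)
    if (da < 0).any() or (db < 0).any():
        raise ValueError("negative allele depths")
    total = da + db
    frac_a = np.divide(da, total, out=np.full(len(da), np.nan), where=total > 0)
    minor = np.minimum(da, db)
    call = np.where(total < max(min_depth, 1), "missing",
                    np.where(minor / np.maximum(total, 1) >= het_fraction,
                             "heterozygous",
                             np.where(da >= db, "homozygous_A", "homozygous_B")))
    return snps.assign(total_depth=total.astype(int), frac_a=frac_a, call=call)


@dataclass
class Transition:
    """Het/hom run structure of genotype calls along one chromosome."""

    chromosome: str
    kind: str                      # 'transition' | 'none' | 'whole_chromosome' | 'undetermined'
    interval: tuple[int, int] | None = None   # 1-based positions bracketing the switch
    retained_parent: str | None = None        # 'A' | 'B'
    hom_side: str | None = None               # 'left' | 'right' (coordinate axis)
    contains_break: bool | None = None
    n_informative: int = 0


def detect_transition(calls: pd.DataFrame, break_site: Locus) -> Transition:
    """Locate the het-to-hom switch on the break-site chromosome.

    Fits the single changepoint that minimizes call misclassification over a
    het-block / hom-block two-run model; ties resolve to the changepoint
    closest to the break.  All-heterozygous chromosomes report kind 'none';
    chromosomes homozygous for one parent throughout report
    'whole_chromosome'; all-missing input is 'undetermined'.
    """
    chrom = break_site.chromosome
    sub = calls[(calls["chrom"] == chrom) & (calls["call"] != "missing")]
    sub = sub.sort_values("pos")
    n = len(sub)
    if n == 0:
        return Transition(chrom, "undetermined")
    pos = sub["pos"].to_numpy()
    call = sub["call"].to_numpy()
    het = (call == "heterozygous").astype(int)
    if het.all():
        return Transition(chrom, "none", n_informative=n)
    if not het.any():
        parents = np.unique(call)
        if len(parents) == 1:
            parent = "A" if parents[0] == "homozygous_A" else "B"
            return Transition(chrom, "whole_chromosome", retained_parent=parent,
                              n_informative=n)
        return Transition(chrom, "undetermined", n_informative=n)
    # single changepoint k in [1, n-1]: prefix gets one state, suffix the other
    chet = np.concatenate([[0], np.cumsum(het)])
    ks = np.arange(1, n)
    # cost when prefix is het / suffix hom, and the reverse
    cost_hh = (ks - chet[ks]) + (chet[n] - chet[ks])
    cost_ht = chet[ks] + ((n - ks) - (chet[n] - chet[ks]))
    costs = np.minimum(cost_hh, cost_ht)
    best = costs.min()
    cands = ks[costs == best]
    mid = (pos[cands - 1] + pos[cands]) / 2.0
    k = int(cands[np.argmin(np.abs(mid - break_site.position))])
    prefix_het = cost_hh[k - 1] <= cost_ht[k - 1]
    hom_side = "right" if prefix_het else "left"
    hom_calls = call[k:] if prefix_het else call[:k]
    hom_calls = hom_calls[hom_calls != "heterozygous"]
    if len(hom_calls) == 0:
        return Transition(chrom, "undetermined", n_informative=n)
    vals, counts = np.unique(hom_calls, return_counts=True)
    parent = "A" if vals[np.argmax(counts)] == "homozygous_A" else "B"
    left, right = int(pos[k - 1]), int(pos[k])
    contains = left <= break_site.position <= right
    return Transition(chrom, "transition", (left, right), parent, hom_side,
                      contains, n)


@dataclass
class LohCall:
    """Mechanism call for a loss-of-heterozygosity event."""

    chromosome: str
    mechanism: str        # 'crossover' | 'segmental_loss' | 'chromosome_loss' | 'undetermined' | 'none'
    extent: str           # 'distal_segment' | 'whole_chromosome' | 'none'
    retained_parent: str | None
    transition: Transition
    marker_status: str | None = None
    diagnostics: dict = field(default_factory=dict)


def classify_mechanism(transition: Transition, dosage: pd.DataFrame,
                       classification: BreakClassification, genome: GenomeMap,
                       dosage_tol: float = 0.25,
                       marker_interval: Interval | None = None) -> LohCall:
    """Resolve crossover vs segmental loss vs whole-chromosome loss.

    Decision logic: a het-to-hom transition at the break with both flanks
    classified as no-rearrangement (dosage stays 2x) is a crossover — the
    unchanged read counts rule out a segment loss.  A transition whose
    homozygous extent coincides with a 1x (arm-deletion) flank is a segmental
    loss.  Chromosome-wide homozygosity with chromosome-wide ~1x dosage is a
    whole-chromosome loss.  Conflicting evidence is reported as undetermined
    with diagnostics.
    """
    chrom = transition.chromosome
    diag: dict = {}
    marker_status = None
    if marker_interval is not None:
        marker_status = marker_presence(dosage, marker_interval, genome)
    sub = dosage[dosage["chrom"] == chrom]
    if len(sub) == 0:
        raise GenomeError(f"dosage track has no windows on {chrom}")
    chrom_median = float(sub["dosage"].median())
    diag["chromosome_median_dosage"] = chrom_median

    def _result(mech, extent, parent):
        return LohCall(chrom, mech, extent, parent, transition, marker_status,
                       diag)

    if transition.kind == "undetermined":
        return _result("undetermined", "none", None)
    if transition.kind == "none":
        return _result("none", "none", None)
    if transition.kind == "whole_chromosome":
        if abs(chrom_median - 1.0) <= dosage_tol:
            return _result("chromosome_loss", "whole_chromosome",
                           transition.retained_parent)
        diag["conflict"] = ("chromosome-wide homozygosity but median dosage "
                            f"{chrom_median:.2f} is not ~1x")
        return _result("undetermined", "whole_chromosome",
                       transition.retained_parent)

    # het/hom transition
    prox = classification.flanks.get("proximal")
    dist = classification.flanks.get("distal")
    labels = {s: (fr.best_label if fr is not None and fr.p_value < classification.alpha
                  else (NULL_LABEL if fr is not None else "missing"))
              for s, fr in (("proximal", prox), ("distal", dist))}
    diag["flank_labels"] = labels
    if not transition.contains_break:
        diag["conflict"] = "genotype transition does not bracket the break"
        return _result("undetermined", "distal_segment",
                       transition.retained_parent)
    # which coordinate side is distal?
    cen = genome.centromere(chrom).position
    distal_side = "right" if cen <= classification.position else "left"
    hom_is_distal = transition.hom_side == distal_side
    diag["hom_side_is_distal"] = hom_is_distal
    if labels["proximal"] == NULL_LABEL and labels["distal"] == NULL_LABEL:
        return _result("crossover", "distal_segment" if hom_is_distal else "none",
                       transition.retained_parent)
    if hom_is_distal and labels["distal"] == "arm_deletion":
        return _result("segmental_loss", "distal_segment",
                       transition.retained_parent)
    diag["conflict"] = (f"homozygous extent with flank labels {labels} fits "
                        "no supported mechanism")
    return _result("undetermined", "distal_segment", transition.retained_parent)


def marker_presence(dosage: pd.DataFrame, marker_interval: Interval,
                    genome: GenomeMap | None = None,
                    zero_threshold: float = 0.3) -> str:
    """Presence call for a marker interval from the dosage track.

    'absent' when dosage is ~0 across the whole interval, 'partial' when a
    contiguous sub-interval is ~0, 'present' otherwise.  A hemizygous marker
    reads ~1x and is 'present'.
    """
    if genome is not None:
        if marker_interval.end > genome.length(marker_interval.chromosome):
            raise GenomeError(f"marker interval {marker_interval} outside genome")
    sub = dosage[(dosage["chrom"] == marker_interval.chromosome)
                 & (dosage["start"] < marker_interval.end)
                 & (dosage["end"] > marker_interval.start)]
    if len(sub) == 0:
        raise GenomeError("marker interval not covered by the window grid")
    zero = (sub.sort_values("start")["dosage"].to_numpy() < zero_threshold)
    if zero.all():
        return "absent"
    if zero.any():
        return "partial"
    return "present"
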