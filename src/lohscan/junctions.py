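"""Chimeric-junction detection from discordant read-pair evidence.

Read pairs whose two ends co-locate (within ``max_gap`` on both sides) and
share a strand configuration are clustered into junction calls; the
breakpoint on each side is the median junction-proximal read end.  Strand
convention: each strand records the reference direction of reading through
the junction on that side, so the two strands agree exactly when the
adjacency joins segments in the same relative orientation — (+,+) and (−,−)
are "forward" adjacencies, (+,−) and (−,+) are "inverted".  A fragment
inserted with one inverted and one forward copy therefore shows one inverted
and one forward junction, the diagnostic signature of an inverted-duplication
translocation.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BEDPE_COLUMNS = ["chromA", "startA", "endA", "chromB", "startB", "endB",
                 "name", "score", "strandA", "strandB"]


@dataclass
class JunctionCall:
    """A clustered non-reference adjacency."""

    chromA: str
    posA: int
    strandA: str
    chromB: str
    posB: int
    strandB: str
    support: int
    orientation: str = ""
    near_break: bool | None = None

    def __post_init__(self):
        if not self.orientation:
            self.orientation = infer_orientation(self.strandA, self.strandB)


def junction_positions(evidence: pd.DataFrame) -> pd.DataFrame:
    """Add junction-proximal coordinates posA/posB to BEDPE evidence.

    For a '+' end the junction sits at the read's high coordinate (`end`),
    for a '−' end at its low coordinate (`start`).
    """
    posA = np.where(evidence["strandA"] == "+", evidence["endA"],
                    evidence["startA"])
    posB = np.where(evidence["strandB"] == "+", evidence["endB"],
                    evidence["startB"])
    return evidence.assign(posA=posA.astype(np.int64),
                           posB=posB.astype(np.int64))


def infer_orientation(strandA: str, strandB: str) -> str:
    """Map a strand configuration to forward/inverted adjacency class.

    Reversing both strands (reading the junction from the other side) leaves
    the class unchanged; unknown strands yield 'ambiguous'.
    """
    if strandA not in "+-" or strandB not in "+-":
        return "ambiguous"
    return "forward" if strandA == strandB else "inverted"


def cluster_evidence(evidence: pd.DataFrame, max_gap: int = 500,
                     min_support: int = 3) -> list[JunctionCall]:
    """Cluster read-pair evidence into junction calls.

    Two records belong to the same cluster when they share chromosomes and
    strand configuration and their junction positions are within ``max_gap``
    on BOTH sides (clusters are the connected components of that relation).
    Clusters with fewer than ``min_support`` records are discarded.
    """
    if max_gap <= 0 or min_support < 1:
        raise ValueError("max_gap must be > 0 and min_support >= 1")
    if len(evidence) == 0:
        return []
    ev = junction_positions(evidence)
    calls: list[JunctionCall] = []
    keys = ["chromA", "strandA", "chromB", "strandB"]
    for key, sub in ev.groupby(keys, sort=True):
        sub = sub.sort_values(["posA", "posB"], kind="mergesort")
        pa = sub["posA"].to_numpy()
        pb = sub["posB"].to_numpy()
        n = len(sub)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            j = i + 1
            while j < n and pa[j] - pa[i] <= max_gap:
                if abs(int(pb[j]) - int(pb[i])) <= max_gap:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
                j += 1
        groups: dict[int, list[int]] = {}
        for i in range(n):
            groups.setdefault(find(i), []).append(i)
        chromA, strandA, chromB, strandB = key
        for members in groups.values():
            if len(members) < min_support:
                continue
            calls.append(JunctionCall(
                chromA, int(np.median(pa[members])), strandA,
                chromB, int(np.median(pb[members])), strandB,
                support=len(members)))
    calls.sort(key=lambda c: (c.chromA, c.posA, c.chromB, c.posB))
    return calls


def match_to_break(junctions: list[JunctionCall], break_site,
                   tolerance_bp: int = 1000) -> list[JunctionCall]:
    """Flag junctions with an endpoint within ``tolerance_bp`` (closed
    interval) of the declared cut site; returns the annotated list."""
    if tolerance_bp < 0:
        raise ValueError("tolerance_bp must be >= 0")
    p0 = break_site.pos0
    for j in junctions:
        near = ((j.chromA == break_site.chromosome
                 and abs(j.posA - p0) <= tolerance_bp)
                or (j.chromB == break_site.chromosome
                    and abs(j.posB - p0) <= tolerance_bp))
        j.near_break = bool(near)
    return junctions


def junctions_to_frame(junctions: list[JunctionCall]) -> pd.DataFrame:
    rows = [{"chromA": j.chromA, "posA": j.posA, "strandA": j.strandA,
             "chromB": j.chromB, "posB": j.posB, "strandB": j.strandB,
             "orientation": j.orientation, "support": j.support,
             "near_break": j.near_break} for j in junctions]
    return pd.DataFrame(rows, columns=["chromA", "posA", "strandA", "chromB",
                                       "posB", "strandB", "orientation",
                                       "support", "near_break"])
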