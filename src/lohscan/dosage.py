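"""GC-normalized read-depth dosage estimation.

Windowed read counts are normalized within-sample: unmasked baseline windows
are stratified into deciles of GC fraction, the mean raw count of each decile
is the diploid expectation for windows of that stratum, and dosage is
reported on the "x" scale where a diploid window reads 2:

    dosage(w) = 2 * count(w) / mean_count(decile of w)

The baseline assumes rearrangements affect a small fraction of the genome
(masked regions and known-rearranged chromosomes can be excluded from the
fit).  Decile edges come from the empirical GC quantiles of the baseline
windows; ties at an edge go to the lower decile, and empty strata are merged
with their neighbour.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import EmptyFlankError, GenomeMap, Locus, windows_in_flank


class NoBaselineError(ValueError):
    """No usable windows to fit the GC normalizer on."""


REQUIRED_COLUMNS = ("chrom", "start", "end", "gc", "count")


def validate_window_track(track: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in track.columns]
    if missing:
        raise ValueError(f"window track lacks columns {missing}")
    if (track["count"] < 0).any():
        raise ValueError("negative window counts")
    for _, sub in track.groupby("chrom"):
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        if not (np.all(np.diff(s) > 0) and np.all(e[:-1] <= s[1:])):
            raise ValueError("windows must be sorted and non-overlapping")


class GcNormalizer:
    """Per-decile diploid count expectations, fitted on baseline windows.

    Attributes (after :meth:`fit`): ``edges_`` — interior GC cut points
    (up to 9), ``means_`` — mean raw count per stratum, ``n_`` — windows per
    stratum, ``gc_range_`` — GC span of the baseline.
    """

    def __init__(self, n_strata: int = 10):
        if n_strata < 1:
            raise ValueError("n_strata must be >= 1")
        self.n_strata = n_strata

    def fit(self, track: pd.DataFrame, baseline: np.ndarray | None = None
            ) -> "GcNormalizer":
        """Fit decile edges and means.  ``baseline`` selects the windows used
        (True = use); by default all windows enter the baseline."""
        validate_window_track(track)
        sub = track if baseline is None else track.loc[np.asarray(baseline)]
        if len(sub) < 10:
            raise NoBaselineError(f"only {len(sub)} baseline windows (need >= 10)")
        counts = sub["count"].to_numpy(dtype=float)
        if not (counts > 0).any():
            raise NoBaselineError("baseline counts are all zero")
        gc = sub["gc"].to_numpy(dtype=float)
        qs = np.linspace(0, 1, self.n_strata + 1)[1:-1]
        edges = np.unique(np.quantile(gc, qs))
        strata = np.searchsorted(edges, gc, side="left")
        means = np.zeros(len(edges) + 1)
        ns = np.zeros(len(edges) + 1, dtype=int)
        for k in range(len(edges) + 1):
            sel = strata == k
            ns[k] = sel.sum()
            means[k] = counts[sel].mean() if ns[k] else np.nan
        # merge empty strata into the nearest non-empty neighbour
        while np.any(ns == 0) and len(ns) > 1:
            k = int(np.flatnonzero(ns == 0)[0])
            warnings.warn(f"empty GC stratum {k} merged with neighbour",
                          stacklevel=2)
            drop_edge = k - 1 if k > 0 else 0
            edges = np.delete(edges, drop_edge)
            strata = np.searchsorted(edges, gc, side="left")
            means = np.zeros(len(edges) + 1)
            ns = np.zeros(len(edges) + 1, dtype=int)
            for k2 in range(len(edges) + 1):
                sel = strata == k2
                ns[k2] = sel.sum()
                means[k2] = counts[sel].mean() if ns[k2] else np.nan
        self.edges_ = edges
        self.means_ = means
        self.n_ = ns
        self.gc_range_ = (float(gc.min()), float(gc.max()))
        return self

    def _check_fitted(self):
        if not hasattr(self, "means_"):
            raise NoBaselineError("normalizer not fitted")

    def stratum(self, gc: np.ndarray) -> np.ndarray:
        """Stratum index for GC values; values outside the fitted range are
        clamped into the terminal strata (with a warning)."""
        self._check_fitted()
        gc = np.asarray(gc, dtype=float)
        lo, hi = self.gc_range_
        if np.any((gc < lo) | (gc > hi)):
            warnings.warn("GC fraction outside fitted range; clamped to the "
                          "nearest stratum", stacklevel=2)
        return np.searchsorted(self.edges_, gc, side="left")

    def expected_diploid(self, track: pd.DataFrame) -> np.ndarray:
        """Expected diploid count per window of ``track``."""
        return self.means_[self.stratum(track["gc"].to_numpy())]

    def transform(self, track: pd.DataFrame) -> pd.DataFrame:
        """Alias of :func:`estimate_dosage` for pipeline-style use."""
        return estimate_dosage(track, self)


def fit_gc_normalizer(track: pd.DataFrame, baseline_mask: np.ndarray | None = None,
                      n_strata: int = 10) -> GcNormalizer:
    """Fit the per-decile diploid expectations.

    ``baseline_mask`` is True for windows EXCLUDED from the baseline (masked),
    matching the masking convention used everywhere else.
    """
    baseline = None if baseline_mask is None else ~np.asarray(baseline_mask)
    return GcNormalizer(n_strata).fit(track, baseline)


def estimate_dosage(track: pd.DataFrame, normalizer: GcNormalizer) -> pd.DataFrame:
    """Dosage track on the diploid x scale: 2 * count / decile mean."""
    validate_window_track(track)
    mu = normalizer.expected_diploid(track)
    dosage = 2.0 * track["count"].to_numpy(dtype=float) / mu
    return track.assign(dosage=dosage)


def flank_mean_dosage(dosage: pd.DataFrame, break_site: Locus, flank_bp: int,
                      side: str, genome: GenomeMap,
                      masked: np.ndarray | None = None) -> tuple[float, int]:
    """Mean window dosage over a 1-sided break flank.

    Returns (mean, number of windows used); raises
    :class:`~lohscan.genome.EmptyFlankError` for an unusable flank.
    """
    if "dosage" not in dosage.columns:
        raise ValueError("expected a dosage track (missing 'dosage' column)")
    sel = windows_in_flank(dosage, break_site, flank_bp, side, genome, masked)
    vals = dosage.loc[sel, "dosage"].to_numpy()
    if len(vals) == 0:
        raise EmptyFlankError(f"empty {side} flank")
    return float(vals.mean()), int(len(vals))
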