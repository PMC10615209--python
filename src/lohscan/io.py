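"""Readers/writers for the plain-text interchange formats.

Window counts travel as bedGraph (chrom, start, end, count) with a companion
GC BED (chrom, start, end, gc_fraction); dosage as bedGraph; SNP depths as a
headered TSV; junction evidence as 10-column BEDPE.  All coordinates on disk
are 0-based half-open, matching the internal convention.
"""
from __future__ import annotations

import pandas as pd

from .junctions import BEDPE_COLUMNS

SNP_COLUMNS = ["chrom", "pos", "allele_a", "allele_b", "depth_a", "depth_b"]


def read_bedgraph(path: str, value: str = "count") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", value])
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_bedgraph(df: pd.DataFrame, path: str, value: str = "count") -> None:
    df[["chrom", "start", "end", value]].to_csv(path, sep="\t", header=False,
                                                index=False)


def read_window_track(bedgraph_path: str, gc_bed_path: str) -> pd.DataFrame:
    """Join a count bedGraph with its GC companion BED on the window grid."""
    counts = read_bedgraph(bedgraph_path, "count")
    gc = read_bedgraph(gc_bed_path, "gc")
    track = counts.merge(gc, on=["chrom", "start", "end"], how="left",
                         validate="one_to_one")
    if track["gc"].isna().any():
        raise ValueError("GC BED does not cover every count window")
    return track[["chrom", "start", "end", "gc", "count"]]


def write_window_track(track: pd.DataFrame, bedgraph_path: str,
                       gc_bed_path: str) -> None:
    write_bedgraph(track, bedgraph_path, "count")
    write_bedgraph(track, gc_bed_path, "gc")


def read_snp_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP table lacks columns {missing}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def write_snp_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_bedpe(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=BEDPE_COLUMNS)
    df["chromA"] = df["chromA"].astype(str)
    df["chromB"] = df["chromB"].astype(str)
    return df


def write_bedpe(df: pd.DataFrame, path: str) -> None:
    df[BEDPE_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
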