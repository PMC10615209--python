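"""End-to-end orchestration: simulate -> dosage -> classify -> LOH -> junctions.

The pipeline is a pure function of its configuration: fixed seeds give
byte-identical outputs.  Every stage writes its table to the output
directory, and the run report only contains numbers traceable to those
files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, simulate
from .dosage import estimate_dosage, fit_gc_normalizer, flank_mean_dosage
from .genome import EmptyFlankError, GenomeMap, Interval, Locus
from .junctions import cluster_evidence, junctions_to_frame, match_to_break
from .loh import call_genotypes, classify_mechanism, detect_transition
from .lrt import classify_break
from .simulate import (DEMO_BREAK, DEMO_MARKER, ObservationConfig, SnpPanel,
                       demo_genome)

log = logging.getLogger("lohscan")

SCENARIOS = ("diploid_control", "bfbc", "arm_loss", "monosomy",
             "chimera_deletion", "crossover", "translocation")


@dataclass
class PipelineConfig:
    """Configuration for a full run.  Defaults mirror the analysis the
    package implements: 250-kb genome-wide and 5-kb zoom windows, 1-Mbp
    flanks, alpha 0.001."""

    outdir: str = "lohscan_run"
    scenario: str = "bfbc"
    seed: int = 0
    window_size: int = 5_000
    genome_window_size: int = 250_000
    per_copy_depth: float = 25.0
    flank_bp: int = 1_000_000
    alpha: float = 0.001
    snp_spacing: int = 100_000
    snp_depth: float = 30.0
    break_chrom: str = DEMO_BREAK.chromosome
    break_pos: int = DEMO_BREAK.position
    marker_start: int = DEMO_MARKER.start
    marker_end: int = DEMO_MARKER.end
    chimera_fraction: float = 1.0
    min_support: int = 3
    max_gap: int = 500

    def __post_init__(self):
        for name in ("window_size", "genome_window_size", "per_copy_depth",
                     "flank_bp", "alpha", "snp_spacing", "snp_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def build_scenario(config: PipelineConfig, genome: GenomeMap):
    """Instantiate the ground-truth karyotype(s) for a named scenario.

    Returns (karyotype, companion_or_None, chimera_fraction, truth_dict).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 17)))
    brk = Locus(config.break_chrom, config.break_pos, "break")
    truth: dict = {"scenario": config.scenario}
    frac = 1.0
    companion = None
    if config.scenario == "diploid_control":
        k = simulate.diploid(genome)
    elif config.scenario == "bfbc":
        k, dup = simulate.bfbc_derivative(genome, brk, rng)
        truth["duplicated_interval"] = [dup.chromosome, dup.start, dup.end]
    elif config.scenario == "arm_loss":
        k = simulate.arm_loss(genome, brk)
    elif config.scenario == "monosomy":
        k = simulate.monosomy(genome, brk.chromosome)
    elif config.scenario == "chimera_deletion":
        region = Interval(brk.chromosome, max(0, brk.pos0 - 6_000_000),
                          brk.pos0 - 1_000_000)
        k = simulate.segmental_deletion(genome, region)
        frac = config.chimera_fraction if config.chimera_fraction < 1.0 else 0.5
        companion = simulate.diploid(genome)
        truth["deleted_region"] = [region.chromosome, region.start, region.end]
        truth["chimera_fraction"] = frac
    elif config.scenario == "crossover":
        k = simulate.crossover_sector(genome, brk)
    elif config.scenario == "translocation":
        target = Locus("ch09", 51_000_000, "insertion")
        k, dup = simulate.translocation_insertion(genome, brk, target, rng)
        truth["translocated_interval"] = [dup.chromosome, dup.start, dup.end]
        truth["insertion_site"] = [target.chromosome, target.position]
    return k, companion, frac, truth


@dataclass
class RunReport:
    """Everything a run produced, traceable to the stage output files."""

    version: str
    config: dict
    chromosome_summaries: list[dict] = field(default_factory=list)
    break_classification: list[dict] = field(default_factory=list)
    call: str = ""
    flank_dosages: dict = field(default_factory=dict)
    loh: dict = field(default_factory=dict)
    junctions: list[dict] = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


def summarize_chromosome(dosage: pd.DataFrame, chromosome: str,
                         masked: np.ndarray | None = None) -> dict:
    """Mean/median dosage and the window fraction near each integer level."""
    sel = dosage["chrom"] == chromosome
    if masked is not None:
        sel &= ~masked
    vals = dosage.loc[sel, "dosage"].to_numpy()
    if len(vals) == 0:
        raise ValueError(f"no usable windows on {chromosome}")
    out = {"chrom": chromosome, "n_windows": int(len(vals)),
           "mean": float(vals.mean()), "median": float(np.median(vals))}
    for level in (0, 1, 2, 3):
        out[f"frac_{level}x"] = float(np.mean(np.abs(vals - level) <= 0.25))
    return out


def run_pipeline(config: PipelineConfig, genome: GenomeMap | None = None
                 ) -> RunReport:
    """Execute the full pipeline and write all intermediates to outdir."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome = demo_genome()
    genome.to_files(str(outdir / "genome.tsv"), str(outdir / "centromeres.bed"),
                    str(outdir / "mask.bed"))
    brk = Locus(config.break_chrom, config.break_pos, "break")
    marker = Interval(config.break_chrom, config.marker_start, config.marker_end)

    log.info("stage simulate: scenario=%s seed=%d", config.scenario, config.seed)
    karyotype, companion, frac, truth = build_scenario(config, genome)
    karyotype.to_json(str(outdir / "karyotype.json"))
    obs = ObservationConfig(window_size=config.window_size,
                            per_copy_depth=config.per_copy_depth,
                            seed=config.seed, chimera_fraction=frac)
    track = simulate.simulate_window_counts(karyotype, obs, companion=companion)
    io.write_window_track(track, str(outdir / "windows.bedgraph"),
                          str(outdir / "gc.bed"))
    panel = SnpPanel.regular(genome, config.snp_spacing,
                             chromosomes=[brk.chromosome])
    snps = simulate.simulate_snp_depths(karyotype, panel, config.snp_depth,
                                        seed=config.seed)
    io.write_snp_table(snps, str(outdir / "snps.tsv"))
    evidence = simulate.simulate_junction_reads(karyotype, seed=config.seed)
    io.write_bedpe(evidence, str(outdir / "junctions.bedpe"))

    log.info("stage dosage: %d windows", len(track))
    masked = genome.mask_array(track)
    baseline_excl = masked | (track["chrom"] == brk.chromosome).to_numpy()
    norm = fit_gc_normalizer(track, baseline_mask=baseline_excl)
    dosage = estimate_dosage(track, norm)
    io.write_bedgraph(dosage, str(outdir / "dosage.bedgraph"), "dosage")

    log.info("stage classify: break %s:%d", brk.chromosome, brk.position)
    cls = classify_break(track, norm, brk, genome, config.flank_bp,
                         config.alpha, masked)
    cls.to_frame().to_csv(outdir / "classification.tsv", sep="\t", index=False)
    flank_dos = {}
    for side in ("proximal", "distal"):
        try:
            mean, n = flank_mean_dosage(dosage, brk, config.flank_bp, side,
                                        genome, masked)
            flank_dos[side] = {"mean_dosage": mean, "windows": n}
        except EmptyFlankError:
            flank_dos[side] = None

    log.info("stage loh")
    calls = call_genotypes(snps)
    transition = detect_transition(calls, brk)
    loh_call = classify_mechanism(transition, dosage, cls, genome,
                                  marker_interval=marker)
    loh_row = {"chromosome": loh_call.chromosome,
               "mechanism": loh_call.mechanism, "extent": loh_call.extent,
               "retained_parent": loh_call.retained_parent,
               "marker_status": loh_call.marker_status,
               "transition_kind": transition.kind,
               "transition_interval": list(transition.interval or ())}
    pd.DataFrame([loh_row]).to_csv(outdir / "loh.tsv", sep="\t", index=False)

    log.info("stage junctions: %d evidence pairs", len(evidence))
    junction_calls = cluster_evidence(evidence, config.max_gap,
                                      config.min_support)
    match_to_break(junction_calls, brk)
    jframe = junctions_to_frame(junction_calls)
    jframe.to_csv(outdir / "junction_calls.tsv", sep="\t", index=False)

    report = RunReport(
        version=__version__, config=config.to_dict(),
        chromosome_summaries=[summarize_chromosome(dosage, c, masked)
                              for c in genome.names],
        break_classification=cls.to_frame().to_dict(orient="records"),
        call=cls.call, flank_dosages=flank_dos, loh=loh_row,
        junctions=jframe.to_dict(orient="records"), truth=truth)
    report.to_json(str(outdir / "report.json"))
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return report
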