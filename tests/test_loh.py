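"""Genotype calling, transition detection and LOH mechanism classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lohscan.dosage import estimate_dosage, fit_gc_normalizer
from lohscan.genome import Interval, Locus
from lohscan.loh import (call_genotypes, classify_mechanism, detect_transition,
                         marker_presence)
from lohscan.lrt import classify_break
from lohscan.simulate import (ObservationConfig, SnpPanel, arm_loss,
                              crossover_sector, diploid, monosomy,
                              segmental_deletion, simulate_snp_depths,
                              simulate_window_counts)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "allele_a", "allele_b",
                                       "depth_a", "depth_b"])


class TestCallGenotypes:
    @pytest.mark.parametrize("da, db, expected", [
        (15, 15, "heterozygous"),
        (20, 0, "homozygous_A"),
        (0, 20, "homozygous_B"),
        (25, 5, "homozygous_A"),   # minor fraction 1/6 < 0.2
        (24, 6, "heterozygous"),   # minor fraction 0.2 meets the threshold
        (3, 2, "missing"),         # below min_depth
        (0, 0, "missing"),
    ])
    def test_threshold_logic(self, da, db, expected):
        calls = call_genotypes(snp_frame([("c", 100, "A", "G", da, db)]),
                               min_depth=8, het_fraction=0.2)
        assert calls["call"].iloc[0] == expected

    def test_zero_depth_never_divides_by_zero(self):
        calls = call_genotypes(snp_frame([("c", 1, "A", "G", 0, 0)]),
                               min_depth=0)
        assert calls["call"].iloc[0] == "missing"

    def test_het_miscall_rate_binomial_30(self):
        # analytic check: at depth 30 and balanced alleles, a heterozygote is
        # miscalled only when the minor count falls below 0.2*30 = 6
        p_miss = stats.binom.cdf(5, 30, 0.5) + stats.binom.sf(24, 30, 0.5)
        assert p_miss < 1e-3
        # and the caller reproduces the boundary exactly
        for minor in range(31):
            call = call_genotypes(
                snp_frame([("c", 1, "A", "G", minor, 30 - minor)]),
                min_depth=8, het_fraction=0.2)["call"].iloc[0]
            assert (call == "heterozygous") == (6 <= minor <= 24)

    def test_simulated_hemizygous_locus_is_homozygous(self, toy_genome):
        k = arm_loss(toy_genome, Locus("cA", 900_001), haplotype="B")
        panel = SnpPanel.regular(toy_genome, 50_000)
        calls = call_genotypes(simulate_snp_depths(k, panel, 30.0, seed=3))
        distal = calls[(calls["chrom"] == "cA") & (calls["pos"] > 900_001)]
        # half-depth loci may drop below min_depth; none may call het or B
        assert set(distal["call"]) <= {"homozygous_A", "missing"}
        assert (distal["call"] == "homozygous_A").mean() > 0.8


def calls_from_pattern(pattern, spacing=100, chrom="c"):
    """'h'=het, 'A'/'B'=homozygous, '.'=missing, at positions 100,200,..."""
    name = {"h": "heterozygous", "A": "homozygous_A", "B": "homozygous_B",
            ".": "missing"}
    rows = [{"chrom": chrom, "pos": (i + 1) * spacing, "call": name[c]}
            for i, c in enumerate(pattern)]
    return pd.DataFrame(rows)


class TestDetectTransition:
    def test_het_to_hom_brackets_break(self):
        calls = calls_from_pattern("hhhhBBBB")
        tr = detect_transition(calls, Locus("c", 450))
        assert tr.kind == "transition"
        assert tr.interval == (400, 500)
        assert tr.retained_parent == "B"
        assert tr.contains_break
        assert tr.hom_side == "right"

    def test_all_heterozygous_is_none(self):
        tr = detect_transition(calls_from_pattern("hhhhhh"), Locus("c", 300))
        assert tr.kind == "none"

    def test_chromosome_wide_homozygosity(self):
        tr = detect_transition(calls_from_pattern("AAAAAA"), Locus("c", 300))
        assert tr.kind == "whole_chromosome"
        assert tr.retained_parent == "A"

    def test_all_missing_undetermined(self):
        tr = detect_transition(calls_from_pattern("......"), Locus("c", 300))
        assert tr.kind == "undetermined"

    def test_single_miscall_does_not_move_transition(self):
        calls = calls_from_pattern("hhBhhhBBBB")  # one stray hom upstream
        tr = detect_transition(calls, Locus("c", 650))
        assert tr.interval == (600, 700)

    def test_axis_reversal_invariance(self):
        for pattern in ("hhhhBB", "hhBBBBB", "AAAAhh", "hAhhBBB"):
            calls = detect_transition(calls_from_pattern(pattern),
                                      Locus("c", 10 + 50 * len(pattern)))
            n = len(pattern)
            flipped = calls_from_pattern(pattern[::-1])
            flipped["pos"] = (n + 1) * 100 - flipped["pos"].to_numpy()[::-1]
            flipped = flipped.iloc[::-1].reset_index(drop=True)
            mirrored = detect_transition(
                flipped.sort_values("pos"),
                Locus("c", (n + 1) * 100 - (10 + 50 * n)))
            fwd = detect_transition(calls_from_pattern(pattern),
                                    Locus("c", 10 + 50 * n))
            assert mirrored.kind == fwd.kind
            if fwd.interval is not None:
                lo, hi = fwd.interval
                assert mirrored.interval == ((n + 1) * 100 - hi,
                                             (n + 1) * 100 - lo)


def run_scenario(genome, karyotype, brk, seed, snp_depth=30.0):
    config = ObservationConfig(per_copy_depth=25.0, seed=seed)
    track = simulate_window_counts(karyotype, config)
    baseline_excl = (track["chrom"] == brk.chromosome).to_numpy()
    norm = fit_gc_normalizer(track, baseline_mask=baseline_excl)
    dosage = estimate_dosage(track, norm)
    cls = classify_break(track, norm, brk, genome)
    panel = SnpPanel.regular(genome, 100_000, chromosomes=[brk.chromosome])
    snps = simulate_snp_depths(karyotype, panel, snp_depth, seed=seed)
    tr = detect_transition(call_genotypes(snps), brk)
    return classify_mechanism(tr, dosage, cls, genome)


class TestClassifyMechanism:
    def test_crossover(self, sim_genome, sim_break):
        k = crossover_sector(sim_genome, sim_break, retained="A")
        call = run_scenario(sim_genome, k, sim_break, seed=31)
        assert call.mechanism == "crossover"
        assert call.retained_parent == "A"

    def test_segmental_loss(self, sim_genome, sim_break):
        k = arm_loss(sim_genome, sim_break, haplotype="B")
        call = run_scenario(sim_genome, k, sim_break, seed=32)
        assert call.mechanism == "segmental_loss"
        assert call.extent == "distal_segment"
        assert call.retained_parent == "A"

    def test_chromosome_loss(self, sim_genome, sim_break):
        k = monosomy(sim_genome, "cE", lost_haplotype="B")
        call = run_scenario(sim_genome, k, sim_break, seed=33)
        assert call.mechanism == "chromosome_loss"
        assert call.extent == "whole_chromosome"

    def test_conflicting_evidence_is_undetermined(self, sim_genome, sim_break):
        # homozygous transition but dosage stays diploid on a 3x-free track
        # with a significant duplication flank: no supported mechanism
        k = crossover_sector(sim_genome, sim_break, retained="A")
        config = ObservationConfig(per_copy_depth=25.0, seed=34)
        track = simulate_window_counts(k, config)
        distal = ((track["chrom"] == "cE")
                  & (track["start"] >= sim_break.pos0)).to_numpy()
        track.loc[distal, "count"] = (track.loc[distal, "count"] * 1.5).astype(int)
        norm = fit_gc_normalizer(
            track, baseline_mask=(track["chrom"] == "cE").to_numpy())
        dosage = estimate_dosage(track, norm)
        cls = classify_break(track, norm, sim_break, sim_genome)
        panel = SnpPanel.regular(sim_genome, 100_000, chromosomes=["cE"])
        snps = simulate_snp_depths(k, panel, 30.0, seed=34)
        tr = detect_transition(call_genotypes(snps), sim_break)
        call = classify_mechanism(tr, dosage, cls, sim_genome)
        assert call.mechanism == "undetermined"
        assert "conflict" in call.diagnostics


class TestMarkerPresence:
    @pytest.fixture
    def dosage_frame(self, sim_genome):
        windows = sim_genome.windows(5_000)
        return windows.assign(dosage=2.0)

    def test_present_absent_partial(self, sim_genome, dosage_frame):
        marker = Interval("cE", 6_000_000, 6_050_000)
        assert marker_presence(dosage_frame, marker, sim_genome) == "present"
        inside = ((dosage_frame["chrom"] == "cE")
                  & (dosage_frame["start"] >= marker.start)
                  & (dosage_frame["end"] <= marker.end))
        zeroed = dosage_frame.copy()
        zeroed.loc[inside, "dosage"] = 0.0
        assert marker_presence(zeroed, marker, sim_genome) == "absent"
        partial = dosage_frame.copy()
        rows = np.flatnonzero(inside.to_numpy())
        partial.loc[partial.index[rows[2:5]], "dosage"] = 0.05
        assert marker_presence(partial, marker, sim_genome) == "partial"

    def test_hemizygous_marker_is_present(self, sim_genome, dosage_frame):
        marker = Interval("cE", 6_000_000, 6_050_000)
        hemi = dosage_frame.copy()
        inside = ((hemi["chrom"] == "cE") & (hemi["start"] >= marker.start)
                  & (hemi["end"] <= marker.end))
        hemi.loc[inside, "dosage"] = 1.0
        assert marker_presence(hemi, marker, sim_genome) == "present"

    def test_interval_outside_genome_rejected(self, sim_genome, dosage_frame):
        with pytest.raises(Exception, match="outside"):
            marker_presence(dosage_frame, Interval("cE", 0, 99_000_000),
                            sim_genome)

    def test_homozygous_deletion_region_reads_absent(self, sim_genome):
        # both haplotypes deleted over the marker: simulated dosage ~0
        region = Interval("cE", 6_000_000, 6_200_000)
        k = segmental_deletion(sim_genome, region, haplotype="A")
        k2 = segmental_deletion(sim_genome, region, haplotype="B")
        k.replace_copy("cE_B", k2.find_copy("cE_B"))
        config = ObservationConfig(per_copy_depth=25.0, seed=35)
        track = simulate_window_counts(k, config)
        norm = fit_gc_normalizer(
            track, baseline_mask=(track["chrom"] == "cE").to_numpy())
        dosage = estimate_dosage(track, norm)
        assert marker_presence(dosage, Interval("cE", 6_050_000, 6_150_000),
                               sim_genome) == "absent"
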