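"""Observation models: window counts, SNP depths, junction read pairs."""

import numpy as np
import pandas as pd
import pytest

from lohscan.events import Karyotype, project_dosage
from lohscan.genome import GenomeMap, Interval, Locus
from lohscan.simulate import (ObservationConfig, SnpPanel, arm_loss,
                              bfbc_derivative, crossover_sector, diploid,
                              flat_gc_bias, monosomy, novel_adjacencies,
                              segmental_deletion, simulate_junction_reads,
                              simulate_snp_depths, simulate_window_counts,
                              translocation_insertion)


@pytest.fixture
def big_flat_genome():
    """Single 50-Mb chromosome: 10^4 five-kb windows for LLN-grade checks."""
    return GenomeMap([("c1", 50_000_000)], centromeres={"c1": 10_000_000})


class TestWindowCounts:
    def test_law_of_large_numbers(self, big_flat_genome):
        # empirical mean/expected mean -> 1 within 1% at 10^4 windows
        config = ObservationConfig(per_copy_depth=25.0, seed=7,
                                   gc_bias=flat_gc_bias)
        track = simulate_window_counts(diploid(big_flat_genome), config)
        assert len(track) == 10_000
        assert track["count"].mean() == pytest.approx(50.0, rel=0.01)

    def test_duplicated_windows_scale_with_copy_number(self, big_flat_genome):
        config = ObservationConfig(per_copy_depth=25.0, seed=8,
                                   gc_bias=flat_gc_bias)
        region = Interval("c1", 20_000_000, 40_000_000)
        k = segmental_deletion(big_flat_genome, region)
        track = simulate_window_counts(k, config)
        inside = ((track["start"] >= region.start)
                  & (track["end"] <= region.end)).to_numpy()
        ratio = track.loc[inside, "count"].mean() / track.loc[~inside,
                                                              "count"].mean()
        assert ratio == pytest.approx(0.5, rel=0.02)

    def test_seed_reproducibility(self, toy_genome):
        config = ObservationConfig(seed=42)
        k = diploid(toy_genome)
        t1 = simulate_window_counts(k, config)
        t2 = simulate_window_counts(k, config)
        pd.testing.assert_frame_equal(t1, t2)
        t3 = simulate_window_counts(k, ObservationConfig(seed=43))
        assert not t3["count"].equals(t1["count"])

    def test_gc_landscape_shared_across_samples(self, toy_genome):
        config = ObservationConfig(seed=5)
        t_dip = simulate_window_counts(diploid(toy_genome), config)
        t_mono = simulate_window_counts(monosomy(toy_genome, "cA"), config)
        assert t_dip["gc"].equals(t_mono["gc"])

    def test_chimera_fraction_halves_the_signal(self, big_flat_genome):
        region = Interval("c1", 20_000_000, 40_000_000)
        k = segmental_deletion(big_flat_genome, region)
        config = ObservationConfig(per_copy_depth=25.0, seed=9,
                                   gc_bias=flat_gc_bias, chimera_fraction=0.5)
        track = simulate_window_counts(k, config)
        inside = ((track["start"] >= region.start)
                  & (track["end"] <= region.end)).to_numpy()
        assert track.loc[inside, "count"].mean() == pytest.approx(37.5, rel=0.02)

    def test_overdispersion_inflates_variance(self, big_flat_genome):
        base = ObservationConfig(per_copy_depth=25.0, seed=3,
                                 gc_bias=flat_gc_bias)
        over = ObservationConfig(per_copy_depth=25.0, seed=3,
                                 gc_bias=flat_gc_bias, overdispersion=0.3)
        k = diploid(big_flat_genome)
        v0 = simulate_window_counts(k, base)["count"].var()
        v1 = simulate_window_counts(k, over)["count"].var()
        assert v1 > 2 * v0  # var = mu + od * mu^2 >> mu at mu = 50


class TestSnpDepths:
    def test_intact_f1_is_balanced(self, toy_genome):
        panel = SnpPanel.regular(toy_genome, 100_000)
        snps = simulate_snp_depths(diploid(toy_genome), panel, 30.0, seed=0)
        total = snps["depth_a"] + snps["depth_b"]
        assert total.mean() == pytest.approx(30.0, rel=0.1)
        assert snps["depth_a"].sum() / total.sum() == pytest.approx(0.5, abs=0.05)

    def test_arm_loss_leaves_only_retained_parent(self, toy_genome):
        brk = Locus("cA", 900_001)
        k = arm_loss(toy_genome, brk, haplotype="B")
        panel = SnpPanel.regular(toy_genome, 50_000)
        snps = simulate_snp_depths(k, panel, 30.0, seed=1)
        distal = snps[(snps["chrom"] == "cA") & (snps["pos"] > brk.position)]
        assert (distal["depth_b"] == 0).all()
        # hemizygous loci carry half depth
        assert (distal["depth_a"] + distal["depth_b"]).mean() == pytest.approx(
            15.0, rel=0.15)

    def test_crossover_keeps_full_depth_but_homozygoses(self, toy_genome):
        brk = Locus("cA", 900_001)
        k = crossover_sector(toy_genome, brk, retained="A")
        panel = SnpPanel.regular(toy_genome, 50_000)
        snps = simulate_snp_depths(k, panel, 30.0, seed=2)
        distal = snps[(snps["chrom"] == "cA") & (snps["pos"] > brk.position)]
        proximal = snps[(snps["chrom"] == "cA") & (snps["pos"] < brk.position)]
        assert (distal["depth_b"] == 0).all()          # homozygous retained parent
        assert (distal["depth_a"] + distal["depth_b"]).mean() == pytest.approx(
            30.0, rel=0.15)                            # read depth unchanged
        assert (proximal["depth_b"] > 0).mean() > 0.95  # still heterozygous


class TestJunctionReads:
    def test_reference_karyotype_has_no_adjacencies(self, toy_genome):
        assert len(novel_adjacencies(diploid(toy_genome))) == 0
        ev = simulate_junction_reads(diploid(toy_genome), seed=0)
        assert len(ev) == 0

    def test_insertion_produces_signature_junctions(self, toy_genome):
        rng = np.random.default_rng(11)
        k, dup = translocation_insertion(toy_genome, Locus("cA", 1_300_001),
                                         Locus("cB", 800_001), rng,
                                         min_duplication_bp=200_000)
        adj = novel_adjacencies(k)
        outer = adj[(adj["chromA"] == "cB") | (adj["chromB"] == "cB")]
        assert len(outer) == 2
        classes = {("forward" if a == b else "inverted")
                   for a, b in zip(outer["strandA"], outer["strandB"])}
        assert classes == {"forward", "inverted"}
        # both insertion junctions anchor at the insertion site on cB
        cb_pos = [r.posA if r.chromA == "cB" else r.posB
                  for r in outer.itertuples()]
        assert set(cb_pos) == {800_000}

    def test_support_scales_with_rate(self, toy_genome):
        k, _ = translocation_insertion(toy_genome, Locus("cA", 1_300_001),
                                       Locus("cB", 800_001),
                                       np.random.default_rng(3),
                                       min_duplication_bp=200_000)
        lo = simulate_junction_reads(k, pairs_per_junction=100, seed=4)
        hi = simulate_junction_reads(k, pairs_per_junction=200, seed=4)
        assert len(hi) / len(lo) == pytest.approx(2.0, rel=0.15)

    def test_noise_free_reads_hit_breakpoints_exactly(self, toy_genome):
        k, _ = translocation_insertion(toy_genome, Locus("cA", 1_300_001),
                                       Locus("cB", 800_001),
                                       np.random.default_rng(3),
                                       min_duplication_bp=200_000)
        adj = novel_adjacencies(k)
        ev = simulate_junction_reads(k, seed=5, jitter=0)
        from lohscan.junctions import junction_positions
        pos = junction_positions(ev)
        truth = set(map(tuple, adj[["chromA", "posA", "chromB", "posB"]]
                        .itertuples(index=False)))
        observed = set(map(tuple, pos[["chromA", "posA", "chromB", "posB"]]
                           .itertuples(index=False)))
        assert observed == truth


class TestBfbcBuilder:
    def test_duplication_covers_requested_span(self, sim_genome, sim_break):
        for seed in range(3):
            rng = np.random.default_rng(seed)
            k, dup = bfbc_derivative(sim_genome, sim_break, rng,
                                     min_duplication_bp=1_100_000)
            assert dup.length >= 1_100_000
            assert dup.chromosome == "cE"
            assert dup.end == sim_break.pos0
            # expected dosage: 3x just proximal of the break, 1x distal
            windows = sim_genome.windows(5_000)
            dos = project_dosage(k, windows)
            w = windows.assign(dos=dos)
            prox = w[(w["chrom"] == "cE") & (w["start"] >= dup.end - 1_000_000)
                     & (w["end"] <= dup.end)]
            dist = w[(w["chrom"] == "cE") & (w["start"] >= sim_break.pos0)]
            assert np.allclose(prox["dos"], 3.0)
            assert np.allclose(dist["dos"], 1.0)
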