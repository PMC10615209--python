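import numpy as np
import pytest

from lohscan.genome import GenomeMap, Interval, Locus


@pytest.fixture
def toy_genome():
    """Two small chromosomes for per-base oracle checks (no masks)."""
    return GenomeMap(
        chromosomes=[("cA", 2_000_000), ("cB", 1_200_000)],
        centromeres={"cA": 400_000, "cB": 300_000},
    )


@pytest.fixture
def masked_genome():
    """Toy genome with a masked centromeric block on cA."""
    return GenomeMap(
        chromosomes=[("cA", 2_000_000), ("cB", 1_200_000)],
        centromeres={"cA": 400_000, "cB": 300_000},
        masked_regions=[Interval("cA", 350_000, 450_000)],
    )


@pytest.fixture
def sim_genome():
    """Two mid-size chromosomes for simulation-recovery tests: cE carries the
    events, cD stays diploid and serves as the normalization baseline."""
    return GenomeMap(
        chromosomes=[("cD", 4_000_000), ("cE", 8_000_000)],
        centromeres={"cD": 1_000_000, "cE": 1_000_000},
    )


@pytest.fixture
def sim_break():
    return Locus("cE", 5_000_001, "break")


class FixedRng:
    """Deterministic stand-in for a Generator: integers() returns a constant."""

    def __init__(self, value):
        self.value = value

    def integers(self, low, high=None):
        return self.value


@pytest.fixture
def fixed_rng():
    return FixedRng
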