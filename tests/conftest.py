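"""Shared fixtures: toy genomes with hand-checkable digestion patterns and a
session-scoped synthetic 4C bundle reused across profile-level tests."""

from __future__ import annotations

import numpy as np
import pytest

import shox4c as s

# DpnII cuts at {2, 18} (GATC, offset 0), Csp6I at {11} (GTAC, offset 1):
# fragments [0,2) terminal, [2,11) P/S, [11,18) S/P, [18,24) terminal.
TOY_GENOME = "AAGATCAAAAGTACAAAAGATCAA"


@pytest.fixture(scope="session")
def toy_map():
    return s.build_fragment_map({"toy": TOY_GENOME}, min_fragment_length=5)


@pytest.fixture(scope="session")
def toy_map_strict():
    """Toy genome with the default 40 bp threshold: every cut-bounded fragment
    is too short."""
    return s.build_fragment_map({"toy": TOY_GENOME}, min_fragment_length=40)


@pytest.fixture(scope="session")
def small_map():
    """50 kb seeded synthetic genome digested with the default enzymes."""
    genome = {"chr_s": s.make_genome(50_000, seed=42)}
    return s.build_fragment_map(genome)


class SimBundle:
    """Default-condition 4C simulation shared by profile-level tests."""

    def __init__(self, seed: int = 7, n_reads: int = 100_000):
        self.length = 2_000_000
        self.genome = {"chrX_sim": s.make_genome(self.length, seed=seed)}
        self.fmap = s.build_fragment_map(self.genome)
        self.model = s.default_contact_model(self.length)
        self.reads, self.truth = s.simulate_4c_reads(
            self.model, self.fmap, n_reads, seed=seed + 1
        )
        vp = self.model.viewpoint_position
        self.viewpoint_region = s.GenomicInterval("chrX_sim", vp, vp + 1)
        self.viewpoint = s.locate_viewpoint(self.fmap, self.viewpoint_region)
        self.profile = s.build_profile(self.fmap, self.reads, self.viewpoint)
        self.features = s.make_features(self.fmap, self.model, seed=seed + 2)


@pytest.fixture(scope="session")
def sim():
    return SimBundle()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
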