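"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import pytest

from anchorpet.simulate import SimulationConfig, simulate_sample


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced-scale run: 7-kb and 30-kb loci, 1,500 pairs, pure tumor."""
    return SimulationConfig(
        locus_lengths=(7_000, 30_000),
        breakpoint_a=3_000,
        breakpoint_b=15_000,
        n_pairs=1_500,
        tumor_fraction=1.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_sample(small_config):
    return simulate_sample(small_config)


@pytest.fixture(scope="session")
def default_sample():
    """Default-scale sample (7 kb / 175 kb loci, 2,000 pairs)."""
    return simulate_sample(SimulationConfig(seed=5))
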