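"""Shared fixtures: generated universes and their detection results."""

import pytest

from phageneck.pipeline import detect_all
from phageneck.synthetic import (
    UniverseConfig,
    generate_universe,
    generate_worked_examples,
)


@pytest.fixture(scope="session")
def worked():
    """The six reference-phage fixtures (SPP1, Lambda, HK97, T4, P22, Phi29)."""
    return generate_worked_examples()


@pytest.fixture(scope="session")
def worked_detections(worked):
    table, models, flags = detect_all(
        worked.genomes, worked.provider, worked.metadata
    )
    return table


@pytest.fixture(scope="session")
def clean_universe():
    """Well-separated families, no relaxed-only members, no decoy hits."""
    config = UniverseConfig(
        n_phages={1: 8, 2: 3, 3: 4, 4: 2},
        n_clusters={1: 2, 2: 1, 3: 2, 4: 1},
        relaxed_fraction=0.0,
        decoy_hit_fraction=0.0,
        low_support_fraction=0.0,
    )
    return generate_universe(config, seed=7)


@pytest.fixture(scope="session")
def default_universe():
    """Default study conditions (relaxed members, decoy hits, noise)."""
    return generate_universe(UniverseConfig(), seed=1)


@pytest.fixture(scope="session")
def default_detections(default_universe):
    u = default_universe
    table, models, flags = detect_all(u.genomes, u.provider, u.metadata)
    return table, models, flags
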