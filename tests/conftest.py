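"""Shared fixtures: a reference panel and a small simulated genome with its
detection/curation products, reused across module test files to keep the
suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from retronest.curate import annotate_elements, curate, rt_validator
from retronest.detect import recursive_detect
from retronest.models import SimConfig
from retronest.simulate import build_family_panel, plant_genome


@pytest.fixture(scope="session")
def panel():
    return build_family_panel(1729)


@pytest.fixture(scope="session")
def sim():
    """A 300-kb genome with 30 planted elements (young, nested)."""
    cfg = SimConfig(genome_length_bp=300_000, n_elements=30,
                    nesting_fraction=0.4, age_range_mya=(0.0, 1.8), rng_seed=3)
    genome, truth = plant_genome(cfg)
    return cfg, genome, truth


@pytest.fixture(scope="session")
def detected(sim, panel):
    cfg, genome, truth = sim
    candidates = recursive_detect(genome, validator=rt_validator(panel))
    return candidates


@pytest.fixture(scope="session")
def curated(sim, panel, detected):
    _, genome, _ = sim
    elements = annotate_elements(detected, panel, genome=genome)
    return curate(elements, genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
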