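import numpy as np
import pytest

from picluster import CoverageTrack, ScenarioConfig, simulate_scenario


def make_track(data, strand="+", library_size=1_000_000):
    """Build a CoverageTrack from {chrom: {pos: count}}."""
    return CoverageTrack.from_mapping(data, strand, library_size)


@pytest.fixture(scope="session")
def default_bundle():
    """Seeded 5-species scenario: 200 genes, 20 piCs, 8 intergenic clusters."""
    cfg = ScenarioConfig.default(seed=11)
    bundle, truth = simulate_scenario(cfg)
    return bundle, truth


@pytest.fixture(scope="session")
def eutherian_bundle():
    """Nine species in three clades with planted gains and losses."""
    cfg = ScenarioConfig.eutherian_like(seed=23)
    bundle, truth = simulate_scenario(cfg)
    return bundle, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
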