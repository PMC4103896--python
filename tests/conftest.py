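import pytest

from pptriad.simulate import SimConfig, simulate_family


@pytest.fixture(scope="session")
def default_family():
    """One moderately sized simulated family shared across read-only tests."""
    cfg = SimConfig(seed=11)
    records, neighborhoods, truth = simulate_family(cfg)
    return cfg, records, neighborhoods, truth


@pytest.fixture(scope="session")
def clean_family():
    """Family without duplication/HGT events and without indels."""
    cfg = SimConfig(seed=5, indel_rate=0.0, n_duplications=0, n_hgt=0)
    records, neighborhoods, truth = simulate_family(cfg)
    return cfg, records, neighborhoods, truth
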