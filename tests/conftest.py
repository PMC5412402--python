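import numpy as np
import pytest

from genefam.simulate import SimConfig, simulate_proteome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated family: 2 tandem + 2 segmental pairs, 12 family genes."""
    cfg = SimConfig(
        n_background_genes=30,
        n_family_genes=12,
        motif_length=30,
        n_chromosomes=8,
        loci_per_chromosome=20,
        duplication_events=[
            (10.0, "tandem", 0.2),
            (5.0, "tandem", 0.2),
            (10.0, "segmental", 0.2),
            (25.0, "segmental", 1.0),
        ],
        codon_length=120,
        rng_seed=42,
    )
    return simulate_proteome(cfg)


@pytest.fixture(scope="session")
def study_sim():
    """Study-scale simulated family: 10 tandem + 10 segmental pairs at
    T = 10 Mya, omega = 0.2, 40 family genes, 100 background genes."""
    events = [(10.0, "tandem", 0.2)] * 10 + [(10.0, "segmental", 0.2)] * 10
    cfg = SimConfig(duplication_events=events, rng_seed=7)
    return simulate_proteome(cfg)
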