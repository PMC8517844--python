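import numpy as np
import pytest

from iglight import (
    CohortConfig,
    GermlineAllele,
    Rearrangement,
    SimulationConfig,
    run_simulated_study,
    simulate_study,
)


@pytest.fixture(scope="session")
def default_cfg():
    return CohortConfig()


@pytest.fixture(scope="session")
def default_study():
    """Full reference-scenario simulation + analysis (shared: it is expensive)."""
    return run_simulated_study(SimulationConfig(seed=1), CohortConfig())


@pytest.fixture(scope="session")
def noise_free_study():
    """Error-free small cohort: inference must recover the truth exactly."""
    sim = SimulationConfig(
        seed=3,
        n_individuals=8,
        seqs_per_individual=1200,
        base_error_rate=0.0,
        upstream_retention_prob=0.0,
    )
    return run_simulated_study(sim, CohortConfig(min_sequences_per_individual=1000))


@pytest.fixture(scope="session")
def small_sim():
    """A small raw simulated study (reference + cohort + reads, unanalysed)."""
    return simulate_study(
        SimulationConfig(seed=5, n_individuals=6, seqs_per_individual=400)
    )


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def make_reads(individual, sequences, prefix="r"):
    return [
        Rearrangement(sequence_id=f"{prefix}{i}", individual_id=individual, sequence=s)
        for i, s in enumerate(sequences)
    ]


@pytest.fixture
def toy_v_allele(rng):
    return GermlineAllele("IGKV4-1", "01", random_dna(rng, 120))
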