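import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_simulation():
    """A modest simulated transcriptome with three planted ancient depths,
    shared across pipeline-level tests."""
    from paleoks.synthetic_data import simulate_duplicated_transcriptome

    records, truth = simulate_duplicated_transcriptome(
        n_families=40,
        depths=[0.27, 0.51, 0.91],
        codons_per_gene=300,
        omega=0.2,
        seed=101,
    )
    return records, truth


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free CDS starting with ATG (test helper)."""
    from paleoks.core_io import SENSE_CODONS

    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)
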