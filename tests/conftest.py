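import numpy as np
import pytest

from gbskit import SimConfig, generate_barcode_set, simulate


@pytest.fixture(scope="session")
def generated_96():
    """A 96-barcode set under the full design constraints (shared: generation
    is the slowest barcode operation)."""
    return generate_barcode_set(96, seed=11)


@pytest.fixture(scope="session")
def clean_bundle():
    """Small error-free simulation: no sequencing errors, no dimers, no
    low-quality reads — the regime where recovery must be exact."""
    cfg = SimConfig(genome_length=60_000, n_lines=8, seed=5,
                    sequencing_error_rate=0.0, dimer_read_fraction=0.0,
                    low_quality_read_fraction=0.0)
    return simulate(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Study-condition simulation of a 40-line doubled-haploid population."""
    return simulate(SimConfig(n_lines=40, seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
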