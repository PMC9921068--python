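import numpy as np
import pytest

from parityewas import SimulationConfig, simulate_cohort, simulate_genotypes


def small_config(**kw):
    """A fast cohort: 24 samples/group, 1500 probes."""
    defaults = dict(n_samples_per_group=24, n_probes=1500, n_spiked_dmps=40,
                    n_signature_per_type=40, n_clock_cpgs=20, seed=0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_dataset():
    cfg = small_config()
    ds = simulate_cohort(cfg)
    simulate_genotypes(cfg, ds)
    return ds


@pytest.fixture(scope="session")
def cohort_dataset():
    """Full-width cohort (96/group) at reduced probe count, seed 1."""
    cfg = SimulationConfig(n_probes=2000, n_samples_per_group=96,
                           n_spiked_dmps=100, n_signature_per_type=50,
                           n_clock_cpgs=30, seed=1)
    ds = simulate_cohort(cfg)
    simulate_genotypes(cfg, ds)
    return ds


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
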