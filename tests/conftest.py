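import numpy as np
import pytest

from diaqc.simulate import DiaDistributionSpec, SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def baseline_dataset():
    """Moderate-size baseline simulation (fixed DIA=30, M=30, p=0.5)."""
    cfg = SimulationConfig(
        n_loci=50_000, depth=30, allele_p=0.5,
        dia_spec=DiaDistributionSpec(kind="fixed", dia_avg=30),
        seed=20_260_930,
    )
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
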