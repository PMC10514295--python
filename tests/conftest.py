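import numpy as np
import pytest

from inhibkit import SyntheticConfig, gen_titration, gen_velocity_dataset

NOISELESS = SyntheticConfig()


@pytest.fixture
def noiseless_cfg() -> SyntheticConfig:
    return NOISELESS


@pytest.fixture
def competitive_dataset():
    """Noiseless competitive velocities on the study grids (Km 1 mM, Ki 11 uM)."""
    return gen_velocity_dataset(km_mM=1.0, vmax=1.0, ki_uM=11.0, cfg=NOISELESS)


@pytest.fixture
def titration_pair():
    """Noiseless titrations at 293/333 K with KA falling on warming."""
    low = gen_titration(ka_per_M=4.05e5, temperature_K=293.0, cfg=NOISELESS)
    high = gen_titration(ka_per_M=3.66e5, temperature_K=333.0, cfg=NOISELESS)
    return low, high


def noisy(seed: int, sd: float) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, noise_model="multiplicative_gaussian", noise_sd_rel=sd)


@pytest.fixture
def make_noisy_cfg():
    return noisy
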