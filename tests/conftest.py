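import numpy as np
import pytest

from methaphen.genetics import build_a_inverse
from methaphen.simulate import SimulationConfig, simulate_pedigree


def recovery_config(**overrides) -> SimulationConfig:
    """1275 cows in 85 herds over a two-generation pedigree with reused sires."""
    base = dict(n_herds=85, cows_per_herd=15, n_founders=200, n_generations=2,
                n_sires_per_gen=40, n_dams_per_gen=300, seed=11)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def recovery_pedigree():
    ped = simulate_pedigree(recovery_config())
    return ped, build_a_inverse(ped)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def random_pedigree(rng, n=40, n_founders=8, p_unknown=0.2):
    """Random valid pedigree records (helper for oracle tests)."""
    recs = []
    for i in range(1, n + 1):
        if i <= n_founders:
            recs.append((i, 0, 0))
        else:
            s = int(rng.integers(1, i))
            d = int(rng.integers(1, i))
            if s == d:
                d = 0
            if rng.random() < p_unknown:
                s = 0
            recs.append((i, s, d))
    return tuple(recs)
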