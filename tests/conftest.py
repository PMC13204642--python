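import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def build_pair(p1, p2, chrom=None, bp=None, func=None, snp=None, z1=None, z2=None):
    """Assemble a minimal harmonized pair table from p-value arrays."""
    from condfdr.io import z_from_p

    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    n = len(p1)
    return pd.DataFrame({
        "SNP": snp if snp is not None else [f"s{i}" for i in range(n)],
        "CHR": chrom if chrom is not None else ["1"] * n,
        "BP": bp if bp is not None else (np.arange(n) + 1) * 1000,
        "A1": "A", "A2": "G",
        "Z1": z1 if z1 is not None else z_from_p(p1, 1.0),
        "P1": p1,
        "Z2": z2 if z2 is not None else z_from_p(p2, 1.0),
        "P2": p2,
        "FUNC": func if func is not None else ["intergenic"] * n,
        "EXCL": [False] * n,
    })


@pytest.fixture
def pair_builder():
    return build_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sim_pair_small():
    """A 2000-SNP independent-SNP pair with the default causal mixture."""
    from condfdr.simulate import SimConfig, simulate_pair

    cfg = SimConfig(m=2000, block_size=1, rho=0.0, seed=11)
    pair, truth, ld = simulate_pair(cfg)
    return pair, truth, ld
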