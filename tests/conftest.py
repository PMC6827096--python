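import numpy as np
import pytest

import mbgp


@pytest.fixture(scope="session")
def tiny_config() -> mbgp.FounderConfig:
    """Two breeds in two groups, a few hundred markers: seconds, not minutes."""
    return mbgp.FounderConfig(
        founders_per_breed={"A": 12, "B": 12},
        group_assignment={"A": "g1", "B": "g2"},
        n_markers=600,
        n_chromosomes=2,
        ancestral_ne=40,
        group_ne=25,
        breed_ne=20,
        generations_base=20,
        generations_group=10,
        generations_breed=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_founders(tiny_config) -> mbgp.GenotypePanel:
    return mbgp.generate_founders(tiny_config)


@pytest.fixture(scope="session")
def tiny_expanded(tiny_founders) -> mbgp.GenotypePanel:
    return mbgp.expand_panel(
        tiny_founders, mbgp.ResampleConfig(block_size_markers=100,
                                           n_simulated_per_breed=200, seed=3)
    )


def hwe_panel(n: int, m: int, seed: int, p_range=(0.1, 0.9)) -> mbgp.GenotypePanel:
    """Unstructured panel under exact HWE: haplotypes Bernoulli(p) i.i.d."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(*p_range, size=m)
    haps = (rng.random((n, 2, m)) < p).astype(np.int8)
    gaps = rng.integers(1000, 8000, size=m)
    pos = np.cumsum(gaps)
    markers = mbgp.MarkerMap(
        np.ones(m, dtype=int), pos, pos * 1e-6,
        np.full(m, "A", dtype=object), np.full(m, "B", dtype=object),
    )
    return mbgp.GenotypePanel(
        markers, haps,
        np.array([f"id{i}" for i in range(n)], dtype=object),
        np.array(["X"] * n, dtype=object),
    )
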