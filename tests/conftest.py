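import numpy as np
import pytest

from melclone import CloneSpec, SimConfig, simulate_reference


@pytest.fixture(scope="session")
def uniform_reference() -> str:
    """50% GC i.i.d. reference; neighbor of any C/G is a pyrimidine w.p. 0.5."""
    return simulate_reference(100_000, gc=0.5, seed=424242)


@pytest.fixture(scope="session")
def skin_like_reference() -> str:
    """40% GC reference, the generator default."""
    return simulate_reference(200_000, gc=0.4, seed=7)


def hypermutator_like_config(seed: int, n_total: int = 2000, depth: float = 500.0) -> SimConfig:
    """Two-clone hypermutator-like tumor with cluster centers 46.8 / 19.81 VAF.

    Founding clone carries the UV 5'-pyrimidine signature; the subclone is
    four times larger and carries a 3'-pyrimidine (non-UV) context instead.
    Purity follows from the founding VAF (2 x 46.8 = 93.6%); the subclone
    prevalence from the VAF ratio.
    """
    purity = 2 * 46.8 / 100.0
    sub_prev = 19.81 / 46.8
    n_sub = int(round(n_total * 0.8))
    return SimConfig(
        clones=[
            CloneSpec("founding", {"tumor": 1.0}, n_total - n_sub, "uv_5prime", 0.93),
            CloneSpec("subclone", {"tumor": sub_prev}, n_sub, "pyr_3prime", 0.9,
                      parent_id="founding"),
        ],
        purity_per_sample={"tumor": purity},
        depth_mean=depth,
        overdispersion=0.0,
        genome_length=200_000,
        seed=seed,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20261001)
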