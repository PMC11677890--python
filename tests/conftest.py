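import numpy as np
import pytest

from corolla import (PetalRecord, SpeciesConfig, SyntheticConfig,
                     default_config, generate_dataset)


@pytest.fixture(scope="session")
def study_scale_dataset():
    """Two-species dataset at the default study scale (~1000 petals)."""
    return generate_dataset(default_config(seed=20240312))


@pytest.fixture(scope="session")
def small_dataset():
    """A quick two-species dataset for structural checks."""
    cfg = SyntheticConfig(
        species=(
            SpeciesConfig(name="narrow", n_flowers=8, petal_count=(6, 8),
                          length_mean=1.5, length_sd=0.15, ratio_mean=0.55,
                          ratio_sd=0.04, p1=1.2, p2=0.8),
            SpeciesConfig(name="round", n_flowers=8, petal_count=(5, 5),
                          length_mean=1.4, length_sd=0.14, ratio_mean=0.9,
                          ratio_sd=0.05, p1=0.7, p2=0.7, notch_depth=0.05),
        ),
        seed=7, n_vertices=128,
    )
    return generate_dataset(cfg)


def exact_me_petals(k: float, n: int, seed: int = 0) -> list[PetalRecord]:
    """Petals satisfying A = k * L * W exactly (no noise)."""
    rng = np.random.default_rng(seed)
    L = rng.uniform(1.0, 2.5, n)
    W = rng.uniform(0.5, 1.5, n)
    return [PetalRecord("sp", f"f{i}", "p1", k * l * w, l, w)
            for i, (l, w) in enumerate(zip(L, W))]
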