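from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fvpack.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 24-structure two-mode dataset shared by the cheaper tests."""
    spec = SyntheticSpec(
        n_A_bound=9,
        n_A_unbound=5,
        n_B_bound=8,
        n_B_unbound=2,
        n_A_small=1,
        n_B_small=5,
        seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def small_structures(small_dataset):
    return small_dataset[0]


@pytest.fixture(scope="session")
def small_truth(small_dataset) -> pd.DataFrame:
    return small_dataset[1]


@pytest.fixture(scope="session")
def small_metadata(small_structures) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": s.id,
                "light_type": s.light_type,
                "species": s.species,
                "resolution": s.resolution,
                "bound": s.bound,
            }
            for s in small_structures
        ]
    )


def random_rigid_transform(rng: np.random.Generator):
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
    t = rng.normal(scale=10.0, size=3)
    return R, t
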