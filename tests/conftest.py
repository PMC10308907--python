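from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitorf import SyntheticSpec, get_code, make_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def codes():
    return {tid: get_code(tid) for tid in (1, 2, 4, 5)}


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded cohort reused across modules (30 viral + 30 decoys)."""
    return make_dataset(SyntheticSpec(n_viral=30, n_decoy=30, seed=11))


@pytest.fixture(scope="session")
def small_dataset_paths(small_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("synthdata")
    return small_dataset.write(out)


def random_contig(rng: np.random.Generator, length: int, at: float = 0.5) -> str:
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return "".join(rng.choice(list("ACGT"), size=length, p=p))
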