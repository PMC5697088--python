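import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ccsearch.seq_io import STANDARD_RESIDUES, ProteinSequence
from ccsearch.synthetic_data import FamilySpec, make_database

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_protein(rng: np.random.Generator, n: int) -> str:
    letters = np.array(list(STANDARD_RESIDUES))
    return "".join(letters[rng.integers(0, 20, size=n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)


@pytest.fixture
def family_collection() -> list[ProteinSequence]:
    """Three families of five block-sharing sequences (redundant by design)."""
    seqs, _ = make_database(
        FamilySpec(
            n_families=3,
            members_per_family=5,
            rep_length=100,
            block_length=40,
            substitution_rate=0.04,
            indel_rate=0.01,
            rng_seed=7,
        )
    )
    return seqs
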