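import numpy as np
import pytest

from gamoscan.codec import AMINO_ACIDS, SequenceRecord
from gamoscan.align import MultipleAlignment


@pytest.fixture
def rng():
    return np.random.default_rng(20240130)


def random_protein(rng, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def make_msa(rows: dict[str, str], species: dict[str, str] | None = None,
             reference_id: str | None = None) -> MultipleAlignment:
    species = species or {}
    recs = [
        SequenceRecord(id=k, residues=v, alphabet="protein",
                       species=species.get(k, k.split("_")[0]))
        for k, v in rows.items()
    ]
    return MultipleAlignment(recs, reference_id=reference_id)


@pytest.fixture(scope="session")
def small_truth():
    """A small five-species family reused by several test modules."""
    from gamoscan.simulate import ml_recovery_config, simulate_family

    cfg = ml_recovery_config(protein_length=300, seed=5)
    return simulate_family(cfg)
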