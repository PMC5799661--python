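import numpy as np
import pytest

from genefam import synthetic


@pytest.fixture(scope="session")
def small_family():
    """A compact synthetic family with planted duplicates, one triple, one
    omega pair, gene models, promoters and expression."""
    spec = synthetic.SyntheticFamilySpec(
        n_genes=8,
        cds_length_range=(150, 300),
        duplicate_specs=[(0.85, 1.0), (0.40, 0.95)],
        triplicate_specs=[0.85],
        omega_targets=[0.2],
        seed=5,
    )
    return synthetic.generate_family(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cds(n_codons: int, seed: int) -> str:
    """One random stop-free CDS for oracle tests."""
    return synthetic.generate_cds(1, (n_codons, n_codons), 0.5, seed)["G001"]
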