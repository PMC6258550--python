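import numpy as np
import pytest

from miipa import IpaOptions, SyntheticSpec, generate, run_ipa
from miipa.msa_io import PairedAlignment


@pytest.fixture
def toy_aln() -> PairedAlignment:
    """Two species (2 and 3 pairs), widths 4 and 5, deterministic content."""
    rng = np.random.default_rng(123)
    X_a = rng.integers(0, 21, size=(5, 4), dtype=np.uint8)
    X_b = rng.integers(0, 21, size=(5, 5), dtype=np.uint8)
    return PairedAlignment(
        ids_a=["a1", "a2", "a3", "a4", "a5"],
        species_a=["sp1", "sp1", "sp2", "sp2", "sp2"],
        X_a=X_a,
        ids_b=["b1", "b2", "b3", "b4", "b5"],
        species_b=["sp1", "sp1", "sp2", "sp2", "sp2"],
        X_b=X_b,
        gold={"a1": "b1", "a2": "b2", "a3": "b3", "a4": "b4", "a5": "b5"},
    )


@pytest.fixture(scope="session")
def strong_aln() -> PairedAlignment:
    """Strongly coupled synthetic data where partner recovery should be easy."""
    spec = SyntheticSpec(
        n_species=50, pairs_per_species=4, L_a=12, L_b=12,
        n_coupled=8, epsilon=0.95, rng_seed=7,
    )
    return generate(spec)


@pytest.fixture(scope="session")
def strong_run(strong_aln):
    """One MI-IPA run on the strongly coupled data (shared across tests)."""
    return run_ipa(strong_aln, IpaOptions(mode="mi", n_increment=10, seed=2))
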