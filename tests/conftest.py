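import pytest

from pseudomap.chemistry import Species, candidate_species
from pseudomap.digestion import RNASE_A, digest, protect_window
from pseudomap.modifications import default_table
from pseudomap.simulate import SimConfig, make_trna_like


@pytest.fixture(scope="session")
def mod_table():
    return default_table()


@pytest.fixture(scope="session")
def trna_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def trna_seq(trna_config):
    """An 85-nt tRNA-Tyr-like substrate: D16, C32, Q34, ms2io6A37, m5U54."""
    return make_trna_like(trna_config)


@pytest.fixture(scope="session")
def window_fragments(trna_seq):
    """RNase A limit digest of the oligo-protected window (positions 10-46)."""
    return digest(protect_window(trna_seq, 10, 46), RNASE_A)


@pytest.fixture(scope="session")
def agac_fragment(window_fragments):
    """The diagnostic tetramer A-G-A-C covering the edit site (29-32)."""
    (fragment,) = [f for f in window_fragments if f.covers(32)]
    return fragment


@pytest.fixture(scope="session")
def gagd_fragment(window_fragments):
    """The reference tetramer G-A-G-D from positions 13-16."""
    (fragment,) = [f for f in window_fragments if f.start == 13]
    return fragment


@pytest.fixture()
def theoretical_species(window_fragments):
    """Matching candidates: diagnostic species at 32 plus plain fragments."""
    species = []
    for fragment in window_fragments:
        if fragment.covers(32):
            species.extend(candidate_species(fragment, 32))
        else:
            species.append(Species(fragment, 1.0))
    return species
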