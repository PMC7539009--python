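import numpy as np
import pytest

from znseal import synth
from znseal.core import Structure


@pytest.fixture(scope="session")
def toy_complex():
    """Ground-truth toy complex (built once per session; ~45 s)."""
    truth, tiers, site = synth.make_toy_complex()
    return truth, tiers, site


@pytest.fixture(scope="session")
def toy_truth(toy_complex):
    return toy_complex[0]


@pytest.fixture(scope="session")
def toy_template(toy_truth):
    return Structure([a for a in toy_truth.atoms if a.chain_id == "A"])


@pytest.fixture(scope="session")
def toy_peaks(toy_truth):
    return synth.simulate_peaks(toy_truth, synth.PeakSimSpec(scale_k=1e6))


@pytest.fixture(scope="session")
def small_structure():
    """A cheap 6-residue all-atom fragment for unit tests."""
    from znseal.anneal import build_peptide
    seq = ["ALA", "CYS", "LEU", "GLY", "SER", "MET"]
    return build_peptide(seq, np.full(6, -57.0), np.full(6, -47.0),
                         chain_id="A", start_resnum=1)
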