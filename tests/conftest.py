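from pathlib import Path

import numpy as np
import pytest

from hkmtkit import synthetic_data as synth
from hkmtkit.structure_io import Chain, Structure

DATA_DIR = Path(__file__).parent / "data"
# user-supplied deposited entries (not distributed with the package)
DEPOSITED_DIR = Path(__file__).parent.parent / "data" / "pdb"


def chain_atoms(chain: Chain):
    return [a for r in chain.residues for a in r.atoms]


def structure_atoms(s: Structure):
    return list(s.iter_atoms())


@pytest.fixture
def helix30() -> Structure:
    return synth.make_helix(30)


@pytest.fixture
def bridge() -> Structure:
    return synth.make_beta_bridge(flip=False)


@pytest.fixture
def bridge_flipped() -> Structure:
    return synth.make_beta_bridge(flip=True)


@pytest.fixture
def two_domain():
    return synth.make_two_domain_pair(core_len=40, mobile_len=17,
                                      noise_sigma=0.1, hinge_shift=5.0, seed=11)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
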