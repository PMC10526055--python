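import pytest

from moladapt.chem import MoleculeRecord
from moladapt.codec import ToyCodec
from moladapt.fixtures import toy_molecule_library


@pytest.fixture(scope="session")
def library():
    return toy_molecule_library()


@pytest.fixture(scope="session")
def codec(library):
    return ToyCodec(library, latent_dim=16)


@pytest.fixture
def benzene():
    return MoleculeRecord.from_smiles("c1ccccc1")


@pytest.fixture
def ethanol():
    return MoleculeRecord.from_smiles("CCO")
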