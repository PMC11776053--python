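import pytest

from alchemap.chemgraph import Molecule
from alchemap.fixtures import FixtureSpec, make_congeneric_series

SMILES = {
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "aniline": "Nc1ccccc1",
    "biphenyl": "c1ccc(-c2ccccc2)cc1",
    "naphthalene": "c1ccc2ccccc2c1",
    "anthracene": "c1ccc2cc3ccccc3cc2c1",
    "methane": "C",
    "ethylbenzene": "CCc1ccccc1",
    "pyridine": "c1ccncc1",
    "acetate": "CC(=O)[O-]",
    "cyclohexane": "C1CCCCC1",
    "styrene": "C=Cc1ccccc1",
}


@pytest.fixture(scope="session")
def mols():
    return {name: Molecule.from_smiles(smi) for name, smi in SMILES.items()}


@pytest.fixture(scope="session")
def toy_series():
    return make_congeneric_series(FixtureSpec())


@pytest.fixture(scope="session")
def close_series():
    """Series with no distant member: all pairwise scores are high."""
    return make_congeneric_series(
        FixtureSpec(substituents=("C", "O", "Cl"), include_distant=False)
    )
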