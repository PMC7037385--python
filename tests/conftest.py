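import numpy as np
import pytest
from hypothesis import settings

from azoleqsar import parse_smiles

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def benzene():
    return parse_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def imidazole():
    return parse_smiles("c1c[nH]cn1", "imidazole")


@pytest.fixture(scope="session")
def named_azole_drugs():
    """Azole drugs with published NRS / branching-index values."""
    return {
        name: parse_smiles(smi, name)
        for name, smi in {
            "fadrozole": "N#Cc1ccc(cc1)C2CCCc3cncn23",
            "surinabant": "CCc1c(-c2ccc(Cl)cc2)n(-c2ccc(Cl)cc2Cl)nc1C(=O)NN1CCCCC1",
            "liarazole": "Clc1cccc(c1)C(n1ccnc1)c1ccc2nc[nH]c2c1",
            "imazodan": "O=C1CCC(=NN1)c1ccc(cc1)n1ccnc1",
            "bifonazole": "c1ccc(cc1)C(c1ccc(cc1)-c1ccccc1)n1ccnc1",
            "medetomidine": "CC(c1cccc(C)c1C)c1c[nH]cn1",
            "imazalil": "C=CCOC(Cn1ccnc1)c1ccc(Cl)cc1Cl",
            "sertaconazole": "Clc1ccc(c(Cl)c1)C(Cn1ccnc1)OCc1csc2c(Cl)cccc12",
        }.items()
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
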