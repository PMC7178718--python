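import pytest
from rdkit import RDLogger

import fragswap as fs

# RDKit logs expected sanitization failures for truncated context keys;
# keep test output readable.
RDLogger.DisableLog("rdApp.*")


@pytest.fixture(scope="session")
def homolog_corpus():
    return fs.synth_corpus("homologs", 3, seed=0)


@pytest.fixture(scope="session")
def toluene_ethyl_records():
    return [fs.parse_smiles("Cc1ccccc1", "tol"), fs.parse_smiles("CCc1ccccc1", "eb")]


@pytest.fixture(scope="session")
def toluene_ethyl_db(toluene_ethyl_records):
    return fs.build_db(toluene_ethyl_records, [1])


@pytest.fixture(scope="session")
def decorated_db():
    corpus = fs.synth_corpus("decorated_aromatics", 6, seed=1)
    return corpus, fs.build_db(list(corpus.molecules), [1, 2, 3])
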