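import numpy as np
import pandas as pd
import pytest

from paradoxflora.config import WorldConfig
from paradoxflora.synthetic import generate_world


@pytest.fixture(scope="session")
def tiny_world():
    """A small fixed world shared by read-only tests."""
    return generate_world(WorldConfig(n_species=300, n_countries=12,
                                      n_families=25, seed=7))


@pytest.fixture()
def mini_checklist():
    """Hand-built checklist with an accepted name, a synonym and a hybrid."""
    return pd.DataFrame([
        {"rawName": "Abies alba", "acceptedName": "Abies alba",
         "family": "Pinaceae", "genus": "Abies", "isHybrid": False,
         "status": "accepted"},
        {"rawName": "Abies pectinata", "acceptedName": "Abies alba",
         "family": "Pinaceae", "genus": "Abies", "isHybrid": False,
         "status": "synonym"},
        {"rawName": "Salix ×rubens", "acceptedName": "Salix ×rubens",
         "family": "Salicaceae", "genus": "Salix", "isHybrid": True,
         "status": "accepted"},
        {"rawName": "Taraxacum officinale", "acceptedName": "Taraxacum officinale",
         "family": "Asteraceae", "genus": "Taraxacum", "isHybrid": False,
         "status": "accepted"},
    ])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
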