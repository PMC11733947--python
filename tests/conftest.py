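import pytest

from pkasense.benchlab import DEFAULT_ACID_RULES, generate_synthetic_set
from pkasense.chemgraph import parse_smiles
from pkasense.pka_mtc import PkaPredictor, TrainingConfig


@pytest.fixture(scope="session")
def molecules():
    return {
        "methane": parse_smiles("C", name="methane"),
        "ethanol": parse_smiles("CCO", name="ethanol"),
        "benzene": parse_smiles("c1ccccc1", name="benzene"),
        "pyridine": parse_smiles("c1ccncc1", name="pyridine"),
        "acetic_acid": parse_smiles("CC(=O)O", name="acetic_acid"),
        "phenol": parse_smiles("Oc1ccccc1", name="phenol"),
    }


@pytest.fixture(scope="session")
def acid_records():
    """Small synthetic acid training draw (positives + sentinel negatives)."""
    return generate_synthetic_set(
        DEFAULT_ACID_RULES, n=400, negative_fraction=0.2, seed=5
    )


@pytest.fixture(scope="session")
def acid_predictor(acid_records):
    """Compact trained acid model shared across unit tests.

    Fewer epochs than the production default keep the suite fast; the
    model still separates the generator's functional groups cleanly.
    """
    config = TrainingConfig(task="acid", epochs=60, seed=5)
    return PkaPredictor.train(
        [r.graph for r in acid_records], [r.pka for r in acid_records], config
    )
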