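import pytest

from faahscreen.chem_io import CompoundRecord
from faahscreen.synthetic import SyntheticConfig, generate_library


def record(smiles: str, id: str = "x", **kwargs) -> CompoundRecord:
    rec = CompoundRecord.from_smiles(smiles, id=id, **kwargs)
    assert rec is not None, f"fixture SMILES {smiles!r} must parse"
    return rec


@pytest.fixture(scope="session")
def small_library():
    """One small synthetic active/decoy library shared across tests."""
    config = SyntheticConfig(n_fi=60, decoy_ratio=5, seed=11)
    fi, dcy, truth = generate_library(config)
    return config, fi, dcy, truth
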