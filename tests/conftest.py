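import pytest

from d2bscreen.chem import BuildingBlock, Role


@pytest.fixture(scope="session")
def toy_blocks() -> dict[str, BuildingBlock]:
    """Minimal one-block-per-role set for scheme-level tests."""
    return {
        "amine": BuildingBlock.from_smiles("A1", Role.AMINE, "CN"),
        "oxo": BuildingBlock.from_smiles("O1", Role.OXO, "CC=O"),
        "acid": BuildingBlock.from_smiles("C1", Role.ACID, "CC(=O)O"),
        "isocyanide": BuildingBlock.from_smiles("IC1", Role.ISOCYANIDE, "C[N+]#[C-]"),
        "formaldehyde": BuildingBlock.formaldehyde(),
        "azide": BuildingBlock.azide_source(),
    }
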