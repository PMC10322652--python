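import numpy as np
import pytest

from metchem import (
    generate_concentrations,
    generate_structural_panel,
    write_concentrations,
    write_fixture_metabocards,
    write_panel,
)


@pytest.fixture(scope="session")
def family_panel():
    """3 structural families x 8 metabolites, with ground truth."""
    panel, truth = generate_structural_panel(8, seed=1)
    return panel, truth


@pytest.fixture(scope="session")
def family_conc(family_panel):
    panel, truth = family_panel
    return generate_concentrations(panel, truth, seed=1)


@pytest.fixture()
def csv_inputs(tmp_path, family_panel, family_conc):
    """Panel + concentration CSV pair on disk."""
    panel, _ = family_panel
    panel_path = tmp_path / "panel.csv"
    conc_path = tmp_path / "conc.csv"
    write_panel(panel, panel_path)
    write_concentrations(family_conc, conc_path)
    return panel_path, conc_path


@pytest.fixture()
def cards_dir(tmp_path, family_panel):
    panel, truth = family_panel
    out = tmp_path / "cards"
    write_fixture_metabocards(panel, truth, out)
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)
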