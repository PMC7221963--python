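import pytest

from teaphenol.bioassay_metrics import load_assay_panel
from teaphenol.spectral_annotation import load_compound_library


@pytest.fixture(scope="session")
def library():
    return load_compound_library()


@pytest.fixture(scope="session")
def panel():
    return load_assay_panel()


@pytest.fixture(scope="session")
def activity_matrix(panel):
    """Raw assay columns as an oriented activity matrix (ID50s lower-better)."""
    from teaphenol.activity_ranking import ActivityMatrix

    values = panel[["id50_dpph", "id50_abts", "id50_tbars", "orac_te"]]
    orientation = {"id50_dpph": "lower-better", "id50_abts": "lower-better",
                   "id50_tbars": "lower-better", "orac_te": "higher-better"}
    return ActivityMatrix(values=values, orientation=orientation)
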