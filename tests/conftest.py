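import pytest

from hmetex.io import load_cp_models, load_runs_table, load_transitions
from hmetex.synthetic_data import default_protein_specs


@pytest.fixture(scope="session")
def cp_models():
    return load_cp_models()


@pytest.fixture(scope="session")
def transitions():
    return load_transitions()


@pytest.fixture(scope="session")
def protein_specs():
    return default_protein_specs()


@pytest.fixture(scope="session")
def screening_runs():
    """The 27-run screening campaign with responses and texture labels."""
    return load_runs_table()
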