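import pytest

from nbpanel import synthetic


@pytest.fixture(scope="session")
def germline_set():
    return synthetic.example_germline_set()


@pytest.fixture(scope="session")
def dose_grid():
    return synthetic.panel_dose_grid()


@pytest.fixture(scope="session")
def panel_affinities():
    return synthetic.panel_affinities_molar()


@pytest.fixture(scope="session")
def epitope_map():
    return synthetic.panel_epitope_map()
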