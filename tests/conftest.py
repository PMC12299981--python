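import pytest

from metid.fragment_model import default_library


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def fixtures21():
    """(manifest row, noise-free spectrum) pairs for the 21 metabolites."""
    from metid.datasets import fixture_spectra

    return fixture_spectra()
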