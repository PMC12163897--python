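import pytest

from khovlap import KhovanovComplex, fixtures
from khovlap.spectral import spectrum_table


@pytest.fixture(scope="session")
def trefoil():
    return fixtures("trefoil_R")


@pytest.fixture(scope="session")
def trefoil_cx(trefoil):
    return KhovanovComplex(trefoil)


@pytest.fixture(scope="session")
def figure8():
    return fixtures("figure8")


@pytest.fixture(scope="session")
def k8_12():
    return fixtures("k8_12")


@pytest.fixture(scope="session")
def k8_12_spectra(k8_12):
    return spectrum_table(KhovanovComplex(k8_12))


@pytest.fixture(scope="session")
def unknot():
    return fixtures("unknot")
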