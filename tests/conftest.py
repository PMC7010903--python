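import numpy as np
import pytest

from celldose.decay import MaterialModel, load_emission_spectrum
from celldose.geometry import TruncatedConeCell
from celldose.transport import TransportEngine


@pytest.fixture(scope="session")
def spectrum():
    return load_emission_spectrum()


@pytest.fixture(scope="session")
def water():
    return MaterialModel.water()


@pytest.fixture(scope="session")
def engine(spectrum, water):
    return TransportEngine(spectrum, water)


@pytest.fixture(scope="session")
def reference_cell():
    cell = TruncatedConeCell.reference()
    cell.validate()
    return cell


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
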