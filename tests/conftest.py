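import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from starchmorph import (GranuleMeasurement, GranuleRecord, alata_default,
                         bulbifera_default, fit_reference,
                         generate_assemblage)

settings.register_profile(
    "suite", max_examples=50, deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

# irregular simple 12-gon used as the shared geometry fixture
TWELVE_GON = np.array([
    [10.0, 0.0], [8.0, 4.0], [3.0, 7.0], [-2.0, 9.0], [-7.0, 6.0],
    [-11.0, 2.0], [-9.0, -2.0], [-6.0, -6.0], [-1.0, -9.0], [4.0, -8.0],
    [8.0, -6.0], [10.0, -3.0]])
TWELVE_GON_HILUM = (2.0, 1.0)


def make_record(length, width, er, angle, taxon="T", sample="s", *,
                shape="oval", lamellae=False, fissure=False, curved=False,
                id=""):
    """Handmade measurement-only record for statistics tests."""
    return GranuleRecord(
        measurement=GranuleMeasurement(length, width, er, angle),
        taxon=taxon, sample_id=sample, shape_class=shape,
        lamellae=lamellae, longitudinal_fissure=fissure, curved=curved,
        id=id)


def _generate(profile, n, seed=None):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_assemblage(profile, n, seed=seed)


@pytest.fixture(scope="session")
def alata300():
    return _generate(alata_default(), 300)


@pytest.fixture(scope="session")
def bulb300():
    return _generate(bulbifera_default(), 300)


@pytest.fixture(scope="session")
def reference_model(alata300, bulb300):
    return fit_reference({"D_alata": alata300, "D_bulbifera": bulb300})


@pytest.fixture(scope="session")
def heldout_assemblages():
    return (_generate(alata_default(), 100, seed=9701),
            _generate(bulbifera_default(), 100, seed=9702))
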