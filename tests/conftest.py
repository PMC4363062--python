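import pytest

from ankledose.datasets import (
    default_fractions,
    default_phantom,
    default_weights,
    newtom_hires_readings,
    published_dose_table,
)
from ankledose.engine import compute_effective_dose
from ankledose.phantom import Aggregation, resolve_groups
from ankledose.uncertainty import build_budget

W_R = 1.0
MGY_TO_USV = 1000.0


@pytest.fixture(scope="session")
def model():
    return default_phantom()


@pytest.fixture(scope="session")
def fractions():
    return default_fractions()


@pytest.fixture(scope="session")
def weights():
    return default_weights()


@pytest.fixture(scope="session")
def groups(model, fractions):
    return resolve_groups(model, fractions)


@pytest.fixture(scope="session")
def estimates():
    """Measured mean doses of the high-resolution small-FOV CBCT protocol."""
    return newtom_hires_readings()


@pytest.fixture(scope="session")
def result(groups, estimates, weights):
    return compute_effective_dose(groups, estimates, weights)


@pytest.fixture(scope="session")
def budget(groups, estimates, result, weights):
    return build_budget(groups, estimates, result, weights)


@pytest.fixture(scope="session")
def published():
    return published_dose_table()


def oracle_effective_dose(fractions, weights, estimates):
    """Brute-force reference: one flat loop over (entry, dosimeter) pairs
    applying the equivalent/effective dose definitions directly."""
    E = 0.0
    for entry in fractions.entries:
        doses = [estimates[no].mean_dose_mGy for no in entry.dosimeters]
        if entry.aggregation is Aggregation.PER_SITE_FRACTION:
            h_entry = sum(entry.f_i * d for d in doses)
        else:
            h_entry = entry.f_i * sum(doses) / len(doses)
        w = weights.weight_for(entry.tissue)
        E += w * weights.w_R * h_entry * MGY_TO_USV
    return E
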