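import numpy as np
import pytest

from cvp2ppl import ConditionSpec, SubjectParams, VentilatorSettings, simulate_condition


@pytest.fixture(scope="session")
def toy_mechanics():
    """CL=25, Ccw=100 (Crs=20), TV=300, T=0.5: every delta is hand-computable."""
    subject = SubjectParams(lung_compliance=25.0)
    cond = ConditionSpec(ccw=100.0, transmission=0.5)
    vent = VentilatorSettings(tidal_volume=300.0)
    return subject, cond, vent


@pytest.fixture(scope="session")
def noise_free_record(toy_mechanics):
    subject, cond, vent = toy_mechanics
    return simulate_condition(subject, cond, vent, seed=11, noise_free=True)


def windows_by_label(record):
    return {a.label: a for a in record.annotations if a.label != "breath_start"}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
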