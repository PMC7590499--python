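import numpy as np
import pytest

from vaval.data_model import (
    NON_CONCLUSIVE,
    Cause,
    CauseDictionary,
    DeathRecord,
    StudyGroup,
    VAOutput,
)


@pytest.fixture(scope="session")
def dictionary():
    from vaval.data_model import default_cause_dictionary

    return default_cause_dictionary()


def toy_dictionary(n_causes: int = 5, group: StudyGroup = StudyGroup.OTHER_ADULT):
    """A one-group dictionary with n generic substantive causes plus NC."""
    groups = frozenset({group})
    causes = [
        Cause(code=f"c{i + 1}", label=f"Cause {i + 1}", groups=groups)
        for i in range(n_causes)
    ] + [Cause(code=NON_CONCLUSIVE, label="Non-conclusive", groups=groups)]
    return CauseDictionary(causes=tuple(causes))


@pytest.fixture
def toy_dict5():
    return toy_dictionary(5)


def make_record(rid, cause, group=StudyGroup.OTHER_ADULT, indicators=None):
    if indicators is None:
        indicators = np.zeros(4, dtype=np.int8)
    return DeathRecord(id=str(rid), group=group, cda_cause=cause, indicators=indicators)


def hard_output(cause, likelihood=1.0):
    """A single-cause coder output with the remaining mass non-conclusive."""
    if cause == NON_CONCLUSIVE:
        return VAOutput(assigned=(), nonconclusive_mass=1.0)
    return VAOutput(
        assigned=((cause, likelihood),), nonconclusive_mass=1.0 - likelihood
    )
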