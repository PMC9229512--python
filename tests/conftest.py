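import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from tables import EX1_PRINTED_CORRECTIONS, EX1_RAW_TIMES, EX2_RAW_TIMES  # noqa: E402

from gvtnorms.io import published_norms
from gvtnorms.types import (
    LINE_IDS,
    LineCorrectionTable,
    LineOutcome,
    ParticipantRecord,
    Sex,
)


@pytest.fixture(scope="session")
def published():
    return published_norms()


def make_record(id, age, education, sex, times):
    """Build a record from a {LineId: time} map; missing lines are incorrect."""
    outcomes = {
        lid: (LineOutcome(True, times[lid]) if lid in times else LineOutcome(False))
        for lid in LINE_IDS
    }
    return ParticipantRecord(
        id=id, age=age, education=education, sex=Sex.parse(sex), outcomes=outcomes
    )


@pytest.fixture(scope="session")
def example1_record():
    return make_record("ex1", 48, 17, "F", EX1_RAW_TIMES)


@pytest.fixture(scope="session")
def example1_corrections():
    """The first-correction row as printed in the worked example itself."""
    return LineCorrectionTable(dict(EX1_PRINTED_CORRECTIONS))


@pytest.fixture(scope="session")
def example2_record():
    return make_record("ex2", 23, 13, "M", EX2_RAW_TIMES)
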