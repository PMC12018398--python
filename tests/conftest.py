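import datetime as dt

import pytest

from phenorule import Encounter, PatientRecord, StudyWindow

D0 = dt.date(2015, 1, 1)


def day(n: int) -> dt.date:
    """Day n of a fixture timeline starting 2015-01-01."""
    return D0 + dt.timedelta(days=n)


def enc(pid, source, n, text="", codes=()):
    return Encounter(pid, source, day(n), text, frozenset(codes))


def patient(pid, *encounters, reg=dt.date(2010, 1, 1)):
    return PatientRecord(pid, reg, encounters=list(encounters))


@pytest.fixture
def window():
    return StudyWindow(dt.date(2010, 1, 1), dt.date(2021, 6, 30))
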