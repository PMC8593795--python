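import datetime as dt

import pytest

from dilidetect import PrescriptionOrder, StudyConfig


@pytest.fixture
def config():
    return StudyConfig()


def order(start: str, days: int, pid="p1", med="M1", name="drug"):
    return PrescriptionOrder(pid, med, name, dt.date.fromisoformat(start), days)


@pytest.fixture
def make_order():
    return order
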