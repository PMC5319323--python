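import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from heavytails import MeasurementRecord, QuantitySeries

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def record(value, u_plus, u_minus=None, qid="Q", **kw):
    return MeasurementRecord(
        quantity_id=qid, value=value, u_plus=u_plus,
        u_minus=u_minus if u_minus is not None else u_plus, **kw)


@pytest.fixture
def worked_example_records():
    """The three asymmetric measurements of the printed worked example:
    x1 = 80 +3/-2, x2 = 100 +5/-4, x3 = 126 +15/-12."""
    return (record(80, 3, 2, record_id="x1"),
            record(100, 5, 4, record_id="x2"),
            record(126, 15, 12, record_id="x3"))


@pytest.fixture
def simple_series():
    recs = tuple(record(v, u, qid="Q1", record_id=f"Q1#{i}", year=2000.0 + i)
                 for i, (v, u) in enumerate(
                     [(10.0, 1.0), (11.0, 1.2), (9.5, 0.8),
                      (10.2, 1.1), (10.8, 0.9), (9.9, 1.0)]))
    return QuantitySeries("Q1", recs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
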