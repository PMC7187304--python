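import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from aladdin import Activity, CompoundRecord, FeatureVector, ScoreMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_column():
    """Six-compound toy screen: actives A1(-9), A2(-5), A3(-2) interleaved
    with decoys D1(-8), D2(-4), D3(-1)."""
    scores = {"A1": -9.0, "D1": -8.0, "A2": -5.0, "D2": -4.0, "A3": -2.0, "D3": -1.0}
    classes = {
        "A1": Activity.ACTIVE, "A2": Activity.ACTIVE, "A3": Activity.ACTIVE,
        "D1": Activity.DECOY, "D2": Activity.DECOY, "D3": Activity.DECOY,
    }
    matrix = ScoreMatrix(frame=pd.DataFrame({"S1": scores}))
    return matrix, classes


def make_raw_compound(cid: str, activity, bits) -> CompoundRecord:
    return CompoundRecord(
        compound_id=cid,
        activity_class=activity,
        features=FeatureVector("raw", np.asarray(bits, dtype=np.uint8)),
    )


@pytest.fixture
def raw_library():
    """20 abstract compounds (10 active, 10 decoy) with random 32-bit features."""
    rng = np.random.default_rng(42)
    lib = []
    for i in range(10):
        lib.append(make_raw_compound(f"A{i}", Activity.ACTIVE, rng.integers(0, 2, 32)))
    for i in range(10):
        lib.append(make_raw_compound(f"D{i}", Activity.DECOY, rng.integers(0, 2, 32)))
    return lib
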