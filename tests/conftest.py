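import numpy as np
import pandas as pd
import pytest

from imprintstat import ChickRecord, ExperimentData, Measurement


def make_chick(cid, batch, trained=True, score=None, approaches=None):
    """Small helper: a valid ChickRecord with consistent approaches."""
    if not trained:
        return ChickRecord(chick_id=cid, batch_id=batch, trained=False)
    if approaches is None and score is not None:
        # pick test approaches that reproduce the score exactly
        total = 10.0
        approaches = (50.0, score / 100.0 * total, total - score / 100.0 * total)
    a_tr, a_ts, a_alt = approaches
    return ChickRecord(
        chick_id=cid,
        batch_id=batch,
        trained=True,
        approach_training=a_tr,
        approach_test_training_stim=a_ts,
        approach_test_alternative_stim=a_alt,
        preference_score=100.0 * a_ts / (a_ts + a_alt),
    )


@pytest.fixture
def four_chick_experiment():
    """Two batches, each one trained + one untrained chick, full base measures."""
    chicks = [
        make_chick("t1", "b1", score=80.0),
        make_chick("u1", "b1", trained=False),
        make_chick("t2", "b2", score=60.0),
        make_chick("u2", "b2", trained=False),
    ]
    measurements = []
    amounts = {"t1": 1.2, "u1": 1.0, "t2": 0.9, "u2": 1.1}
    for cid, base in amounts.items():
        for i, measure in enumerate(("Total", "P416", "P527")):
            measurements.append(
                Measurement(chick_id=cid, region="IMM", hemisphere="left",
                            measure=measure, relative_amount=base + 0.1 * i)
            )
    return ExperimentData(chicks=chicks, measurements=measurements, timepoint="h1")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a, b)
        return True
    except AssertionError:
        return False
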