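import numpy as np
import pytest
from hypothesis import settings

from painweeks import ParticipantSeries, ResponseMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_series(values, participant_id="P1"):
    """Build a ParticipantSeries from a list where None means missing."""
    arr = np.array([np.nan if v is None else float(v) for v in values])
    return ParticipantSeries(participant_id, arr)


def make_matrix(rows, study_weeks=None):
    """Build a ResponseMatrix from {participant_id: [values-with-None]}."""
    series = [make_series(vals, pid) for pid, vals in rows.items()]
    return ResponseMatrix.from_series(series, study_weeks=study_weeks)


@pytest.fixture
def toy_matrix():
    """Three participants over 8 weeks covering zero/pain/missing patterns."""
    return make_matrix(
        {
            "A": [0, 0, 0, 0, 1, 2, 3, 0],       # 4-run at the start
            "B": [5, 4, None, 0, 0, 0, 0, 0],    # 5-run at the end
            "C": [1, 2, 3, 4, 5, 6, 7, 1],       # constant pain
        }
    )
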