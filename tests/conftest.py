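import numpy as np
import pandas as pd
import pytest

from hybridsearch.trial_io import TrialTable


def make_trials(rows):
    """Build a validated TrialTable from a list of dicts with defaults."""
    defaults = dict(
        participant_id="P000",
        trial_index=0,
        stimulus_id="stim000",
        mss=4,
        vss=4,
        context_present=False,
        target_present=True,
        response="present",
        rt=1.0,
        correct=True,
    )
    recs = []
    for i, row in enumerate(rows):
        rec = dict(defaults, trial_index=i)
        rec.update(row)
        recs.append(rec)
    df = pd.DataFrame(recs)
    return TrialTable.from_dataframe(df, validate=True)


@pytest.fixture
def small_trials():
    """12 hand-built trials: 2 participants x mixed outcomes."""
    rows = []
    for pid in ("P000", "P001"):
        rows += [
            dict(participant_id=pid, response="present", target_present=True, rt=1.2, correct=True),
            dict(participant_id=pid, response="absent", target_present=False, rt=2.0, correct=True),
            dict(participant_id=pid, response="present", target_present=False, rt=0.9, correct=False),
            dict(participant_id=pid, response="absent", target_present=True, rt=1.4, correct=False),
            dict(participant_id=pid, response="none", target_present=True, rt=np.nan, correct=np.nan),
            dict(participant_id=pid, response="present", target_present=True, rt=0.15, correct=True),
        ]
    return make_trials(rows)
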