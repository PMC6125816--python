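import numpy as np
import pandas as pd
import pytest

from stopnet.simulate import (
    RaceParams,
    StaircaseConfig,
    generate_task_design,
    simulate_race_behavior,
)


@pytest.fixture(scope="session")
def default_design():
    """Full-size task: 360 Go / 80 Stop / 40 No-Go over two sessions."""
    return generate_task_design(seed=11)


@pytest.fixture(scope="session")
def small_design():
    return generate_task_design(n_go=70, n_stop=20, n_nogo=10, n_sessions=1, seed=5)


@pytest.fixture(scope="session")
def default_behavior(default_design):
    return simulate_race_behavior(default_design, RaceParams(), seed=13)


def make_trials(categories, rts=None, ssds=None, session=1, iti=2.0):
    """Hand-built trial table in presentation order."""
    n = len(categories)
    type_of = {
        "correctGo": "Go", "GoCommission": "Go", "GoOmission": "Go",
        "correctNoGo": "NoGo", "NoGoCommission": "NoGo",
        "SuccStop": "Stop", "UnsuccStop": "Stop",
        "EarlySS": "Stop", "IncorrectSS": "Stop",
    }
    rts = rts if rts is not None else [np.nan] * n
    ssds = ssds if ssds is not None else [np.nan] * n
    return pd.DataFrame(
        {
            "trial_type": [type_of[c] for c in categories],
            "onset": np.arange(n) * iti,
            "arrow_dir": ["left"] * n,
            "session": session,
            "response": [c in ("correctGo", "GoCommission", "UnsuccStop",
                               "EarlySS", "IncorrectSS", "NoGoCommission")
                         for c in categories],
            "response_correct": [c in ("correctGo", "correctNoGo", "SuccStop")
                                 for c in categories],
            "rt_ms": rts,
            "ssd_ms": ssds,
            "category": categories,
        }
    )


@pytest.fixture
def trials_factory():
    return make_trials
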