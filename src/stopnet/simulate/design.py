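"""Stop-Signal/No-Go (SNG) task design generation.

The default paradigm interleaves 360 Go (70%), 80 Stop-Signal (20%) and
40 No-Go (10%) trials at random across two scanning runs.  Go trials show
a black arrow whose direction must be reported; on Stop-Signal trials the
arrow turns red after a variable stop-signal delay (SSD) and the response
must be withheld; No-Go trials are red from the outset (SSD = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GO, STOP, NOGO = "Go", "Stop", "NoGo"
TRIAL_TYPES = (GO, STOP, NOGO)


@dataclass
class TaskDesign:
    """Ordered trial list plus scan geometry.

    ``trials`` has columns: trial_type, onset (s, within session),
    arrow_dir ('left'/'right'), session (1-based).
    """

    trials: pd.DataFrame
    tr_s: float = 2.0
    n_volumes_per_session: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_sessions(self) -> int:
        return int(self.trials["session"].max())

    def session(self, s: int) -> pd.DataFrame:
        return self.trials[self.trials["session"] == s].reset_index(drop=True)

    def counts(self) -> dict:
        return self.trials["trial_type"].value_counts().to_dict()


def _split_counts(n: int, n_sessions: int) -> list[int]:
    base, rem = divmod(n, n_sessions)
    return [base + (1 if s < rem else 0) for s in range(n_sessions)]


def generate_task_design(
    n_go: int = 360,
    n_stop: int = 80,
    n_nogo: int = 40,
    n_sessions: int = 2,
    iti_s: float = 2.6,
    tr_s: float = 2.0,
    jitter_s: float = 0.5,
    tail_s: float = 16.0,
    seed: int | np.random.Generator = 0,
) -> TaskDesign:
    """Randomly interleave Go/Stop/No-Go trials with exact per-type counts.

    Counts are split as evenly as possible across sessions; trial order is
    a seeded permutation within each session.  Onsets are regular with a
    uniform jitter of up to ``jitter_s`` (kept strictly increasing).
    ``tail_s`` of rest is appended so late-trial hemodynamic responses are
    sampled.
    """
    for name, n in (("n_go", n_go), ("n_stop", n_stop), ("n_nogo", n_nogo)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0, got {n}")
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    if jitter_s >= iti_s:
        raise ValueError("jitter must be smaller than the inter-trial interval")
    rng = np.random.default_rng(seed)

    per_sess = {
        GO: _split_counts(n_go, n_sessions),
        STOP: _split_counts(n_stop, n_sessions),
        NOGO: _split_counts(n_nogo, n_sessions),
    }
    rows = []
    max_dur = 0.0
    for s in range(n_sessions):
        types = np.array(
            [GO] * per_sess[GO][s] + [STOP] * per_sess[STOP][s] + [NOGO] * per_sess[NOGO][s]
        )
        types = types[rng.permutation(types.size)]
        onsets = np.arange(types.size) * iti_s + rng.uniform(0.0, jitter_s, types.size)
        dirs = rng.choice(["left", "right"], size=types.size)
        for tt, on, d in zip(types, onsets, dirs):
            rows.append({"trial_type": tt, "onset": on, "arrow_dir": d, "session": s + 1})
        if types.size:
            max_dur = max(max_dur, onsets[-1] + tail_s)
    trials = pd.DataFrame(rows, columns=["trial_type", "onset", "arrow_dir", "session"])
    n_volumes = int(np.ceil(max_dur / tr_s)) if rows else 0
    return TaskDesign(
        trials=trials,
        tr_s=tr_s,
        n_volumes_per_session=n_volumes,
        meta={"n_go": n_go, "n_stop": n_stop, "n_nogo": n_nogo, "iti_s": iti_s},
    )
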