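"""Head-motion trace simulation.

Realignment parameters (3 translations in mm, 3 rotations in radians)
are simulated as a Gaussian random walk whose step scale grows with a
subject-level severity factor and, optionally, with age — emulating the
positive age-motion association seen in adult life-span cohorts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: baseline random-walk step scales at severity 1 (mm, mm, mm, rad, rad, rad)
BASE_STEP = np.array([0.02, 0.02, 0.02, 4e-4, 4e-4, 4e-4])


def simulate_motion(
    n_volumes: int,
    severity: float = 1.0,
    age: float = 50.0,
    age_slope: float = 0.015,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Random-walk realignment parameters for one session.

    Step scale is ``BASE_STEP * severity * (1 + age_slope * (age - 53))``
    (53 being the midpoint of an 18-88 year range), floored at zero.
    ``severity = 0`` yields an all-zero table.
    """
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    rng = np.random.default_rng(seed)
    scale = BASE_STEP * max(0.0, severity) * max(0.0, 1.0 + age_slope * (age - 53.0))
    steps = rng.standard_normal((n_volumes, 6)) * scale
    steps[0] = 0.0
    params = np.cumsum(steps, axis=0)
    return pd.DataFrame(params, columns=list(MOTION_COLUMNS))
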