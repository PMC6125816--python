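"""Independent-race simulation of stop-signal behavior.

A response on a Stop-Signal trial occurs iff the go process finishes
before SSD + stop latency (or the stop process fails to trigger).  Go
finishing times are ex-Gaussian; stop latencies are truncated normal
(truncated at zero).  SSD is adapted by a 1-up/1-down staircase in fixed
steps, which converges to ~50% response rate on stop trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import GO, NOGO, STOP, TaskDesign

# behavioral outcome categories used by the downstream GLM
CATEGORIES = (
    "correctGo",
    "GoCommission",
    "GoOmission",
    "correctNoGo",
    "NoGoCommission",
    "SuccStop",
    "UnsuccStop",
    "EarlySS",
    "IncorrectSS",
)


@dataclass
class RaceParams:
    """Generative parameters of the race between going and stopping (ms)."""

    go_rt_mu: float = 450.0
    go_rt_sigma: float = 60.0
    go_rt_tau: float = 100.0
    ssrt_mu: float = 180.0
    ssrt_sigma: float = 30.0
    go_omission_p: float = 0.02
    go_error_p: float = 0.02
    trigger_failure_p: float = 0.0

    def __post_init__(self):
        for name in ("go_rt_sigma", "go_rt_tau", "ssrt_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("go_omission_p", "go_error_p", "trigger_failure_p"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    @property
    def mean_go_rt(self) -> float:
        return self.go_rt_mu + self.go_rt_tau

    @property
    def mean_ssrt(self) -> float:
        # truncated-at-zero normal mean
        from scipy.stats import truncnorm

        a = -self.ssrt_mu / self.ssrt_sigma
        return float(truncnorm.mean(a, np.inf, loc=self.ssrt_mu, scale=self.ssrt_sigma))


@dataclass
class StaircaseConfig:
    """1-up/1-down SSD tracker configuration (ms)."""

    initial_ssd_ms: float = 250.0
    step_ms: float = 50.0
    min_ssd_ms: float = 0.0
    max_ssd_ms: float = 900.0

    def __post_init__(self):
        if self.step_ms <= 0:
            raise ValueError("step_ms must be > 0")
        if not self.min_ssd_ms <= self.initial_ssd_ms <= self.max_ssd_ms:
            raise ValueError("require min_ssd_ms <= initial_ssd_ms <= max_ssd_ms")


def _draw_go_time(params: RaceParams, rng: np.random.Generator) -> float:
    return (
        params.go_rt_mu
        + params.go_rt_sigma * rng.standard_normal()
        + rng.exponential(params.go_rt_tau)
    )


def _draw_stop_time(params: RaceParams, rng: np.random.Generator) -> float:
    while True:  # truncate at zero
        t = params.ssrt_mu + params.ssrt_sigma * rng.standard_normal()
        if t > 0:
            return t


def simulate_race_behavior(
    design: TaskDesign,
    params: RaceParams | None = None,
    staircase: StaircaseConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate trialwise responses for a task design.

    Returns the trial table of ``design`` augmented with columns
    response (bool), response_correct (bool), rt_ms, ssd_ms (stop trials
    only, NaN elsewhere) and category (see ``CATEGORIES``).

    The staircase raises SSD by one step after a successful stop and
    lowers it after a response, clamped to its configured bounds; No-Go
    trials are races with SSD = 0 and do not move the staircase.
    """
    if design.trials.empty:
        raise ValueError("design has no trials")
    params = params or RaceParams()
    staircase = staircase or StaircaseConfig()
    rng = np.random.default_rng(seed)

    ssd = float(staircase.initial_ssd_ms)
    records = []
    for row in design.trials.itertuples(index=False):
        rec = {
            "trial_type": row.trial_type,
            "onset": row.onset,
            "arrow_dir": row.arrow_dir,
            "session": row.session,
            "response": False,
            "response_correct": False,
            "rt_ms": np.nan,
            "ssd_ms": np.nan,
        }
        if row.trial_type == GO:
            if rng.random() < params.go_omission_p:
                rec["category"] = "GoOmission"
            else:
                rec["response"] = True
                rec["rt_ms"] = _draw_go_time(params, rng)
                if rng.random() < params.go_error_p:
                    rec["category"] = "GoCommission"
                else:
                    rec["response_correct"] = True
                    rec["category"] = "correctGo"
        elif row.trial_type == NOGO:
            go_t = _draw_go_time(params, rng)
            omitted = rng.random() < params.go_omission_p
            triggered = rng.random() >= params.trigger_failure_p
            responded = (not omitted) and (
                not triggered or go_t < _draw_stop_time(params, rng)
            )
            if responded:
                rec["response"] = True
                rec["rt_ms"] = go_t
                rec["category"] = "NoGoCommission"
            else:
                rec["response_correct"] = True
                rec["category"] = "correctNoGo"
        else:  # Stop-Signal
            rec["ssd_ms"] = ssd
            go_t = _draw_go_time(params, rng)
            omitted = rng.random() < params.go_omission_p
            triggered = rng.random() >= params.trigger_failure_p
            responded = (not omitted) and (
                not triggered or go_t < ssd + _draw_stop_time(params, rng)
            )
            if responded:
                rec["response"] = True
                rec["rt_ms"] = go_t
                if go_t < ssd:
                    rec["category"] = "EarlySS"
                elif rng.random() < params.go_error_p:
                    rec["category"] = "IncorrectSS"
                else:
                    rec["category"] = "UnsuccStop"
                ssd = max(staircase.min_ssd_ms, ssd - staircase.step_ms)
            else:
                rec["response_correct"] = True
                rec["category"] = "SuccStop"
                ssd = min(staircase.max_ssd_ms, ssd + staircase.step_ms)
        records.append(rec)
    return pd.DataFrame.from_records(records)
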