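"""Stop-signal behavioral statistics.

Implements the premature-response-corrected p(respond|signal), the
block-based integration estimator of the stop-signal reaction time
(SSRT), performance summaries, root-mean-square volume-to-volume head
displacement, and cohort exclusion rules (too few usable stop trials;
extreme motion beyond age effects).

The integration method estimates SSRT per block as the p(respond|signal)
quantile of the ranked correct-Go RT distribution (the "critical Go RT",
with Go omissions assigned the block's maximum RT) minus the block's
mean SSD; the subject's SSRT is the mean over blocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StopCounts",
    "SsrtBlockEstimate",
    "p_respond_given_signal",
    "stop_counts",
    "partition_blocks",
    "estimate_ssrt_block_integration",
    "summarize_performance",
    "rms_displacement",
    "apply_exclusions",
]

STOP_CATEGORIES = ("SuccStop", "UnsuccStop", "EarlySS", "IncorrectSS")


@dataclass
class StopCounts:
    """Counts entering the corrected p(respond|signal) formula."""

    n_stopsignal: int
    n_succstop: int
    n_rt_lt_ssd: int

    def __post_init__(self):
        if not 0 <= self.n_succstop + self.n_rt_lt_ssd <= self.n_stopsignal:
            raise ValueError("inconsistent stop-trial counts")


@dataclass
class SsrtBlockEstimate:
    block_id: int
    n_go: int
    n_stop: int
    p_respond_signal: float
    critical_go_rt_ms: float
    mean_ssd_ms: float
    ssrt_ms: float
    estimable: bool = True
    note: str = ""


def p_respond_given_signal(counts: StopCounts) -> float:
    """(N_stop - N_succ - N_early) / (N_stop - N_early).

    Premature responses (RT < SSD, before the signal appeared) are
    removed from both numerator and denominator.
    """
    denom = counts.n_stopsignal - counts.n_rt_lt_ssd
    if denom <= 0:
        raise ValueError("p(respond|signal) undefined: no post-signal stop trials")
    return (counts.n_stopsignal - counts.n_succstop - counts.n_rt_lt_ssd) / denom


def stop_counts(trials: pd.DataFrame) -> StopCounts:
    """StopCounts from a categorized trial table."""
    cat = trials["category"]
    n_stop = int(cat.isin(STOP_CATEGORIES).sum())
    return StopCounts(
        n_stopsignal=n_stop,
        n_succstop=int((cat == "SuccStop").sum()),
        n_rt_lt_ssd=int((cat == "EarlySS").sum()),
    )


def partition_blocks(
    trials: pd.DataFrame, stops_per_block: int = 30, min_trailing: int = 15
) -> list[pd.DataFrame]:
    """Group consecutive trials into blocks of ``stops_per_block`` stop trials.

    Trials must be in presentation order.  A block closes when it has
    accumulated ``stops_per_block`` Stop-Signal trials; the trailing
    remainder forms a final block if it contains at least
    ``min_trailing`` stop trials, otherwise it is merged into the last
    full block.  Block boundaries never split a trial.
    """
    is_stop = trials["category"].isin(STOP_CATEGORIES).to_numpy()
    if is_stop.sum() == 0:
        return []
    cum = np.cumsum(is_stop)
    # block index of each trial: completed stop trials before it // size
    block_of = (cum - is_stop) // stops_per_block
    n_blocks = int(block_of.max()) + 1
    blocks = [trials[block_of == b] for b in range(n_blocks)]
    tail_stops = int(is_stop[block_of == n_blocks - 1].sum())
    if n_blocks > 1 and tail_stops < min_trailing:
        merged = pd.concat([blocks[-2], blocks[-1]])
        blocks = blocks[:-2] + [merged]
    return [b.reset_index(drop=True) for b in blocks]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def estimate_ssrt_block_integration(
    trials: pd.DataFrame,
    stops_per_block: int = 30,
    min_trailing: int = 15,
) -> tuple[float, list[SsrtBlockEstimate]]:
    """Subject SSRT (ms) via the block-based integration method.

    Per block: Go omissions are replaced by the block's maximum Go RT;
    RTs of correct Go trials are ranked ascending; the critical Go RT is
    the n-th ranked RT with ``n = max(1, round(p * N_go))`` (half-up);
    block SSRT = critical RT - mean SSD.  Returns the mean over
    estimable blocks and the per-block detail.
    """
    blocks = partition_blocks(trials, stops_per_block, min_trailing)
    if not blocks:
        raise ValueError("no Stop-Signal trials: SSRT is not estimable")
    estimates: list[SsrtBlockEstimate] = []
    for b_id, block in enumerate(blocks):
        cat = block["category"]
        go_rts = block.loc[cat == "correctGo", "rt_ms"].to_numpy(dtype=float)
        n_omis = int((cat == "GoOmission").sum())
        counts = stop_counts(block)
        note = ""
        if go_rts.size == 0 or counts.n_stopsignal - counts.n_rt_lt_ssd <= 0:
            estimates.append(
                SsrtBlockEstimate(b_id, go_rts.size, counts.n_stopsignal, np.nan,
                                  np.nan, np.nan, np.nan, False, "no usable trials")
            )
            continue
        if n_omis:  # omission correction: omissions count as maximal RTs
            go_rts = np.concatenate([go_rts, np.full(n_omis, go_rts.max())])
        p = p_respond_given_signal(counts)
        # premature-response trials are removed from p(respond|signal); for
        # consistency their SSDs do not enter the mean SSD either
        post_signal = cat.isin(STOP_CATEGORIES) & (cat != "EarlySS")
        ssds = block.loc[post_signal, "ssd_ms"].to_numpy(dtype=float)
        mean_ssd = float(np.nanmean(ssds))
        if p <= 0:
            estimates.append(
                SsrtBlockEstimate(b_id, go_rts.size, counts.n_stopsignal, p,
                                  np.nan, mean_ssd, np.nan, False, "p(respond|signal) = 0")
            )
            continue
        n = max(1, _round_half_up(p * go_rts.size))
        n = min(n, go_rts.size)
        critical = float(np.sort(go_rts)[n - 1])
        estimates.append(
            SsrtBlockEstimate(b_id, go_rts.size, counts.n_stopsignal, p,
                              critical, mean_ssd, critical - mean_ssd, True, note)
        )
    valid = [e.ssrt_ms for e in estimates if e.estimable]
    if not valid:
        raise ValueError("no estimable blocks")
    return float(np.mean(valid)), estimates


def summarize_performance(trials: pd.DataFrame) -> dict:
    """Subject-level performance summary.

    Keys: go_rt_mean_ms (correct Go), go_accuracy, nogo_accuracy,
    p_respond_signal, n_premature, ssrt_ms (NaN when not estimable),
    flags (list of data issues).
    """
    cat = trials["category"]
    flags: list[str] = []
    go_mask = trials["trial_type"] == "Go"
    nogo_mask = trials["trial_type"] == "NoGo"
    n_go, n_nogo = int(go_mask.sum()), int(nogo_mask.sum())
    go_acc = float((cat[go_mask] == "correctGo").mean()) if n_go else np.nan
    nogo_acc = float((cat[nogo_mask] == "correctNoGo").mean()) if n_nogo else np.nan
    if not n_nogo:
        flags.append("no NoGo trials: accuracy undefined")
    go_rts = trials.loc[cat == "correctGo", "rt_ms"]
    go_rt_mean = float(go_rts.mean()) if len(go_rts) else np.nan
    counts = stop_counts(trials)
    try:
        p_rs = p_respond_given_signal(counts)
    except ValueError:
        p_rs, flags = np.nan, flags + ["p(respond|signal) undefined"]
    try:
        ssrt, _ = estimate_ssrt_block_integration(trials)
    except ValueError as e:
        ssrt = np.nan
        flags.append(str(e))
    return {
        "go_rt_mean_ms": go_rt_mean,
        "go_accuracy": go_acc,
        "nogo_accuracy": nogo_acc,
        "p_respond_signal": p_rs,
        "n_premature": counts.n_rt_lt_ssd,
        "n_stopsignal": counts.n_stopsignal,
        "ssrt_ms": ssrt,
        "flags": flags,
    }


def _rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def rms_displacement(motion: pd.DataFrame, radius_mm: float = 80.0) -> tuple[np.ndarray, float]:
    """Volume-to-volume RMS displacement over a sphere of ``radius_mm``.

    For each consecutive pair of volumes with parameter difference
    (dt translations, dr rotations): ``sqrt(radius^2/5 * trace(A'A) + t't)``
    with ``A = R(dr) - I`` and ``t = dt`` — the RMS of the displacement
    of points on a sphere of the given radius under the rigid-body
    difference transform.  Returns (per-pair displacement, mean).
    """
    cols = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    if not all(c in motion.columns for c in cols):
        raise ValueError(f"motion table must contain columns {cols}")
    p = motion[cols].to_numpy(dtype=float)
    if p.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.diff(p, axis=0)
    out = np.empty(d.shape[0])
    for i, row in enumerate(d):
        t, r = row[:3], row[3:]
        A = _rotation_matrix(*r) - np.eye(3)
        out[i] = np.sqrt(radius_mm**2 / 5.0 * np.trace(A.T @ A) + t @ t)
    return out, float(out.mean())


@dataclass
class ExclusionLog:
    excluded: dict[str, str] = field(default_factory=dict)

    def add(self, subject_id: str, reason: str):
        self.excluded[subject_id] = (
            self.excluded[subject_id] + "; " + reason if subject_id in self.excluded else reason
        )


def apply_exclusions(
    summaries: pd.DataFrame,
    max_premature: int = 10,
    motion_sd_cut: float = 3.5,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Cohort exclusion rules.

    ``summaries`` is indexed by subject with columns ``n_premature``,
    ``mean_displacement`` and ``age_years``.  Excludes (a) subjects with
    more than ``max_premature`` premature stop-trial responses (fewer
    than N_stop - max_premature usable stop trials) and (b) subjects
    whose motion, after regressing out a linear age trend, lies at or
    above ``motion_sd_cut`` SDs of the residual distribution.  Returns
    the summaries with an ``excluded`` flag plus a {subject: reason} log.
    """
    df = summaries.copy()
    log = ExclusionLog()
    for sid, row in df.iterrows():
        if row["n_premature"] > max_premature:
            log.add(str(sid), "stop-trial minimum")
    if "mean_displacement" in df.columns and len(df) >= 3:
        age = df["age_years"].to_numpy(dtype=float)
        disp = df["mean_displacement"].to_numpy(dtype=float)
        X = np.column_stack([np.ones_like(age), age])
        beta, *_ = np.linalg.lstsq(X, disp, rcond=None)
        resid = disp - X @ beta
        sd = resid.std(ddof=1)
        if sd > 0:
            for sid, r in zip(df.index, resid):
                if r >= motion_sd_cut * sd:
                    log.add(str(sid), "excessive motion")
    df["excluded"] = [str(s) in log.excluded for s in df.index]
    df["exclusion_reason"] = [log.excluded.get(str(s), "") for s in df.index]
    return df, dict(log.excluded)
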