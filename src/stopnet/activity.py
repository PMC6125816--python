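"""Component responsivity: design matrices, GLMs and group statistics.

The responsivity index of a component is the GLM beta-weight difference
between successful and unsuccessful stop conditions, averaged across
recording sessions.  Group-level consistency is assessed by one-sample
t tests with Benjamini-Hochberg FDR at alpha = 0.01; age dependence by
robust (Huber) regression with age as the dependent variable and FDR at
alpha = 0.05, mirroring the different natures of the two tests (mean
difference vs continuous association).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .hrf import cosine_drifts, event_regressor

__all__ = [
    "DesignMatrix",
    "build_design_matrix",
    "component_glm",
    "responsivity_index",
    "responsivity_table",
    "group_responsivity_test",
    "age_effect_robust",
    "fdr_bh",
    "peri_event_average",
]

#: event regressors: name -> outcome categories pooled into the column
#: (Go commission and omission errors form a single error regressor)
EVENT_REGRESSORS: dict[str, tuple[str, ...]] = {
    "correctGo": ("correctGo",),
    "correctNoGo": ("correctNoGo",),
    "SuccStop": ("SuccStop",),
    "UnsuccStop": ("UnsuccStop",),
    "GoError": ("GoCommission", "GoOmission"),
    "NoGoCommission": ("NoGoCommission",),
    "EarlySS": ("EarlySS",),
    "IncorrectSS": ("IncorrectSS",),
}

TASK_OF_INTEREST = ("correctGo", "correctNoGo", "SuccStop", "UnsuccStop")


@dataclass
class DesignMatrix:
    """Per-session design: HRF-convolved event columns + nuisance columns.

    ``task_columns`` name the event regressors (Psi, the psychological
    part); ``confound_columns`` the motion/drift/intercept part (C).
    """

    X: pd.DataFrame
    task_columns: list[str]
    confound_columns: list[str]
    session: int
    dropped: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    def columns_matrix(self, names: list[str]) -> np.ndarray:
        return self.X[names].to_numpy(dtype=float)


def build_design_matrix(
    behavior: pd.DataFrame,
    session: int,
    n_volumes: int,
    tr_s: float,
    motion: pd.DataFrame | None = None,
    high_pass_s: float = 128.0,
) -> DesignMatrix:
    """Design matrix for one session from actual behavioral outcomes.

    Event regressors are built per observed outcome category (not
    nominal trial type), modeled as impulses at trial onset convolved
    with the double-gamma HRF.  Categories with zero events are omitted
    and recorded in ``dropped``.  Nuisance columns: 6 realignment
    parameters (when given), discrete-cosine drifts up to 1/``high_pass_s``
    Hz, and an intercept.
    """
    sess = behavior[behavior["session"] == session]
    cols: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for name, cats in EVENT_REGRESSORS.items():
        onsets = sess.loc[sess["category"].isin(cats), "onset"].to_numpy(dtype=float)
        if onsets.size == 0:
            dropped.append(name)
            continue
        cols[name] = event_regressor(onsets, n_volumes, tr_s)
    task_columns = list(cols)
    confound_columns: list[str] = []
    if motion is not None:
        for c in motion.columns:
            cols[c] = motion[c].to_numpy(dtype=float)
            confound_columns.append(c)
    drifts = cosine_drifts(n_volumes, tr_s, high_pass_s)
    for i in range(drifts.shape[1]):
        cols[f"drift_{i + 1:02d}"] = drifts[:, i]
        confound_columns.append(f"drift_{i + 1:02d}")
    cols["intercept"] = np.ones(n_volumes)
    confound_columns.append("intercept")
    X = pd.DataFrame(cols)
    return DesignMatrix(X, task_columns, confound_columns, session, dropped)


def component_glm(tc: np.ndarray, design: DesignMatrix) -> pd.Series:
    """Ordinary least squares of a component time course on the design.

    Returns the beta vector indexed by design column; raises on rank
    deficiency, naming the collinear columns.
    """
    X = design.matrix
    if len(tc) != X.shape[0]:
        raise ValueError("time course and design differ in length")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify involved columns by near-zero singular directions
        _, sv, vt = np.linalg.svd(X, full_matrices=False)
        bad = vt[sv < sv[0] * 1e-10]
        names = [
            design.X.columns[j]
            for j in np.unique(np.nonzero(np.abs(bad) > 1e-6)[1])
        ]
        raise np.linalg.LinAlgError(f"design matrix is rank deficient; columns: {names}")
    beta, *_ = np.linalg.lstsq(X, np.asarray(tc, dtype=float), rcond=None)
    return pd.Series(beta, index=design.X.columns)


def responsivity_index(
    betas_per_session: list[pd.Series],
    positive: str = "SuccStop",
    negative: str = "UnsuccStop",
) -> tuple[float, bool]:
    """Contrast of betas averaged over sessions.

    Sessions missing either condition are skipped; returns (value,
    complete) where ``complete`` is False when any session was skipped
    (single-session values are flagged, not discarded).
    """
    vals = [
        float(b[positive] - b[negative])
        for b in betas_per_session
        if positive in b.index and negative in b.index
    ]
    if not vals:
        raise ValueError(f"no session contains both {positive} and {negative}")
    return float(np.mean(vals)), len(vals) == len(betas_per_session)


def responsivity_table(
    subject_tcs: dict[str, np.ndarray],
    designs_per_subject: dict[str, list[DesignMatrix]],
    session_lengths: list[int],
) -> pd.DataFrame:
    """Responsivity [subjects x components] from concatenated TCs.

    ``subject_tcs`` holds the back-reconstructed [time x k] series with
    sessions stacked in order; ``session_lengths`` gives the per-session
    volume counts used to unstack.
    """
    rows = {}
    bounds = np.concatenate([[0], np.cumsum(session_lengths)])
    for sid, tc in subject_tcs.items():
        designs = designs_per_subject[sid]
        vals = []
        for c in range(tc.shape[1]):
            betas = [
                component_glm(tc[bounds[s] : bounds[s + 1], c], designs[s])
                for s in range(len(designs))
            ]
            v, _ = responsivity_index(betas)
            vals.append(v)
        rows[sid] = vals
    k = len(next(iter(rows.values())))
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"ic{c:02d}" for c in range(k)]
    )


def fdr_bh(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p values must lie in [0, 1]")
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def group_responsivity_test(values: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Per-component one-sample t tests vs 0 with BH-FDR at ``alpha``.

    Returns a table with t, p, q-significance flag per component;
    zero-variance columns are flagged and given p = 1.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 subjects")
    t, p, flags = [], [], []
    for c in values.columns:
        v = values[c].to_numpy(dtype=float)
        if np.std(v, ddof=1) == 0:
            t.append(np.nan), p.append(1.0), flags.append("zero variance")
        else:
            res = stats.ttest_1samp(v, 0.0)
            t.append(res.statistic), p.append(res.pvalue), flags.append("")
    out = pd.DataFrame(
        {"t": t, "p": p, "mean": values.mean(), "flag": flags}, index=values.columns
    )
    out["significant"] = fdr_bh(out["p"].to_numpy(), alpha)
    return out


def age_effect_robust(
    values: pd.DataFrame,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Robust (Huber) regression of age on each measure, BH-FDR over measures.

    Follows the orientation with age as the dependent variable and the
    brain measure plus covariates of no interest as independent
    variables.  Constant covariates are dropped (noted in ``flag``).
    Also reports the equivalent partial correlation ``r_partial =
    t / sqrt(t^2 + df)`` for interpretability.
    """
    age = np.asarray(age, dtype=float)
    rows = []
    for c in values.columns:
        v = values[c].to_numpy(dtype=float)
        flag = ""
        X = [v]
        names = [c]
        if covariates is not None:
            for cc in covariates.columns:
                col = covariates[cc].to_numpy(dtype=float)
                if np.std(col) == 0:
                    flag = f"dropped constant covariate {cc}"
                    continue
                X.append(col)
                names.append(cc)
        if np.std(v) == 0:
            rows.append({"coef": np.nan, "t": np.nan, "p": 1.0,
                         "r_partial": np.nan, "flag": "zero variance"})
            continue
        Xm = sm.add_constant(np.column_stack(X))
        fit = sm.RLM(age, Xm, M=sm.robust.norms.HuberT(t=1.345)).fit(
            maxiter=max_iter, tol=1e-6
        )
        tval = float(fit.tvalues[1])
        df = len(age) - Xm.shape[1]
        rows.append(
            {
                "coef": float(fit.params[1]),
                "t": tval,
                "p": float(fit.pvalues[1]),
                "r_partial": tval / np.sqrt(tval**2 + df),
                "flag": flag,
            }
        )
    out = pd.DataFrame(rows, index=values.columns)
    out["significant"] = fdr_bh(out["p"].to_numpy(), alpha)
    return out


def peri_event_average(
    tc: np.ndarray,
    onsets_s: np.ndarray,
    window_s: float,
    tr_s: float,
) -> tuple[np.ndarray, list[str]]:
    """Event-locked average time course, baseline-subtracted at onset.

    Windows are aligned to the nearest volume; windows running past the
    end of the series are truncated (flagged).  Returns (mean window,
    flags); an empty onset list yields an empty array.
    """
    tc = np.asarray(tc, dtype=float)
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    flags: list[str] = []
    if onsets_s.size == 0:
        flags.append("no events")
        return np.empty(0), flags
    w = int(round(window_s / tr_s))
    segs = []
    for on in onsets_s:
        i0 = int(round(on / tr_s))
        if i0 >= len(tc):
            flags.append(f"onset {on:.1f}s beyond series")
            continue
        seg = tc[i0 : i0 + w]
        if len(seg) < w:
            flags.append(f"window at {on:.1f}s truncated")
            seg = np.pad(seg, (0, w - len(seg)), constant_values=np.nan)
        segs.append(seg - seg[0])
    if not segs:
        return np.empty(0), flags
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN tail bins
        return np.nanmean(np.stack(segs), axis=0), flags
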