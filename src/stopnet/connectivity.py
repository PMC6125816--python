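"""Context-independent and context-dependent (cPPI) connectivity.

Context-independent ("spontaneous") connectivity between two component
time courses is the coefficient of TC_j in a multiple regression with
TC_i as the dependent variable and all task regressors plus confounds
as covariates — association that remains after task-evoked structure is
removed.

Context-dependent connectivity uses correlational psychophysiological
interactions (cPPI) contrasting the two stop outcomes: for each
condition, both time courses are multiplied by that condition's
psychological series, the interaction terms are orthogonalized against
Z = {TC_i, TC_j, task design Psi, confounds C}, and their Pearson
correlation estimates the pair's coupling expressed during that
condition.  The cPPI value is the (tanh-compressed) Fisher-z difference
of the successful-stop minus unsuccessful-stop coupling — symmetric in
(i, j), positive when the pair couples more strongly during successful
stopping, and, crucially, null when coupling is strong but constant
across conditions.  The psychological series defaults to the condition
epoch indicator (a short window from each event onset); HRF convolution
of the psychological term is available as a flag for neural-level
interpretations of the modulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .activity import DesignMatrix, age_effect_robust, fdr_bh
from .hrf import event_regressor

__all__ = [
    "spontaneous_connectivity",
    "build_psych_contrast",
    "psych_contrast_pair",
    "cppi",
    "cppi_pvalue",
    "ConnectivityMatrix",
    "connectivity_matrix",
    "connectivity_group_tests",
]


def _residualize(y: np.ndarray, Z: np.ndarray, ridge: float = 1e-8) -> np.ndarray:
    """Least-squares residual of y against the columns of Z.

    Falls back to a tiny ridge penalty when Z is numerically singular.
    """
    try:
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    except np.linalg.LinAlgError:
        beta = np.linalg.solve(Z.T @ Z + ridge * np.eye(Z.shape[1]), Z.T @ y)
    return y - Z @ beta


def spontaneous_connectivity(
    tc_i: np.ndarray,
    tc_j: np.ndarray,
    design: DesignMatrix,
    confounds: np.ndarray | None = None,
) -> tuple[float, float]:
    """Task- and confound-controlled regression coefficient of TC_j on TC_i.

    Returns (coefficient, partial correlation).  The model regresses
    TC_i on [TC_j, task regressors, design confounds, extra confounds];
    collinearity raises with the offending column count.
    """
    tc_i = np.asarray(tc_i, dtype=float)
    tc_j = np.asarray(tc_j, dtype=float)
    if tc_i.shape != tc_j.shape:
        raise ValueError("time courses differ in length")
    covars = [design.matrix]
    if confounds is not None:
        covars.append(np.asarray(confounds, dtype=float))
    C = np.column_stack(covars)
    X = np.column_stack([tc_j, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear columns in connectivity regression")
    beta, *_ = np.linalg.lstsq(X, tc_i, rcond=None)
    ri = _residualize(tc_i, C)
    rj = _residualize(tc_j, C)
    r = float(np.corrcoef(ri, rj)[0, 1])
    return float(beta[0]), r


def build_psych_contrast(
    behavior: pd.DataFrame,
    session: int,
    n_volumes: int,
    tr_s: float,
    condition: str = "SuccStop",
    window_s: float = 4.0,
    hrf: bool = False,
    center: bool = False,
) -> np.ndarray:
    """Psychological series for one condition.

    Default: a boxcar indicator covering ``window_s`` seconds from each
    event onset of ``condition`` (the epoch over which coupling is
    interrogated).  With ``hrf`` set, impulses at the onsets are
    HRF-convolved instead.  ``center`` removes the series mean.
    """
    sess = behavior[behavior["session"] == session]
    onsets = sess.loc[sess["category"] == condition, "onset"].to_numpy(dtype=float)
    if onsets.size == 0:
        raise ValueError(f"no {condition} events in session {session}")
    if hrf:
        series = event_regressor(onsets, n_volumes, tr_s)
    else:
        t = np.arange(n_volumes) * tr_s
        series = np.zeros(n_volumes)
        for on in onsets:
            series[(t >= on) & (t < on + window_s)] = 1.0
    if center:
        series = series - series.mean()
    return series


def psych_contrast_pair(
    behavior: pd.DataFrame,
    session: int,
    n_volumes: int,
    tr_s: float,
    positive: str = "SuccStop",
    negative: str = "UnsuccStop",
    window_s: float = 4.0,
    hrf: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """The two condition series of a contrast (positive, negative)."""
    return (
        build_psych_contrast(behavior, session, n_volumes, tr_s, positive, window_s, hrf),
        build_psych_contrast(behavior, session, n_volumes, tr_s, negative, window_s, hrf),
    )


def _interaction_corr(tc_i, tc_j, psych, Z) -> tuple[float, float]:
    """Correlation of the orthogonalized interaction terms and the
    effective sample size (Kish) of the psychological weighting."""
    ii = _residualize(tc_i * psych, Z)
    jj = _residualize(tc_j * psych, Z)
    if ii.std() <= 1e-12 or jj.std() <= 1e-12:
        raise ValueError("degenerate interaction residual (zero variance)")
    r = float(np.corrcoef(ii, jj)[0, 1])
    n_eff = float((psych**2).sum() ** 2 / (psych**4).sum())
    return r, n_eff


def cppi(
    tc_i: np.ndarray,
    tc_j: np.ndarray,
    psych_pos: np.ndarray,
    psych_neg: np.ndarray,
    design: DesignMatrix | np.ndarray | None = None,
    confounds: np.ndarray | None = None,
    return_parts: bool = False,
):
    """Context-dependent coupling contrast between two conditions.

    For each condition series, forms the interaction terms
    ``tc_i * psych`` and ``tc_j * psych``, orthogonalizes them against
    Z = {tc_i, tc_j, task design, confounds, intercept}, and correlates
    the residuals.  Returns ``tanh(arctanh(r_pos) - arctanh(r_neg))`` —
    bounded in (-1, 1), symmetric in (i, j), zero in expectation when
    coupling does not differ between conditions.

    ``return_parts`` additionally yields the per-condition correlations
    and effective sample sizes, as needed for parametric inference.
    """
    tc_i = np.asarray(tc_i, dtype=float)
    tc_j = np.asarray(tc_j, dtype=float)
    psych_pos = np.asarray(psych_pos, dtype=float)
    psych_neg = np.asarray(psych_neg, dtype=float)
    if not (len(tc_i) == len(tc_j) == len(psych_pos) == len(psych_neg)):
        raise ValueError("series lengths differ")
    Z = _interaction_nuisance(tc_i, tc_j, design, confounds, len(tc_i))
    # remove evoked/confound structure from the TCs before weighting
    ri = _residualize(tc_i, np.delete(Z, [1, 2], axis=1))
    rj = _residualize(tc_j, np.delete(Z, [1, 2], axis=1))
    r_pos, ne_pos = _interaction_corr(ri, rj, psych_pos, Z)
    r_neg, ne_neg = _interaction_corr(ri, rj, psych_neg, Z)
    zdiff = np.arctanh(np.clip(r_pos, -0.999999, 0.999999)) - np.arctanh(
        np.clip(r_neg, -0.999999, 0.999999)
    )
    value = float(np.tanh(zdiff))
    if return_parts:
        return value, {"r_pos": r_pos, "r_neg": r_neg, "n_eff_pos": ne_pos,
                       "n_eff_neg": ne_neg, "zdiff": float(zdiff)}
    return value


def _interaction_nuisance(tc_i, tc_j, design, confounds, n) -> np.ndarray:
    cols = [np.ones(n), tc_i, tc_j]
    if design is not None:
        psi = design.columns_matrix(design.task_columns) if isinstance(
            design, DesignMatrix
        ) else np.asarray(design, dtype=float)
        cols.append(psi)
    if confounds is not None:
        cols.append(np.asarray(confounds, dtype=float))
    return np.column_stack(cols)


def cppi_pvalue(parts_per_session: list[dict]) -> tuple[float, float]:
    """Combined two-sided p for a cPPI contrast across sessions.

    Each session contributes a Fisher-z difference with variance
    ``1/(n_eff_pos - 3) + 1/(n_eff_neg - 3)``; sessions are combined by
    inverse-variance weighting.  Returns (combined z difference, p).
    """
    num = den = 0.0
    for parts in parts_per_session:
        v = 1.0 / max(parts["n_eff_pos"] - 3, 1) + 1.0 / max(parts["n_eff_neg"] - 3, 1)
        num += parts["zdiff"] / v
        den += 1.0 / v
    z = num / den
    p = float(2.0 * stats.norm.sf(abs(z) * np.sqrt(den)))
    return z, p


@dataclass
class ConnectivityMatrix:
    """Symmetric per-subject component-pair values."""

    values: np.ndarray  # [k x k], zero diagonal
    kind: str  # 'spontaneous' | 'cppi'
    contrast: str = "SuccStop>UnsuccStop"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("connectivity matrix must be symmetric")
        np.fill_diagonal(v, 0.0)
        self.values = v

    def pairs(self) -> pd.Series:
        k = self.values.shape[0]
        iu = np.triu_indices(k, 1)
        names = [f"ic{i:02d}-ic{j:02d}" for i, j in zip(*iu)]
        return pd.Series(self.values[iu], index=names)


def connectivity_matrix(
    tcs: np.ndarray,
    designs: list[DesignMatrix],
    behavior: pd.DataFrame,
    session_lengths: list[int],
    tr_s: float,
    kind: str = "cppi",
    confounds_per_session: list[np.ndarray] | None = None,
    window_s: float = 4.0,
) -> ConnectivityMatrix:
    """All-pairs connectivity for one subject, averaged over sessions.

    ``tcs`` is the concatenated [time x k] component series.  For
    ``kind='cppi'`` the condition epoch series are built per session
    from actual outcomes; sessions missing either condition are skipped.
    """
    k = tcs.shape[1]
    bounds = np.concatenate([[0], np.cumsum(session_lengths)])
    per_session = []
    for s, design in enumerate(designs):
        seg = tcs[bounds[s] : bounds[s + 1]]
        conf = confounds_per_session[s] if confounds_per_session else None
        mat = np.zeros((k, k))
        if kind == "cppi":
            try:
                p_pos, p_neg = psych_contrast_pair(
                    behavior, design.session, seg.shape[0], tr_s, window_s=window_s
                )
            except ValueError:
                continue
        for i in range(k):
            for j in range(i + 1, k):
                if kind == "cppi":
                    v = cppi(seg[:, i], seg[:, j], p_pos, p_neg, design, conf)
                elif kind == "spontaneous":
                    _, v = spontaneous_connectivity(seg[:, i], seg[:, j], design, conf)
                else:
                    raise ValueError(f"unknown kind {kind!r}")
                mat[i, j] = mat[j, i] = v
        per_session.append(mat)
    if not per_session:
        raise ValueError("no session allowed connectivity estimation")
    return ConnectivityMatrix(np.mean(per_session, axis=0), kind=kind)


def connectivity_group_tests(
    pair_values: pd.DataFrame,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    group_alpha: float = 0.01,
    age_alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Group and age effects per connection on Fisher-z values.

    ``pair_values`` is [subjects x connections] of raw correlations (or
    regression coefficients for spontaneous connectivity, used as-is).
    Values in (-1, 1) are Fisher-z transformed before every test.
    Group effects: one-sample t tests, BH-FDR at ``group_alpha``; age
    effects: robust age regression, BH-FDR at ``age_alpha``.
    """
    if len(pair_values) < 3:
        raise ValueError("need at least 3 subjects")
    vals = pair_values.to_numpy(dtype=float)
    z = np.where(np.abs(vals) < 1, np.arctanh(np.clip(vals, -0.999999, 0.999999)), vals)
    zdf = pd.DataFrame(z, index=pair_values.index, columns=pair_values.columns)
    t, p = [], []
    for c in zdf.columns:
        res = stats.ttest_1samp(zdf[c].to_numpy(), 0.0)
        t.append(res.statistic)
        p.append(res.pvalue)
    group = pd.DataFrame({"t": t, "p": p, "mean_z": zdf.mean()}, index=zdf.columns)
    group["significant"] = fdr_bh(group["p"].to_numpy(), group_alpha)
    age_tab = age_effect_robust(zdf, age, covariates, alpha=age_alpha)
    return {"group": group, "age": age_tab}
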