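"""Cross-validated brain-behavior prediction and age moderation.

SSRT is predicted from brain features by multiple linear regression
with well-conditioned (Ledoit-Wolf) covariance shrinkage, embedded in a
three-stage permutation-based k-fold cross-validation:

1. fit the shrinkage MLR on the training folds;
2. apply the training weights to the held-out fold, yielding one
   "subject score" (predicted SSRT) per subject;
3. correlate assembled subject scores with observed SSRT.

Model significance comes from permutations of the behavioral values
re-run through all three stages; fold-partition variance is quantified
by repeating the CV over many random repartitions, whose mean r values
also support model comparison against a permuted-label null.  The
moderation analysis regresses SSRT on subject scores, age and their
interaction (variables mean-centered before forming the product).

The Ledoit-Wolf intensity is computed analytically per training fold,
so the whole procedure is deterministic given the fold assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .activity import fdr_bh

__all__ = [
    "ledoit_wolf_shrinkage",
    "shrinkage_mlr_fit",
    "cv_predict_scores",
    "permutation_pvalue",
    "repartition_distribution",
    "compare_models",
    "model_comparison",
    "structure_coefficients",
    "moderation_analysis",
    "independence_check",
    "PredictionResult",
    "ModerationResult",
]


def ledoit_wolf_shrinkage(Xc: np.ndarray) -> tuple[float, float]:
    """Analytic well-conditioned shrinkage intensity for centered data.

    Returns (gamma, nu): the optimal weight of the scaled-identity
    target ``nu * I`` (nu = mean eigenvalue of the sample covariance)
    minimizing expected Frobenius loss.
    """
    n, p = Xc.shape
    S = Xc.T @ Xc / n
    nu = float(np.trace(S)) / p
    d2 = float(((S - nu * np.eye(p)) ** 2).sum()) / p
    if d2 <= 0:
        return 0.0, nu
    sq = (Xc**2).sum(axis=1)
    # sum_t ||x_t x_t' - S||_F^2 = sum_t (x_t.x_t)^2 - n ||S||_F^2
    b_bar2 = (float((sq**2).sum()) - n * float((S**2).sum())) / (n**2 * p)
    b2 = min(max(b_bar2, 0.0), d2)
    return b2 / d2, nu


def shrinkage_mlr_fit(
    X: np.ndarray, y: np.ndarray, gamma: float | None = None
) -> tuple[np.ndarray, float, float]:
    """Shrinkage-regularized MLR weights.

    Solves ``((1-gamma) S + gamma nu I) w = cov(X, y)`` on centered
    data, where S is the sample covariance of X and nu its mean
    eigenvalue; gamma defaults to the analytic Ledoit-Wolf intensity.
    Returns (weights, intercept, gamma); finite for any p, including
    p > n.  gamma = 0 with well-conditioned X reduces to OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be [n x p] with matching y")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 training samples")
    if np.std(y) == 0:
        raise ValueError("y has zero variance")
    xm, ym = X.mean(axis=0), y.mean()
    Xc, yc = X - xm, y - ym
    g, nu = ledoit_wolf_shrinkage(Xc)
    if gamma is not None:
        g = float(gamma)
    n, p = Xc.shape
    S = Xc.T @ Xc / n
    target = (1.0 - g) * S + g * nu * np.eye(p)
    cxy = Xc.T @ yc / n
    if g == 0.0:
        w = np.linalg.lstsq(target, cxy, rcond=None)[0]
    else:
        w = np.linalg.solve(target, cxy)
    return w, float(ym - xm @ w), g


@dataclass
class PredictionResult:
    subject_scores: np.ndarray
    y_used: np.ndarray  # behavioral values the scores are correlated with
    observed_r: float
    weights_per_fold: list[np.ndarray] = field(default_factory=list)
    gamma_per_fold: list[float] = field(default_factory=list)
    permutation_p: float | None = None
    repartition_r: np.ndarray | None = None


def _fold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    idx = rng.permutation(n)
    return [f for f in np.array_split(idx, k)]


def _residualize_covariates(train_C, test_C, train_v, test_v):
    """Remove covariate fits (estimated on the training fold) from both folds."""
    X1 = np.column_stack([np.ones(len(train_C)), train_C])
    X2 = np.column_stack([np.ones(len(test_C)), test_C])
    beta, *_ = np.linalg.lstsq(X1, train_v, rcond=None)
    return train_v - X1 @ beta, test_v - X2 @ beta


def cv_predict_scores(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    keep_weights: bool = True,
) -> PredictionResult:
    """Three-stage k-fold cross-validated subject scores.

    Covariates of no interest are residualized out of y and X with
    parameters estimated on the training folds only.  Each subject's
    score is produced by a model whose training set excluded that
    subject; the observed r is the Pearson correlation between the
    assembled scores and the (covariate-adjusted) behavioral values.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k}-fold CV")
    rng = np.random.default_rng(seed)
    folds = _fold_indices(n, k, rng)
    scores = np.empty(n)
    y_used = y.astype(float).copy()
    weights, gammas = [], []
    for f in folds:
        if len(f) < 2:
            raise ValueError("fold smaller than 2 subjects")
        tr = np.setdiff1d(np.arange(n), f, assume_unique=False)
        Xtr, Xte = X[tr], X[f]
        ytr, yte = y[tr], y[f]
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            ytr, yte = _residualize_covariates(C[tr], C[f], ytr, yte)
            Xtr2 = np.empty_like(Xtr)
            Xte2 = np.empty_like(Xte)
            for j in range(X.shape[1]):
                Xtr2[:, j], Xte2[:, j] = _residualize_covariates(
                    C[tr], C[f], Xtr[:, j], Xte[:, j]
                )
            Xtr, Xte = Xtr2, Xte2
            y_used[f] = yte
        w, b, g = shrinkage_mlr_fit(Xtr, ytr)
        scores[f] = Xte @ w + b
        if keep_weights:
            weights.append(w)
            gammas.append(g)
    r = float(np.corrcoef(scores, y_used)[0, 1])
    return PredictionResult(scores, y_used, r, weights, gammas)


def permutation_pvalue(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 1000,
    k: int = 10,
    seed: int | np.random.Generator = 0,
    observed_r: float | None = None,
    redraw_folds: bool = True,
) -> tuple[float, np.ndarray]:
    """Permutation p for the observed CV correlation.

    Permutes the behavioral values (covariate rows travel with y) and
    reruns the full three-stage procedure per permutation, re-drawing
    the fold partition each time unless ``redraw_folds`` is False.
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    if observed_r is None:
        observed_r = cv_predict_scores(
            X, y, covariates, k=k, seed=rng.integers(2**31 - 1), keep_weights=False
        ).observed_r
    n = len(y)
    fold_seed = rng.integers(2**31 - 1)
    r_null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        cov_p = None if covariates is None else np.asarray(covariates)[perm]
        cv_seed = rng.integers(2**31 - 1) if redraw_folds else fold_seed
        r_null[b] = cv_predict_scores(
            X, np.asarray(y)[perm], cov_p, k=k, seed=cv_seed, keep_weights=False
        ).observed_r
    p = (1.0 + np.sum(r_null >= observed_r)) / (n_perm + 1.0)
    return float(p), r_null


def repartition_distribution(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_repart: int = 1000,
    k: int = 10,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Observed r over ``n_repart`` independent fold partitions."""
    rng = np.random.default_rng(seed)
    return np.array(
        [
            cv_predict_scores(
                X, y, covariates, k=k, seed=rng.integers(2**31 - 1), keep_weights=False
            ).observed_r
            for _ in range(n_repart)
        ]
    )


def compare_models(
    r_dist_a: np.ndarray,
    r_dist_b: np.ndarray,
    null_pairs: np.ndarray,
) -> tuple[float, float]:
    """Mean-difference model comparison against a permuted-label null.

    The statistic is ``mean(r_A) - mean(r_B)``; ``null_pairs`` holds
    [B x 2] mean r values of the two models computed on permuted
    behavioral labels.  Returns (difference, one-sided p that A exceeds
    B beyond the null).
    """
    r_dist_a, r_dist_b = np.asarray(r_dist_a), np.asarray(r_dist_b)
    null_pairs = np.asarray(null_pairs)
    if null_pairs.ndim != 2 or null_pairs.shape[1] != 2:
        raise ValueError("null_pairs must be [B x 2]")
    diff = float(r_dist_a.mean() - r_dist_b.mean())
    null_diff = null_pairs[:, 0] - null_pairs[:, 1]
    p = (1.0 + np.sum(null_diff >= diff)) / (len(null_diff) + 1.0)
    return diff, float(p)


def model_comparison(
    X_a: np.ndarray,
    X_b: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_repart: int = 100,
    n_perm: int = 99,
    n_repart_null: int = 20,
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Full mean-difference comparison of two feature sets on the same y.

    Computes observed repartition distributions for both models, then
    ``n_perm`` permutations of y, each evaluated by the mean r over
    ``n_repart_null`` repartitions per model.  Both models always see
    identical fold partitions (a paired design), which removes
    partition noise from the difference statistic.
    """
    rng = np.random.default_rng(seed)
    obs_seed = int(rng.integers(2**31 - 1))
    ra = repartition_distribution(X_a, y, covariates, n_repart, k, obs_seed)
    rb = repartition_distribution(X_b, y, covariates, n_repart, k, obs_seed)
    n = len(y)
    null_pairs = np.empty((n_perm, 2))
    for b in range(n_perm):
        perm = rng.permutation(n)
        cov_p = None if covariates is None else np.asarray(covariates)[perm]
        yp = np.asarray(y)[perm]
        null_seed = int(rng.integers(2**31 - 1))
        null_pairs[b, 0] = repartition_distribution(
            X_a, yp, cov_p, n_repart_null, k, null_seed
        ).mean()
        null_pairs[b, 1] = repartition_distribution(
            X_b, yp, cov_p, n_repart_null, k, null_seed
        ).mean()
    diff, p = compare_models(ra, rb, null_pairs)
    return {"r_a": ra, "r_b": rb, "difference": diff, "p": p, "null_pairs": null_pairs}


def structure_coefficients(
    X: np.ndarray | pd.DataFrame,
    subject_scores: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlation of each feature with the latent subject score.

    Zero-variance features get r = NaN and p = 1 (flagged).  Significance
    by t test with BH-FDR over features.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{j:03d}" for j in range(Xv.shape[1])]
    s = np.asarray(subject_scores, dtype=float)
    rows = []
    for j in range(Xv.shape[1]):
        col = Xv[:, j]
        if np.std(col) == 0:
            rows.append({"r": np.nan, "p": 1.0, "flag": "zero variance"})
            continue
        r, p = stats.pearsonr(col, s)
        rows.append({"r": float(r), "p": float(p), "flag": ""})
    out = pd.DataFrame(rows, index=names)
    out["significant"] = fdr_bh(out["p"].to_numpy(), alpha)
    return out


@dataclass
class ModerationResult:
    table: pd.DataFrame  # coef, t, p, r_partial per term
    model: object  # fitted statsmodels results

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def moderation_analysis(
    subject_scores: np.ndarray,
    age: np.ndarray,
    y: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    cov_type: str = "HC3",
) -> ModerationResult:
    """Test whether the score-behavior association changes with age.

    Fits ``y ~ scores + age + scores x age (+ covariates)`` with scores
    and age mean-centered before forming the interaction.  Inference
    uses heteroscedasticity-consistent (HC3) standard errors by default:
    a genuine moderation makes the residual variance age-dependent, and
    classical OLS errors are then anticonservative for the interaction
    term.  Reports per term the coefficient, t, p and partial
    correlation ``t / sqrt(t^2 + df)``.
    """
    s = np.asarray(subject_scores, dtype=float)
    a = np.asarray(age, dtype=float)
    y = np.asarray(y, dtype=float)
    sc, ac = s - s.mean(), a - a.mean()
    cols = {"subject_scores": sc, "age": ac, "scores_x_age": sc * ac}
    if covariates is not None:
        C = (
            covariates
            if isinstance(covariates, pd.DataFrame)
            else pd.DataFrame(
                np.asarray(covariates, dtype=float),
                columns=[f"cov{j}" for j in range(np.asarray(covariates).shape[1])],
            )
        )
        for c in C.columns:
            cols[str(c)] = C[c].to_numpy(dtype=float)
    Xdf = pd.DataFrame(cols)
    if len(y) <= Xdf.shape[1] + 2:
        raise ValueError("too few subjects for the moderation model")
    Xm = sm.add_constant(Xdf)
    if np.linalg.matrix_rank(Xm.to_numpy()) < Xm.shape[1]:
        raise np.linalg.LinAlgError("collinear moderation design")
    fit = sm.OLS(y, Xm).fit(cov_type=cov_type) if cov_type else sm.OLS(y, Xm).fit()
    df = int(fit.df_resid)
    tvals = pd.Series(np.asarray(fit.tvalues), index=Xm.columns)
    pvals = pd.Series(np.asarray(fit.pvalues), index=Xm.columns)
    params = pd.Series(np.asarray(fit.params), index=Xm.columns)
    table = pd.DataFrame(
        {
            "coef": params,
            "t": tvals,
            "p": pvals,
            "r_partial": tvals / np.sqrt(tvals**2 + df),
        }
    ).drop(index="const")
    return ModerationResult(table=table, model=fit)


def independence_check(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two sets of subject scores."""
    r, p = stats.pearsonr(np.asarray(scores_a, float), np.asarray(scores_b, float))
    return float(r), float(p)
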