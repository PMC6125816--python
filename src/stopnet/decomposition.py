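"""Group spatial ICA with stability clustering.

Subject data are temporally concatenated, PCA-reduced to a model order
selected by the minimum-description-length (MDL) criterion on the
covariance eigenvalues, and decomposed by fixed-point ICA repeated from
random initializations.  Components are clustered across runs by
absolute spatial correlation; cluster centrotypes form the group maps
and the cluster compactness yields a per-component stability index
(ICASSO-style).  Subject time courses are obtained by spatial
regression of each subject's data onto the group maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.signal import periodogram
from scipy.spatial.distance import squareform
from scipy.stats import f_oneway, skew
from sklearn.decomposition import FastICA

__all__ = [
    "ComponentSet",
    "regress_confounds",
    "select_model_order_mdl",
    "group_ica",
    "backreconstruct_subject_tcs",
    "classify_noise_components",
    "match_components",
    "split_half_similarity",
]


@dataclass
class ComponentSet:
    """Group decomposition: z-scored maps, subject TCs, stability, labels."""

    spatial_maps: np.ndarray  # [k x voxels], z-scored
    subject_tcs: dict[str, np.ndarray]  # subject -> [time x k], z-scored
    stability_index: np.ndarray  # [k], in [0, 1]
    order_k: int
    labels: np.ndarray | None = None  # 'signal' / 'noise' per component
    tr_s: float = 2.0
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    def signal_components(self) -> np.ndarray:
        if self.labels is None:
            return np.arange(self.n_components)
        return np.flatnonzero(self.labels == "signal")


def _zscore(a: np.ndarray, axis: int = 0) -> np.ndarray:
    return (a - a.mean(axis=axis, keepdims=True)) / (a.std(axis=axis, keepdims=True) + 1e-12)


def regress_confounds(
    data: np.ndarray,
    confounds: np.ndarray | pd.DataFrame,
    detrend: bool = True,
    derivatives: bool = True,
) -> np.ndarray:
    """Linear confound regression of voxel data.

    Residualizes ``data`` [time x voxels] against the confound columns
    (realignment parameters, WM/CSF signals, ...), optionally their
    first temporal derivatives, a linear trend and an intercept.
    """
    data = np.asarray(data, dtype=float)
    c = np.asarray(confounds, dtype=float)
    if c.shape[0] != data.shape[0]:
        raise ValueError("confounds and data differ in volume count")
    cols = [np.ones(data.shape[0]), c]
    if derivatives:
        d = np.vstack([np.zeros((1, c.shape[1])), np.diff(c, axis=0)])
        cols.append(d)
    if detrend:
        cols.append(np.linspace(-1, 1, data.shape[0]))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, data, rcond=None)
    return data - X @ beta


def select_model_order_mdl(
    data: np.ndarray,
    max_order: int | None = None,
    sample_size_factor: float = 1.0,
) -> int:
    """MDL model order for a signal-plus-isotropic-noise model.

    ``data`` is [time x voxels] (orientation is handled internally: the
    smaller dimension indexes the candidate signal subspace, the larger
    one the observations).  For each candidate order k, the description
    length combines the log ratio of geometric to arithmetic mean of the
    trailing eigenvalues with a parameter-count penalty
    ``0.5 * k * (2p - k) * log(N)``; the minimizing k is returned.
    ``sample_size_factor`` rescales the effective number of observations
    (e.g., for temporally smoothed data); 1 uses the raw count.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or min(data.shape) < 2:
        raise ValueError("data must be a 2-D array with both dims >= 2")
    if data.shape[0] > data.shape[1]:
        data = data.T  # rows now the (smaller) feature dimension
    p, n_obs = data.shape
    data = data - data.mean(axis=1, keepdims=True)
    cov = data @ data.T / n_obs
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 1e-12, None)
    rank = int(np.sum(eig > eig[0] * 1e-10))
    n_eff = max(2.0, sample_size_factor * n_obs)
    kmax = rank - 1 if max_order is None else min(max_order, rank - 1)

    mdl = np.empty(kmax + 1)
    for k in range(kmax + 1):
        tail = eig[k:p]
        m = p - k
        gm = np.mean(np.log(tail))
        am = np.log(np.mean(tail))
        mdl[k] = -n_eff * m * (gm - am) + 0.5 * k * (2 * p - k) * np.log(n_eff)
    return int(np.argmin(mdl))


def _ica_runs(
    reduced: np.ndarray, k: int, n_runs: int, rng: np.random.Generator, max_iter: int = 2000
) -> list[np.ndarray]:
    """Run FastICA ``n_runs`` times on whitened [k x voxels] data.

    Uses the kurtosis ('cube') contrast: spatial fMRI sources are sparse
    and strongly super-Gaussian, and the kurtosis fixed point is
    reliable for them, whereas the tanh contrast exhibits spurious
    stable rotations for sparse disjoint sources once the mixture is
    nearly exact.  Non-convergent runs are kept (FastICA returns the
    last iterate) but flagged via warnings by sklearn; genuinely failed
    runs are dropped.
    """
    out = []
    for _ in range(n_runs):
        w0 = rng.standard_normal((k, k))
        ica = FastICA(
            whiten=False,
            fun="cube",
            w_init=w0,
            max_iter=max_iter,
            tol=1e-6,
        )
        try:
            s = ica.fit_transform(reduced.T).T  # [k x voxels]
        except Exception:
            continue
        out.append(_zscore(s, axis=1))
    if not out:
        raise RuntimeError("all ICA runs failed")
    return out


def _fix_sign(maps: np.ndarray) -> np.ndarray:
    """Positive-skewness sign convention (ties: positive peak voxel)."""
    out = maps.copy()
    for i, m in enumerate(out):
        s = skew(m)
        if s < 0 or (s == 0 and m[np.argmax(np.abs(m))] < 0):
            out[i] = -m
    return out


def group_ica(
    subject_data: dict[str, np.ndarray] | list[np.ndarray],
    k: int,
    n_runs: int = 100,
    seed: int | np.random.Generator = 0,
    tr_s: float = 2.0,
) -> ComponentSet:
    """Temporal-concatenation group ICA with ICASSO-style stability.

    ``subject_data`` maps subject ids to [time x voxels] matrices (a list
    gets synthetic ids).  The concatenated data are PCA-whitened to
    ``k`` dimensions; FastICA runs ``n_runs`` times from random starts;
    components are clustered across runs (average linkage on 1 - |r|)
    and each cluster's centrotype (the member with the highest total
    within-cluster similarity) becomes a group map.  The stability index
    is mean within-cluster |r| minus mean between-cluster |r|.
    """
    if isinstance(subject_data, list):
        subject_data = {f"sub-{i + 1:03d}": d for i, d in enumerate(subject_data)}
    ids = list(subject_data)
    vox = {d.shape[1] for d in subject_data.values()}
    if len(vox) != 1:
        raise ValueError("all subjects must share the voxel space")
    rng = np.random.default_rng(seed)

    concat = np.concatenate([subject_data[i] for i in ids], axis=0)
    concat = concat - concat.mean(axis=0, keepdims=True)
    # PCA reduction across time; rows of `reduced` are whitened spatial modes
    u, sv, vt = np.linalg.svd(concat, full_matrices=False)
    if k > len(sv):
        raise ValueError(f"k={k} exceeds data rank {len(sv)}")
    reduced = vt[:k] * np.sqrt(concat.shape[0])  # unit-variance rows

    runs = _ica_runs(reduced, k, n_runs, rng)
    allc = np.concatenate(runs, axis=0)  # [n_runs*k x voxels]
    sim = np.abs(np.corrcoef(allc))
    np.fill_diagonal(sim, 1.0)
    dist = np.clip(1.0 - sim, 0.0, None)
    link = linkage(squareform(dist, checks=False), method="average")
    clusters = fcluster(link, t=k, criterion="maxclust")

    maps = np.empty((k, allc.shape[1]))
    stability = np.empty(k)
    for ci, c in enumerate(np.unique(clusters)):
        idx = np.flatnonzero(clusters == c)
        ext = np.flatnonzero(clusters != c)
        intra = sim[np.ix_(idx, idx)]
        within = (intra.sum(axis=1) - 1.0) / max(1, len(idx) - 1)
        centro = idx[np.argmax(within)] if len(idx) > 1 else idx[0]
        maps[ci] = allc[centro]
        mean_within = within.mean() if len(idx) > 1 else 1.0
        mean_between = sim[np.ix_(idx, ext)].mean() if len(ext) else 0.0
        stability[ci] = np.clip(mean_within - mean_between, 0.0, 1.0)

    order = np.argsort(-stability)
    maps, stability = maps[order], stability[order]
    maps = _zscore(_fix_sign(maps), axis=1)

    tcs = {i: backreconstruct_subject_tcs(maps, subject_data[i]) for i in ids}
    return ComponentSet(
        spatial_maps=maps,
        subject_tcs=tcs,
        stability_index=stability,
        order_k=k,
        tr_s=tr_s,
        meta={"n_runs": n_runs, "n_subjects": len(ids)},
    )


def backreconstruct_subject_tcs(group_maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Subject time courses by spatial regression onto the group maps.

    Solves data[t, :] ~ tc[t, :] @ maps for each volume (least squares
    over voxels) and z-scores each component's time course.
    """
    if data.shape[1] != group_maps.shape[1]:
        raise ValueError("subject data and group maps differ in voxel count")
    tc, *_ = np.linalg.lstsq(group_maps.T, data.T, rcond=None)
    return _zscore(tc.T, axis=0)


def classify_noise_components(
    components: ComponentSet,
    reference_maps: dict[str, tuple[np.ndarray, str]] | None = None,
    freq_cut_hz: float = 0.1,
    ratio_threshold: float = 0.9,
) -> np.ndarray:
    """Label components 'signal' or 'noise'.

    A component is noise when the ratio of spectral power above
    ``freq_cut_hz`` to power below it (averaged over subject TCs)
    exceeds ``ratio_threshold``, or when its spatial correlation is
    highest with a reference map designated non-neuronal.
    ``reference_maps`` maps names to (map, kind) with kind in
    {'signal', 'noise'}.
    """
    k = components.n_components
    labels = np.array(["signal"] * k, dtype=object)
    fs = 1.0 / components.tr_s
    tcs = np.concatenate(list(components.subject_tcs.values()), axis=0)
    for c in range(k):
        f, pxx = periodogram(tcs[:, c], fs=fs)
        hi = pxx[f > freq_cut_hz].sum()
        lo = pxx[(f > 0) & (f <= freq_cut_hz)].sum()
        if lo <= 0 or hi / lo > ratio_threshold:
            labels[c] = "noise"
    if reference_maps:
        names = list(reference_maps)
        refs = np.stack([np.ravel(reference_maps[n][0]) for n in names])
        kinds = [reference_maps[n][1] for n in names]
        r = np.abs(_corr_rows(components.spatial_maps, refs))
        for c in range(k):
            if kinds[int(np.argmax(r[c]))] == "noise":
                labels[c] = "noise"
    components.labels = labels
    return labels


def _corr_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix between two [*, voxels] arrays."""
    az = _zscore(a, axis=1)
    bz = _zscore(b, axis=1)
    return az @ bz.T / a.shape[1]


def match_components(maps_a: np.ndarray, maps_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of component maps by absolute correlation.

    Returns (column indices of ``maps_b`` matched to rows of ``maps_a``,
    the |r| of each matched pair).
    """
    r = np.abs(_corr_rows(maps_a, maps_b))
    ri, ci = linear_sum_assignment(-r)
    return ci, r[ri, ci]


def split_half_similarity(
    subject_data: dict[str, np.ndarray],
    split_labels: dict[str, int],
    k: int,
    n_runs: int = 20,
    seed: int = 0,
    tr_s: float = 2.0,
) -> dict:
    """Split-half validation of the group decomposition.

    Reruns the group ICA within each split, matches each split's
    components to the full-sample decomposition, and summarizes
    similarity as Fisher-z spatial correlations and between-subject
    temporal ICCs (correlation of a subject's concatenated component
    time course in split vs full decomposition), plus within-subject
    ICCs on vectorized connectivity profiles.  Differences between
    splits are tested by one-way ANOVA on the Fisher-z values.
    """
    full = group_ica(subject_data, k, n_runs=n_runs, seed=seed, tr_s=tr_s)
    groups = sorted(set(split_labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least two split groups")
    out: dict = {"full": full, "splits": {}}
    spatial_z: dict[int, np.ndarray] = {}
    icc_between_z: dict[int, np.ndarray] = {}
    icc_within_z: dict[int, np.ndarray] = {}
    for g in groups:
        ids = [i for i, lab in split_labels.items() if lab == g]
        if len(ids) < 2:
            raise ValueError("each split needs >= 2 subjects")
        sub = {i: subject_data[i] for i in ids}
        dec = group_ica(sub, k, n_runs=n_runs, seed=seed + 1 + g, tr_s=tr_s)
        matched, r_spatial = match_components(full.spatial_maps, dec.spatial_maps)
        spatial_z[g] = np.arctanh(np.clip(r_spatial, -0.999999, 0.999999))
        rb = []
        for i in ids:
            a = full.subject_tcs[i]
            b = dec.subject_tcs[i][:, matched]
            rb.extend(
                abs(np.corrcoef(a[:, c], b[:, c])[0, 1]) for c in range(k)
            )
        icc_between_z[g] = np.arctanh(np.clip(np.asarray(rb), -0.999999, 0.999999))
        rw = []
        for i in ids:
            fa = np.corrcoef(full.subject_tcs[i].T)[np.triu_indices(k, 1)]
            fb = np.corrcoef(dec.subject_tcs[i][:, matched].T)[np.triu_indices(k, 1)]
            rw.append(np.corrcoef(fa, fb)[0, 1])
        icc_within_z[g] = np.arctanh(np.clip(np.asarray(rw), -0.999999, 0.999999))
        out["splits"][g] = {
            "decomposition": dec,
            "matched": matched,
            "spatial_r": r_spatial,
            "icc_between": np.tanh(icc_between_z[g].mean()),
            "icc_within": np.tanh(icc_within_z[g].mean()),
        }
    out["spatial_r_mean"] = {g: float(np.tanh(spatial_z[g].mean())) for g in groups}
    out["anova_spatial"] = f_oneway(*[spatial_z[g] for g in groups])
    out["anova_icc_between"] = f_oneway(*[icc_between_z[g] for g in groups])
    out["anova_icc_within"] = f_oneway(*[icc_within_z[g] for g in groups])
    return out
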