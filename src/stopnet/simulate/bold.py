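"""Forward model for multi-subject BOLD-like data.

Each subject's data are generated as

    voxels = TC @ spatial_maps + motion artifacts + white noise

where the component time courses ``TC`` carry (i) condition-evoked
responses (event onsets convolved with the double-gamma HRF, scaled by
per-condition amplitudes), (ii) latent shared fluctuations inducing a
configured context-independent coupling between components, and (iii) an
epoch-dependent change of that coupling during successful vs unsuccessful
stop epochs (the ground truth that cPPI must recover).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..hrf import event_regressor
from .design import TaskDesign

#: behavioral categories that can carry evoked responses
EVOKED_CONDITIONS = ("correctGo", "correctNoGo", "SuccStop", "UnsuccStop")


@dataclass
class GroundTruthSpec:
    """Generative ground truth for one cohort (or one subject).

    ``spatial_maps`` rows are unit-norm component maps over the flattened
    voxel grid.  ``base_coupling`` is the context-independent correlation
    between component fluctuations; ``coupling_modulation`` is the
    coupling *difference* between successful- and unsuccessful-stop
    epochs (applied as +/- half around the base).  ``age_slopes`` maps
    parameter names to linear age coefficients used by the cohort
    generator.
    """

    spatial_maps: np.ndarray
    evoked_amplitudes: dict[str, np.ndarray]
    base_coupling: np.ndarray
    coupling_modulation: np.ndarray
    noise_sd: float = 1.0
    tc_noise_sd: float = 0.0
    motion_artifact_gain: float = 0.0
    epoch_window_s: float = 4.0
    grid_shape: tuple[int, int, int] = (12, 12, 10)
    age_slopes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.spatial_maps = np.asarray(self.spatial_maps, dtype=float)
        k = self.n_components
        for name in ("base_coupling", "coupling_modulation"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be [{k} x {k}]")
            if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
                raise ValueError(f"{name} must be symmetric with zero diagonal")
            setattr(self, name, m)
        norms = np.linalg.norm(self.spatial_maps, axis=1)
        if np.any(norms <= 0):
            raise ValueError("spatial maps must be nonzero")
        self.spatial_maps = self.spatial_maps / norms[:, None]

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.spatial_maps.shape[1]


def gaussian_blob_maps(
    n_components: int,
    grid_shape: tuple[int, int, int] = (12, 12, 10),
    sigma_vox: float = 1.4,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Unit-norm smooth Gaussian-blob spatial maps on a small 3-D lattice.

    Blob centers are spread over the grid interior; well-separated for
    small ``n_components`` relative to the grid volume.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = grid_shape
    xs, ys, zs = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    coords = np.stack([xs, ys, zs], axis=-1).reshape(-1, 3).astype(float)
    maps = np.zeros((n_components, coords.shape[0]))
    centers = []
    for c in range(n_components):
        # rejection-sample centers to keep blobs apart
        for _ in range(200):
            cand = rng.uniform([1, 1, 1], [nx - 2, ny - 2, nz - 2])
            if all(np.linalg.norm(cand - prev) > 3.0 * sigma_vox for prev in centers):
                break
        centers.append(cand)
        d2 = np.sum((coords - cand) ** 2, axis=1)
        maps[c] = np.exp(-d2 / (2.0 * sigma_vox**2))
    return maps / np.linalg.norm(maps, axis=1, keepdims=True)


def _chol_of_corr(corr: np.ndarray) -> np.ndarray:
    """Cholesky factor of a correlation matrix, eigenvalue-clipped to PSD."""
    w, v = np.linalg.eigh(corr)
    w = np.clip(w, 1e-8, None)
    m = (v * w) @ v.T
    d = np.sqrt(np.diag(m))
    m = m / np.outer(d, d)
    return np.linalg.cholesky(m)


def epoch_labels(
    behavior: pd.DataFrame, session: int, n_volumes: int, tr_s: float, window_s: float
) -> np.ndarray:
    """Per-volume state labels: 0 neutral, 1 SuccStop epoch, 2 UnsuccStop epoch.

    An epoch is a window of ``window_s`` seconds starting at each
    Stop-Signal trial onset; later trials overwrite in the (rare) case of
    overlap.
    """
    labels = np.zeros(n_volumes, dtype=int)
    t_vol = np.arange(n_volumes) * tr_s
    sess = behavior[behavior["session"] == session]
    for cat, lab in (("SuccStop", 1), ("UnsuccStop", 2), ("EarlySS", 2), ("IncorrectSS", 2)):
        for onset in sess.loc[sess["category"] == cat, "onset"]:
            labels[(t_vol >= onset) & (t_vol < onset + window_s)] = lab
    return labels


def component_timecourses(
    design: TaskDesign,
    behavior: pd.DataFrame,
    truth: GroundTruthSpec,
    session: int,
    rng: np.random.Generator,
    evoked_scale: float = 1.0,
) -> np.ndarray:
    """Latent component time courses [n_volumes x k] for one session."""
    k = truth.n_components
    T = design.n_volumes_per_session
    tr = design.tr_s
    sess = behavior[behavior["session"] == session]

    evoked = np.zeros((T, k))
    for cond, amps in truth.evoked_amplitudes.items():
        onsets = sess.loc[sess["category"] == cond, "onset"].to_numpy()
        if onsets.size == 0:
            continue
        reg = event_regressor(onsets, T, tr)
        evoked += np.outer(reg, np.asarray(amps, dtype=float))

    labels = epoch_labels(sess, session, T, tr, truth.epoch_window_s)
    eye = np.eye(k)
    chols = {
        0: _chol_of_corr(eye + truth.base_coupling),
        1: _chol_of_corr(eye + truth.base_coupling + truth.coupling_modulation / 2.0),
        2: _chol_of_corr(eye + truth.base_coupling - truth.coupling_modulation / 2.0),
    }
    eps = rng.standard_normal((T, k))
    intrinsic = np.empty_like(eps)
    for state, L in chols.items():
        m = labels == state
        if m.any():
            intrinsic[m] = eps[m] @ L.T

    tc = evoked_scale * evoked + intrinsic
    if truth.tc_noise_sd > 0:
        tc = tc + truth.tc_noise_sd * rng.standard_normal((T, k))
    return tc


def synthesize_bold(
    design: TaskDesign,
    behavior: pd.DataFrame,
    truth: GroundTruthSpec,
    motion: dict[int, pd.DataFrame] | None = None,
    seed: int | np.random.Generator = 0,
    evoked_scale: float = 1.0,
) -> dict[int, np.ndarray]:
    """Voxel-by-time data per session: {session: [n_volumes x n_voxels]}."""
    rng = np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for s in range(1, design.n_sessions + 1):
        tc = component_timecourses(design, behavior, truth, s, rng, evoked_scale)
        data = tc @ truth.spatial_maps
        if motion is not None and truth.motion_artifact_gain > 0:
            mp = motion[s].to_numpy()
            if mp.shape[0] != data.shape[0]:
                raise ValueError("motion table length does not match n_volumes")
            mz = (mp - mp.mean(0)) / (mp.std(0) + 1e-12)
            loadings = rng.standard_normal((6, truth.n_voxels)) / np.sqrt(truth.n_voxels)
            data = data + truth.motion_artifact_gain * (mz @ loadings)
        if truth.noise_sd > 0:
            data = data + truth.noise_sd * rng.standard_normal(data.shape)
        out[s] = data
    return out
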