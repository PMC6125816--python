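"""Hemodynamic response modelling utilities.

The canonical double-gamma HRF (response peak ~6 s, undershoot ~16 s,
peak/undershoot amplitude ratio 6, 32 s support) is used throughout for
event convolution, together with discrete-cosine drift regressors that
absorb slow signal changes with periods above a cutoff (128 s by default).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as _gamma

__all__ = [
    "double_gamma_hrf",
    "event_regressor",
    "cosine_drifts",
]

#: temporal oversampling grid (seconds) used when convolving event onsets
HRF_DT = 0.1


def double_gamma_hrf(
    dt: float = HRF_DT,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Sampled double-gamma HRF, normalized to unit peak.

    Parameters follow the conventional parameterization: two gamma
    densities, the second (undershoot) scaled down by ``ratio`` and
    subtracted from the first.
    """
    t = np.arange(0, length_s, dt)
    peak = _gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = _gamma.pdf(t, undershoot_delay / undershoot_disp, scale=undershoot_disp)
    h = peak - under / ratio
    return h / h.max()


def event_regressor(
    onsets_s: np.ndarray,
    n_volumes: int,
    tr_s: float,
    amplitudes: np.ndarray | float = 1.0,
    dt: float = HRF_DT,
    hrf: np.ndarray | None = None,
) -> np.ndarray:
    """Convolve delta events at ``onsets_s`` with the HRF, sampled at TR.

    Events are modelled with zero duration (impulses) on a fine grid
    (``dt`` seconds), convolved, then sampled at volume acquisition times
    ``0, TR, 2*TR, ...``.  Onsets falling beyond the scan are ignored.
    """
    onsets_s = np.atleast_1d(np.asarray(onsets_s, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets_s.shape)
    if hrf is None:
        hrf = double_gamma_hrf(dt=dt)
    total_s = n_volumes * tr_s
    n_fine = int(np.ceil(total_s / dt)) + 1
    impulses = np.zeros(n_fine)
    idx = np.round(onsets_s / dt).astype(int)
    keep = (idx >= 0) & (idx < n_fine)
    np.add.at(impulses, idx[keep], amplitudes[keep])
    fine = np.convolve(impulses, hrf)[:n_fine]
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    return fine[vol_idx]


def cosine_drifts(n_volumes: int, tr_s: float, high_pass_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift columns spanning periods >= ``high_pass_s``.

    Returns a [n_volumes x k] matrix (without the constant term); k is the
    number of DCT basis functions with period at least the cutoff.
    """
    total_s = n_volumes * tr_s
    order = int(np.floor(2.0 * total_s / high_pass_s))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (t + 0.5) * k / n_volumes)
        for k in range(1, order + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)
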