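"""Reading and writing the pipeline's on-disk formats.

Events go to BIDS-style TSV (onset, duration, trial_type, response,
response_time, ssd, plus the outcome category), confounds to TSV with
the conventional realignment-parameter column names, and voxel data to
NIfTI volumes with a JSON sidecar carrying TR, session and grid info.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate.bold import GroundTruthSpec
from .simulate.motion import MOTION_COLUMNS

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "write_confounds_tsv",
    "read_confounds_tsv",
    "write_bold_nifti",
    "read_bold_nifti",
]


def write_events_tsv(behavior: pd.DataFrame, path: str | Path, session: int | None = None):
    """Write (one session of) a behavioral trial table as a BIDS-style TSV."""
    df = behavior if session is None else behavior[behavior["session"] == session]
    out = pd.DataFrame(
        {
            "onset": df["onset"].round(3),
            "duration": 0.0,
            "trial_type": df["trial_type"],
            "response": df["response"].astype(int),
            "response_time": (df["rt_ms"] / 1000.0).round(4),
            "ssd": (df["ssd_ms"] / 1000.0).round(4),
            "category": df["category"],
            "session": df["session"],
        }
    )
    out.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    """Read an events TSV back into the internal trial-table layout."""
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    out = pd.DataFrame(
        {
            "trial_type": df["trial_type"],
            "onset": df["onset"].astype(float),
            "session": df.get("session", pd.Series([1] * len(df))).astype(int),
            "response": df["response"].astype(bool) if "response" in df else np.nan,
            "rt_ms": df["response_time"].astype(float) * 1000.0,
            "ssd_ms": df["ssd"].astype(float) * 1000.0,
        }
    )
    if "category" in df:
        out["category"] = df["category"]
    return out


def write_confounds_tsv(motion: pd.DataFrame, path: str | Path):
    motion.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_confounds_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"confounds file missing columns {missing}")
    return df


def write_bold_nifti(
    data: np.ndarray,
    grid_shape: tuple[int, int, int],
    path: str | Path,
    tr_s: float,
    session: int = 1,
    voxel_size_mm: float = 3.0,
):
    """Save a [time x voxels] matrix as a 4-D NIfTI plus JSON sidecar."""
    T = data.shape[0]
    vol = data.T.reshape(*grid_shape, T).astype(np.float32)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((voxel_size_mm,) * 3 + (tr_s,))
    nib.save(img, str(path))
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    sidecar.write_text(
        json.dumps({"RepetitionTime": tr_s, "session": session, "grid_shape": list(grid_shape)})
    )


def read_bold_nifti(path: str | Path) -> tuple[np.ndarray, float, dict]:
    """Load a 4-D NIfTI as [time x voxels] with TR and sidecar metadata."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    T = vol.shape[-1]
    data = vol.reshape(-1, T).T
    sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    tr = float(meta.get("RepetitionTime", img.header.get_zooms()[-1]))
    return data, tr, meta
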