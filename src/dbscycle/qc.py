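"""Motion and signal-change quality control: FD, DVARS, frame censoring.

Framewise displacement follows the Power formulation: the absolute sum
of frame-to-frame changes in the six rigid-body parameters, with the
three rotation deltas converted to arc length on a 50 mm sphere.
DVARS is the root-mean-square of the frame-to-frame intensity
difference over in-mask voxels, standardized by dividing by the
within-run median so that a threshold of 1.5 is meaningful on a
run-relative, dimensionless scale (median ~ 1 under stationary noise).

Frames with FD > 0.5 mm or standardized DVARS > 1.5 (strict
inequalities) are flagged for censoring; the first frame of a run is
assigned FD = DVARS = 0 and is never censored by these metrics alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MOTION_COLUMNS",
    "QCConfig",
    "framewise_displacement",
    "std_dvars",
    "censor_frames",
    "compute_confounds",
    "read_confounds",
    "write_confounds",
]

#: BIDS-style motion parameter columns: translations in mm, rotations in radians.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass(frozen=True)
class QCConfig:
    """Censoring thresholds and the rotation-to-mm conversion radius."""

    fd_thresh_mm: float = 0.5
    dvars_thresh: float = 1.5
    head_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.fd_thresh_mm <= 0 or self.dvars_thresh <= 0 or self.head_radius_mm <= 0:
            raise ValueError("QC thresholds and head radius must be positive")


def _motion_array(motion) -> np.ndarray:
    """Coerce motion parameters to an (n_frames, 6) array."""
    if isinstance(motion, pd.DataFrame):
        missing = [c for c in MOTION_COLUMNS if c not in motion.columns]
        if missing:
            raise ValueError(f"motion table missing columns: {missing}")
        arr = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion parameters must have six columns "
                         "(trans_x/y/z in mm, rot_x/y/z in rad)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("motion parameters must be finite")
    return arr


def framewise_displacement(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power framewise displacement in mm per frame.

    FD_t = sum_i |delta trans_i| + r * sum_j |delta rot_j| with
    rotations converted to arc length on a sphere of radius
    ``head_radius_mm``.  FD_0 = 0.
    """
    arr = _motion_array(motion)
    if head_radius_mm <= 0:
        raise ValueError("head_radius_mm must be positive")
    delta = np.abs(np.diff(arr, axis=0))
    fd = delta[:, :3].sum(axis=1) + head_radius_mm * delta[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def std_dvars(bold: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Median-standardized DVARS per frame (frame 0 = 0).

    Raw DVARS_t is the RMS over in-mask voxels of the intensity
    difference between frames t and t-1; the trace is divided by its
    within-run median (over frames 1..T-1).  A constant run, whose raw
    DVARS is identically zero, is returned as all zeros.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 4:
        raise ValueError("bold must be a 4D (x, y, z, t) array")
    if bold.shape[-1] < 2:
        raise ValueError("DVARS needs at least 2 frames")
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.shape != bold.shape[:3]:
        raise ValueError("mask shape must match the volume grid")
    if not mask.any():
        raise ValueError("brain mask is empty")
    ts = bold[mask]  # (voxels, frames)
    diff = np.diff(ts, axis=1)
    raw = np.sqrt(np.mean(diff**2, axis=0))
    med = np.median(raw)
    out = np.zeros(bold.shape[-1])
    if med > 0:
        out[1:] = raw / med
    return out


def censor_frames(fd: np.ndarray, dvars: np.ndarray, qc: QCConfig = QCConfig()) -> np.ndarray:
    """Boolean censor mask: True where FD or standardized DVARS strictly
    exceeds its threshold."""
    fd = np.asarray(fd, dtype=float)
    dvars = np.asarray(dvars, dtype=float)
    if fd.shape != dvars.shape:
        raise ValueError("fd and dvars must have the same length")
    if np.any(fd < 0) or np.any(dvars < 0):
        raise ValueError("fd and dvars must be non-negative")
    return (fd > qc.fd_thresh_mm) | (dvars > qc.dvars_thresh)


def compute_confounds(
    bold: np.ndarray,
    brain_mask: np.ndarray,
    motion: pd.DataFrame,
    qc: QCConfig = QCConfig(),
) -> pd.DataFrame:
    """Full confounds table for one run.

    Columns: the six motion parameters, ``framewise_displacement``,
    ``std_dvars`` and the boolean ``censor`` flag.
    """
    arr = _motion_array(motion)
    if arr.shape[0] != bold.shape[-1]:
        raise ValueError("motion table and BOLD run disagree on frame count")
    fd = framewise_displacement(arr, qc.head_radius_mm)
    dv = std_dvars(bold, brain_mask)
    table = pd.DataFrame(arr, columns=list(MOTION_COLUMNS))
    table["framewise_displacement"] = fd
    table["std_dvars"] = dv
    table["censor"] = censor_frames(fd, dv, qc)
    return table


def write_confounds(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_confounds(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in table.columns]
    if missing:
        warnings.warn(f"confounds file {path} missing motion columns: {missing}")
    if "censor" in table.columns:
        table["censor"] = table["censor"].astype(bool)
    return table
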