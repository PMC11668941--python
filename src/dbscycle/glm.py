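"""Per-run GLM: design matrix, mean-100 scaling, OLS fit, On-Off contrast.

Each run is modeled with ordinary least squares: an On and an Off
boxcar (plateaus only, ramps unmodeled) convolved with the canonical
double-gamma HRF, plus a constant and three polynomial drift terms.
Censored frames are removed by row deletion before fitting.  The
quantity of interest is the per-voxel [On] - [Off] contrast; because
every voxel time series is scaled to a temporal mean of 100 first, the
contrast is in percent-signal units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .design import CyclingDesign, HRFParams, condition_regressors, drift_basis

__all__ = [
    "BoldRun",
    "RunMeta",
    "ContrastMap",
    "DesignMatrix",
    "CollinearDesignError",
    "scale_to_mean_100",
    "build_design_matrix",
    "fit_run_glm",
    "on_off_contrast",
    "GLMResult",
]


@dataclass
class BoldRun:
    """One 4D BOLD run: (x, y, z, t) data, affine, repetition time."""

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def save(self, path: str | Path) -> None:
        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(str(path))

    @classmethod
    def load(cls, path: str | Path, tr_s: float) -> "BoldRun":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, tr_s)


@dataclass(frozen=True)
class RunMeta:
    """Identifying metadata carried with each run's contrast map."""

    subject: str
    run: str
    config_id: str = ""
    hemisphere: str = ""
    therapeutic: bool = False
    responder: bool = False

    def to_dict(self) -> Dict:
        return {
            "subject": self.subject,
            "run": self.run,
            "config_id": self.config_id,
            "hemisphere": self.hemisphere,
            "therapeutic": bool(self.therapeutic),
            "responder": bool(self.responder),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "RunMeta":
        return cls(**{k: d[k] for k in
                      ("subject", "run", "config_id", "hemisphere", "therapeutic", "responder")
                      if k in d})


@dataclass
class ContrastMap:
    """Per-run [On] - [Off] effect volume in percent-signal units."""

    data: np.ndarray
    affine: np.ndarray
    meta: RunMeta

    def save(self, nii_path: str | Path, meta_path: str | Path | None = None) -> None:
        nib.Nifti1Image(self.data.astype(np.float32), self.affine).to_filename(str(nii_path))
        if meta_path is not None:
            Path(meta_path).write_text(json.dumps(self.meta.to_dict(), indent=2))

    @classmethod
    def load(cls, nii_path: str | Path, meta_path: str | Path) -> "ContrastMap":
        img = nib.load(str(nii_path))
        meta = RunMeta.from_dict(json.loads(Path(meta_path).read_text()))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, meta)


class CollinearDesignError(ValueError):
    """Raised when the design matrix is rank deficient or near collinear."""


@dataclass
class DesignMatrix:
    """Frame-by-regressor design with a censoring mask.

    ``censor`` marks frames excluded from the fit (row deletion).
    """

    matrix: np.ndarray
    names: List[str]
    censor: np.ndarray
    design: Optional[CyclingDesign] = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.censor = np.asarray(self.censor, dtype=bool)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("one name per regressor required")
        if len(self.censor) != self.matrix.shape[0]:
            raise ValueError("censor mask length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    @property
    def kept(self) -> np.ndarray:
        return ~self.censor

    def kept_matrix(self) -> np.ndarray:
        return self.matrix[self.kept]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.names)
        df["censor"] = self.censor
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_collinearity(
    x: np.ndarray, names: List[str], steady: np.ndarray, r2_tol: float = 1e-8
) -> None:
    """Raise :class:`CollinearDesignError` naming offending columns.

    Exact rank deficiency is checked on all kept rows.  Near
    collinearity is assessed on steady-state rows only (frames past the
    HRF duration): identification of the condition regressors must not
    rest on HRF-onset transients, so e.g. a zero-ramp design in which
    On + Off equals the constant at steady state is rejected even
    though onset frames make it technically full rank.
    """
    if x.shape[0] < x.shape[1]:
        raise CollinearDesignError(
            f"only {x.shape[0]} uncensored frames for {x.shape[1]} regressors"
        )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise CollinearDesignError(_collinear_sets(x, names, r2_tol))
    xs = x[steady]
    if xs.shape[0] > x.shape[1]:
        msg = _collinear_sets(xs, names, r2_tol)
        if msg:
            raise CollinearDesignError("near-collinear at steady state: " + msg)


def _collinear_sets(x: np.ndarray, names: List[str], r2_tol: float) -> str:
    flagged = []
    for j in range(x.shape[1]):
        others = np.delete(x, j, axis=1)
        target = x[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        denom = np.sum((target - target.mean()) ** 2)
        if denom == 0:
            continue
        r2 = 1.0 - np.sum(resid**2) / denom
        if r2 > 1.0 - r2_tol:
            flagged.append(names[j])
    return f"collinear regressors: {flagged}" if flagged else ""


def build_design_matrix(
    design: CyclingDesign,
    hrf: HRFParams | None = None,
    drift_order: int = 3,
    censor_mask: np.ndarray | None = None,
) -> DesignMatrix:
    """Design matrix with On/Off condition regressors and drift terms.

    Columns: ``on``, ``off`` (HRF-convolved plateau boxcars), then
    ``poly0..polyN`` discrete orthogonal drift polynomials over the full
    run.  Raises :class:`CollinearDesignError` when the design is rank
    deficient or near collinear after censoring.
    """
    hrf = hrf or HRFParams()
    conds = condition_regressors(design, hrf)
    drift = drift_basis(design.n_frames, drift_order)
    x = np.column_stack([conds, drift])
    names = ["on", "off"] + [f"poly{i}" for i in range(drift_order + 1)]
    if censor_mask is None:
        censor_mask = np.zeros(design.n_frames, dtype=bool)
    censor_mask = np.asarray(censor_mask, dtype=bool)
    if len(censor_mask) != design.n_frames:
        raise ValueError("censor mask length must equal n_frames")
    dm = DesignMatrix(x, names, censor_mask, design)
    t = np.arange(design.n_frames) * design.tr_s
    steady = (t >= hrf.duration_s)[dm.kept]
    _check_collinearity(dm.kept_matrix(), names, steady)
    return dm


def scale_to_mean_100(bold: np.ndarray, mask: np.ndarray | None = None):
    """Scale each voxel time series to a temporal mean of 100.

    Voxels with non-positive mean (inside the mask) are zeroed out and
    removed from the returned validity mask, with a warning.  Returns
    ``(scaled, valid_mask)``.
    """
    data = np.asarray(bold, dtype=float)
    if data.ndim != 4:
        raise ValueError("bold must be 4D")
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    means = data.mean(axis=-1)
    bad = mask & (means <= 0)
    if bad.any():
        warnings.warn(f"{bad.sum()} voxels with non-positive mean masked out of scaling")
    valid = mask & (means > 0)
    scaled = np.zeros_like(data)
    scaled[valid] = data[valid] * (100.0 / means[valid])[:, None]
    return scaled, valid


@dataclass
class GLMResult:
    """Per-voxel OLS estimates for one run."""

    betas: np.ndarray  # (x, y, z, n_regressors)
    names: List[str]
    resid_var: np.ndarray  # (x, y, z)
    dof: int
    affine: np.ndarray

    def beta(self, name: str) -> np.ndarray:
        return self.betas[..., self.names.index(name)]


def fit_run_glm(bold, dm: DesignMatrix, affine: np.ndarray | None = None) -> GLMResult:
    """Ordinary least squares per voxel with censored rows deleted."""
    if isinstance(bold, BoldRun):
        data = bold.data
        affine = bold.affine if affine is None else affine
    else:
        data = np.asarray(bold, dtype=float)
        if affine is None:
            affine = np.eye(4)
    if data.ndim != 4:
        raise ValueError("bold must be 4D")
    if data.shape[-1] != dm.n_frames:
        raise ValueError("BOLD frame count does not match the design matrix")
    x = dm.kept_matrix()
    n, k = x.shape
    if n <= k:
        raise CollinearDesignError(f"only {n} uncensored frames for {k} regressors")
    y = data[..., dm.kept].reshape(-1, n).T  # (n_kept, n_voxels)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    dof = n - k
    resid_var = (resid**2).sum(axis=0) / dof
    shape3 = data.shape[:3]
    return GLMResult(
        betas=beta.T.reshape(shape3 + (k,)),
        names=list(dm.names),
        resid_var=resid_var.reshape(shape3),
        dof=dof,
        affine=np.asarray(affine, dtype=float),
    )


def on_off_contrast(result: GLMResult, meta: RunMeta) -> ContrastMap:
    """[On] - [Off] contrast volume with run metadata attached."""
    if "on" not in result.names or "off" not in result.names:
        raise ValueError("GLM result lacks 'on'/'off' regressors")
    data = result.beta("on") - result.beta("off")
    return ContrastMap(data=data, affine=result.affine, meta=meta)
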