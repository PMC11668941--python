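"""Group-level inference: mixed-effects comparison and cluster correction.

Per-run [On] - [Off] contrasts are compared across conditions with a
linear mixed-effects model: therapeutic configuration and responder
status enter as fixed effects and subjects as random intercepts (REML).
When the random-intercept variance estimate degenerates to the
boundary, the fit falls back to OLS with a logged warning — with five
subjects and 23 runs, boundary estimates are common and the fallback is
the correct limiting model.

Cluster-extent correction follows the Monte-Carlo procedure: simulate
smooth Gaussian null fields, threshold voxelwise (two-sided), record
the maximum cluster size per iteration, and take the (1 - alpha)
quantile as the minimum significant cluster size.  The resulting
threshold is specific to the grid and smoothness supplied; it is the
procedure, not any particular published voxel count, that is portable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

import statsmodels.api as sm

from .atlas import ParcelAtlas
from .glm import ContrastMap
from .netstats import parcel_means

__all__ = [
    "GroupDesign",
    "ClusterConfig",
    "Cluster",
    "fit_parcelwise_lme",
    "fit_voxelwise_lme",
    "cluster_components",
    "cluster_table",
    "cluster_size_threshold",
]

logger = logging.getLogger(__name__)

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class GroupDesign:
    """Run-level design for the group comparison.

    One row per run: subject id, therapeutic flag, responder flag.
    ``formula`` selects the fixed-effects structure: ``"full"`` models
    therapeutic + responder (the default; note the two are partially
    confounded because therapeutic runs occur only in responders),
    ``"reduced"`` models therapeutic only.
    """

    subjects: Sequence[str]
    therapeutic: Sequence[bool]
    responder: Sequence[bool]
    formula: str = "full"

    def __post_init__(self) -> None:
        n = len(self.subjects)
        if len(self.therapeutic) != n or len(self.responder) != n:
            raise ValueError("subjects, therapeutic and responder must have equal length")
        if self.formula not in ("full", "reduced"):
            raise ValueError("formula must be 'full' or 'reduced'")
        if len(set(self.subjects)) < 2:
            raise ValueError("group inference needs at least 2 subjects")
        ther = np.asarray(self.therapeutic, dtype=bool)
        if ther.all() or not ther.any():
            raise ValueError("both therapeutic and non-therapeutic runs are required")

    @property
    def n_runs(self) -> int:
        return len(self.subjects)

    def exog(self) -> np.ndarray:
        ther = np.asarray(self.therapeutic, dtype=float)
        resp = np.asarray(self.responder, dtype=float)
        if self.formula == "full":
            return np.column_stack([np.ones(self.n_runs), ther, resp])
        return np.column_stack([np.ones(self.n_runs), ther])

    def exog_names(self) -> List[str]:
        return (["intercept", "therapeutic", "responder"]
                if self.formula == "full" else ["intercept", "therapeutic"])

    @classmethod
    def from_metas(cls, metas, formula: str = "full") -> "GroupDesign":
        return cls(
            subjects=[m.subject for m in metas],
            therapeutic=[m.therapeutic for m in metas],
            responder=[m.responder for m in metas],
            formula=formula,
        )


def _fit_single(y: np.ndarray, design: GroupDesign) -> Dict:
    """Mixed model with OLS fallback for one parcel/voxel response."""
    x = design.exog()
    groups = np.asarray(design.subjects)
    idx = design.exog_names().index("therapeutic")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            model = sm.MixedLM(y, x, groups=groups)
            fit = model.fit(reml=True)
            re_var = float(np.squeeze(fit.cov_re))
            resid_var = float(fit.scale)
            degenerate = (not fit.converged) or re_var <= 1e-8 * max(resid_var, 1e-12)
        except (np.linalg.LinAlgError, ValueError):
            degenerate = True
            fit = None
    if not degenerate:
        # small-sample reference: t with residual df rather than the
        # normal approximation (23 runs is far from asymptotic)
        tval = float(fit.fe_params[idx] / fit.bse_fe[idx])
        df = len(y) - x.shape[1]
        return {
            "estimate": float(fit.fe_params[idx]),
            "se": float(fit.bse_fe[idx]),
            "stat": tval,
            "p": float(2.0 * stats.t.sf(abs(tval), df)),
            "method": "lme",
        }
    ols = sm.OLS(y, x).fit()
    return {
        "estimate": float(ols.params[idx]),
        "se": float(ols.bse[idx]),
        "stat": float(ols.tvalues[idx]),
        "p": float(ols.pvalues[idx]),
        "method": "ols",
    }


def fit_parcelwise_lme(
    contrasts: Sequence[ContrastMap],
    design: GroupDesign,
    atlas: ParcelAtlas,
) -> pd.DataFrame:
    """Parcel-wise mixed-effects estimate of the therapeutic effect.

    Each run's contrast map is reduced to parcel means; per parcel a
    REML mixed model with subject random intercepts estimates the
    therapeutic-configuration effect.  Returns a table with one row per
    parcel: estimate, SE, statistic, p, and the method actually used
    ('lme' or the degenerate-variance 'ols' fallback).
    """
    if len(contrasts) != design.n_runs:
        raise ValueError("one contrast map per design row required")
    if len(contrasts) < 6:
        raise ValueError("at least 6 runs are required for group inference")
    pm = np.stack([parcel_means(c, atlas) for c in contrasts])  # (runs, parcels)
    rows = []
    n_fallback = 0
    for j in range(atlas.n_parcels):
        y = pm[:, j]
        if not np.all(np.isfinite(y)):
            rows.append({"estimate": np.nan, "se": np.nan, "stat": np.nan,
                         "p": np.nan, "method": "failed"})
            logger.warning("parcel %d: non-finite parcel means, model skipped", j + 1)
            continue
        res = _fit_single(y, design)
        n_fallback += res["method"] == "ols"
        rows.append(res)
    if n_fallback:
        logger.warning("OLS fallback used for %d/%d parcels (degenerate random-effect variance)",
                       n_fallback, atlas.n_parcels)
    out = pd.DataFrame(rows)
    out.insert(0, "parcel_id", atlas.parcel_ids)
    out["network_id"] = atlas.assignment
    out["network_name"] = [atlas.network_names[a - 1] for a in atlas.assignment]
    return out


def fit_voxelwise_lme(
    contrasts: Sequence[ContrastMap],
    design: GroupDesign,
    mask: np.ndarray,
) -> Dict[str, np.ndarray]:
    """Voxel-wise therapeutic-effect map (for the cluster-correction path).

    Same model as :func:`fit_parcelwise_lme`, fitted per in-mask voxel.
    Returns 3D arrays ``estimate``, ``se``, ``stat``, ``p`` (NaN outside
    the mask or where the model failed) plus a boolean ``lme`` map of
    voxels where the mixed fit was retained.
    """
    if len(contrasts) != design.n_runs:
        raise ValueError("one contrast map per design row required")
    mask = np.asarray(mask, dtype=bool)
    stack = np.stack([c.data for c in contrasts])  # (runs, x, y, z)
    shape = mask.shape
    out = {k: np.full(shape, np.nan) for k in ("estimate", "se", "stat", "p")}
    lme_used = np.zeros(shape, dtype=bool)
    for ijk in np.argwhere(mask):
        y = stack[:, ijk[0], ijk[1], ijk[2]]
        if not np.all(np.isfinite(y)):
            continue
        res = _fit_single(y, design)
        for k in ("estimate", "se", "stat", "p"):
            out[k][tuple(ijk)] = res[k]
        lme_used[tuple(ijk)] = res["method"] == "lme"
    out["lme"] = lme_used
    return out


# ----------------------------------------------------------------------
# clusters
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    size: int
    voxels: np.ndarray  # (n, 3) indices
    peak: tuple
    peak_value: float
    centroid: tuple


def _structure(nn: int) -> np.ndarray:
    if nn not in (1, 2, 3):
        raise ValueError("nn must be 1 (faces), 2 (+edges) or 3 (+corners)")
    return ndimage.generate_binary_structure(3, nn)


def cluster_components(
    stat_map: np.ndarray,
    voxel_threshold: float,
    nn: int = 1,
    two_sided: bool = True,
) -> List[Cluster]:
    """Connected suprathreshold components under NN-face/edge/corner adjacency.

    With ``two_sided`` the map is thresholded on |value|; positive and
    negative excursions are labeled separately so a cluster never mixes
    signs.  Clusters are returned largest first.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    structure = _structure(nn)
    masks = []
    if two_sided:
        masks = [stat_map > voxel_threshold, stat_map < -voxel_threshold]
    else:
        masks = [stat_map > voxel_threshold]
    clusters: List[Cluster] = []
    for m in masks:
        lab, n = ndimage.label(m, structure=structure)
        for i in range(1, n + 1):
            vox = np.argwhere(lab == i)
            vals = stat_map[lab == i]
            peak_local = np.argmax(np.abs(vals))
            clusters.append(
                Cluster(
                    size=len(vox),
                    voxels=vox,
                    peak=tuple(vox[peak_local]),
                    peak_value=float(vals[peak_local]),
                    centroid=tuple(vox.mean(axis=0)),
                )
            )
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def cluster_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "size": [c.size for c in clusters],
            "peak_i": [c.peak[0] for c in clusters],
            "peak_j": [c.peak[1] for c in clusters],
            "peak_k": [c.peak[2] for c in clusters],
            "peak_value": [c.peak_value for c in clusters],
            "centroid_i": [c.centroid[0] for c in clusters],
            "centroid_j": [c.centroid[1] for c in clusters],
            "centroid_k": [c.centroid[2] for c in clusters],
        }
    )


@dataclass(frozen=True)
class ClusterConfig:
    """Monte-Carlo cluster-extent correction parameters."""

    voxel_p: float = 0.05
    alpha: float = 0.05
    nn: int = 1
    n_iterations: int = 10_000
    smoothness_fwhm_vox: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.nn not in (1, 2, 3):
            raise ValueError("nn must be 1, 2 or 3")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.smoothness_fwhm_vox < 0:
            raise ValueError("smoothness must be non-negative")


def cluster_size_threshold(
    grid_shape: Sequence[int],
    cfg: ClusterConfig = ClusterConfig(),
    seed: int = 0,
) -> int:
    """Monte-Carlo minimum significant cluster size.

    Gaussian white-noise fields are smoothed to the configured FWHM (in
    voxels), standardized, thresholded two-sided at ``voxel_p``, and the
    maximum cluster size recorded per iteration; the threshold is the
    ceiling of the (1 - alpha) quantile (at least 1 voxel).
    """
    rng = np.random.default_rng(seed)
    z_crit = stats.norm.isf(cfg.voxel_p / 2.0)
    structure = _structure(cfg.nn)
    sigma = cfg.smoothness_fwhm_vox * FWHM_TO_SIGMA
    max_sizes = np.empty(cfg.n_iterations, dtype=int)
    for i in range(cfg.n_iterations):
        field_ = rng.standard_normal(tuple(grid_shape))
        if sigma > 0:
            field_ = ndimage.gaussian_filter(field_, sigma)
            field_ = field_ / field_.std()
        supra = np.abs(field_) > z_crit
        lab, n = ndimage.label(supra, structure=structure)
        if n == 0:
            max_sizes[i] = 0
        else:
            max_sizes[i] = np.bincount(lab.ravel())[1:].max()
    thr = int(np.ceil(np.quantile(max_sizes, 1.0 - cfg.alpha)))
    return max(1, thr)
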