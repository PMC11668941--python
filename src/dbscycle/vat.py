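"""Stimulation fields, streamline filtering, and network fractions.

The volume of activated tissue (VAT) for a bipolar configuration is
modeled as the union of two spheres centered on the anode and cathode
contacts, with radius r = k * sqrt(amplitude_mA) (k = 1.8 mm by
default).  This is a declared geometric surrogate with a configurable
radius law, not a volume-conductor solution; all downstream statistics
are agnostic to how the VAT was produced, and an externally computed
binary VAT mask can be supplied instead.

Whole-brain tractograms are filtered to the streamlines that pass
through the VAT (exact segment-sphere intersection, so a streamline
crossing the field between two outside vertices is kept), and each
surviving streamline is assigned to the cortical parcel at its endpoint
farther from the VAT centroid.  Per-network counts and fractions of the
filtered total feed the spatial permutation tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .netstats import PermutationResult, one_sided_increase_test, two_sided_difference_test

__all__ = [
    "StreamlineSet",
    "ElectrodeModel",
    "StimulationConfig",
    "VAT",
    "MaskVAT",
    "estimate_vat",
    "streamlines_through_vat",
    "network_streamline_fractions",
    "connectivity_permutation_test",
    "ConnectivityProfile",
]


# ----------------------------------------------------------------------
# streamlines
# ----------------------------------------------------------------------

class StreamlineSet:
    """Ordered collection of polylines in world mm."""

    def __init__(self, streamlines: Sequence[np.ndarray]):
        self.streamlines = [np.asarray(s, dtype=float) for s in streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or len(s) < 2:
                raise ValueError("each streamline must be an (n>=2, 3) polyline")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i):
        return self.streamlines[i]

    def subset(self, mask: np.ndarray) -> "StreamlineSet":
        mask = np.asarray(mask, dtype=bool)
        return StreamlineSet([s for s, m in zip(self.streamlines, mask) if m])

    def transformed(self, affine: np.ndarray) -> "StreamlineSet":
        return StreamlineSet(
            [nib.affines.apply_affine(affine, s) for s in self.streamlines]
        )

    def save_tck(self, path: str | Path) -> None:
        tractogram = nib.streamlines.Tractogram(
            self.streamlines, affine_to_rasmm=np.eye(4)
        )
        nib.streamlines.save(tractogram, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "StreamlineSet":
        tf = nib.streamlines.load(str(path))
        return cls(list(tf.tractogram.streamlines))


# ----------------------------------------------------------------------
# electrodes and stimulation fields
# ----------------------------------------------------------------------

@dataclass
class ElectrodeModel:
    """One DBS lead: ordered contact centers along the lead axis (mm)."""

    lead_id: str
    contacts: np.ndarray  # (n_contacts, 3) world mm, ordered along the lead
    hemisphere: str = ""
    collinearity_tol_mm: float = 0.5

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=float)
        if self.contacts.ndim != 2 or self.contacts.shape[1] != 3:
            raise ValueError("contacts must be an (n, 3) array of mm coordinates")
        if len(self.contacts) < 2:
            raise ValueError("a lead needs at least 2 contacts")
        centered = self.contacts - self.contacts.mean(axis=0)
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        resid = centered - np.outer(centered @ vt[0], vt[0])
        if np.linalg.norm(resid, axis=1).max() > self.collinearity_tol_mm:
            raise ValueError("contacts are not collinear within tolerance")

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def to_dict(self) -> Dict:
        return {
            "lead_id": self.lead_id,
            "hemisphere": self.hemisphere,
            "contacts_mm": self.contacts.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Dict) -> "ElectrodeModel":
        return cls(
            lead_id=d["lead_id"],
            contacts=np.asarray(d["contacts_mm"], dtype=float),
            hemisphere=d.get("hemisphere", ""),
        )


@dataclass(frozen=True)
class StimulationConfig:
    """Bipolar stimulation setting: adjacent anode/cathode pair + amplitude."""

    lead_id: str
    anode: int
    cathode: int
    amplitude_ma: float
    therapeutic: bool = False
    config_id: str = ""

    def __post_init__(self) -> None:
        if self.anode == self.cathode:
            raise ValueError("anode and cathode must differ")
        if self.amplitude_ma <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class VAT:
    """Paired-sphere stimulation field for a bipolar configuration."""

    centers: np.ndarray  # (2, 3) mm
    radius_mm: float

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.shape[1] != 3:
            raise ValueError("centers must be (n, 3) mm coordinates")
        if not self.radius_mm > 0:
            raise ValueError("VAT radius must be positive")

    @property
    def centroid(self) -> np.ndarray:
        return self.centers.mean(axis=0)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        d2 = ((pts[:, None, :] - self.centers[None, :, :]) ** 2).sum(axis=2)
        return (d2 <= self.radius_mm**2).any(axis=1)

    def volume_mm3(self) -> float:
        """Analytic volume of the union of the two spheres."""
        r = self.radius_mm
        v_sphere = 4.0 / 3.0 * np.pi * r**3
        if len(self.centers) == 1:
            return v_sphere
        d = float(np.linalg.norm(self.centers[0] - self.centers[1]))
        if d >= 2 * r:
            return 2 * v_sphere
        # lens (intersection) of two equal spheres
        lens = np.pi * (2 * r - d) ** 2 * (d**2 + 4 * r * d) / (12 * d) if d > 0 else v_sphere
        return 2 * v_sphere - lens

    def segment_intersects(self, p0: np.ndarray, p1: np.ndarray) -> bool:
        """Exact segment-sphere test against either sphere."""
        d = p1 - p0
        dd = float(d @ d)
        for c in self.centers:
            if dd == 0:
                closest = p0
            else:
                t = float(np.clip((c - p0) @ d / dd, 0.0, 1.0))
                closest = p0 + t * d
            if np.sum((closest - c) ** 2) <= self.radius_mm**2:
                return True
        return False

    def intersects_polyline(self, polyline: np.ndarray) -> bool:
        pts = np.asarray(polyline, dtype=float)
        if self.contains(pts).any():
            return True
        # vectorized closest-approach over segments, per sphere
        p0 = pts[:-1]
        d = pts[1:] - p0
        dd = (d * d).sum(axis=1)
        dd_safe = np.where(dd == 0, 1.0, dd)
        for c in self.centers:
            t = np.clip(((c - p0) * d).sum(axis=1) / dd_safe, 0.0, 1.0)
            closest = p0 + t[:, None] * d
            if (((closest - c) ** 2).sum(axis=1) <= self.radius_mm**2).any():
                return True
        return False

    def to_mask(self, grid_shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
        """Rasterize to a boolean voxel mask on the given grid."""
        idx = np.indices(tuple(grid_shape)).reshape(3, -1).T
        world = nib.affines.apply_affine(np.asarray(affine, float), idx)
        return self.contains(world).reshape(tuple(grid_shape))

    def save_mask(self, path: str | Path, grid_shape: Sequence[int], affine) -> None:
        mask = self.to_mask(grid_shape, affine).astype(np.uint8)
        nib.Nifti1Image(mask, np.asarray(affine, float)).to_filename(str(path))


class MaskVAT:
    """Stimulation field supplied as an external binary mask (NIfTI).

    Polyline intersection falls back to dense resampling (0.5 mm steps)
    because no analytic surface is available.
    """

    def __init__(self, mask: np.ndarray, affine: np.ndarray, step_mm: float = 0.5):
        self.mask = np.asarray(mask).astype(bool)
        self.affine = np.asarray(affine, dtype=float)
        self.inv_affine = np.linalg.inv(self.affine)
        self.step_mm = step_mm
        if not self.mask.any():
            raise ValueError("VAT mask is empty")
        vox = np.argwhere(self.mask)
        self.centroid = nib.affines.apply_affine(self.affine, vox.mean(axis=0))

    @classmethod
    def load(cls, path: str | Path) -> "MaskVAT":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0, img.affine)

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(points)
        ijk = np.round(nib.affines.apply_affine(self.inv_affine, pts)).astype(int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.mask.shape)), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        idx = ijk[inside]
        out[inside] = self.mask[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out

    def intersects_polyline(self, polyline: np.ndarray) -> bool:
        pts = np.asarray(polyline, dtype=float)
        if self.contains(pts).any():
            return True
        seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        for p0, p1, L in zip(pts[:-1], pts[1:], seglen):
            n = max(int(np.ceil(L / self.step_mm)), 1)
            samples = p0 + np.linspace(0, 1, n + 1)[:, None] * (p1 - p0)
            if self.contains(samples).any():
                return True
        return False


def estimate_vat(
    electrode: ElectrodeModel,
    cfg: StimulationConfig,
    radius_coef_mm_per_sqrt_ma: float = 1.8,
    allow_nonadjacent: bool = False,
) -> VAT:
    """Paired-sphere VAT for a bipolar configuration.

    Radius law: r = k * sqrt(amplitude_mA).  Non-adjacent contact pairs
    are rejected (the cycling protocol used adjacent pairs) unless
    explicitly overridden.
    """
    if cfg.lead_id != electrode.lead_id:
        raise ValueError(f"configuration targets lead {cfg.lead_id!r}, "
                         f"electrode is {electrode.lead_id!r}")
    n = electrode.n_contacts
    for c in (cfg.anode, cfg.cathode):
        if not 0 <= c < n:
            raise ValueError(f"contact index {c} out of range for {n}-contact lead")
    if abs(cfg.anode - cfg.cathode) != 1 and not allow_nonadjacent:
        raise ValueError(
            "bipolar pair is not adjacent; pass allow_nonadjacent=True to override"
        )
    if radius_coef_mm_per_sqrt_ma <= 0:
        raise ValueError("radius coefficient must be positive")
    r = radius_coef_mm_per_sqrt_ma * np.sqrt(cfg.amplitude_ma)
    centers = electrode.contacts[[cfg.anode, cfg.cathode]]
    return VAT(centers=centers, radius_mm=r)


# ----------------------------------------------------------------------
# filtering and fractions
# ----------------------------------------------------------------------

def streamlines_through_vat(streams: StreamlineSet, vat) -> StreamlineSet:
    """Streamlines with any vertex inside the VAT or any segment
    crossing it; input order is preserved."""
    keep = np.array([vat.intersects_polyline(s) for s in streams], dtype=bool)
    return streams.subset(keep)


@dataclass
class ConnectivityProfile:
    """Per-parcel terminal counts and per-network fractions for one VAT."""

    total: int
    parcel_counts: np.ndarray  # length P
    network_fractions: np.ndarray  # length K
    unassigned_fraction: float
    network_names: List[str]

    def to_frame(self) -> pd.DataFrame:
        rows = pd.DataFrame(
            {
                "network": list(self.network_names) + ["unassigned"],
                "fraction": list(self.network_fractions) + [self.unassigned_fraction],
            }
        )
        rows["total_streamlines"] = self.total
        return rows

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def network_streamline_fractions(
    filtered: StreamlineSet,
    atlas: ParcelAtlas,
    vat=None,
    assignment_mode: str = "endpoint",
    denominator: str = "total",
) -> ConnectivityProfile:
    """Fraction of VAT-filtered streamlines terminating in each network.

    ``assignment_mode='endpoint'`` (default) assigns each streamline by
    the endpoint farther from the VAT centroid (the distal termination);
    ``'traversal'`` counts every parcel a streamline passes through
    (vertex-wise).  Endpoints in background or outside the grid count as
    unassigned.  With ``denominator='total'`` fractions are over all
    filtered streamlines including unassigned terminations; with
    ``'cortical'`` only parcel-assigned ones.
    """
    if assignment_mode not in ("endpoint", "traversal"):
        raise ValueError("assignment_mode must be 'endpoint' or 'traversal'")
    if denominator not in ("total", "cortical"):
        raise ValueError("denominator must be 'total' or 'cortical'")
    p = atlas.n_parcels
    counts = np.zeros(p, dtype=float)
    unassigned = 0.0
    if assignment_mode == "endpoint":
        centroid = (np.asarray(vat.centroid, dtype=float) if vat is not None
                    else np.zeros(3))
        for s in filtered:
            ends = np.array([s[0], s[-1]])
            dist = np.linalg.norm(ends - centroid, axis=1)
            terminal = ends[int(np.argmax(dist))]
            label = int(atlas.labels_at(terminal[None, :])[0])
            if label > 0:
                counts[label - 1] += 1
            else:
                unassigned += 1
    else:
        for s in filtered:
            labels = np.unique(atlas.labels_at(s))
            labels = labels[labels > 0]
            if len(labels) == 0:
                unassigned += 1
            else:
                counts[labels - 1] += 1
    total = len(filtered)
    denom = total if denominator == "total" else max(total - unassigned, 0)
    if denom > 0:
        m = np.zeros((p, atlas.n_networks))
        m[np.arange(p), atlas.assignment - 1] = 1.0
        net_fracs = (counts @ m) / denom
        unassigned_frac = unassigned / denom if denominator == "total" else 0.0
    else:
        net_fracs = np.zeros(atlas.n_networks)
        unassigned_frac = 0.0
    return ConnectivityProfile(
        total=total,
        parcel_counts=counts,
        network_fractions=net_fracs,
        unassigned_fraction=float(unassigned_frac),
        network_names=list(atlas.network_names),
    )


def connectivity_permutation_test(
    counts: np.ndarray,
    assignment: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    network_names: Sequence[str] | None = None,
) -> PermutationResult:
    """One-sided spatial permutation test for elevated streamline counts.

    Statistic: mean member-parcel streamline count per network, larger
    meaning more connected (sign convention flipped relative to the
    BOLD suppression test); delegates to the shared permutation
    machinery.  Two-sided therapeutic-vs-non-therapeutic differences
    use :func:`dbscycle.netstats.two_sided_difference_test` identically.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("streamline counts must be non-negative")
    return one_sided_increase_test(
        counts, assignment, n_perm=n_perm, seed=seed,
        network_names=network_names, statistic="mean_count",
    )
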