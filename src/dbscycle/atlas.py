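"""Labeled parcellation volumes with parcel-to-network assignments.

A :class:`ParcelAtlas` mirrors the structure of a Schaefer-style
cortical parcellation: an integer label volume (0 = background,
1..P parcels) plus an assignment of each parcel to one of K canonical
networks.  The default study uses 100 parcels grouped into the seven
canonical resting-state networks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["SEVEN_NETWORKS", "ParcelAtlas"]

#: Names of the seven canonical resting-state networks.
SEVEN_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "control",
    "default_mode",
)


@dataclass
class ParcelAtlas:
    """Parcellation volume plus parcel-to-network lookup.

    Parameters
    ----------
    labels : 3D integer array, 0 = background, values 1..P label parcels.
    affine : 4x4 voxel-to-world (mm) affine.
    assignment : length-P integer array; ``assignment[i]`` is the network
        id (1..K) of parcel ``i + 1``.
    network_names : K network names, index j naming network id j + 1.
    """

    labels: np.ndarray
    affine: np.ndarray
    assignment: np.ndarray
    network_names: Sequence[str] = field(default_factory=lambda: list(SEVEN_NETWORKS))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.affine = np.asarray(self.affine, dtype=float)
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        p = len(self.assignment)
        present = np.unique(self.labels)
        present = present[present > 0]
        if p == 0 or not np.array_equal(present, np.arange(1, p + 1)):
            raise ValueError(
                "every parcel id 1..P must occur in the label volume "
                f"(assignment has {p} parcels, volume has ids {present})"
            )
        k = len(self.network_names)
        if not np.all((self.assignment >= 1) & (self.assignment <= k)):
            raise ValueError("assignment values must be network ids in 1..K")

    # ------------------------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return len(self.assignment)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def parcel_ids(self) -> np.ndarray:
        return np.arange(1, self.n_parcels + 1)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def membership_matrix(self) -> np.ndarray:
        """(P, K) one-hot matrix of parcel-to-network membership."""
        m = np.zeros((self.n_parcels, self.n_networks))
        m[np.arange(self.n_parcels), self.assignment - 1] = 1.0
        return m

    def network_sizes(self) -> np.ndarray:
        return self.membership_matrix().sum(axis=0).astype(int)

    def parcels_of(self, network: int | str) -> np.ndarray:
        """Parcel ids belonging to a network (by id 1..K or name)."""
        if isinstance(network, str):
            network = list(self.network_names).index(network) + 1
        return self.parcel_ids[self.assignment == network]

    def parcel_voxel_coords(self, parcel_id: int) -> np.ndarray:
        """(n, 3) voxel indices of one parcel."""
        return np.argwhere(self.labels == parcel_id)

    def world_coords(self, voxel_ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices to world mm via the affine."""
        ijk = np.atleast_2d(voxel_ijk)
        return nib.affines.apply_affine(self.affine, ijk)

    def voxel_index(self, world_mm: np.ndarray) -> np.ndarray:
        """Map world mm to nearest voxel indices (may be out of bounds)."""
        pts = np.atleast_2d(world_mm)
        inv = np.linalg.inv(self.affine)
        return np.round(nib.affines.apply_affine(inv, pts)).astype(int)

    def labels_at(self, world_mm: np.ndarray) -> np.ndarray:
        """Parcel label at each world-mm point; 0 for out-of-grid points."""
        ijk = self.voxel_index(world_mm)
        out = np.zeros(len(ijk), dtype=int)
        inside = np.all((ijk >= 0) & (ijk < np.array(self.labels.shape)), axis=1)
        idx = ijk[inside]
        out[inside] = self.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        return out

    # ------------------------------------------------------------------
    def lookup_table(self) -> pd.DataFrame:
        """Parcel lookup table (TSV serialization format)."""
        return pd.DataFrame(
            {
                "parcel_id": self.parcel_ids,
                "parcel_name": [f"parcel-{i:03d}" for i in self.parcel_ids],
                "network_id": self.assignment,
                "network_name": [self.network_names[a - 1] for a in self.assignment],
            }
        )

    def save(self, labels_path: str | Path, lookup_path: str | Path) -> None:
        img = nib.Nifti1Image(self.labels.astype(np.int32), self.affine)
        img.to_filename(str(labels_path))
        self.lookup_table().to_csv(lookup_path, sep="\t", index=False)

    @classmethod
    def load(cls, labels_path: str | Path, lookup_path: str | Path) -> "ParcelAtlas":
        img = nib.load(str(labels_path))
        lut = pd.read_csv(lookup_path, sep="\t")
        lut = lut.sort_values("parcel_id")
        names_by_id = (
            lut.drop_duplicates("network_id").set_index("network_id")["network_name"]
        )
        network_names = [names_by_id[i] for i in sorted(names_by_id.index)]
        return cls(
            labels=np.asarray(img.dataobj).astype(int),
            affine=img.affine,
            assignment=lut["network_id"].to_numpy(),
            network_names=network_names,
        )
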