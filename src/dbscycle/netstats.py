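"""Spatial permutation tests on parcel-to-network assignment.

The central statistic of the pipeline: parcel values (mean On-Off
contrast in percent signal, or VAT streamline counts) are aggregated to
network means, and significance is assessed against a surrogate
distribution obtained by uniformly permuting the parcel-to-network
assignment (equivalently, the parcel values) while preserving network
sizes.  With n_perm = 10,000 surrogates, the smallest attainable
one-tailed p is the resolution floor 1/n_perm = 1.0e-4.

Conventions
-----------
* "Suppression" of a network is the negated mean of its member parcels
  (positive = BOLD decrease).
* A surrogate counts toward the p-value when its statistic is at least
  the observed one (ties never count in favor of significance); for
  continuous data this is indistinguishable from a strict rule, and it
  keeps degenerate inputs (e.g. a constant parcel vector) at p = 1.
* p_uncorrected = max(b, 1) / n_perm, flooring at 1/n_perm; Bonferroni
  over the K networks caps at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .atlas import ParcelAtlas
from .glm import ContrastMap

__all__ = [
    "PermutationResult",
    "parcel_means",
    "network_means",
    "network_suppressions",
    "one_sided_suppression_test",
    "one_sided_increase_test",
    "two_sided_difference_test",
    "bonferroni_adjust",
]


@dataclass
class PermutationResult:
    """Observed network statistics with their permutation null summary."""

    networks: List[str]
    observed: np.ndarray
    n_beyond: np.ndarray  # surrogates at or beyond the observed value, per network
    n_perm: int
    seed: int
    sidedness: str  # 'one-sided-greater' or 'two-sided'
    statistic: str  # e.g. 'suppression', 'mean_count', 'abs_difference'
    p_uncorrected: np.ndarray
    p_bonferroni: np.ndarray
    surrogate_mean: np.ndarray
    surrogate_sd: np.ndarray
    surrogate_min: np.ndarray
    surrogate_max: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "network": self.networks,
                "observed": self.observed,
                "p_uncorrected": self.p_uncorrected,
                "p_bonferroni": self.p_bonferroni,
                "surrogate_mean": self.surrogate_mean,
                "surrogate_sd": self.surrogate_sd,
                "surrogate_min": self.surrogate_min,
                "surrogate_max": self.surrogate_max,
                "n_perm": self.n_perm,
                "seed": self.seed,
                "statistic": self.statistic,
                "sidedness": self.sidedness,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary_dict(self) -> Dict:
        return {
            "statistic": self.statistic,
            "sidedness": self.sidedness,
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
            "networks": {
                name: {
                    "observed": float(obs),
                    "p_uncorrected": float(pu),
                    "p_bonferroni": float(pb),
                    "surrogate_mean": float(sm),
                    "surrogate_sd": float(ss),
                    "surrogate_min": float(smin),
                    "surrogate_max": float(smax),
                }
                for name, obs, pu, pb, sm, ss, smin, smax in zip(
                    self.networks,
                    self.observed,
                    self.p_uncorrected,
                    self.p_bonferroni,
                    self.surrogate_mean,
                    self.surrogate_sd,
                    self.surrogate_min,
                    self.surrogate_max,
                )
            },
        }


# ----------------------------------------------------------------------
# aggregation
# ----------------------------------------------------------------------

def parcel_means(contrast: ContrastMap | np.ndarray, atlas: ParcelAtlas) -> np.ndarray:
    """Unweighted mean of in-parcel voxel values for each parcel.

    Empty parcels (none exist for a valid atlas, but masked data may
    produce NaN input) yield NaN with a warning.
    """
    data = contrast.data if isinstance(contrast, ContrastMap) else np.asarray(contrast)
    if data.shape != atlas.labels.shape:
        raise ValueError("contrast and atlas grids differ")
    labels = atlas.labels.ravel()
    vals = data.ravel()
    finite = np.isfinite(vals)
    counts = np.bincount(labels[finite], minlength=atlas.n_parcels + 1)[1:]
    sums = np.bincount(
        labels[finite], weights=vals[finite], minlength=atlas.n_parcels + 1
    )[1:]
    out = np.full(atlas.n_parcels, np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if not nz.all():
        warnings.warn(f"{(~nz).sum()} parcels have no finite voxels; means set to NaN")
    return out


def _check_vector(v: np.ndarray, assignment: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    assignment = np.asarray(assignment, dtype=int)
    if v.shape != assignment.shape:
        raise ValueError("parcel vector and assignment must be aligned")
    if not np.all(np.isfinite(v)):
        raise ValueError("parcel vector must be finite")
    return v


def network_means(v: np.ndarray, assignment: np.ndarray, n_networks: int | None = None) -> np.ndarray:
    """Unweighted mean over member parcels, per network id 1..K."""
    v = _check_vector(v, np.asarray(assignment))
    assignment = np.asarray(assignment, dtype=int)
    k = n_networks or assignment.max()
    counts = np.bincount(assignment, minlength=k + 1)[1:]
    if np.any(counts == 0):
        raise ValueError("assignment must cover every network 1..K")
    sums = np.bincount(assignment, weights=v, minlength=k + 1)[1:]
    return sums / counts


def network_suppressions(v: np.ndarray, assignment: np.ndarray, n_networks: int | None = None) -> np.ndarray:
    """Negated network means: positive values indicate BOLD suppression."""
    return -network_means(v, assignment, n_networks)


# ----------------------------------------------------------------------
# permutation machinery
# ----------------------------------------------------------------------

def _surrogate_network_means(
    v: np.ndarray, assignment: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, K) network means under uniformly permuted assignments.

    Permuting the parcel values is equivalent to permuting the
    assignment labels and preserves network sizes; the identity
    permutation is not excluded.
    """
    k = assignment.max()
    membership = np.zeros((len(assignment), k))
    membership[np.arange(len(assignment)), assignment - 1] = 1.0
    sizes = membership.sum(axis=0)
    perm_v = rng.permuted(np.broadcast_to(v, (n_perm, len(v))).copy(), axis=1)
    return (perm_v @ membership) / sizes


def _floor_p(n_beyond: np.ndarray, n_perm: int) -> np.ndarray:
    return np.maximum(n_beyond, 1) / n_perm


def _build_result(
    observed: np.ndarray,
    surr: np.ndarray,
    n_beyond: np.ndarray,
    n_perm: int,
    seed: int,
    sidedness: str,
    statistic: str,
    network_names: Sequence[str] | None,
) -> PermutationResult:
    k = len(observed)
    names = list(network_names) if network_names is not None else [
        f"network-{i + 1}" for i in range(k)
    ]
    p_unc = _floor_p(n_beyond, n_perm)
    return PermutationResult(
        networks=names,
        observed=observed,
        n_beyond=n_beyond,
        n_perm=n_perm,
        seed=seed,
        sidedness=sidedness,
        statistic=statistic,
        p_uncorrected=p_unc,
        p_bonferroni=bonferroni_adjust(p_unc, k),
        surrogate_mean=surr.mean(axis=0),
        surrogate_sd=surr.std(axis=0),
        surrogate_min=surr.min(axis=0),
        surrogate_max=surr.max(axis=0),
    )


def one_sided_suppression_test(
    v: np.ndarray,
    assignment: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    network_names: Sequence[str] | None = None,
) -> PermutationResult:
    """One-tailed spatial permutation test for network BOLD suppression.

    For each network the observed suppression (negated member-parcel
    mean) is compared against ``n_perm`` surrogate suppressions obtained
    by permuting the parcel-to-network assignment; the p-value is the
    proportion of surrogates with suppression at or beyond the observed
    value, floored at 1/n_perm.
    """
    v = _check_vector(v, assignment)
    assignment = np.asarray(assignment, dtype=int)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = network_suppressions(v, assignment)
    surr = -_surrogate_network_means(v, assignment, n_perm, rng)
    n_beyond = (surr >= observed[None, :]).sum(axis=0)
    return _build_result(
        observed, surr, n_beyond, n_perm, seed,
        "one-sided-greater", "suppression", network_names,
    )


def one_sided_increase_test(
    v: np.ndarray,
    assignment: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    network_names: Sequence[str] | None = None,
    statistic: str = "mean_value",
) -> PermutationResult:
    """One-tailed test for an elevated network mean (e.g. streamline
    counts); the sign convention is flipped relative to suppression."""
    v = _check_vector(v, assignment)
    assignment = np.asarray(assignment, dtype=int)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed = network_means(v, assignment)
    surr = _surrogate_network_means(v, assignment, n_perm, rng)
    n_beyond = (surr >= observed[None, :]).sum(axis=0)
    return _build_result(
        observed, surr, n_beyond, n_perm, seed,
        "one-sided-greater", statistic, network_names,
    )


def two_sided_difference_test(
    v_a: np.ndarray,
    v_b: np.ndarray,
    assignment: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    network_names: Sequence[str] | None = None,
) -> PermutationResult:
    """Two-sided permutation test on per-parcel differences.

    d = v_a - v_b is fixed; surrogates permute the assignment.  For each
    network the statistic is |mean of member d|; surrogates count with a
    >= rule (conservative on ties).  The reported ``observed`` is the
    signed network mean of d.
    """
    v_a = np.asarray(v_a, dtype=float)
    v_b = np.asarray(v_b, dtype=float)
    if v_a.shape != v_b.shape:
        raise ValueError("parcel vectors must be aligned")
    d = _check_vector(v_a - v_b, assignment)
    assignment = np.asarray(assignment, dtype=int)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    observed_signed = network_means(d, assignment)
    surr = _surrogate_network_means(d, assignment, n_perm, rng)
    n_beyond = (np.abs(surr) >= np.abs(observed_signed)[None, :]).sum(axis=0)
    res = _build_result(
        observed_signed, surr, n_beyond, n_perm, seed,
        "two-sided", "difference", network_names,
    )
    return res


def bonferroni_adjust(p: np.ndarray, m: int = 7) -> np.ndarray:
    """Bonferroni correction: min(1, m * p)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
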