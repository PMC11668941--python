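"""Synthetic DBS cycling study generator.

Produces a complete artificial study with the statistical structure the
downstream analysis assumes: a parcellated atlas with seven networks,
4D BOLD runs following the On/Off cycling design (TR 2 s, 6-min runs,
1-min cycles with 8 s ramps, starting in Off), BIDS-style motion
confounds, per-subject electrode geometry with bipolar configurations,
and whole-brain streamline sets anchored at the stimulation field.

The default :class:`StudyConfig` reproduces the study design: five
subjects (three responders, two non-responders), 23 runs in total of
which 6 are therapeutic (two per responder), and stimulation at 5-6 mA
on adjacent bipolar contact pairs.  The default effect profile
suppresses the default-mode network by 0.3% signal during therapeutic
stimulation; per-network effect sizes are free generator parameters,
not published values.

Everything is a pure function of (config, seed): regenerating a study
with the same configuration yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .atlas import SEVEN_NETWORKS, ParcelAtlas
from .design import CyclingDesign, HRFParams, condition_regressors, drift_basis
from .glm import BoldRun, RunMeta
from .qc import MOTION_COLUMNS
from .vat import ElectrodeModel, StimulationConfig, StreamlineSet, estimate_vat

__all__ = [
    "NetworkEffectProfile",
    "NoiseSpec",
    "StudyConfig",
    "StudyLayout",
    "make_atlas",
    "simulate_run",
    "simulate_streamlines",
    "generate_study",
    "load_study",
]

_FACE_NEIGHBORS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


# ----------------------------------------------------------------------
# configuration types
# ----------------------------------------------------------------------

@dataclass
class NetworkEffectProfile:
    """Per-network On-vs-Off amplitudes in percent signal.

    Negative amplitudes are suppressions.  Networks absent from a table
    carry amplitude 0.  ``parcel_jitter_sd`` adds independent Gaussian
    jitter to each parcel's amplitude.
    """

    therapeutic: Dict[str, float] = field(default_factory=lambda: {"default_mode": -0.3})
    non_therapeutic: Dict[str, float] = field(default_factory=dict)
    parcel_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        for table in (self.therapeutic, self.non_therapeutic):
            for name, amp in table.items():
                if not np.isfinite(amp):
                    raise ValueError(f"amplitude for {name!r} must be finite")
        if self.parcel_jitter_sd < 0:
            raise ValueError("parcel_jitter_sd must be non-negative")

    def parcel_amplitudes(
        self, atlas: ParcelAtlas, therapeutic: bool, rng: np.random.Generator
    ) -> np.ndarray:
        table = self.therapeutic if therapeutic else self.non_therapeutic
        names = list(atlas.network_names)
        amp = np.zeros(atlas.n_parcels)
        for name, a in table.items():
            if name not in names:
                raise ValueError(f"unknown network {name!r}; atlas has {names}")
            amp[atlas.assignment == names.index(name) + 1] = a
        if self.parcel_jitter_sd > 0:
            amp = amp + rng.normal(0.0, self.parcel_jitter_sd, atlas.n_parcels)
        return amp


@dataclass
class NoiseSpec:
    """Artifact model for simulated runs.

    ``sd`` is the stationary voxel noise SD in percent signal; ``ar1``
    the lag-1 autocorrelation; ``drift_coefficients`` the amplitudes (in
    percent) of the zero-mean orthogonal drift polynomials of degrees
    1..len(coeffs); motion spikes occur independently per frame and add
    a step of ``spike_magnitude_mm`` to one translation trace.
    """

    sd: float = 0.5
    ar1: float = 0.3
    drift_coefficients: Tuple[float, ...] = (0.2, 0.1, 0.1)
    spike_prob: float = 0.02
    spike_magnitude_mm: float = 1.0
    motion_step_sd_mm: float = 0.02

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")
        if not 0 <= self.spike_prob <= 1:
            raise ValueError("spike probability must lie in [0, 1]")
        if self.motion_step_sd_mm < 0 or self.spike_magnitude_mm < 0:
            raise ValueError("motion magnitudes must be non-negative")


def _default_runs() -> List[List[bool]]:
    # 6 therapeutic runs across the 3 responders, 17 non-therapeutic across all 5
    return [
        [True, True, False, False, False],
        [True, True, False, False, False],
        [True, True, False, False, False],
        [False, False, False, False],
        [False, False, False, False],
    ]


def _default_therapeutic_weights() -> Dict[str, float]:
    return {
        "default_mode": 0.35,
        "limbic": 0.20,
        "control": 0.10,
        "visual": 0.05,
        "somatomotor": 0.05,
        "dorsal_attention": 0.05,
        "ventral_attention": 0.05,
        "elsewhere": 0.15,
    }


def _default_nontherapeutic_weights() -> Dict[str, float]:
    w = {name: 0.05 for name in SEVEN_NETWORKS}
    w["elsewhere"] = 1.0 - sum(w.values())
    return w


@dataclass
class StudyConfig:
    """Complete description of one synthetic study."""

    n_subjects: int = 5
    runs_per_subject: List[List[bool]] = field(default_factory=_default_runs)
    responder_flags: Tuple[bool, ...] = (True, True, True, False, False)
    grid_shape: Tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 4.0
    tr_s: float = 2.0
    run_length_s: float = 360.0
    cycle_s: float = 60.0
    ramp_s: float = 8.0
    n_parcels: int = 100
    network_sizes: Tuple[int, ...] = (17, 13, 12, 13, 12, 13, 20)
    effect_profile: NetworkEffectProfile = field(default_factory=NetworkEffectProfile)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    n_streamlines: int = 200_000
    therapeutic_streamline_weights: Dict[str, float] = field(
        default_factory=_default_therapeutic_weights
    )
    non_therapeutic_streamline_weights: Dict[str, float] = field(
        default_factory=_default_nontherapeutic_weights
    )
    amplitude_choices_ma: Tuple[float, ...] = (5.0, 6.0)
    contacts_per_lead: int = 4
    contact_spacing_mm: float = 3.0
    effect_waveform_mode: Optional[str] = None  # model-mismatch option
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.runs_per_subject) != self.n_subjects:
            raise ValueError("runs_per_subject must have one entry per subject")
        if len(self.responder_flags) != self.n_subjects:
            raise ValueError("responder_flags must have one entry per subject")
        for flags, resp in zip(self.runs_per_subject, self.responder_flags):
            if any(flags) and not resp:
                raise ValueError("therapeutic runs can only occur in responders")
        if self.run_length_s <= 0 or self.run_length_s % (2 * self.cycle_s) != 0:
            raise ValueError("run_length_s must be a positive multiple of 2*cycle_s")
        if sum(self.network_sizes) != self.n_parcels:
            raise ValueError("network sizes must sum to n_parcels")
        if self.n_streamlines < 0:
            raise ValueError("n_streamlines must be non-negative")

    @property
    def n_runs(self) -> int:
        return sum(len(r) for r in self.runs_per_subject)

    @property
    def n_therapeutic_runs(self) -> int:
        return sum(sum(r) for r in self.runs_per_subject)

    @property
    def design(self) -> CyclingDesign:
        return CyclingDesign.from_run_length(
            self.run_length_s, tr_s=self.tr_s, cycle_s=self.cycle_s, ramp_s=self.ramp_s
        )

    def subject_ids(self) -> List[str]:
        return [f"sub-{i + 1:02d}" for i in range(self.n_subjects)]

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> Dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "StudyConfig":
        d = dict(d)
        if "effect_profile" in d and isinstance(d["effect_profile"], dict):
            d["effect_profile"] = NetworkEffectProfile(**d["effect_profile"])
        if "noise" in d and isinstance(d["noise"], dict):
            d["noise"] = NoiseSpec(**d["noise"])
        for key in ("responder_flags", "network_sizes", "amplitude_choices_ma", "grid_shape"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if "noise" in d and isinstance(d["noise"], NoiseSpec):
            d["noise"] = replace(
                d["noise"], drift_coefficients=tuple(d["noise"].drift_coefficients)
            )
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert to YAML/JSON-safe plain Python types."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ----------------------------------------------------------------------
# atlas generation
# ----------------------------------------------------------------------

def make_atlas(
    n_parcels: int = 100,
    network_sizes: Sequence[int] = (17, 13, 12, 13, 12, 13, 20),
    grid_shape: Sequence[int] = (24, 24, 24),
    seed: int = 0,
    voxel_size_mm: float = 4.0,
    background_margin: int = 1,
    network_names: Sequence[str] | None = None,
) -> ParcelAtlas:
    """Grow a parcellation by seeded region growing.

    Parcels are grown from random seed voxels by repeated face-neighbor
    dilation inside the interior of the grid (a background shell of
    ``background_margin`` voxels is kept at label 0); parcel ids are
    then randomly assigned to networks with the requested sizes.
    Spatial realism is irrelevant to the permutation statistics, which
    depend only on the label structure.
    """
    network_sizes = tuple(int(s) for s in network_sizes)
    if len(network_sizes) < 2:
        raise ValueError("need at least 2 networks")
    if n_parcels < len(network_sizes):
        raise ValueError("need at least as many parcels as networks")
    if sum(network_sizes) != n_parcels:
        raise ValueError("network sizes must sum to n_parcels")
    if any(s < 1 for s in network_sizes):
        raise ValueError("every network needs at least one parcel")
    grid_shape = tuple(int(g) for g in grid_shape)
    interior = np.zeros(grid_shape, dtype=bool)
    m = background_margin
    if any(g <= 2 * m for g in grid_shape):
        raise ValueError("grid too small for the background margin")
    interior[m:grid_shape[0] - m, m:grid_shape[1] - m, m:grid_shape[2] - m] = True
    coords = np.argwhere(interior)
    if len(coords) < n_parcels:
        raise ValueError(
            f"grid too small: {len(coords)} interior voxels for {n_parcels} parcels"
        )
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid_shape, dtype=np.int32)
    seed_idx = rng.choice(len(coords), size=n_parcels, replace=False)
    frontiers: List[np.ndarray] = []
    for pid, si in enumerate(seed_idx, start=1):
        c = coords[si]
        labels[tuple(c)] = pid
        frontiers.append(c[None, :])
    shape_arr = np.array(grid_shape)
    grew = True
    while grew:
        grew = False
        for pid in rng.permutation(n_parcels) + 1:
            f = frontiers[pid - 1]
            if len(f) == 0:
                continue
            nb = (f[:, None, :] + _FACE_NEIGHBORS[None, :, :]).reshape(-1, 3)
            ok = np.all((nb >= 0) & (nb < shape_arr), axis=1)
            nb = nb[ok]
            free = interior[nb[:, 0], nb[:, 1], nb[:, 2]] & (
                labels[nb[:, 0], nb[:, 1], nb[:, 2]] == 0
            )
            nb = np.unique(nb[free], axis=0)
            # recheck after unique (duplicates collapse)
            if len(nb) == 0:
                frontiers[pid - 1] = np.empty((0, 3), dtype=int)
                continue
            labels[nb[:, 0], nb[:, 1], nb[:, 2]] = pid
            frontiers[pid - 1] = nb
            grew = True
    assignment = rng.permutation(
        np.repeat(np.arange(1, len(network_sizes) + 1), network_sizes)
    )
    if network_names is None:
        network_names = (
            list(SEVEN_NETWORKS)
            if len(network_sizes) == 7
            else [f"network-{i + 1}" for i in range(len(network_sizes))]
        )
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -(shape_arr - 1) / 2.0 * voxel_size_mm
    return ParcelAtlas(labels, affine, assignment, list(network_names))


# ----------------------------------------------------------------------
# BOLD run simulation
# ----------------------------------------------------------------------

def simulate_run(
    design: CyclingDesign,
    atlas: ParcelAtlas,
    effects: NetworkEffectProfile,
    noise: NoiseSpec,
    seed: int = 0,
    therapeutic: bool = False,
    hrf: HRFParams | None = None,
    effect_waveform_mode: str | None = None,
) -> Tuple[BoldRun, pd.DataFrame]:
    """Simulate one cycling run plus its motion-parameter trace.

    In-brain voxels follow ``100 + drift + amplitude * x(t) + AR(1)
    noise`` where x(t) is the HRF-convolved On waveform of the design,
    temporally mean-centered so that noiseless voxel means are exactly
    100 (mean-100 rescaling is then the identity and the GLM recovers
    the injected amplitude to machine precision).  Amplitudes apply to
    every voxel of each network's parcels per the effect profile.
    ``effect_waveform_mode`` overrides the ramp handling of the injected
    effect only (model-mismatch studies); by default it equals the
    design's, so simulation and analysis share one waveform.
    """
    rng = np.random.default_rng(seed)
    sim_design = design
    if effect_waveform_mode is not None and effect_waveform_mode != design.ramp_mode:
        sim_design = replace(design, ramp_mode=effect_waveform_mode)
    x = condition_regressors(sim_design, hrf)[:, 0]
    xc = x - x.mean()
    n_frames = design.n_frames

    coeffs = np.asarray(noise.drift_coefficients, dtype=float)
    if len(coeffs) > 0:
        basis = drift_basis(n_frames, len(coeffs))[:, 1:]
        drift = basis @ coeffs
    else:
        drift = np.zeros(n_frames)

    amp_parcel = effects.parcel_amplitudes(atlas, therapeutic, rng)
    amp_vox = np.zeros(atlas.labels.shape)
    for pid in atlas.parcel_ids:
        amp_vox[atlas.labels == pid] = amp_parcel[pid - 1]

    mask = atlas.brain_mask
    data = np.zeros(atlas.labels.shape + (n_frames,))
    data[mask] = 100.0 + drift[None, :] + amp_vox[mask][:, None] * xc[None, :]

    if noise.sd > 0:
        nvox = int(mask.sum())
        e = np.empty((nvox, n_frames))
        innov_sd = noise.sd * np.sqrt(1.0 - noise.ar1**2)
        e[:, 0] = noise.sd * rng.standard_normal(nvox)
        for t in range(1, n_frames):
            e[:, t] = noise.ar1 * e[:, t - 1] + innov_sd * rng.standard_normal(nvox)
        data[mask] += e

    # motion traces: slow random walk plus occasional step spikes
    steps = rng.normal(0.0, noise.motion_step_sd_mm, size=(n_frames, 6))
    steps[0] = 0.0
    spikes = rng.random(n_frames) < noise.spike_prob
    spikes[0] = False
    steps[spikes, 2] += noise.spike_magnitude_mm  # trans_z step
    motion = pd.DataFrame(np.cumsum(steps, axis=0), columns=list(MOTION_COLUMNS))
    # rotations in radians: scale down the walk
    motion.loc[:, ["rot_x", "rot_y", "rot_z"]] /= 100.0

    return BoldRun(data, atlas.affine, design.tr_s), motion


# ----------------------------------------------------------------------
# streamline simulation
# ----------------------------------------------------------------------

def simulate_streamlines(
    n_streamlines: int,
    atlas: ParcelAtlas,
    vat_region,
    network_weights: Dict[str, float],
    seed: int = 0,
    n_vertices: int = 12,
    curvature_mm: float = 2.0,
) -> StreamlineSet:
    """Sample a tractogram with controlled VAT-to-network structure.

    ``network_weights`` maps network names (plus the special key
    ``"elsewhere"``) to probabilities summing to 1.  A streamline drawn
    for a network starts inside the VAT and terminates at a random
    voxel of a random parcel of that network, so downstream VAT
    filtering plus endpoint assignment recovers the weights within
    binomial error; "elsewhere" streamlines avoid the VAT entirely.
    """
    if vat_region is None:
        raise ValueError("a VAT region is required")
    if n_streamlines < 0:
        raise ValueError("n_streamlines must be non-negative")
    names = list(atlas.network_names)
    probs = np.array([network_weights.get(n, 0.0) for n in names]
                     + [network_weights.get("elsewhere", 0.0)])
    unknown = set(network_weights) - set(names) - {"elsewhere"}
    if unknown:
        raise ValueError(f"unknown weight keys: {sorted(unknown)}")
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(vat_region.centers) if hasattr(vat_region, "centers") else None
    centroid = np.asarray(vat_region.centroid, dtype=float)
    radius = getattr(vat_region, "radius_mm", 2.0)

    # world-space bounding box of the grid
    corners_ijk = np.array(np.meshgrid(*[[0, s - 1] for s in atlas.labels.shape])).reshape(3, -1).T
    corners = atlas.world_coords(corners_ijk)
    lo, hi = corners.min(axis=0), corners.max(axis=0)

    parcel_voxels = {
        int(pid): atlas.parcel_voxel_coords(int(pid)) for pid in atlas.parcel_ids
    }
    cats = rng.choice(len(probs), size=n_streamlines, p=probs)
    s_param = np.linspace(0.0, 1.0, n_vertices)
    streamlines: List[np.ndarray] = []
    for cat in cats:
        if cat < len(names):  # network streamline through the VAT
            if centers is not None:
                c = centers[rng.integers(len(centers))]
            else:
                c = centroid
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            start = c + direction * radius * rng.random() ** (1.0 / 3.0)
            members = atlas.parcels_of(cat + 1)
            end = None
            for _ in range(8):
                pid = int(members[rng.integers(len(members))])
                vox = parcel_voxels[pid]
                end_try = atlas.world_coords(vox[rng.integers(len(vox))])[0]
                if np.linalg.norm(end_try - centroid) > np.linalg.norm(start - centroid):
                    end = end_try
                    break
            if end is None:
                start = centroid + 0.1 * (start - centroid)
                end = end_try
            line = start[None, :] + s_param[:, None] * (end - start)[None, :]
            if curvature_mm > 0:
                axis = end - start
                norm = np.linalg.norm(axis)
                if norm > 0:
                    perp = np.cross(axis / norm, rng.standard_normal(3))
                    pn = np.linalg.norm(perp)
                    if pn > 0:
                        bow = curvature_mm * rng.random() * np.sin(np.pi * s_param)
                        line = line + bow[:, None] * (perp / pn)[None, :]
            streamlines.append(line)
        else:  # elsewhere: avoid the VAT
            for _ in range(100):
                p0 = lo + rng.random(3) * (hi - lo)
                p1 = lo + rng.random(3) * (hi - lo)
                line = p0[None, :] + s_param[:, None] * (p1 - p0)[None, :]
                if not vat_region.intersects_polyline(line):
                    break
            streamlines.append(line)
    return StreamlineSet(streamlines)


# ----------------------------------------------------------------------
# whole-study generation
# ----------------------------------------------------------------------

@dataclass
class StudyLayout:
    """On-disk layout of a generated (or exported) study."""

    root: Path
    atlas_labels: Path
    atlas_lookup: Path
    runs: List[Dict]
    subjects: List[Dict]
    manifest_path: Path

    def load_atlas(self) -> ParcelAtlas:
        return ParcelAtlas.load(self.atlas_labels, self.atlas_lookup)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _lead_contacts(side: str, config: StudyConfig) -> np.ndarray:
    fov = np.array(config.grid_shape) * config.voxel_size_mm
    x = -0.15 * fov[0] if side == "left" else 0.15 * fov[0]
    n = config.contacts_per_lead
    z0 = -(n - 1) / 2.0 * config.contact_spacing_mm
    return np.array(
        [[x, 0.0, z0 + i * config.contact_spacing_mm] for i in range(n)]
    )


def generate_study(config: StudyConfig, out_dir: str | Path) -> StudyLayout:
    """Write a complete synthetic study to ``out_dir``.

    Layout: ``atlas/`` (label NIfTI + lookup TSV), per subject a
    ``func/`` directory with BOLD NIfTI + confounds TSV + metadata JSON
    per run, an electrode-geometry JSON, and a whole-brain TCK
    tractogram; plus a manifest with SHA-256 checksums of every file.
    """
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    seeds = np.random.default_rng(config.seed).integers(
        0, 2**31 - 1, size=1 + config.n_runs + 3 * config.n_subjects
    )
    seed_iter = iter(seeds.tolist())

    atlas = make_atlas(
        config.n_parcels,
        config.network_sizes,
        config.grid_shape,
        seed=next(seed_iter),
        voxel_size_mm=config.voxel_size_mm,
    )
    atlas_dir = root / "atlas"
    atlas_dir.mkdir(exist_ok=True)
    atlas_labels = atlas_dir / "atlas_labels.nii.gz"
    atlas_lookup = atlas_dir / "atlas_lookup.tsv"
    atlas.save(atlas_labels, atlas_lookup)

    design = config.design
    runs: List[Dict] = []
    subjects: List[Dict] = []
    files = [atlas_labels, atlas_lookup]

    for s_idx, sub in enumerate(config.subject_ids()):
        responder = bool(config.responder_flags[s_idx])
        sub_dir = root / sub
        func_dir = sub_dir / "func"
        func_dir.mkdir(parents=True, exist_ok=True)
        leads = {
            side: ElectrodeModel(
                lead_id=f"{sub}-{side}",
                contacts=_lead_contacts(side, config),
                hemisphere=side,
            )
            for side in ("left", "right")
        }
        electrodes_path = sub_dir / "electrodes.json"
        electrodes_path.write_text(
            json.dumps({side: lead.to_dict() for side, lead in leads.items()}, indent=2)
        )
        files.append(electrodes_path)

        sub_rng = np.random.default_rng(next(seed_iter))
        ther_pair = (1, 2)  # fixed therapeutic adjacent pair per subject
        for r_idx, therapeutic in enumerate(config.runs_per_subject[s_idx]):
            run_id = f"run-{r_idx + 1:02d}"
            side = ("left", "right")[r_idx % 2]
            if therapeutic:
                anode, cathode = ther_pair
            else:
                while True:
                    a = int(sub_rng.integers(0, config.contacts_per_lead - 1))
                    if (a, a + 1) != ther_pair or not responder:
                        break
                anode, cathode = a, a + 1
            amplitude = float(sub_rng.choice(config.amplitude_choices_ma))
            stim = StimulationConfig(
                lead_id=leads[side].lead_id,
                anode=anode,
                cathode=cathode,
                amplitude_ma=amplitude,
                therapeutic=therapeutic,
                config_id=f"{side[0]}{anode}{cathode}",
            )
            bold, motion = simulate_run(
                design,
                atlas,
                config.effect_profile,
                config.noise,
                seed=next(seed_iter),
                therapeutic=therapeutic,
                effect_waveform_mode=config.effect_waveform_mode,
            )
            bold_path = func_dir / f"{sub}_{run_id}_bold.nii.gz"
            conf_path = func_dir / f"{sub}_{run_id}_confounds.tsv"
            meta_path = func_dir / f"{sub}_{run_id}_meta.json"
            bold.save(bold_path)
            motion.to_csv(conf_path, sep="\t", index=False)
            meta = {
                "subject": sub,
                "run": run_id,
                "config_id": stim.config_id,
                "hemisphere": side,
                "lead_id": stim.lead_id,
                "anode": stim.anode,
                "cathode": stim.cathode,
                "amplitude_ma": stim.amplitude_ma,
                "therapeutic": bool(therapeutic),
                "responder": responder,
                "tr_s": config.tr_s,
            }
            meta_path.write_text(json.dumps(meta, indent=2))
            files += [bold_path, conf_path, meta_path]
            runs.append({"bold": bold_path, "confounds": conf_path,
                         "meta_path": meta_path, "meta": meta})

        if config.n_streamlines > 0:
            weights = (
                config.therapeutic_streamline_weights
                if responder
                else config.non_therapeutic_streamline_weights
            )
            per_lead = config.n_streamlines // 2
            parts = []
            for side in ("left", "right"):
                lead = leads[side]
                stim = StimulationConfig(
                    lead_id=lead.lead_id,
                    anode=ther_pair[0],
                    cathode=ther_pair[1],
                    amplitude_ma=max(config.amplitude_choices_ma),
                    therapeutic=responder,
                )
                seed_vat = estimate_vat(lead, stim)
                parts.append(
                    simulate_streamlines(
                        per_lead, atlas, seed_vat, weights, seed=next(seed_iter)
                    )
                )
            tck_path = sub_dir / f"{sub}_tractogram.tck"
            StreamlineSet(
                list(parts[0]) + list(parts[1])
            ).save_tck(tck_path)
            files.append(tck_path)
            tractogram = tck_path
        else:
            next(seed_iter), next(seed_iter)  # keep seed stream stable
            tractogram = None
        subjects.append(
            {
                "subject": sub,
                "responder": responder,
                "electrodes": electrodes_path,
                "tractogram": tractogram,
            }
        )

    config_path = root / "study_config.yaml"
    config.to_yaml(config_path)
    files.append(config_path)

    manifest = {
        "seed": int(config.seed),
        "n_runs": config.n_runs,
        "n_therapeutic_runs": config.n_therapeutic_runs,
        "files": {str(p.relative_to(root)): _sha256(p) for p in files},
    }
    manifest_path = root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return StudyLayout(
        root=root,
        atlas_labels=atlas_labels,
        atlas_lookup=atlas_lookup,
        runs=runs,
        subjects=subjects,
        manifest_path=manifest_path,
    )


def load_study(root: str | Path) -> StudyLayout:
    """Reconstruct a :class:`StudyLayout` from a study directory."""
    root = Path(root)
    atlas_labels = root / "atlas" / "atlas_labels.nii.gz"
    atlas_lookup = root / "atlas" / "atlas_lookup.tsv"
    runs = []
    subjects = []
    for sub_dir in sorted(root.glob("sub-*")):
        if not sub_dir.is_dir():
            continue
        tck = sorted(sub_dir.glob("*_tractogram.tck"))
        electrodes = sub_dir / "electrodes.json"
        responder = False
        for meta_path in sorted(sub_dir.glob("func/*_meta.json")):
            meta = json.loads(meta_path.read_text())
            responder = meta.get("responder", False)
            stem = meta_path.name.replace("_meta.json", "")
            runs.append(
                {
                    "bold": sub_dir / "func" / f"{stem}_bold.nii.gz",
                    "confounds": sub_dir / "func" / f"{stem}_confounds.tsv",
                    "meta_path": meta_path,
                    "meta": meta,
                }
            )
        subjects.append(
            {
                "subject": sub_dir.name,
                "responder": responder,
                "electrodes": electrodes if electrodes.exists() else None,
                "tractogram": tck[0] if tck else None,
            }
        )
    return StudyLayout(
        root=root,
        atlas_labels=atlas_labels,
        atlas_lookup=atlas_lookup,
        runs=runs,
        subjects=subjects,
        manifest_path=root / "manifest.json",
    )


def run_meta_from_dict(meta: Dict) -> RunMeta:
    return RunMeta(
        subject=meta["subject"],
        run=meta["run"],
        config_id=meta.get("config_id", ""),
        hemisphere=meta.get("hemisphere", ""),
        therapeutic=bool(meta.get("therapeutic", False)),
        responder=bool(meta.get("responder", False)),
    )
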