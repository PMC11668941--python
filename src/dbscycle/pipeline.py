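"""End-to-end orchestration: generate/QC/GLM/group/netstats/connectivity.

Stages communicate through files (NIfTI / TSV / CSV / JSON), so any
stage can be re-run standalone on exported data.  All randomness flows
from the single seed in :class:`PipelineConfig`; rerunning a pipeline
with an identical configuration produces byte-identical statistics
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import ParcelAtlas
from .design import CyclingDesign, HRFParams
from .glm import (
    BoldRun,
    ContrastMap,
    build_design_matrix,
    fit_run_glm,
    on_off_contrast,
    scale_to_mean_100,
)
from .group import (
    ClusterConfig,
    GroupDesign,
    cluster_components,
    cluster_size_threshold,
    cluster_table,
    fit_parcelwise_lme,
    fit_voxelwise_lme,
)
from .netstats import (
    one_sided_suppression_test,
    parcel_means,
    two_sided_difference_test,
)
from .qc import QCConfig, compute_confounds, read_confounds
from .synthdata import (
    StudyConfig,
    StudyLayout,
    generate_study,
    load_study,
    run_meta_from_dict,
)
from .vat import (
    ElectrodeModel,
    StimulationConfig,
    StreamlineSet,
    connectivity_permutation_test,
    estimate_vat,
    network_streamline_fractions,
)

__all__ = ["PipelineConfig", "ResultsBundle", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to run the pipeline reproducibly."""

    out_dir: str = "dbscycle_out"
    study_dir: Optional[str] = None  # use an existing study instead of synthesizing
    synth: StudyConfig = field(default_factory=StudyConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    drift_order: int = 3
    ramp_mode: str = "exclude"
    voxelwise_group: bool = True
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    n_perm: int = 10_000
    vat_radius_coef: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    def to_dict(self) -> Dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("synth"), dict):
            d["synth"] = StudyConfig.from_dict(d["synth"])
        if isinstance(d.get("qc"), dict):
            d["qc"] = QCConfig(**d["qc"])
        if isinstance(d.get("cluster"), dict):
            d["cluster"] = ClusterConfig(**d["cluster"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        from .synthdata import _plain

        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        from .synthdata import _plain

        blob = json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seeds(self) -> Dict[str, int]:
        vals = np.random.default_rng(self.seed).integers(0, 2**31 - 1, size=5)
        keys = ("synth", "cluster", "netstats", "connectivity", "spare")
        return dict(zip(keys, vals.tolist()))


@dataclass
class ResultsBundle:
    """Paths and key tables produced by a pipeline run."""

    out_dir: Path
    contrast_paths: List[Path]
    group_parcel_table: pd.DataFrame
    cluster_table: pd.DataFrame
    cluster_threshold: int
    network_table: pd.DataFrame
    connectivity_table: Optional[pd.DataFrame]
    provenance: Dict


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------

def _stage_study(config: PipelineConfig, out: Path) -> StudyLayout:
    if config.study_dir is not None:
        return load_study(config.study_dir)
    study_root = out / "study"
    if (study_root / "manifest.json").exists():
        logger.info("study already generated, reusing %s", study_root)
        return load_study(study_root)
    synth = dataclasses.replace(config.synth, seed=config.stage_seeds()["synth"])
    return generate_study(synth, study_root)


def _stage_qc(study: StudyLayout, atlas: ParcelAtlas, qc: QCConfig, out: Path) -> Dict[str, Path]:
    qc_dir = out / "qc"
    qc_dir.mkdir(parents=True, exist_ok=True)
    paths: Dict[str, Path] = {}
    for run in study.runs:
        meta = run["meta"]
        key = f"{meta['subject']}_{meta['run']}"
        dest = qc_dir / f"{key}_confounds.tsv"
        paths[key] = dest
        if dest.exists():
            continue
        try:
            bold = BoldRun.load(run["bold"], meta.get("tr_s", 2.0))
            motion = read_confounds(run["confounds"])
            table = compute_confounds(bold.data, atlas.brain_mask, motion, qc)
            table.to_csv(dest, sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001 - annotate failing run
            raise RuntimeError(f"qc stage failed for {key}: {exc}") from exc
    return paths


def _stage_glm(
    config: PipelineConfig,
    study: StudyLayout,
    atlas: ParcelAtlas,
    qc_paths: Dict[str, Path],
    out: Path,
) -> List[ContrastMap]:
    glm_dir = out / "contrasts"
    glm_dir.mkdir(parents=True, exist_ok=True)
    contrasts: List[ContrastMap] = []
    for run in study.runs:
        meta = run["meta"]
        key = f"{meta['subject']}_{meta['run']}"
        nii = glm_dir / f"{key}_contrast.nii.gz"
        meta_path = glm_dir / f"{key}_contrast.json"
        if nii.exists() and meta_path.exists():
            contrasts.append(ContrastMap.load(nii, meta_path))
            continue
        try:
            bold = BoldRun.load(run["bold"], meta.get("tr_s", 2.0))
            design = CyclingDesign.from_run_length(
                bold.n_frames * bold.tr_s, tr_s=bold.tr_s, ramp_mode=config.ramp_mode
            )
            censor = read_confounds(qc_paths[key])["censor"].to_numpy(dtype=bool)
            dm = build_design_matrix(design, drift_order=config.drift_order,
                                     censor_mask=censor)
            dm.to_tsv(glm_dir / f"{key}_design.tsv")
            scaled, _ = scale_to_mean_100(bold.data, atlas.brain_mask)
            result = fit_run_glm(scaled, dm, affine=bold.affine)
            cmap = on_off_contrast(result, run_meta_from_dict(meta))
            cmap.save(nii, meta_path)
            contrasts.append(cmap)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"glm stage failed for {key}: {exc}") from exc
    return contrasts


def _stage_group(
    config: PipelineConfig,
    contrasts: List[ContrastMap],
    atlas: ParcelAtlas,
    out: Path,
):
    group_dir = out / "group"
    group_dir.mkdir(parents=True, exist_ok=True)
    design = GroupDesign.from_metas([c.meta for c in contrasts])
    parcel_table = fit_parcelwise_lme(contrasts, design, atlas)
    parcel_table.to_csv(group_dir / "parcelwise_lme.csv", index=False)

    threshold = cluster_size_threshold(
        atlas.labels.shape, config.cluster, seed=config.stage_seeds()["cluster"]
    )
    clusters = pd.DataFrame()
    if config.voxelwise_group:
        maps = fit_voxelwise_lme(contrasts, design, atlas.brain_mask)
        stat = np.nan_to_num(maps["stat"])
        nib.Nifti1Image(stat.astype(np.float32), atlas.affine).to_filename(
            str(group_dir / "therapeutic_stat.nii.gz")
        )
        from scipy import stats as sps

        z_crit = sps.norm.isf(config.cluster.voxel_p / 2.0)
        comps = cluster_components(stat, z_crit, nn=config.cluster.nn)
        clusters = cluster_table(comps)
        clusters["significant"] = clusters["size"] >= threshold
        clusters.to_csv(group_dir / "clusters.csv", index=False)
    (group_dir / "cluster_null.json").write_text(
        json.dumps(
            {
                "cluster_size_threshold": int(threshold),
                "voxel_p": config.cluster.voxel_p,
                "alpha": config.cluster.alpha,
                "nn": config.cluster.nn,
                "n_iterations": config.cluster.n_iterations,
                "smoothness_fwhm_vox": config.cluster.smoothness_fwhm_vox,
            },
            indent=2,
        )
    )
    return parcel_table, clusters, threshold


def _condition_vectors(contrasts: List[ContrastMap], atlas: ParcelAtlas):
    """Run-averaged parcel vectors for each condition."""
    ther = [c for c in contrasts if c.meta.therapeutic]
    nonther = [c for c in contrasts if not c.meta.therapeutic]
    if not ther or not nonther:
        raise ValueError("both conditions are required for the network statistics")
    v_ther = np.mean([parcel_means(c, atlas) for c in ther], axis=0)
    v_non = np.mean([parcel_means(c, atlas) for c in nonther], axis=0)
    return v_ther, v_non


def _stage_netstats(
    config: PipelineConfig,
    contrasts: List[ContrastMap],
    atlas: ParcelAtlas,
    out: Path,
):
    net_dir = out / "netstats"
    net_dir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seeds()["netstats"]
    v_ther, v_non = _condition_vectors(contrasts, atlas)
    names = list(atlas.network_names)
    res_t = one_sided_suppression_test(
        v_ther, atlas.assignment, n_perm=config.n_perm, seed=seed, network_names=names
    )
    res_n = one_sided_suppression_test(
        v_non, atlas.assignment, n_perm=config.n_perm, seed=seed + 1, network_names=names
    )
    res_d = two_sided_difference_test(
        v_ther, v_non, atlas.assignment, n_perm=config.n_perm, seed=seed + 2,
        network_names=names,
    )
    table = pd.DataFrame(
        {
            "network": names,
            "mean_therapeutic": res_t.observed * -1.0,  # back to signed BOLD change
            "p_therapeutic": res_t.p_uncorrected,
            "p_therapeutic_bonferroni": res_t.p_bonferroni,
            "mean_non_therapeutic": res_n.observed * -1.0,
            "p_non_therapeutic": res_n.p_uncorrected,
            "p_non_therapeutic_bonferroni": res_n.p_bonferroni,
            "difference": res_d.observed,
            "p_difference": res_d.p_uncorrected,
            "p_difference_bonferroni": res_d.p_bonferroni,
        }
    )
    table["n_perm"] = config.n_perm
    table["p_resolution_floor"] = 1.0 / config.n_perm
    table.to_csv(net_dir / "network_stats.csv", index=False)
    (net_dir / "surrogates.json").write_text(
        json.dumps(
            {
                "therapeutic": res_t.summary_dict(),
                "non_therapeutic": res_n.summary_dict(),
                "difference": res_d.summary_dict(),
            },
            indent=2,
        )
    )
    return table


def _stage_connectivity(
    config: PipelineConfig,
    study: StudyLayout,
    atlas: ParcelAtlas,
    out: Path,
) -> Optional[pd.DataFrame]:
    conn_dir = out / "connectivity"
    conn_dir.mkdir(parents=True, exist_ok=True)
    seed = config.stage_seeds()["connectivity"]
    subjects = {s["subject"]: s for s in study.subjects}
    if not any(s.get("tractogram") for s in subjects.values()):
        logger.info("no tractograms in study; skipping connectivity stage")
        return None
    frac_rows = {"therapeutic": [], "non_therapeutic": []}
    for run in study.runs:
        meta = run["meta"]
        sub = subjects[meta["subject"]]
        if not sub.get("tractogram"):
            continue
        key = f"{meta['subject']}_{meta['run']}"
        try:
            leads = {
                d["lead_id"]: ElectrodeModel.from_dict(d)
                for d in json.loads(Path(sub["electrodes"]).read_text()).values()
            }
            stim = StimulationConfig(
                lead_id=meta["lead_id"],
                anode=int(meta["anode"]),
                cathode=int(meta["cathode"]),
                amplitude_ma=float(meta["amplitude_ma"]),
                therapeutic=bool(meta["therapeutic"]),
                config_id=meta.get("config_id", ""),
            )
            vat = estimate_vat(leads[stim.lead_id], stim,
                               radius_coef_mm_per_sqrt_ma=config.vat_radius_coef)
            streams = StreamlineSet.load(sub["tractogram"])
            filtered = [s for s in streams if vat.intersects_polyline(s)]
            profile = network_streamline_fractions(
                StreamlineSet(filtered) if filtered else _empty_streamset(),
                atlas, vat=vat,
            )
            profile.to_csv(conn_dir / f"{key}_profile.csv")
            total = max(profile.total, 1)
            cond = "therapeutic" if meta["therapeutic"] else "non_therapeutic"
            frac_rows[cond].append(profile.parcel_counts / total)
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"connectivity stage failed for {key}: {exc}") from exc
    names = list(atlas.network_names)
    v_ther = np.mean(frac_rows["therapeutic"], axis=0) if frac_rows["therapeutic"] else None
    v_non = np.mean(frac_rows["non_therapeutic"], axis=0) if frac_rows["non_therapeutic"] else None
    if v_ther is None or v_non is None:
        logger.info("connectivity stage needs both conditions; partial results written")
        return None
    res_t = connectivity_permutation_test(
        v_ther, atlas.assignment, n_perm=config.n_perm, seed=seed, network_names=names
    )
    res_n = connectivity_permutation_test(
        v_non, atlas.assignment, n_perm=config.n_perm, seed=seed + 1, network_names=names
    )
    res_d = two_sided_difference_test(
        v_ther, v_non, atlas.assignment, n_perm=config.n_perm, seed=seed + 2,
        network_names=names,
    )
    table = pd.DataFrame(
        {
            "network": names,
            "fraction_therapeutic": res_t.observed,
            "p_therapeutic": res_t.p_uncorrected,
            "p_therapeutic_bonferroni": res_t.p_bonferroni,
            "fraction_non_therapeutic": res_n.observed,
            "p_non_therapeutic": res_n.p_uncorrected,
            "p_non_therapeutic_bonferroni": res_n.p_bonferroni,
            "difference": res_d.observed,
            "p_difference": res_d.p_uncorrected,
            "p_difference_bonferroni": res_d.p_bonferroni,
        }
    )
    table["n_perm"] = config.n_perm
    table["p_resolution_floor"] = 1.0 / config.n_perm
    table.to_csv(conn_dir / "connectivity_stats.csv", index=False)
    return table


def _empty_streamset() -> StreamlineSet:
    return StreamlineSet([])


def run_pipeline(config: PipelineConfig) -> ResultsBundle:
    """Execute every stage in order and return the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = _stage_study(config, out)
    atlas = study.load_atlas()
    qc_paths = _stage_qc(study, atlas, config.qc, out)
    contrasts = _stage_glm(config, study, atlas, qc_paths, out)
    parcel_table, clusters, threshold = _stage_group(config, contrasts, atlas, out)
    network_table = _stage_netstats(config, contrasts, atlas, out)
    connectivity_table = _stage_connectivity(config, study, atlas, out)

    import scipy
    import statsmodels

    provenance = {
        "dbscycle_version": __version__,
        "config_hash": config.config_hash(),
        "seed": int(config.seed),
        "stage_seeds": config.stage_seeds(),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nib.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    contrast_paths = sorted((out / "contrasts").glob("*_contrast.nii.gz"))
    return ResultsBundle(
        out_dir=out,
        contrast_paths=contrast_paths,
        group_parcel_table=parcel_table,
        cluster_table=clusters,
        cluster_threshold=threshold,
        network_table=network_table,
        connectivity_table=connectivity_table,
        provenance=provenance,
    )


# ----------------------------------------------------------------------
# validation
# ----------------------------------------------------------------------

def validate_inputs(study_dir: str | Path) -> List[str]:
    """Consistency report for a study directory; empty list = no failures."""
    failures: List[str] = []
    study = load_study(study_dir)
    if not study.atlas_labels.exists() or not study.atlas_lookup.exists():
        return [f"atlas files missing under {study_dir}"]
    try:
        atlas = study.load_atlas()
    except Exception as exc:  # noqa: BLE001
        return [f"atlas failed to load: {exc}"]
    if not study.runs:
        failures.append("no runs found")
    for run in study.runs:
        meta = run["meta"]
        key = f"{meta.get('subject', '?')}_{meta.get('run', '?')}"
        for field_ in ("subject", "run", "therapeutic", "responder"):
            if field_ not in meta:
                failures.append(f"{key}: metadata missing field '{field_}'")
        if not Path(run["bold"]).exists():
            failures.append(f"{key}: BOLD file missing")
            continue
        img = nib.load(str(run["bold"]))
        if img.shape[:3] != atlas.labels.shape:
            failures.append(f"{key}: BOLD grid {img.shape[:3]} != atlas {atlas.labels.shape}")
        if not np.allclose(img.affine, atlas.affine, atol=1e-4):
            failures.append(f"{key}: BOLD affine differs from atlas affine")
        if not Path(run["confounds"]).exists():
            failures.append(f"{key}: confounds file missing")
        else:
            table = pd.read_csv(run["confounds"], sep="\t")
            from .qc import MOTION_COLUMNS

            missing = [c for c in MOTION_COLUMNS if c not in table.columns]
            if missing:
                failures.append(f"{key}: confounds missing columns {missing}")
            elif len(table) != img.shape[-1]:
                failures.append(
                    f"{key}: confounds rows ({len(table)}) != BOLD frames ({img.shape[-1]})"
                )
    return failures
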