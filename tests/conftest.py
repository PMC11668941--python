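"""Shared fixtures: small deterministic atlases and study builders."""

import logging

import numpy as np
import pytest

import dbscycle as d
from dbscycle.design import CyclingDesign

# the parcel-wise OLS-fallback warnings are expected on null data and
# would otherwise flood the test output
logging.getLogger("dbscycle.group").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def atlas100():
    """Default-scale atlas: 100 parcels, seven networks, 24^3 grid."""
    return d.make_atlas(100, (17, 13, 12, 13, 12, 13, 20), (24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def tiny_atlas():
    """6 parcels in 2 equal networks: small enough to enumerate all
    distinct assignments (C(6,3) = 20)."""
    return d.make_atlas(6, (3, 3), (6, 6, 6), seed=1, voxel_size_mm=10.0)


@pytest.fixture(scope="session")
def small_atlas():
    """14 parcels, seven 2-parcel networks on an 8^3 grid (fast sims)."""
    return d.make_atlas(14, (2,) * 7, (8, 8, 8), seed=11, voxel_size_mm=8.0)


@pytest.fixture(scope="session")
def default_design():
    return CyclingDesign()


def simulate_study_maps(atlas, effect_profile, noise, seed, runs_per_subject=None,
                        design=None):
    """Simulate a full study and return its per-run contrast maps.

    Runs the real path: simulate -> scale to mean 100 -> GLM -> contrast.
    Default run structure mirrors the full study: three responders with
    2 therapeutic + 3 non-therapeutic runs each, two non-responders with
    4 non-therapeutic runs each (23 runs, 6 therapeutic).
    """
    if runs_per_subject is None:
        runs_per_subject = [[True, True, False, False, False]] * 3 + [[False] * 4] * 2
    design = design or CyclingDesign()
    rng = np.random.default_rng(seed)
    dm = d.build_design_matrix(design)
    maps = []
    for s_idx, flags in enumerate(runs_per_subject):
        for r_idx, ther in enumerate(flags):
            run, _ = d.simulate_run(
                design, atlas, effect_profile, noise,
                seed=int(rng.integers(2**31)), therapeutic=ther,
            )
            scaled, _ = d.scale_to_mean_100(run.data, atlas.brain_mask)
            res = d.fit_run_glm(scaled, dm)
            maps.append(
                d.on_off_contrast(
                    res,
                    d.RunMeta(f"sub-{s_idx + 1:02d}", f"run-{r_idx + 1:02d}",
                              therapeutic=ther, responder=s_idx < 3),
                )
            )
    return maps
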