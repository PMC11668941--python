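"""Cycling design, HRF, design matrix, and per-run GLM behaviour."""

import numpy as np
import pytest

import dbscycle as d
from dbscycle.design import CyclingDesign, HRFParams, condition_waveforms, drift_basis
from dbscycle.glm import CollinearDesignError, DesignMatrix


class TestCyclingDesign:
    def test_default_run_covers_six_minutes_in_180_frames(self):
        design = CyclingDesign()
        assert design.n_frames == 180
        assert design.run_length_s == 360.0

    def test_run_starts_in_off_state(self):
        design = CyclingDesign()
        assert design.state_at(0.0) == "off"
        assert design.state_at(59.0) == "off"
        assert design.state_at(60.0) == "on"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tr_s": 0.0},
            {"ramp_s": 60.0},
            {"ramp_s": -1.0},
            {"start_state": "maybe"},
            {"ramp_mode": "trapezoid"},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CyclingDesign(**kwargs)

    def test_waveforms_exclude_ramps_by_default(self):
        design = CyclingDesign()
        t, on, off = condition_waveforms(design, dt=1.0)
        # first 8 s of every block are ramps: neither condition modeled
        assert on[:68].sum() == 0  # off block + on ramp
        assert np.all(on[68:120] == 1)  # on plateau
        assert np.all(off[8:60] == 1)  # first off plateau
        assert np.all((on + off) <= 1)

    def test_linear_ramps_interpolate_and_partition_unity(self):
        design = CyclingDesign(ramp_mode="linear")
        t, on, off = condition_waveforms(design, dt=1.0)
        np.testing.assert_allclose(on + off, 1.0)
        assert on[64] == pytest.approx(0.5)  # halfway up the 8 s ramp


class TestHRF:
    def test_unit_integral_and_peak_location(self):
        dt = 0.1
        h = HRFParams().sample(dt)
        assert h.sum() * dt == pytest.approx(1.0)
        assert np.argmax(h) * dt == pytest.approx(5.0, abs=0.3)

    def test_matches_canonical_spm_shape(self):
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        dt = 0.1
        ours = HRFParams().sample(dt)
        ref = nilearn_hrf.spm_hrf(t_r=dt * 10, oversampling=10, time_length=32.0)
        n = min(len(ours), len(ref))
        cos = np.dot(ours[:n], ref[:n]) / (
            np.linalg.norm(ours[:n]) * np.linalg.norm(ref[:n])
        )
        assert cos > 0.999


class TestDesignMatrix:
    def test_default_shape_and_names(self, default_design):
        dm = d.build_design_matrix(default_design)
        assert dm.matrix.shape == (180, 6)
        assert dm.names == ["on", "off", "poly0", "poly1", "poly2", "poly3"]

    def test_on_regressor_silent_before_first_on_block(self, default_design):
        dm = d.build_design_matrix(default_design)
        # first On plateau starts at 68 s = frame 34; HRF onset delays further
        assert np.all(dm.matrix[:34, 0] == 0)
        assert dm.matrix[40:60, 0].max() > 0.5

    def test_drift_order_zero_gives_three_columns(self, default_design):
        dm = d.build_design_matrix(default_design, drift_order=0)
        assert dm.matrix.shape == (180, 3)

    def test_polynomials_orthogonal_and_zero_mean(self):
        basis = drift_basis(180, 3)
        gram = basis.T @ basis
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-12
        assert np.abs(basis[:, 1:].mean(axis=0)).max() < 1e-14

    def test_zero_ramp_design_is_rejected_as_collinear(self):
        with pytest.raises(CollinearDesignError):
            d.build_design_matrix(CyclingDesign(ramp_s=0.0))

    def test_censor_mask_length_validated(self, default_design):
        with pytest.raises(ValueError):
            d.build_design_matrix(default_design, censor_mask=np.zeros(10, dtype=bool))


class TestScaling:
    def test_constant_voxel_scaled_to_100(self):
        data = np.full((2, 2, 2, 10), 50.0)
        scaled, valid = d.scale_to_mean_100(data)
        assert np.all(scaled == 100.0)
        assert valid.all()

    def test_voxel_at_mean_100_unchanged(self):
        ts = np.tile([90.0, 110.0], 5)
        data = ts.reshape(1, 1, 1, 10)
        scaled, _ = d.scale_to_mean_100(data)
        np.testing.assert_allclose(scaled[0, 0, 0], ts)

    def test_nonpositive_mean_voxels_warned_and_masked(self):
        data = np.zeros((1, 1, 2, 4))
        data[0, 0, 0] = 100.0
        with pytest.warns(UserWarning):
            _, valid = d.scale_to_mean_100(data)
        assert valid[0, 0, 0] and not valid[0, 0, 1]


class TestRunGLM:
    def test_hand_solved_toy_betas(self):
        # exact 3-frame system: y = on + off * [0,1,2]
        dm = DesignMatrix(
            np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 2.0]]),
            ["on", "off"],
            np.zeros(3, dtype=bool),
        )
        y = np.array([2.0, 5.0, 8.0]).reshape(1, 1, 1, 3)
        res = d.fit_run_glm(y, dm)
        assert res.beta("on")[0, 0, 0] == pytest.approx(2.0)
        assert res.beta("off")[0, 0, 0] == pytest.approx(3.0)

    def test_noiseless_injected_amplitude_recovered_exactly(self, tiny_atlas,
                                                            default_design):
        eff = d.NetworkEffectProfile(therapeutic={"network-1": -0.3},
                                     non_therapeutic={})
        noise = d.NoiseSpec(sd=0.0, drift_coefficients=(0.5, 0.2, 0.1),
                            spike_prob=0.0, motion_step_sd_mm=0.0)
        run, _ = d.simulate_run(default_design, tiny_atlas, eff, noise, seed=3,
                                therapeutic=True)
        scaled, _ = d.scale_to_mean_100(run.data, tiny_atlas.brain_mask)
        dm = d.build_design_matrix(default_design)
        cmap = d.on_off_contrast(d.fit_run_glm(scaled, dm),
                                 d.RunMeta("s", "r", therapeutic=True))
        in_net1 = np.isin(tiny_atlas.labels, tiny_atlas.parcels_of(1))
        in_net2 = np.isin(tiny_atlas.labels, tiny_atlas.parcels_of(2))
        assert np.abs(cmap.data[in_net1] + 0.3).max() < 1e-9
        assert np.abs(cmap.data[in_net2]).max() < 1e-9

    def test_contrast_invariant_to_cubic_drift(self, tiny_atlas, default_design):
        eff = d.NetworkEffectProfile(therapeutic={"network-1": -0.3},
                                     non_therapeutic={})
        noise = d.NoiseSpec(sd=0.0, drift_coefficients=(), spike_prob=0.0,
                            motion_step_sd_mm=0.0)
        run, _ = d.simulate_run(default_design, tiny_atlas, eff, noise, seed=3,
                                therapeutic=True)
        dm = d.build_design_matrix(default_design)
        res0 = d.fit_run_glm(run.data, dm)
        x = np.linspace(-1, 1, default_design.n_frames)
        cubic = 3.0 + 2.0 * x - 1.5 * x**2 + 0.7 * x**3
        drifted = run.data + run.data.astype(bool).any(-1, keepdims=True) * cubic
        res1 = d.fit_run_glm(drifted, dm)
        c0 = res0.beta("on") - res0.beta("off")
        c1 = res1.beta("on") - res1.beta("off")
        np.testing.assert_allclose(c1, c0, atol=1e-10)

    def test_censoring_20pct_preserves_noiseless_recovery(self, tiny_atlas,
                                                          default_design):
        eff = d.NetworkEffectProfile(therapeutic={"network-1": -0.3},
                                     non_therapeutic={})
        noise = d.NoiseSpec(sd=0.0, drift_coefficients=(0.3, 0.1, 0.05),
                            spike_prob=0.0, motion_step_sd_mm=0.0)
        run, _ = d.simulate_run(default_design, tiny_atlas, eff, noise, seed=5,
                                therapeutic=True)
        scaled, _ = d.scale_to_mean_100(run.data, tiny_atlas.brain_mask)
        rng = np.random.default_rng(9)
        censor = np.zeros(180, dtype=bool)
        censor[rng.choice(180, size=36, replace=False)] = True
        dm = d.build_design_matrix(default_design, censor_mask=censor)
        res = d.fit_run_glm(scaled, dm)
        contrast = res.beta("on") - res.beta("off")
        in_net1 = np.isin(tiny_atlas.labels, tiny_atlas.parcels_of(1))
        assert np.abs(contrast[in_net1] + 0.3).max() < 1e-9

    def test_pure_noise_contrast_unbiased(self, tiny_atlas, default_design):
        """Mean contrast over replicates of signal-free runs stays within
        3 standard errors of zero."""
        eff = d.NetworkEffectProfile(therapeutic={}, non_therapeutic={})
        noise = d.NoiseSpec(sd=0.5, ar1=0.3, drift_coefficients=(),
                            spike_prob=0.0, motion_step_sd_mm=0.0)
        dm = d.build_design_matrix(default_design)
        mask = tiny_atlas.brain_mask
        means = []
        for seed in range(200):
            run, _ = d.simulate_run(default_design, tiny_atlas, eff, noise,
                                    seed=seed)
            res = d.fit_run_glm(run.data, dm)
            contrast = res.beta("on") - res.beta("off")
            means.append(contrast[mask].mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se

    def test_too_few_uncensored_frames_rejected(self, default_design):
        censor = np.ones(180, dtype=bool)
        censor[:5] = False
        with pytest.raises(CollinearDesignError):
            dm = d.build_design_matrix(default_design, censor_mask=censor)
            d.fit_run_glm(np.zeros((1, 1, 1, 180)), dm)

    def test_contrast_antisymmetric_under_beta_swap(self, default_design):
        dm = d.build_design_matrix(default_design)
        y = np.random.default_rng(0).normal(100, 1, size=(2, 2, 2, 180))
        res = d.fit_run_glm(y, dm)
        flipped = d.GLMResult(
            betas=res.betas[..., [1, 0, 2, 3, 4, 5]],
            names=res.names, resid_var=res.resid_var, dof=res.dof,
            affine=res.affine,
        )
        c = d.on_off_contrast(res, d.RunMeta("s", "r")).data
        cf = d.on_off_contrast(flipped, d.RunMeta("s", "r")).data
        np.testing.assert_allclose(cf, -c)
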