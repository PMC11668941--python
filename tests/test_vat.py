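"""Stimulation-field geometry, streamline filtering, network fractions."""

import numpy as np
import pytest

import dbscycle as d
from dbscycle.vat import VAT, MaskVAT


@pytest.fixture
def lead():
    return d.ElectrodeModel(
        "L", np.array([[0.0, 0.0, z] for z in (-4.5, -1.5, 1.5, 4.5)]),
        hemisphere="left",
    )


class TestElectrodeModel:
    def test_non_collinear_contacts_rejected(self):
        with pytest.raises(ValueError):
            d.ElectrodeModel("L", np.array([[0, 0, 0], [0, 0, 3], [5, 5, 5]]))

    def test_round_trip(self, lead):
        back = d.ElectrodeModel.from_dict(lead.to_dict())
        np.testing.assert_allclose(back.contacts, lead.contacts)
        assert back.hemisphere == "left"


class TestEstimateVAT:
    def test_radius_follows_sqrt_amplitude(self, lead):
        v5 = d.estimate_vat(lead, d.StimulationConfig("L", 0, 1, 5.0))
        v6 = d.estimate_vat(lead, d.StimulationConfig("L", 0, 1, 6.0))
        assert v5.radius_mm == pytest.approx(1.8 * np.sqrt(5.0))
        assert v6.radius_mm > v5.radius_mm

    def test_volume_vanishes_with_amplitude(self, lead):
        tiny = d.estimate_vat(lead, d.StimulationConfig("L", 0, 1, 1e-8))
        assert tiny.volume_mm3() < 1e-9

    def test_doubling_radius_scales_sphere_volume_eightfold(self):
        a = VAT(centers=np.array([[0, 0, 0.0]]), radius_mm=2.0)
        b = VAT(centers=np.array([[0, 0, 0.0]]), radius_mm=4.0)
        assert b.volume_mm3() == pytest.approx(8 * a.volume_mm3())

    def test_nonadjacent_pair_needs_override(self, lead):
        cfg = d.StimulationConfig("L", 0, 2, 5.0)
        with pytest.raises(ValueError):
            d.estimate_vat(lead, cfg)
        vat = d.estimate_vat(lead, cfg, allow_nonadjacent=True)
        assert vat.radius_mm > 0

    def test_configurations_sharing_a_contact_overlap(self, lead):
        a = d.estimate_vat(lead, d.StimulationConfig("L", 0, 1, 5.0))
        b = d.estimate_vat(lead, d.StimulationConfig("L", 1, 2, 5.0))
        shared = lead.contacts[1]
        assert a.contains(shared[None, :])[0] and b.contains(shared[None, :])[0]

    def test_wrong_lead_rejected(self, lead):
        with pytest.raises(ValueError):
            d.estimate_vat(lead, d.StimulationConfig("R", 0, 1, 5.0))


class TestStreamlineFiltering:
    def test_vertex_and_segment_rules(self):
        vat = VAT(centers=np.array([[0.0, 0.0, 0.0]]), radius_mm=2.0)
        outside = np.array([[10.0, 10, 10], [12, 12, 12]])
        at_center = np.array([[0.0, 0, 0], [10, 10, 10]])
        crossing = np.array([[-10.0, 0, 0], [10.0, 0, 0]])  # passes through center
        streams = d.StreamlineSet([outside, at_center, crossing])
        kept = d.streamlines_through_vat(streams, vat)
        assert len(kept) == 2
        np.testing.assert_allclose(kept[0], at_center)
        np.testing.assert_allclose(kept[1], crossing)

    def test_filtering_monotone_in_radius(self):
        rng = np.random.default_rng(12)
        streams = d.StreamlineSet(
            [rng.uniform(-10, 10, size=(5, 3)) for _ in range(300)]
        )
        small = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=2.0)
        big = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=4.0)
        kept_small = {i for i, s in enumerate(streams)
                      if small.intersects_polyline(s)}
        kept_big = {i for i, s in enumerate(streams) if big.intersects_polyline(s)}
        assert kept_small <= kept_big

    def test_mask_vat_agrees_with_spheres_on_coarse_grid(self):
        sphere = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=5.0)
        affine = np.diag([1.0, 1, 1, 1])
        affine[:3, 3] = -10
        mask = sphere.to_mask((21, 21, 21), affine)
        mvat = MaskVAT(mask, affine)
        rng = np.random.default_rng(3)
        compared = 0
        for _ in range(100):
            line = rng.uniform(-9, 9, size=(4, 3))
            # voxelization blurs the boundary; compare away from it
            dense = np.concatenate(
                [p0 + np.linspace(0, 1, 200)[:, None] * (p1 - p0)
                 for p0, p1 in zip(line[:-1], line[1:])]
            )
            dmin = np.linalg.norm(dense, axis=1).min()
            if abs(dmin - 5.0) < 1.5:
                continue
            assert sphere.intersects_polyline(line) == mvat.intersects_polyline(line)
            compared += 1
        assert compared > 50

    def test_tck_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        streams = d.StreamlineSet([rng.normal(size=(7, 3)) for _ in range(10)])
        path = tmp_path / "streams.tck"
        streams.save_tck(path)
        back = d.StreamlineSet.load(path)
        assert len(back) == 10
        for a, b in zip(streams, back):
            np.testing.assert_allclose(a, b, atol=1e-5)


class TestNetworkFractions:
    def test_all_endpoints_in_one_network(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=3.0)
        target = tiny_atlas.parcels_of(1)[0]
        vox = tiny_atlas.parcel_voxel_coords(target)
        streams = []
        for i in range(20):
            end = tiny_atlas.world_coords(vox[i % len(vox)])[0]
            streams.append(np.array([[0.0, 0, 0], end]))
        prof = d.network_streamline_fractions(
            d.StreamlineSet(streams), tiny_atlas, vat=vat
        )
        assert prof.network_fractions[0] == 1.0
        assert prof.network_fractions[1] == 0.0
        assert prof.unassigned_fraction == 0.0

    def test_background_endpoints_counted_unassigned(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=3.0)
        corner = tiny_atlas.world_coords(np.array([0, 0, 0]))[0]  # background shell
        streams = d.StreamlineSet([np.array([[0.0, 0, 0], corner])])
        prof = d.network_streamline_fractions(streams, tiny_atlas, vat=vat)
        assert prof.unassigned_fraction == 1.0
        assert prof.network_fractions.sum() == 0.0

    def test_fractions_invariant_to_order_and_rigid_motion(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0], [0, 0, 3.0]]), radius_mm=4.0)
        sl = d.simulate_streamlines(
            300, tiny_atlas, vat,
            {"network-1": 0.5, "network-2": 0.3, "elsewhere": 0.2}, seed=8,
        )
        filt = d.streamlines_through_vat(sl, vat)
        prof = d.network_streamline_fractions(filt, tiny_atlas, vat=vat)
        # order permutation
        perm = np.random.default_rng(0).permutation(len(filt))
        prof_perm = d.network_streamline_fractions(
            d.StreamlineSet([filt[i] for i in perm]), tiny_atlas, vat=vat
        )
        np.testing.assert_allclose(
            prof_perm.network_fractions, prof.network_fractions
        )
        # rigid transform applied jointly to streams, atlas and VAT
        theta = 0.4
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0, 5.0],
                [np.sin(theta), np.cos(theta), 0, -3.0],
                [0, 0, 1, 2.0],
                [0, 0, 0, 1.0],
            ]
        )
        atlas_t = d.ParcelAtlas(
            tiny_atlas.labels, rot @ tiny_atlas.affine,
            tiny_atlas.assignment, tiny_atlas.network_names,
        )
        import nibabel as nib

        vat_t = VAT(nib.affines.apply_affine(rot, vat.centers), vat.radius_mm)
        filt_t = d.StreamlineSet(
            [nib.affines.apply_affine(rot, s) for s in filt]
        )
        prof_t = d.network_streamline_fractions(filt_t, atlas_t, vat=vat_t)
        np.testing.assert_allclose(
            prof_t.network_fractions, prof.network_fractions
        )

    def test_generator_weights_recovered(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=3.0)
        n = 4000
        sl = d.simulate_streamlines(
            n, tiny_atlas, vat, {"network-1": 0.6, "network-2": 0.4}, seed=4
        )
        filt = d.streamlines_through_vat(sl, vat)
        assert len(filt) == n
        prof = d.network_streamline_fractions(filt, tiny_atlas, vat=vat)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(prof.network_fractions[0] - 0.6) < 3 * se
        assert abs(prof.network_fractions[1] - 0.4) < 3 * se

    def test_same_seed_identical_polylines(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=3.0)
        w = {"network-1": 0.7, "elsewhere": 0.3}
        a = d.simulate_streamlines(50, tiny_atlas, vat, w, seed=6)
        b = d.simulate_streamlines(50, tiny_atlas, vat, w, seed=6)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1, s2)

    def test_weights_must_sum_to_one(self, tiny_atlas):
        vat = VAT(centers=np.array([[0.0, 0, 0]]), radius_mm=3.0)
        with pytest.raises(ValueError):
            d.simulate_streamlines(10, tiny_atlas, vat, {"network-1": 0.5}, seed=0)


class TestConnectivityPermutation:
    def test_equal_counts_give_p_one(self, atlas100):
        res = d.connectivity_permutation_test(
            np.full(100, 7.0), atlas100.assignment, n_perm=200, seed=0
        )
        np.testing.assert_array_equal(res.p_uncorrected, 1.0)

    def test_concentrated_counts_hit_floor(self, atlas100):
        counts = np.where(atlas100.assignment == 3, 50.0, 0.0)
        res = d.connectivity_permutation_test(
            counts, atlas100.assignment, n_perm=10_000, seed=1
        )
        assert res.p_uncorrected[2] == 1.0 / 10_000

    def test_matches_exhaustive_enumeration(self, tiny_atlas):
        from test_netstats import exhaustive_one_sided

        counts = np.array([9.0, 4.0, 7.0, 1.0, 0.0, 2.0])
        # increase test on counts == suppression test on negated counts
        exact = exhaustive_one_sided(-counts, tiny_atlas.assignment)
        n_perm = 10_000
        res = d.connectivity_permutation_test(
            counts, tiny_atlas.assignment, n_perm=n_perm, seed=3
        )
        mc = res.n_beyond / n_perm
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert np.all(np.abs(mc - exact) <= 2 * se + 1e-12)

    def test_negative_counts_rejected(self, tiny_atlas):
        with pytest.raises(ValueError):
            d.connectivity_permutation_test(
                np.array([-1.0, 0, 0, 0, 0, 0]), tiny_atlas.assignment
            )
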