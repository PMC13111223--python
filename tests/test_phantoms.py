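"""Phantom generators: geometry, electrodes, tensors, toy tractograms."""

import numpy as np
import pytest

import voxstim as vx
from voxstim.grids import AIR, COPPER, SPONGE, TISSUE_CODES, WHITE_MATTER
from voxstim.tensors import fractional_anisotropy, six_to_mat


class TestSlabPhantom:
    def test_single_layer_box(self):
        vol = vx.make_slab_phantom(1, ["white_matter"], [20.0], (20.0, 20.0),
                                   1.0)
        assert vol.shape == (20, 20, 20)
        assert np.all(vol.labels == WHITE_MATTER)

    def test_two_layer_z_split(self):
        vol = vx.make_slab_phantom(2, ["csf", "white_matter"], [10.0, 10.0],
                                   (20.0, 20.0), 1.0)
        assert np.all(vol.labels[:, :, :10] == TISSUE_CODES["csf"])
        assert np.all(vol.labels[:, :, 10:] == WHITE_MATTER)

    def test_half_mm_spacing_voxel_count(self):
        vol = vx.make_slab_phantom(
            3, ["skin", "csf", "white_matter"], [20.0, 20.0, 20.0],
            (20.0, 20.0), 0.5)
        assert vol.shape == (40, 40, 120)

    def test_incommensurate_spacing_rejected(self):
        with pytest.raises(ValueError, match="commensurate"):
            vx.make_slab_phantom(1, ["white_matter"], [20.0], (20.0, 20.0),
                                 0.3)


class TestSpherePhantom:
    RADII = (50.0, 45.0, 40.0, 35.0)
    LABELS = ["skin", "bone_cortical", "csf", "grey_matter"]

    def test_shell_volumes_match_analytic(self):
        """Shell voxel counts approximate analytic shell volumes to 5%."""
        vol = vx.make_layered_sphere_phantom(self.RADII, self.LABELS, 2.0)
        vox_vol = 8.0
        radii = list(self.RADII) + [0.0]
        for i, lab in enumerate(self.LABELS):
            count = int((vol.labels == TISSUE_CODES[lab]).sum())
            analytic = 4 / 3 * np.pi * (radii[i] ** 3 - radii[i + 1] ** 3) \
                / vox_vol
            assert abs(count - analytic) / analytic < 0.05

    def test_solid_ball_volume(self):
        vol = vx.make_layered_sphere_phantom([30.0], ["grey_matter"], 1.0)
        count = int((vol.labels == TISSUE_CODES["grey_matter"]).sum())
        analytic = 4 / 3 * np.pi * 30.0**3
        assert abs(count - analytic) / analytic < 0.05

    def test_volume_error_shrinks_linearly_with_spacing(self):
        """Voxelization error of the ball volume at least halves from
        2 mm to 1 mm spacing."""
        analytic = 4 / 3 * np.pi * 20.0**3
        errs = []
        for sp in (2.0, 1.0):
            vol = vx.make_layered_sphere_phantom([20.0], ["csf"], sp)
            v = (vol.labels == TISSUE_CODES["csf"]).sum() * sp**3
            errs.append(abs(v - analytic))
        assert errs[1] <= errs[0] / 2.0 * 1.05

    def test_subvoxel_sphere_keeps_center(self):
        vol = vx.make_layered_sphere_phantom([0.4], ["grey_matter"], 1.0)
        assert (vol.labels == TISSUE_CODES["grey_matter"]).sum() >= 1

    def test_nondecreasing_radii_rejected(self):
        with pytest.raises(ValueError, match="decreasing"):
            vx.make_layered_sphere_phantom([30.0, 30.0], ["skin", "csf"], 1.0)


class TestAttachElectrodes:
    def _slab(self):
        return vx.make_slab_phantom(1, ["white_matter"], [20.0],
                                    (40.0, 40.0), 1.0)

    def test_flat_pad_sponge_and_copper_counts(self):
        """30x30 mm pad, 5 mm sponge, 1 mm copper on a flat face."""
        e = vx.ElectrodeSpec("a", (20, 20, 20.0), (0, 0, 1.0), (30, 30),
                             1.0, 5.0, 1.0)
        c = vx.ElectrodeSpec("c", (20, 20, 0.0), (0, 0, -1.0), (30, 30),
                             1.0, 5.0, -1.0)
        volE = vx.attach_electrodes(self._slab(), [e, c])
        sponge, copper = volE.electrode_voxels["a"]
        assert len(sponge) == 30 * 30 * 5
        assert len(copper) == 30 * 30 * 1

    def test_opposite_pads_are_disjoint(self):
        e = vx.ElectrodeSpec("a", (20, 20, 20.0), (0, 0, 1.0), (30, 30),
                             1.0, 5.0, 1.0)
        c = vx.ElectrodeSpec("c", (20, 20, 0.0), (0, 0, -1.0), (30, 30),
                             1.0, 5.0, -1.0)
        volE = vx.attach_electrodes(self._slab(), [e, c])
        sa = {tuple(v) for arr in volE.electrode_voxels["a"] for v in arr}
        sc = {tuple(v) for arr in volE.electrode_voxels["c"] for v in arr}
        assert not sa & sc

    def test_no_tissue_overwritten(self):
        vol = self._slab()
        n_wm = (vol.labels == WHITE_MATTER).sum()
        e = vx.ElectrodeSpec("a", (20, 20, 20.0), (0, 0, 1.0), (30, 30),
                             1.0, 5.0, 1.0)
        c = vx.ElectrodeSpec("c", (20, 20, 0.0), (0, 0, -1.0), (30, 30),
                             1.0, 5.0, -1.0)
        volE = vx.attach_electrodes(vol, [e, c])
        assert (volE.labels == WHITE_MATTER).sum() == n_wm

    def test_overlapping_electrodes_rejected(self):
        e1 = vx.ElectrodeSpec("a", (20, 20, 20.0), (0, 0, 1.0), (30, 30),
                              1.0, 5.0, 1.0)
        e2 = vx.ElectrodeSpec("b", (22, 20, 20.0), (0, 0, 1.0), (30, 30),
                              1.0, 5.0, -1.0)
        with pytest.raises(ValueError, match="overlap"):
            vx.attach_electrodes(self._slab(), [e1, e2])

    def test_footprint_off_surface_rejected(self):
        e = vx.ElectrodeSpec("a", (200, 200, 20.0), (0, 0, 1.0), (30, 30),
                             1.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            vx.attach_electrodes(self._slab(), [e])

    def test_paper_default_pads_on_sphere(self):
        vol = vx.make_layered_sphere_phantom(
            (50.0, 45.0, 40.0), ["skin", "bone_cortical", "csf"], 2.0)
        a = vx.anode_spec((0, 0, 50.0), (0, 0, 1.0))
        c = vx.cathode_spec((0, 0, -50.0), (0, 0, -1.0))
        volE = vx.attach_electrodes(vol, [a, c])
        for name in ("anode", "cathode"):
            sponge, copper = volE.electrode_voxels[name]
            assert len(sponge) > 0 and len(copper) > 0
        # sponge layer must touch the skin somewhere
        sponge, _ = volE.electrode_voxels["anode"]
        below = sponge.copy()
        below[:, 2] -= 1
        touching = volE.labels[tuple(below.T)] == TISSUE_CODES["skin"]
        assert touching.any()


class TestFiberTensorField:
    def _wm_slab(self):
        return vx.make_slab_phantom(1, ["white_matter"], [10.0],
                                    (10.0, 10.0), 1.0)

    def test_major_eigenvector_and_fa(self):
        """lambda = (1.7, 0.3, 0.3)e-3 along x gives FA ~ 0.81."""
        lam = (1.7e-3, 0.3e-3, 0.3e-3)
        tf = vx.make_fiber_tensor_field(
            self._wm_slab(),
            [{"principal_direction": (1, 0, 0), "eigenvalues": lam}])
        mats = tf.matrices()
        ev, evec = np.linalg.eigh(mats)
        np.testing.assert_allclose(ev[:, 2], 1.7e-3, rtol=1e-12)
        major = evec[:, :, 2]
        np.testing.assert_allclose(np.abs(major[:, 0]), 1.0, atol=1e-10)
        # hand computation: FA = sqrt(1.5 * 1.306667) / sqrt(3.07) = 0.79902
        fa_expected = fractional_anisotropy(np.array(lam))
        assert abs(fa_expected - 0.79902) < 5e-5
        np.testing.assert_allclose(fractional_anisotropy(ev), fa_expected,
                                   rtol=1e-10)

    def test_isotropic_eigenvalues_ignore_direction(self):
        lam = (1e-3, 1e-3, 1e-3)
        t1 = vx.make_fiber_tensor_field(
            self._wm_slab(),
            [{"principal_direction": (1, 0, 0), "eigenvalues": lam}])
        t2 = vx.make_fiber_tensor_field(
            self._wm_slab(),
            [{"principal_direction": (0, 0.6, 0.8), "eigenvalues": lam}])
        np.testing.assert_allclose(t1.components, t2.components, atol=1e-18)

    def test_two_disjoint_bundles_piecewise_constant(self):
        vol = self._wm_slab()
        lam = (1.7e-3, 0.3e-3, 0.3e-3)
        left = {"principal_direction": (1, 0, 0), "eigenvalues": lam,
                "predicate": lambda p: p[:, 0] < 5.0}
        right = {"principal_direction": (0, 1, 0), "eigenvalues": lam,
                 "predicate": lambda p: p[:, 0] >= 5.0}
        tf = vx.make_fiber_tensor_field(vol, [left, right])
        assert tf.mask.all()
        # piecewise constant on either side of x = 5
        assert len(np.unique(tf.components[:5].reshape(-1, 6), axis=0)) == 1
        assert len(np.unique(tf.components[5:].reshape(-1, 6), axis=0)) == 1
        assert not np.array_equal(tf.components[0, 0, 0],
                                  tf.components[9, 0, 0])

    def test_spd_everywhere(self):
        tf = vx.make_fiber_tensor_field(
            self._wm_slab(),
            [{"principal_direction": (0.6, 0, 0.8),
              "eigenvalues": (1.7e-3, 0.4e-3, 0.2e-3)}])
        rep = vx.check_spd(tf)
        assert rep["n_failures"] == 0
        mats = tf.matrices()
        np.testing.assert_allclose(mats, np.swapaxes(mats, -1, -2),
                                   atol=0.0)

    def test_nonpositive_eigenvalue_rejected(self):
        with pytest.raises(ValueError, match="SPD|positive"):
            vx.make_fiber_tensor_field(
                self._wm_slab(),
                [{"principal_direction": (1, 0, 0),
                  "eigenvalues": (1e-3, 1e-4, -1e-5)}])


class TestToyTractogram:
    def _atlas(self):
        labels = np.zeros((10, 10, 4), dtype=np.int16)
        labels[1:4, 1:4, 1:3] = 1
        labels[6:9, 6:9, 1:3] = 2
        labels[6:9, 1:4, 1:3] = 3
        return vx.ParcelAtlas(labels, np.eye(4))

    def test_counts_reproduced_exactly(self):
        atlas = self._atlas()
        counts = {(1, 2): 3, (1, 3): 5}
        t = vx.make_toy_tractogram(atlas, counts, seed=9)
        assert len(t) == 8
        sc = vx.sc_matrix(t, atlas, weighting="raw_count")
        assert sc.edge(1, 2) == 3
        assert sc.edge(1, 3) == 5
        assert sc.edge(2, 3) == 0

    def test_all_zero_matrix_gives_empty_tractogram(self):
        t = vx.make_toy_tractogram(self._atlas(), np.zeros((3, 3), int),
                                   seed=0)
        assert len(t) == 0

    def test_same_seed_identical_geometry(self):
        atlas = self._atlas()
        counts = {(1, 2): 4}
        t1 = vx.make_toy_tractogram(atlas, counts, seed=77)
        t2 = vx.make_toy_tractogram(atlas, counts, seed=77)
        for a, b in zip(t1.streamlines, t2.streamlines):
            np.testing.assert_array_equal(a, b)

    def test_absent_parcel_rejected(self):
        with pytest.raises(ValueError, match="empty or absent"):
            vx.make_toy_tractogram(self._atlas(), {(1, 9): 2}, seed=0)


def test_generators_are_pure_functions_of_seed():
    """Bit-reproducibility of every randomized generator."""
    b1 = vx.make_cohort(3, 0.4, 1.0, seed=11)
    b2 = vx.make_cohort(3, 0.4, 1.0, seed=11)
    for a, b in zip(b1, b2):
        np.testing.assert_array_equal(a.labeled_volume.labels,
                                      b.labeled_volume.labels)
        np.testing.assert_array_equal(a.diffusion_tensors.components,
                                      b.diffusion_tensors.components)
        assert a.anisotropy_param == b.anisotropy_param
        for s1, s2 in zip(a.tractogram.streamlines, b.tractogram.streamlines):
            np.testing.assert_array_equal(s1, s2)
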