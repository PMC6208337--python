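"""Rigid transforms, registration, ion volumes, dissection, composites."""

import numpy as np
import pytest

from msi3d.errors import InputError, RegistrationError
from msi3d.volume3d import (
    IonVolume,
    RigidTransform,
    apply_transform,
    build_volume,
    composite_channels,
    estimate_rigid,
    register_stack,
    virtual_dissection,
)


def smooth_blob(n=64, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.exp(-(((xx - n / 2 + 6) / 8) ** 2 + ((yy - n / 2) / 12) ** 2))
    img += 0.7 * np.exp(-(((xx - n / 2 - 10) / 5) ** 2 + ((yy - n / 2 - 8) / 6) ** 2))
    return img + 0.01 * rng.random((n, n))


class TestRigidTransform:
    def test_identity_and_compose_inverse(self):
        t = RigidTransform(12.0, 3.5, -2.0)
        r = t.compose(t.inverse())
        assert r.rotation_deg == pytest.approx(0.0, abs=1e-12)
        assert np.hypot(*r.translation) == pytest.approx(0.0, abs=1e-12)

    def test_composition_order(self):
        a = RigidTransform(90.0, 1.0, 0.0)
        b = RigidTransform(0.0, 1.0, 0.0)
        # apply b (shift +x), then a (rotate 90 deg): shift becomes +y
        c = a.compose(b)
        assert c.translation[0] == pytest.approx(1.0, abs=1e-12)
        assert c.translation[1] == pytest.approx(1.0, abs=1e-12)

    def test_apply_identity_is_exact(self):
        img = smooth_blob()
        np.testing.assert_allclose(apply_transform(img, RigidTransform()), img)

    def test_roundtrip_and_mass_preservation(self):
        img = smooth_blob()
        t = RigidTransform(7.0, 2.0, -3.0)
        back = apply_transform(apply_transform(img, t), t.inverse())
        interior = np.s_[10:-10, 10:-10]
        err = np.linalg.norm(back[interior] - img[interior]) / np.linalg.norm(img[interior])
        assert err < 0.02
        moved = apply_transform(img, t)
        assert moved.sum() == pytest.approx(img.sum(), rel=0.01)


class TestEstimateRigid:
    def test_identity_pair(self):
        img = smooth_blob()
        t = estimate_rigid(img, img)
        assert abs(t.rotation_deg) <= 0.1
        assert np.hypot(*t.translation) <= 0.1
        assert t.ncc > 0.999

    def test_known_transform_recovered(self, reg_stack_study):
        study, _ = reg_stack_study
        img = study.sections[0].tic_image()
        true = RigidTransform(4.0, 3.0, -2.0)
        est = estimate_rigid(img, apply_transform(img, true))
        resid = est.compose(true)
        assert abs(resid.rotation_deg) < 0.5
        assert np.hypot(*resid.translation) < 0.5

    def test_blank_image_rejected(self):
        img = smooth_blob()
        with pytest.raises(RegistrationError):
            estimate_rigid(img, np.full_like(img, 3.0))
        with pytest.raises(InputError):
            estimate_rigid(img, img[:32, :32])


class TestRegisterStack:
    def test_prealigned_stack_stays_put(self):
        img = smooth_blob()
        transforms = register_stack([img, img, img])
        for t in transforms:
            assert abs(t.rotation_deg) <= 0.2
            assert np.hypot(*t.translation) <= 0.2

    def test_recovers_phantom_misalignments(self, reg_stack_study):
        study, truth = reg_stack_study
        keys = sorted(truth.true_transforms)
        estimated = register_stack([s.tic_image() for s in study])
        ref = truth.true_transforms[keys[0]]
        rot_err, trans_err = [], []
        for key, est in zip(keys, estimated):
            resid = est.compose(truth.true_transforms[key]).compose(ref.inverse())
            rot_err.append(abs(resid.rotation_deg))
            trans_err.append(np.hypot(*resid.translation))
        assert np.mean(rot_err) < 1.0
        assert np.mean(trans_err) < 1.0


class TestVolumes:
    def test_single_section_and_conservation(self):
        img = smooth_blob()
        vol = build_volume([img], z_spacing_um=204.0)
        assert vol.shape == (1, *img.shape)
        stack = [smooth_blob(seed=s) for s in range(4)]
        vol = build_volume(stack, 204.0)
        assert vol.data.sum() == pytest.approx(sum(im.sum() for im in stack))

    def test_volume_validation(self):
        with pytest.raises(InputError):
            build_volume([], 204.0)
        with pytest.raises(InputError):
            IonVolume(-np.ones((2, 3, 3)), (40, 40, 204))

    def test_dissection_constant_volume_and_axis_aligned_slab(self):
        const = IonVolume(np.full((6, 10, 10), 2.5), (40.0, 40.0, 204.0))
        plane = virtual_dissection(
            const, point_um=(180, 180, 510), normal_um=(0, 0, 1), half_extent_um=100
        )
        np.testing.assert_allclose(plane, 2.5)

        data = np.zeros((5, 8, 8))
        for z in range(5):
            data[z] = z + 1.0
        vol = IonVolume(data, (40.0, 40.0, 204.0))
        # plane z = 2 * 204 um exactly on a voxel layer -> slab values
        plane = virtual_dissection(vol, (140, 140, 2 * 204.0), (0, 0, 1), half_extent_um=120,
                                   step_um=40.0)
        inside = plane[plane > 0]
        np.testing.assert_allclose(inside, 3.0)

    def test_day3_shell_encloses_core(self, day3_volumes):
        """The margin-ion volume is one connected shell that encloses the
        core-ion volume (hollow turnip)."""
        from scipy import ndimage

        margin, core = day3_volumes[400.3], day3_volumes[518.3]
        shell = margin.data > 0.5 * margin.data.max()
        core_mask = core.data > 0.5 * core.data.max()
        assert core_mask.sum() > 0

        structure = np.ones((3, 3, 3))  # 26-connectivity
        labels, n = ndimage.label(shell, structure=structure)
        sizes = np.bincount(labels.ravel())[1:]
        assert sizes.max() / shell.sum() >= 0.95  # one connected shell

        free = ~shell
        border = np.zeros_like(free)
        border[[0, -1]] = border[:, [0, -1]] = border[:, :, [0, -1]] = True
        free_labels, _ = ndimage.label(free, structure=structure)
        outside = np.unique(free_labels[border & free])
        assert not np.isin(free_labels[core_mask], outside).any()

    def test_day3_longitudinal_dissection_shows_flanking_bands(self, day3_volumes):
        margin, core = day3_volumes[400.3], day3_volumes[518.3]
        nz, ny, nx = margin.data.shape
        vx, vy, vz = margin.voxel_size_um
        center = ((nx - 1) / 2 * vx, (ny - 1) / 2 * vy, (nz - 1) / 2 * vz)
        pm = virtual_dissection(margin, center, (0, 1, 0), step_um=vx)
        pc = virtual_dissection(core, center, (0, 1, 0), step_um=vx)
        bands = pm > 0.5 * pm.max()
        core_px = pc > 0.5 * pc.max()
        assert core_px.sum() > 0
        assert pm[bands].mean() > 3 * pm[core_px].mean()


class TestComposite:
    def test_single_channel_grayscale(self):
        vol = np.random.default_rng(0).random((3, 5, 5))
        rgb = composite_channels([vol], [(1.0, 1.0, 1.0)])
        scaled = (vol - vol.min()) / (vol.max() - vol.min())
        for c in range(3):
            np.testing.assert_allclose(rgb[..., c], scaled)

    def test_disjoint_channels_do_not_mix_and_overlap_is_pink(self):
        a = np.zeros((2, 6, 6))
        b = np.zeros((2, 6, 6))
        a[:, :3] = 1.0
        b[:, 4:] = 1.0
        rgb = composite_channels([a, b], [(1, 0, 0), (0, 0, 1)])
        assert rgb[0, 0, 0].tolist() == [1.0, 0.0, 0.0]
        assert rgb[0, 5, 0].tolist() == [0.0, 0.0, 1.0]

        b2 = np.zeros((2, 6, 6))
        b2[:, 2:4] = 1.0
        a2 = np.zeros((2, 6, 6))
        a2[:, :4] = 1.0
        rgb = composite_channels([a2, b2], [(1, 0, 0), (0, 0, 1)])
        both = (a2 > 0.5) & (b2 > 0.5)
        pink = (rgb[..., 0] > 0.5) & (rgb[..., 2] > 0.5)
        np.testing.assert_array_equal(pink, both)

    def test_mip(self):
        vol = np.zeros((4, 5, 5))
        vol[2, 1, 1] = 3.0
        img = composite_channels([vol], [(0, 1, 0)], mip_axis=0)
        assert img.shape == (5, 5, 3)
        assert img[1, 1, 1] == 1.0
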