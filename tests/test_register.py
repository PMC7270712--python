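"""Registration: NMI metric, rigid/affine recovery, FFD warps, chains."""

import numpy as np
import pytest

from rodentmri.images import Grid, VolumeImage, resample
from rodentmri.phantom import (
    PhantomSpec,
    apply_known_transform,
    make_head_phantom,
    make_slice_distortion,
)
from rodentmri.register import (
    apply_chain,
    compose,
    invert,
    nmi,
    register_affine,
    register_nonlinear,
    register_rigid,
    register_slicewise,
)
from rodentmri.transforms import (
    TransformChain,
    identity_transform,
    rigid_from_params,
    rigid_params_from_matrix,
    transform_deviation,
)


class TestNmi:
    def test_self_similarity_is_two(self, small_phantom):
        _, image, _ = small_phantom
        assert nmi(image, image) == pytest.approx(2.0, abs=1e-6)

    def test_symmetric(self, small_phantom, rng):
        _, image, _ = small_phantom
        other = VolumeImage(rng.random(image.shape) + 0.1, image.affine)
        assert nmi(image, other) == nmi(other, image)

    def test_independent_noise_has_nmi_near_one(self, rng):
        a = rng.random((64, 64, 64)) + 0.1
        b = rng.random((64, 64, 64)) + 0.1
        value = nmi(a, b)
        assert 1.0 < value <= 1.05

    def test_self_similarity_is_maximal(self, small_phantom, rng):
        _, image, _ = small_phantom
        self_score = nmi(image, image)
        for _ in range(3):
            other = VolumeImage(rng.random(image.shape) + 0.1, image.affine)
            assert self_score >= nmi(image, other)

    def test_empty_overlap_refused(self):
        a = np.zeros((8, 8, 8))
        b = np.zeros((8, 8, 8))
        a[:2] = 1.0
        b[-2:] = 1.0
        with pytest.raises(ValueError):
            nmi(a, b)

    def test_too_few_bins_refused(self, small_phantom):
        _, image, _ = small_phantom
        with pytest.raises(ValueError):
            nmi(image, image, bins=4)


class TestRigid:
    def test_identity_pair_recovers_identity(self, small_phantom):
        _, image, _ = small_phantom
        t = register_rigid(image, image)
        params = rigid_params_from_matrix(
            t, center=image.grid.world_center())
        assert np.abs(params[:3]).max() < 0.1  # degrees
        assert np.abs(params[3:]).max() < 0.05 * image.voxel_sizes.min()

    def test_known_transform_recovered(self, head_phantom):
        _, image, truth = head_phantom
        center = image.grid.world_center()
        true = rigid_from_params([0, 0, 7.0, 1.0, -0.6, 0.5], center=center)
        warped, _ = apply_known_transform(image, true, truth)
        est = register_rigid(image, warped)
        dev = transform_deviation(est, true, radius_mm=5.0, center=center)
        assert dev["rotation_deg"] <= 0.5
        assert dev["max_displacement_mm"] <= 0.25 * image.voxel_sizes.min() \
            + 5.0 * np.deg2rad(dev["rotation_deg"])

    def test_inverse_consistency(self, head_phantom):
        _, image, truth = head_phantom
        center = image.grid.world_center()
        true = rigid_from_params([0, 0, 5.0, 0.6, 0.4, 0.0], center=center)
        warped, _ = apply_known_transform(image, true, truth)
        fwd = register_rigid(image, warped)
        bwd = register_rigid(warped, image)
        composed = fwd @ bwd
        dev = transform_deviation(composed, identity_transform(),
                                  radius_mm=5.0, center=center)
        assert dev["rotation_deg"] <= 0.5
        assert dev["max_displacement_mm"] <= 0.25 * image.voxel_sizes.max()

    def test_deterministic(self, small_phantom):
        _, image, truth = small_phantom
        center = image.grid.world_center()
        true = rigid_from_params([0, 0, 4.0, 0.8, 0, 0], center=center)
        warped, _ = apply_known_transform(image, true, truth)
        a = register_rigid(image, warped)
        b = register_rigid(image, warped)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestAffine:
    def test_scale_and_rotation_recovered(self, head_phantom):
        from rodentmri.transforms import affine_from_params
        _, image, truth = head_phantom
        center = image.grid.world_center()
        true = affine_from_params(
            [0, 0, 5.0, 0.3, -0.2, 0.1, 0.0, np.log(1.08), 0.0, 0, 0, 0],
            center=center)
        warped, _ = apply_known_transform(image, true, truth)
        est = register_affine(image, warped)
        scales = np.linalg.svd(est.matrix[:3, :3], compute_uv=False)
        true_scales = np.sort(np.linalg.svd(true.matrix[:3, :3],
                                            compute_uv=False))
        np.testing.assert_allclose(np.sort(scales), true_scales, atol=0.02)
        rel = np.linalg.inv(est.matrix) @ true.matrix
        U, _, Vt = np.linalg.svd(rel[:3, :3])
        angle = np.rad2deg(np.arccos(np.clip(
            (np.trace(U @ Vt) - 1) / 2, -1, 1)))
        assert angle <= 0.5

    def test_affine_score_at_least_rigid_score(self, small_phantom):
        _, image, truth = small_phantom
        center = image.grid.world_center()
        true = rigid_from_params([0, 0, 6.0, 0.8, -0.4, 0], center=center)
        warped, _ = apply_known_transform(image, true, truth)
        rigid = register_rigid(image, warped)
        affine = register_affine(image, warped, init=rigid)
        def score(t):
            warped_src = resample(image, warped.grid, t, "trilinear")
            return nmi(warped_src, warped)
        assert score(affine) >= score(rigid) - 1e-9


class TestNonlinear:
    def _sinusoidal_field(self, grid, amp_voxels=1.5):
        from rodentmri.transforms import DisplacementField
        shape = grid.shape
        vox = grid.voxel_sizes
        ii, jj, kk = np.indices(shape, dtype=float)
        vecs = np.zeros(shape + (3,))
        vecs[..., 0] = amp_voxels * vox[0] * np.sin(
            2 * np.pi * ii / shape[0]) * np.cos(2 * np.pi * jj / shape[1])
        vecs[..., 1] = amp_voxels * vox[1] * np.cos(
            2 * np.pi * ii / shape[0]) * np.sin(2 * np.pi * kk / shape[2])
        vecs[..., 2] = 0.5 * amp_voxels * vox[2] * np.sin(
            2 * np.pi * jj / shape[1])
        return DisplacementField(vecs, grid.affine)

    def test_identity_pair_gives_tiny_field(self, small_phantom):
        _, image, _ = small_phantom
        field = register_nonlinear(image, image, max_level=1)
        rms = np.sqrt((field.vectors / image.voxel_sizes) ** 2
                      ).sum(axis=-1).mean()
        assert rms <= 0.05

    def test_known_smooth_warp_recovered(self, head_phantom):
        _, image, truth = head_phantom
        grid = image.grid
        true_field = self._sinusoidal_field(grid)
        warped = resample(image, grid, true_field, "trilinear")
        est = register_nonlinear(image, warped, max_level=3)
        brain = truth.brain_mask.data.astype(bool)
        diff = (est.vectors - true_field.vectors) / grid.voxel_sizes
        rms = np.sqrt((diff[brain] ** 2).sum(axis=-1).mean())
        assert rms <= 0.5

    def test_jacobian_strictly_positive(self, head_phantom):
        _, image, truth = head_phantom
        grid = image.grid
        true_field = self._sinusoidal_field(grid)
        warped = resample(image, grid, true_field, "trilinear")
        est = register_nonlinear(image, warped, max_level=2)
        jac = est.jacobian_determinant()[1:-1, 1:-1, 1:-1]
        assert np.all(jac > 0)

    def test_bad_level_refused(self, small_phantom):
        _, image, _ = small_phantom
        with pytest.raises(ValueError):
            register_nonlinear(image, image, max_level=0)


class TestSlicewise:
    def test_undistorted_pair_gives_tiny_warps(self, small_phantom):
        _, image, _ = small_phantom
        stack = register_slicewise(image, image)
        rms = np.sqrt((stack.inplane ** 2).sum(axis=-1)).mean()
        assert rms <= 0.05

    def test_known_quadratic_distortion_corrected(self, head_phantom):
        _, image, truth = head_phantom
        stack_true = make_slice_distortion(image.grid, max_voxels=2.0)
        distorted = resample(image, image.grid, stack_true, "trilinear")
        est = register_slicewise(distorted, image)
        brain = truth.brain_mask.data.astype(bool)
        resid = np.sqrt(((est.inplane - stack_true.inplane) ** 2
                         ).sum(axis=-1))
        assert resid[brain].mean() <= 0.5

    def test_empty_slice_keeps_identity_warp(self, head_phantom):
        _, image, _ = head_phantom
        stack = register_slicewise(image, image)
        assert not stack.inplane[:, :, 0].any()  # top/bottom slices empty
        assert not stack.inplane[:, :, -1].any()

    def test_z_mismatch_refused(self, small_phantom):
        _, image, _ = small_phantom
        cropped = VolumeImage(image.data[:, :, :-2], image.affine)
        with pytest.raises(ValueError):
            register_slicewise(image, cropped)


class TestChainsAndInversion:
    def test_chain_of_exact_inverses_is_identity_resampling(
            self, small_phantom):
        _, image, _ = small_phantom
        t = rigid_from_params([0, 0, 9.0, 0.5, 0.2, -0.1],
                              center=image.grid.world_center())
        chain = TransformChain([t, invert(t)])
        out = apply_chain(image, chain, image.grid)
        ref = resample(image, image.grid, identity_transform(), "trilinear")
        np.testing.assert_allclose(out.data, ref.data, atol=1e-6)

    def test_single_element_chain_equals_direct_application(
            self, small_phantom):
        _, image, _ = small_phantom
        t = rigid_from_params([0, 0, 4.0, 0.3, 0, 0],
                              center=image.grid.world_center())
        via_chain = apply_chain(image, TransformChain([t]), image.grid)
        direct = resample(image, image.grid, t, "trilinear")
        np.testing.assert_array_equal(via_chain.data, direct.data)

    def test_one_big_step_beats_sequential_resampling(self):
        """Analytic oracle: a closed-form smooth intensity function warped
        through two affines; composing and resampling once must be closer
        (L2) to the exact answer than resampling twice."""
        shape = (48, 48, 24)
        affine = np.diag([0.2, 0.2, 0.5, 1.0])
        grid = Grid(shape, affine)
        world = grid.world_grid()

        def f(points):
            blobs = [([2.0, 3.0, 2.0], 2.0), ([5.0, 4.0, 4.0], 1.5),
                     ([3.0, 6.0, 6.0], 1.0)]
            val = np.zeros(points.shape[1])
            for c, s in blobs:
                d2 = ((points - np.asarray(c)[:, None]) ** 2).sum(axis=0)
                val += np.exp(-d2 / (2 * s ** 2))
            return val

        image = VolumeImage(f(world).reshape(shape), affine)
        center = grid.world_center()
        t1 = rigid_from_params([0, 0, 11.0, 0.33, -0.21, 0.14],
                               center=center)
        t2 = rigid_from_params([4.0, -3.0, 0, -0.18, 0.27, 0.22],
                               center=center)
        chain = TransformChain([t1, t2])

        one_step = apply_chain(image, chain, grid).data
        first = resample(image, grid, t2, "trilinear")
        sequential = resample(first, grid, t1, "trilinear").data
        exact = f(t2.apply(t1.apply(world))).reshape(shape)

        interior = np.zeros(shape, dtype=bool)
        interior[4:-4, 4:-4, 2:-2] = True
        err_one = np.sqrt(((one_step - exact)[interior] ** 2).mean())
        err_seq = np.sqrt(((sequential - exact)[interior] ** 2).mean())
        assert err_one < err_seq

    def test_affine_inversion_exact(self):
        t = rigid_from_params([12, -7, 3, 1.2, -0.4, 0.9])
        np.testing.assert_allclose((t @ invert(t)).matrix, np.eye(4),
                                   atol=1e-10)

    def test_capped_field_inverts_within_tolerance(self, small_phantom):
        _, image, truth = small_phantom
        field = register_nonlinear(
            image,
            resample(image, image.grid,
                     self_field := TestNonlinear()._sinusoidal_field(
                         image.grid, amp_voxels=1.0), "trilinear"),
            max_level=2)
        inv_field = invert(field)
        pts = field.grid.world_grid()[:, ::11]
        rt = field.apply(inv_field.apply(pts))
        resid = np.sqrt(((rt - pts) ** 2).sum(axis=0))
        assert resid.mean() / image.voxel_sizes.min() <= 0.1
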