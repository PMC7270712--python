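"""BOLD preprocessing, coregistration, and template-space workflows."""

import numpy as np
import pytest

from rodentmri.images import Grid, LabelImage, SeriesImage, VolumeImage, \
    resample
from rodentmri.phantom import (
    PhantomSpec,
    make_head_phantom,
    simulate_bold_series,
)
from rodentmri.pipelines import (
    coregister,
    inverse_transform_towards_modality,
    realign,
    register_to_template,
    slice_timing_correct,
    temporal_mean,
    transform_modality_to_template,
)
from rodentmri.register import apply_chain
from rodentmri.transforms import TransformChain, rigid_from_params


def _epi_like(image, factor=2):
    grid = Grid(tuple(s // factor for s in image.shape),
                image.affine @ np.diag([factor, factor, factor, 1.0]))
    return resample(image, grid)


class TestSliceTiming:
    def _series(self, rng, n_t=6):
        data = rng.random((8, 8, 4, n_t))
        return SeriesImage(data, np.eye(4))

    def test_constant_series_unchanged(self):
        data = np.ones((6, 6, 4, 5)) * 3.0
        series = SeriesImage(data, np.eye(4))
        out = slice_timing_correct(series, [0, 1, 2, 3], 2.0)
        np.testing.assert_allclose(out.data, data, atol=1e-12)

    def test_linear_signal_exactly_interpolated(self):
        n_t = 8
        times = np.arange(n_t, dtype=float) * 2.0
        data = np.zeros((4, 4, 4, n_t))
        data[..., :] = 5.0 + 3.0 * times  # linear in time everywhere
        series = SeriesImage(data, np.eye(4))
        out = slice_timing_correct(series, [0, 1, 2, 3], 2.0)
        acq = np.array([0.0, 0.5, 1.0, 1.5])
        ref = np.median(acq)
        for z in range(4):
            shift = acq[z] - ref
            expected = 5.0 + 3.0 * np.clip(times + shift, 0, times[-1])
            np.testing.assert_allclose(out.data[0, 0, z], expected,
                                       atol=1e-9)

    def test_reference_slice_unchanged(self, rng):
        # odd slice count: the middle-of-acquisition slice is exactly the
        # reference and must pass through untouched
        data = rng.random((6, 6, 5, 6))
        series = SeriesImage(data, np.eye(4))
        out = slice_timing_correct(series, [0, 1, 2, 3, 4], 2.0)
        np.testing.assert_allclose(out.data[:, :, 2],
                                   series.data[:, :, 2], atol=1e-9)

    def test_invalid_slice_order_refused(self, rng):
        series = self._series(rng)
        with pytest.raises(ValueError):
            slice_timing_correct(series, [0, 1, 1, 3], 2.0)


class TestTemporalMean:
    def test_single_frame_is_that_frame(self, rng):
        data = rng.random((6, 6, 4, 1))
        series = SeriesImage(data, np.eye(4))
        np.testing.assert_array_equal(temporal_mean(series).data,
                                      data[..., 0])

    def test_two_frames_average_exactly(self, rng):
        a = rng.random((6, 6, 4))
        b = rng.random((6, 6, 4))
        series = SeriesImage(np.stack([a, b], axis=-1), np.eye(4))
        np.testing.assert_allclose(temporal_mean(series).data, (a + b) / 2)

    def test_identical_frames_reproduce_the_frame(self, rng):
        a = rng.random((6, 6, 4))
        series = SeriesImage(np.stack([a] * 5, axis=-1), np.eye(4))
        np.testing.assert_allclose(temporal_mean(series).data, a)


class TestRealign:
    def test_motion_free_series_reports_zero_motion(self, small_phantom):
        _, image, _ = small_phantom
        series, _ = simulate_bold_series(image, np.zeros((3, 6)))
        _, table = realign(series)
        np.testing.assert_array_equal(table[0], np.zeros(6))
        assert np.abs(table[1:, :3]).max() <= 0.1
        assert np.abs(table[1:, 3:]).max() <= 0.05 * image.voxel_sizes.min()

    def test_simulated_translations_recovered(self, head_phantom):
        _, image, _ = head_phantom
        vx = image.voxel_sizes
        motion = np.zeros((4, 6))
        motion[1, 3:] = [1.5 * vx[0], 0, 0]
        motion[2, 3:] = [0, -1.2 * vx[1], 0.8 * vx[2]]
        motion[3, 3:] = [-0.7 * vx[0], 0.9 * vx[1], 0]
        series, _ = simulate_bold_series(image, motion)
        _, table = realign(series)
        err_vox = (table[:, 3:] - motion[:, 3:]) / vx
        rms = np.sqrt((err_vox ** 2).mean())
        assert rms <= 0.25

    def test_realignment_sharpens_the_temporal_mean(self, small_phantom):
        _, image, _ = small_phantom
        vx = image.voxel_sizes
        rng = np.random.default_rng(8)
        motion = np.zeros((4, 6))
        motion[1:, 3:] = rng.uniform(-1.5, 1.5, (3, 3)) * vx
        series, _ = simulate_bold_series(image, motion)
        realigned, _ = realign(series)

        def gradient_energy(vol):
            return sum(np.sum(g ** 2) for g in np.gradient(vol))

        raw_mean = temporal_mean(series).data
        fixed_mean = temporal_mean(realigned).data
        assert gradient_energy(fixed_mean) > gradient_energy(raw_mean)

    def test_single_frame_refused(self, small_phantom):
        _, image, _ = small_phantom
        series = SeriesImage(image.data[..., None], image.affine)
        with pytest.raises(ValueError):
            realign(series)


class TestCoregister:
    def test_self_consistent_pair_aligns_nearly_identically(
            self, head_phantom):
        from rodentmri.evaluate import dice
        from rodentmri.preprocess import extract_brain
        _, image, _ = head_phantom
        epi = _epi_like(image)
        series, _ = simulate_bold_series(epi, np.zeros((3, 6)))
        result = coregister(image, series, modality="bold",
                            rigid_mode="rigid")
        rms = np.sqrt((result.slice_warps.inplane ** 2).sum(axis=-1)).mean()
        assert rms <= 0.1
        d = dice(extract_brain(result.anat_in_modality_space, "auto"),
                 extract_brain(result.modality_mean, "auto"))
        assert d >= 0.95

    def test_reorient_only_matches_rigid_when_motionless(self,
                                                         head_phantom):
        _, image, _ = head_phantom
        epi = _epi_like(image)
        series, _ = simulate_bold_series(epi, np.zeros((3, 6)))
        a = coregister(image, series, rigid_mode="rigid")
        b = coregister(image, series, rigid_mode="reorient_only")
        diff = np.abs(a.anat_in_modality_space.data
                      - b.anat_in_modality_space.data)
        # images agree except within interpolation distance of edges
        assert np.median(diff) < 1e-3
        assert b.rigid is None and a.rigid is not None

    def test_unknown_modality_refused(self, small_phantom):
        _, image, _ = small_phantom
        series, _ = simulate_bold_series(image, np.zeros((2, 6)))
        with pytest.raises(ValueError):
            coregister(image, series, modality="diffusion")


class TestTemplateSpace:
    def test_identical_anat_and_template_give_near_identity_chain(
            self, small_phantom):
        _, image, _ = small_phantom
        chain = register_to_template(image, image, nonlinear_levels=1)
        warped = apply_chain(image, chain, image.grid)
        interior = np.abs(warped.data - image.data)[3:-3, 3:-3, 2:-2]
        assert np.percentile(interior, 95) <= 0.1

    def test_one_big_step_equals_explicit_chain(self, small_phantom):
        from rodentmri.pipelines import CoregResult
        from rodentmri.phantom import make_slice_distortion
        _, image, _ = small_phantom
        grid = image.grid
        warps = make_slice_distortion(grid, max_voxels=0.5)
        rigid = rigid_from_params([0, 0, 3.0, 0.4, 0, 0],
                                  center=grid.world_center())
        coreg = CoregResult(anat_in_modality_space=image,
                            slice_warps=warps, modality_mean=image,
                            rigid=rigid)
        anat_chain = TransformChain([rigid_from_params(
            [0, 0, -2.0, 0, 0.3, 0], center=grid.world_center())])
        one_step = transform_modality_to_template(image, coreg, anat_chain,
                                                  grid)
        explicit = apply_chain(
            image,
            TransformChain(list(anat_chain.elements) + [rigid, warps]),
            grid)
        np.testing.assert_array_equal(one_step.data, explicit.data)

    def test_round_trip_template_modality_template(self, small_phantom):
        from rodentmri.pipelines import CoregResult
        _, image, truth = small_phantom
        grid = image.grid
        # smooth template-space image: the round trip interpolates twice,
        # so the contract is stated for smooth content
        world = grid.world_grid()
        c = grid.world_center()
        smooth_vals = np.exp(-((world - c[:, None]) ** 2).sum(axis=0) / 8.0)
        smooth = VolumeImage(smooth_vals.reshape(grid.shape), grid.affine)
        from rodentmri.phantom import make_slice_distortion
        warps = make_slice_distortion(grid, max_voxels=0.4)
        rigid = rigid_from_params([0, 0, 2.0, 0.2, -0.1, 0],
                                  center=grid.world_center())
        coreg = CoregResult(anat_in_modality_space=image,
                            slice_warps=warps, modality_mean=image,
                            rigid=rigid)
        anat_chain = TransformChain([rigid_from_params(
            [0, 0, -1.0, 0.1, 0, 0], center=grid.world_center())])
        down = inverse_transform_towards_modality(smooth, coreg, anat_chain)
        back = transform_modality_to_template(down, coreg, anat_chain, grid)
        brain = truth.brain_mask.data.astype(bool)
        err = np.abs(back.data - smooth.data)[brain]
        assert err.mean() <= 0.02 * np.ptp(smooth.data)

    def test_labels_survive_inverse_transport_without_new_labels(
            self, small_phantom):
        from rodentmri.pipelines import CoregResult
        from rodentmri.phantom import make_slice_distortion
        _, image, truth = small_phantom
        grid = image.grid
        warps = make_slice_distortion(grid, max_voxels=0.5)
        coreg = CoregResult(anat_in_modality_space=image,
                            slice_warps=warps, modality_mean=image,
                            rigid=None)
        anat_chain = TransformChain([rigid_from_params(
            [0, 0, 1.5, 0.2, 0, 0], center=grid.world_center())])
        atlas = truth.tissue_labels
        moved = inverse_transform_towards_modality(
            atlas, coreg, anat_chain, interpolation="nearest")
        assert isinstance(moved, LabelImage)
        assert set(np.unique(moved.data)) <= set(np.unique(atlas.data))


class TestDeterminismAndCache:
    def test_coregister_is_bit_deterministic(self, small_phantom):
        _, image, _ = small_phantom
        epi = _epi_like(image)
        series, _ = simulate_bold_series(epi, np.zeros((2, 6)))
        a = coregister(image, series, rigid_mode="reorient_only")
        b = coregister(image, series, rigid_mode="reorient_only")
        np.testing.assert_array_equal(a.anat_in_modality_space.data,
                                      b.anat_in_modality_space.data)
        np.testing.assert_array_equal(a.slice_warps.inplane,
                                      b.slice_warps.inplane)

    def test_memoized_rerun_equals_fresh_run(self, small_phantom, tmp_path):
        _, image, _ = small_phantom
        epi = _epi_like(image)
        series, _ = simulate_bold_series(epi, np.zeros((2, 6)))
        fresh = coregister(image, series, rigid_mode="reorient_only")
        first = coregister(image, series, rigid_mode="reorient_only",
                           workdir=tmp_path)
        cached = coregister(image, series, rigid_mode="reorient_only",
                            workdir=tmp_path)
        assert list(tmp_path.glob("*.pkl"))
        for a, b in ((first, cached), (fresh, cached)):
            np.testing.assert_array_equal(a.anat_in_modality_space.data,
                                          b.anat_in_modality_space.data)
            np.testing.assert_array_equal(a.slice_warps.inplane,
                                          b.slice_warps.inplane)
            np.testing.assert_array_equal(a.modality_mean.data,
                                          b.modality_mean.data)
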