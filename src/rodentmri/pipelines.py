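"""Ready-to-use workflows: within-subject coregistration and template space.

Two pipelines cover the common study layouts:

* :func:`coregister` — align an anatomical scan with another modality
  (BOLD or FAIR perfusion) in the individual's space.  BOLD series get
  optional slice-timing correction, rigid realignment to the first volume
  and a temporal mean; perfusion series contribute their fitted
  equilibrium-magnetization (M0) map as the representative volume.  The
  anatomical image is reoriented to the modality axes, optionally
  rigid-aligned, and the residual EPI distortion is corrected slice by
  slice.

* :func:`register_to_template` plus
  :func:`transform_modality_to_template` — match the anatomical to a
  reference template (rigid -> affine on brain-masked images -> nonlinear
  on whole heads) and carry any modality image into template space through
  the whole chain (per-slice warps, rigid, anatomical warp) in a single
  "one big step" resampling;
  :func:`inverse_transform_towards_modality` runs the inverted chain to
  bring template-space images (atlases, statistical maps) back to the
  individual's modality space.

Steps accept a ``workdir`` for content-hash memoization: a cache hit
returns exactly what a fresh run computes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._cache import cached_call
from .images import (
    MaskImage,
    SeriesImage,
    VolumeImage,
    reorient_like,
    resample,
)
from .register import (
    apply_chain,
    register_affine,
    register_nonlinear,
    register_rigid,
    register_slicewise,
)
from .transforms import (
    AffineTransform,
    SliceWarpStack,
    TransformChain,
    identity_transform,
    invert,
    rigid_params_from_matrix,
)

__all__ = [
    "CoregResult",
    "slice_timing_correct",
    "realign",
    "temporal_mean",
    "coregister",
    "register_to_template",
    "transform_modality_to_template",
    "inverse_transform_towards_modality",
]


@dataclass
class CoregResult:
    """Within-subject anatomical-to-modality alignment."""

    anat_in_modality_space: VolumeImage
    slice_warps: SliceWarpStack
    modality_mean: VolumeImage
    rigid: AffineTransform | None = None  # anatomical -> modality (pull)


def slice_timing_correct(bold: SeriesImage, slice_order,
                         repetition_time: float) -> SeriesImage:
    """Interpolate each voxel time-series to the reference slice's timing.

    ``slice_order`` lists slice indices in acquisition order; acquisition
    is assumed evenly spread over the repetition time.  The reference is
    the middle of acquisition, interpolation is linear in time, and the
    first/last frames are clamped.
    """
    if repetition_time <= 0:
        raise ValueError("repetition_time must be positive")
    nz = bold.shape[2]
    order = list(slice_order)
    if sorted(order) != list(range(nz)):
        raise ValueError("slice_order must be a permutation of the z indices")
    n_t = bold.n_frames
    acq_time = np.empty(nz)
    for pos, z in enumerate(order):
        acq_time[z] = pos / nz * repetition_time
    ref_time = np.median(acq_time)
    times = np.arange(n_t, dtype=float) * repetition_time
    out = np.empty_like(bold.data)
    for z in range(nz):
        shift = acq_time[z] - ref_time
        sample_at = np.clip(times + shift, times[0], times[-1])
        # linear interpolation of the (x, y, t) block along t
        lo = np.clip(np.floor(sample_at / repetition_time).astype(int),
                     0, n_t - 1)
        hi = np.clip(lo + 1, 0, n_t - 1)
        w = np.where(hi > lo, sample_at / repetition_time - lo, 0.0)
        block = bold.data[:, :, z, :]
        out[:, :, z, :] = block[..., lo] * (1 - w) + block[..., hi] * w
    return SeriesImage(out, bold.affine, list(bold.frame_metadata))


def realign(bold: SeriesImage, metric: str = "ssd"
            ) -> tuple[SeriesImage, np.ndarray]:
    """Rigid-register every frame to the first and resample.

    Frames of one series share contrast, so the default metric is the sum
    of squared differences (``"nmi"`` available).  Returns the realigned
    series and the (T, 6) motion table — rotations (deg) and translations
    (mm) about the grid centre; frame 0 is exactly zero.
    """
    if bold.n_frames < 2:
        raise ValueError("realignment needs at least 2 frames")
    grid = bold.grid
    center = grid.world_center()
    first = bold.frame(0)
    frames = [first.data]
    params = [np.zeros(6)]
    for t in range(1, bold.n_frames):
        frame = bold.frame(t)
        try:
            q = register_rigid(frame, first, metric=metric)
        except Exception as exc:
            raise RuntimeError(f"realignment failed at frame {t}: {exc}"
                               ) from exc
        frames.append(resample(frame, grid, q, "trilinear").data)
        params.append(rigid_params_from_matrix(invert(q), center=center))
    series = SeriesImage(np.stack(frames, axis=-1), bold.affine,
                         list(bold.frame_metadata))
    return series, np.vstack(params)


def temporal_mean(bold: SeriesImage, method: str = "mean") -> VolumeImage:
    """Voxelwise temporal mean (or median) of a 4D series."""
    if method == "mean":
        data = bold.data.mean(axis=3)
    elif method == "median":
        data = np.median(bold.data, axis=3)
    else:
        raise ValueError("method must be 'mean' or 'median'")
    return VolumeImage(data, bold.affine)


def _representative_volume(modality_series, modality, slice_order,
                           repetition_time, realign_metric):
    if modality == "bold":
        series = modality_series
        if slice_order is not None:
            series = slice_timing_correct(series, slice_order,
                                          repetition_time)
        realigned, motion = realign(series, metric=realign_metric)
        return temporal_mean(realigned), {"motion": motion}
    if modality == "perfusion":
        from .perfusion import FairSeries, fit_inversion_recovery, m0_map
        if not isinstance(modality_series, FairSeries):
            raise TypeError("perfusion coregistration needs a FairSeries")
        fit = fit_inversion_recovery(modality_series)
        return m0_map(fit), {"fit": fit}
    raise ValueError("modality must be 'bold' or 'perfusion'")


def coregister(anat: VolumeImage, modality_series, modality: str = "bold",
               rigid_mode: str = "rigid", slice_order=None,
               repetition_time: float | None = None,
               anat_mask: MaskImage | None = None,
               realign_metric: str = "ssd", slice_warp_levels: int = 2,
               workdir=None) -> CoregResult:
    """Align an anatomical image with a BOLD or perfusion series.

    The modality's representative volume (temporal mean of the realigned
    BOLD, or fitted M0 for perfusion) defines the target space.  The
    anatomical image is reoriented — without resampling — to the modality
    axes; with ``rigid_mode="rigid"`` a modality-to-anatomical rigid
    transform is estimated and its inverse applied to the anatomical,
    while ``"reorient_only"`` assumes negligible inter-scan motion.
    Finally each slice of the modality is registered nonlinearly to the
    matching anatomical slice, correcting EPI distortion.
    """
    if rigid_mode not in ("rigid", "reorient_only"):
        raise ValueError("rigid_mode must be 'rigid' or 'reorient_only'")

    def _run():
        repr_vol, _extras = _representative_volume(
            modality_series, modality, slice_order, repetition_time,
            realign_metric)
        anat_reor = reorient_like(anat, repr_vol)
        if rigid_mode == "rigid":
            # modality -> structural transform; its inverse carries the
            # structural image into the modality space
            fwd = register_rigid(repr_vol, anat_reor,
                                 target_mask=anat_mask)
            anat_in_mod = resample(anat_reor, repr_vol.grid, invert(fwd),
                                   "trilinear")
            rigid = fwd
        else:
            anat_in_mod = resample(anat_reor, repr_vol.grid, None,
                                   "trilinear")
            rigid = None
        warps = register_slicewise(repr_vol, anat_in_mod,
                                   max_level=slice_warp_levels)
        return CoregResult(anat_in_modality_space=anat_in_mod,
                           slice_warps=warps, modality_mean=repr_vol,
                           rigid=rigid)

    key = ("coregister", anat, modality_series, modality, rigid_mode,
           slice_order, repetition_time, anat_mask, realign_metric,
           slice_warp_levels)
    return cached_call(workdir, key, _run)


def register_to_template(anat: VolumeImage, template: VolumeImage,
                         anat_mask: MaskImage | None = None,
                         template_mask: MaskImage | None = None,
                         nonlinear_levels: int = 2,
                         workdir=None) -> TransformChain:
    """Anatomical-to-template chain: rigid -> affine -> nonlinear.

    The linear stages use brain-masked images (masks are auto-extracted
    when not supplied); the nonlinear stage runs on whole heads.  The
    returned chain maps template world coordinates to the individual's
    anatomical space (pull convention) and resamples in one step.
    """

    def _auto_mask(image):
        from .preprocess import extract_brain
        try:
            return extract_brain(image, "auto")
        except ValueError:
            return None

    def _run():
        a_mask = anat_mask or _auto_mask(anat)
        t_mask = template_mask or _auto_mask(template)
        affine = register_affine(anat, template, source_mask=a_mask,
                                 target_mask=t_mask)
        # an affine indistinguishable from identity is snapped to identity
        # so the nonlinear stage is not fed a needlessly resampled image
        world = template.grid.world_grid()[:, ::17]
        max_disp = np.abs(affine.apply(world) - world).max()
        if max_disp < 0.05 * float(template.voxel_sizes.min()):
            affine = identity_transform()
            anat_aff = anat if anat.grid.matches(template.grid) \
                else resample(anat, template.grid, None, "trilinear")
        else:
            anat_aff = resample(anat, template.grid, affine, "trilinear")
        warp = register_nonlinear(anat_aff, template,
                                  max_level=nonlinear_levels)
        return TransformChain([warp, affine])

    key = ("register_to_template", anat, template, anat_mask, template_mask,
           nonlinear_levels)
    return cached_call(workdir, key, _run)


def _full_chain(coreg: CoregResult, anat_chain: TransformChain
                ) -> TransformChain:
    elements = list(anat_chain.elements)
    if coreg.rigid is not None:
        elements.append(coreg.rigid)
    elements.append(coreg.slice_warps)
    return TransformChain(elements)


def transform_modality_to_template(modality_image, coreg: CoregResult,
                                   anat_chain: TransformChain, reference,
                                   interpolation: str = "trilinear"):
    """Carry a modality-space image onto the template grid in one step.

    The per-slice distortion warps, the modality-to-anatomical rigid
    transform and the anatomical-to-template chain are composed and the
    image is interpolated exactly once.
    """
    return apply_chain(modality_image, _full_chain(coreg, anat_chain),
                       reference, interpolation)


def inverse_transform_towards_modality(image_in_template, coreg: CoregResult,
                                       anat_chain: TransformChain,
                                       interpolation: str = "trilinear"):
    """Bring a template-space image back into the individual's modality
    space (atlas propagation, for example), inverting every element of the
    composite chain and applying them in reverse order with one
    resampling."""
    chain = _full_chain(coreg, anat_chain).invert()
    return apply_chain(image_in_template, chain, coreg.modality_mean.grid,
                       interpolation)
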