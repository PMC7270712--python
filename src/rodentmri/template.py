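"""Iterative group-wise registration and study-template construction.

A study template is built by the classic multi-level scheme: start from a
rough average of bias-corrected heads centred on their brain-mask
centroids, then repeatedly register every subject to the current template
and re-average, increasing the degrees of freedom of the transform as the
template sharpens (centroid -> rigid -> affine -> nonlinear).  Each
subject accumulates a transform chain, applied in one resampling step, so
the final template and the per-subject mappings into it come from a single
interpolation of the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .images import Grid, MaskImage, VolumeImage, image_centroid, resample
from .register import (
    apply_chain,
    nmi,
    register_affine,
    register_nonlinear,
    register_rigid,
)
from .transforms import AffineTransform, TransformChain, identity_transform

__all__ = [
    "TemplateStage",
    "TemplateSchedule",
    "TemplateResult",
    "intensity_normalize",
    "initialize_template",
    "build_template",
    "default_schedule",
]

_DOF_RANK = {"centroid": 0, "rigid6": 1, "affine12": 2, "nonlinear": 3}


@dataclass(frozen=True)
class TemplateStage:
    transform_kind: str  # centroid | rigid6 | affine12 | nonlinear
    iterations: int = 1
    max_level: int = 1  # only used by nonlinear stages

    def __post_init__(self):
        if self.transform_kind not in _DOF_RANK:
            raise ValueError(f"unknown transform kind {self.transform_kind!r}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass(frozen=True)
class TemplateSchedule:
    """Ordered stages with non-decreasing degrees of freedom."""

    stages: tuple
    convergence_tol: float = 1e-4

    def __post_init__(self):
        stages = tuple(self.stages)
        if not stages:
            raise ValueError("schedule needs at least one stage")
        if stages[0].transform_kind != "centroid":
            raise ValueError("first stage must be centroid alignment")
        ranks = [_DOF_RANK[s.transform_kind] for s in stages]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise ValueError("degrees of freedom must not decrease along "
                             "the schedule")
        object.__setattr__(self, "stages", stages)


def default_schedule() -> TemplateSchedule:
    """centroid -> rigid x2 -> affine x2 -> nonlinear (levels 1, 2)."""
    return TemplateSchedule(stages=(
        TemplateStage("centroid"),
        TemplateStage("rigid6", iterations=2),
        TemplateStage("affine12", iterations=2),
        TemplateStage("nonlinear", iterations=1, max_level=1),
        TemplateStage("nonlinear", iterations=1, max_level=2),
    ))


@dataclass
class TemplateResult:
    template: VolumeImage
    per_subject_chains: dict
    convergence_log: list = field(default_factory=list)


def intensity_normalize(image: VolumeImage, mask: MaskImage) -> VolumeImage:
    """Scale an image so its median intensity within the mask is 1."""
    med = float(np.median(image.data[mask.data.astype(bool)]))
    if med == 0:
        raise ValueError("median intensity within the mask is zero")
    return VolumeImage(image.data / med, image.affine)


def _centroid_translation(mask: MaskImage, grid: Grid) -> AffineTransform:
    """Pull transform mapping template-grid world to subject world so the
    subject's mask centroid lands at the grid centre."""
    offset = image_centroid(mask) - grid.world_center()
    m = np.eye(4)
    m[:3, 3] = offset
    return AffineTransform(m, "rigid6")


def _average(images: list, trim: bool = False) -> np.ndarray:
    stack = np.stack([im.data for im in images], axis=-1)
    if trim and stack.shape[-1] > 2:
        stack = np.sort(stack, axis=-1)[..., 1:-1]  # drop min and max
    return stack.mean(axis=-1)


def initialize_template(images, masks, grid: Grid | None = None,
                        trim: bool = False) -> VolumeImage:
    """Rough first template: centroid-centred average of normalized heads."""
    if len(images) < 2:
        raise ValueError("template construction needs at least 2 subjects")
    if len(masks) != len(images):
        raise ValueError("need one mask per image")
    grid = grid or images[0].grid
    centred = []
    for img, mask in zip(images, masks):
        norm = intensity_normalize(img, mask)
        t = _centroid_translation(mask, grid)
        centred.append(resample(norm, grid, t, "trilinear"))
    return VolumeImage(_average(centred, trim), grid.affine)


def build_template(images, masks, schedule: TemplateSchedule | None = None,
                   grid: Grid | None = None, trim: bool = False,
                   metric: str = "nmi", reg_maxiter: int = 15
                   ) -> TemplateResult:
    """Run the full multi-level iterative template construction.

    ``images`` should already be bias corrected.  Per stage and iteration,
    every subject is registered to the current template with the stage's
    transform kind (prepending to that subject's chain), resampled in one
    step from its original image, and the normalized average becomes the
    new template.  A stage iteration stops early when the mean voxelwise
    relative template change drops below the schedule's tolerance.  The
    log records, per iteration, the stage, the mean relative change, and
    the mean pairwise NMI of the aligned subjects.
    """
    schedule = schedule or default_schedule()
    if len(images) < 2:
        raise ValueError("template construction needs at least 2 subjects")
    grid = grid or images[0].grid
    normalized = [intensity_normalize(img, mask)
                  for img, mask in zip(images, masks)]
    chains = {i: TransformChain([]) for i in range(len(images))}
    template = None
    log = []

    for stage_idx, stage in enumerate(schedule.stages):
        for it in range(stage.iterations):
            tpl_mask = _template_mask(template)
            aligned = []
            for i, (img, mask) in enumerate(zip(normalized, masks)):
                if stage.transform_kind == "centroid":
                    t = _centroid_translation(mask, grid)
                    chains[i] = TransformChain([t])
                else:
                    try:
                        current = apply_chain(img, chains[i], grid) \
                            if len(chains[i]) else resample(img, grid)
                        cur_mask = _warp_mask(mask, chains[i], grid)
                        if stage.transform_kind == "rigid6":
                            t = register_rigid(current, template,
                                               source_mask=cur_mask,
                                               target_mask=tpl_mask,
                                               metric=metric,
                                               maxiter=reg_maxiter)
                        elif stage.transform_kind == "affine12":
                            # subjects reach this stage already rigid-
                            # aligned, so the affine search starts from
                            # identity
                            t = register_affine(current, template,
                                                source_mask=cur_mask,
                                                target_mask=tpl_mask,
                                                metric=metric,
                                                maxiter=reg_maxiter,
                                                init=identity_transform())
                        else:
                            t = register_nonlinear(current, template,
                                                   max_level=stage.max_level)
                    except Exception as exc:
                        raise RuntimeError(
                            f"subject {i}: {stage.transform_kind} "
                            f"registration failed: {exc}") from exc
                    # guarded update: never let a stage worsen a subject's
                    # similarity to the current template
                    candidate = TransformChain(
                        [t] + list(chains[i].elements))
                    new_img = apply_chain(img, candidate, grid)
                    if nmi(new_img, template) >= nmi(current, template):
                        chains[i] = candidate
                try:
                    aligned.append(apply_chain(img, chains[i], grid))
                except Exception as exc:
                    raise RuntimeError(
                        f"subject {i}: applying chain failed: {exc}"
                    ) from exc
            new_template = VolumeImage(_average(aligned, trim), grid.affine)
            if template is None:
                change = np.inf
            else:
                denom = np.abs(template.data).mean()
                change = float(np.abs(new_template.data - template.data
                                      ).mean() / max(denom, 1e-12))
            template = new_template
            log.append({
                "stage": stage_idx,
                "kind": stage.transform_kind,
                "iteration": it,
                "mean_relative_change": change,
                "mean_pairwise_nmi": _mean_pairwise_nmi(aligned),
            })
            if change < schedule.convergence_tol:
                break
    return TemplateResult(template=template, per_subject_chains=chains,
                          convergence_log=log)


def _template_mask(template: VolumeImage | None) -> MaskImage | None:
    if template is None:
        return None
    from .preprocess import extract_brain
    try:
        return extract_brain(template, "auto")
    except ValueError:
        return None


def _warp_mask(mask: MaskImage, chain: TransformChain,
               grid: Grid) -> MaskImage | None:
    if not len(chain):
        return mask
    warped = apply_chain(mask, chain, grid, interpolation="nearest")
    if not warped.data.any():
        return None
    return MaskImage(warped.data, grid.affine)


def _mean_pairwise_nmi(images: list) -> float:
    vals = []
    for i in range(len(images)):
        for j in range(i + 1, len(images)):
            vals.append(nmi(images[i], images[j]))
    return float(np.mean(vals)) if vals else np.nan
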