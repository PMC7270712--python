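"""Seeded synthetic rodent-head phantoms with known ground truth.

Every pipeline stage in this package is validated against data whose truth
is known by construction: an ellipsoidal "head" with a bright skull/scalp
shell, a brain with a cortex-like bright rim, a mid-intensity interior and
dark ventricle-like inclusions; smooth multiplicative bias fields; rigid /
affine / nonlinear deformations; frame-wise subject motion; and FAIR
inversion-recovery signal series with known T1, M0 and CBF.  All generators
are pure functions of their spec and seed.

The default geometry (64 x 64 x 32 voxels at 0.2 x 0.2 x 0.5 mm) mimics the
strongly anisotropic multislice acquisitions typical of rodent imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .images import Grid, LabelImage, MaskImage, SeriesImage, VolumeImage, resample
from .transforms import AffineTransform, SliceWarpStack, rigid_from_params

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_head_phantom",
    "make_bias_field",
    "apply_known_transform",
    "simulate_fair_series",
    "simulate_bold_series",
    "make_slice_distortion",
    "make_perfusion_ground_truth",
    "TISSUE_LABELS",
]

# intensity levels relative to the cortex-like shell (= 1.0); the skull is
# deliberately brighter than cortex so histogram-based extraction sees two
# separable tissue modes above background
SKULL_INTENSITY = 1.3
CORTEX_INTENSITY = 1.0
INTERIOR_INTENSITY = 0.75
VENTRICLE_INTENSITY = 0.25
CSF_GAP_INTENSITY = 0.02

TISSUE_LABELS = {1: "skull_scalp", 2: "cortex_shell", 3: "interior",
                 4: "ventricle"}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic head."""

    grid_shape: tuple = (64, 64, 32)
    voxel_sizes: tuple = (0.2, 0.2, 0.5)
    brain_semiaxes: tuple = (4.0, 4.4, 5.0)  # mm, (RL, AP, IS)
    skull_thickness: float = 0.5  # mm
    csf_gap: float = 1.0  # mm between brain surface and skull (> z voxel)
    ventricle_fraction: float = 0.04  # fraction of brain volume
    asymmetry: float = 0.0  # 0..1 left-right intensity skew
    texture_amplitude: float = 0.15  # smooth within-brain intensity modulation
    noise_sigma: float = 0.0  # fraction of cortex intensity
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or len(self.voxel_sizes) != 3:
            raise ValueError("grid_shape and voxel_sizes must have 3 entries")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.ventricle_fraction <= 1:
            raise ValueError("ventricle_fraction must be in [0, 1]")
        fov = np.asarray(self.grid_shape) * np.asarray(self.voxel_sizes)
        outer = (np.asarray(self.brain_semiaxes) + self.csf_gap
                 + self.skull_thickness)
        if np.any(2 * outer >= fov):
            raise ValueError(
                f"head (semiaxes {self.brain_semiaxes} mm + shell) does not "
                f"fit in the {tuple(fov)} mm field of view"
            )

    @property
    def affine(self) -> np.ndarray:
        """Axis-aligned RAS affine centred on the world origin."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_sizes)
        aff[:3, 3] = -(np.asarray(self.grid_shape) - 1) / 2.0 * np.asarray(
            self.voxel_sizes
        )
        return aff

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.affine)


@dataclass
class GroundTruth:
    """Everything known by construction about a generated phantom."""

    brain_mask: MaskImage
    tissue_labels: LabelImage
    applied_transform: object | None = None
    bias_field: VolumeImage | None = None
    motion_params: np.ndarray | None = None
    t1_map: VolumeImage | None = None
    m0_map: VolumeImage | None = None
    cbf_map: VolumeImage | None = None
    warnings: list = field(default_factory=list)


def _normalized_radius(spec: PhantomSpec, semiaxes_mm) -> np.ndarray:
    """Ellipsoidal radius (1.0 on the surface) on the phantom grid, in mm."""
    shape = spec.grid_shape
    vox = np.asarray(spec.voxel_sizes)
    center = (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.indices(shape, dtype=float)
    x = (ii - center[0]) * vox[0]
    y = (jj - center[1]) * vox[1]
    z = (kk - center[2]) * vox[2]
    a = np.asarray(semiaxes_mm, dtype=float)
    return np.sqrt((x / a[0]) ** 2 + (y / a[1]) ** 2 + (z / a[2]) ** 2)


def make_head_phantom(spec: PhantomSpec) -> tuple[VolumeImage, GroundTruth]:
    """Build the synthetic head and its ground truth.

    The head consists of concentric ellipsoids: brain (cortex-like shell,
    interior, ventricle-like inclusions), a near-zero CSF gap, and a bright
    skull/scalp shell.  Background is ~0.  Identical specs (including seed)
    give bit-identical output.
    """
    a = np.asarray(spec.brain_semiaxes, dtype=float)
    r_brain = _normalized_radius(spec, a)
    r_gap = _normalized_radius(spec, a + spec.csf_gap)
    r_skull = _normalized_radius(spec, a + spec.csf_gap + spec.skull_thickness)

    brain = r_brain <= 1.0
    cortex = brain & (r_brain > 0.82)
    interior = brain & ~cortex
    gap = (r_gap <= 1.0) & ~brain
    skull = (r_skull <= 1.0) & (r_gap > 1.0)

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[skull] = 1
    labels[cortex] = 2
    labels[interior] = 3

    data = np.zeros(spec.grid_shape, dtype=float)
    data[skull] = SKULL_INTENSITY
    data[cortex] = CORTEX_INTENSITY
    data[interior] = INTERIOR_INTENSITY
    data[gap] = CSF_GAP_INTENSITY

    if spec.ventricle_fraction > 0:
        # two lateral-ventricle-like ellipsoids, mirrored about the mid-x plane
        scale = (spec.ventricle_fraction / 2) ** (1.0 / 3.0)
        v_ax = a * scale
        center = (np.asarray(spec.grid_shape) - 1) / 2.0
        vox = np.asarray(spec.voxel_sizes)
        ii, jj, kk = np.indices(spec.grid_shape, dtype=float)
        for side in (-1.0, 1.0):
            cx = side * 0.35 * a[0]
            x = (ii - center[0]) * vox[0] - cx
            y = (jj - center[1]) * vox[1] - 0.1 * a[1]
            z = (kk - center[2]) * vox[2]
            rv = np.sqrt((x / v_ax[0]) ** 2 + (y / v_ax[1]) ** 2
                         + (z / v_ax[2]) ** 2)
            vent = rv <= 1.0
            data[vent] = VENTRICLE_INTENSITY
            labels[vent] = 4

    if spec.texture_amplitude > 0:
        # deterministic internal "anatomy": piecewise-constant pseudo-
        # structures carved from a smooth harmonic field, so nonlinear warps
        # are identifiable inside the brain while intensities stay discrete
        # (real brains are near-piecewise-constant compartments).  Even in
        # (x - centre), keeping the noise-free symmetric phantom exactly
        # mirror-symmetric.
        center = (np.asarray(spec.grid_shape) - 1) / 2.0
        ii, jj, kk = np.indices(spec.grid_shape, dtype=float)
        tx = np.cos(2 * np.pi * (ii - center[0]) / 16.0)
        ty = np.sin(2 * np.pi * (jj - center[1]) / 18.0)
        tz = np.sin(2 * np.pi * (kk - center[2]) / 7.0)
        harmonic = 0.6 * tx * ty + 0.4 * ty * tz
        quantized = np.clip(np.floor((harmonic + 1.0) * 2.0), 0, 3)  # 4 levels
        texture = 1.0 + spec.texture_amplitude * (quantized - 1.5) / 1.5
        data *= np.where(brain, texture, 1.0)

    if spec.asymmetry > 0:
        center = (np.asarray(spec.grid_shape) - 1) / 2.0
        ii = np.indices(spec.grid_shape, dtype=float)[0]
        x_norm = (ii - center[0]) * spec.voxel_sizes[0] / a[0]
        data *= np.where(brain, 1.0 + spec.asymmetry * 0.2 * x_norm, 1.0)

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(
            0.0, spec.noise_sigma * CORTEX_INTENSITY, size=data.shape
        )

    affine = spec.affine
    image = VolumeImage(data, affine)
    truth = GroundTruth(
        brain_mask=MaskImage(brain.astype(np.uint8), affine),
        tissue_labels=LabelImage(labels, affine, label_names=dict(TISSUE_LABELS)),
    )
    return image, truth


def make_bias_field(spec: PhantomSpec, amplitude: float,
                    order: int = 2) -> VolumeImage:
    """Smooth multiplicative bias field with mean exactly 1 over the grid.

    Built from a low-order polynomial in normalised coordinates with
    seeded coefficients, then centred (mean 0) and scaled so the deviation
    from 1 never exceeds ``amplitude``.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    shape = spec.grid_shape
    if amplitude == 0:
        return VolumeImage(np.ones(shape), spec.affine)
    rng = np.random.default_rng(spec.seed + 7919)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    raw = np.zeros(shape)
    for px in range(order + 1):
        for py in range(order + 1 - px):
            for pz in range(order + 1 - px - py):
                if px == py == pz == 0:
                    continue
                raw += rng.normal() * xx ** px * yy ** py * zz ** pz
    raw -= raw.mean()
    peak = np.abs(raw).max()
    if peak > 0:
        raw *= amplitude / peak
    return VolumeImage(1.0 + raw, spec.affine)


def apply_known_transform(image: VolumeImage, transform,
                          ground_truth: GroundTruth
                          ) -> tuple[VolumeImage, GroundTruth]:
    """Warp a phantom and its ground truth consistently, recording the truth.

    The image is resampled trilinearly and the mask/labels with nearest
    neighbour through the *same* pull transform.  If more than 10% of the
    brain leaves the field of view a warning is recorded on the returned
    ground truth.
    """
    grid = image.grid
    warped = resample(image, grid, transform, "trilinear")
    mask = resample(ground_truth.brain_mask, grid, transform, "nearest")
    labels = resample(ground_truth.tissue_labels, grid, transform, "nearest")
    warnings_list = list(ground_truth.warnings)
    lost = 1.0 - mask.data.sum() / max(ground_truth.brain_mask.data.sum(), 1)
    if lost > 0.10:
        warnings_list.append(
            f"transform moved {lost:.0%} of the brain outside the field of view"
        )
    truth = GroundTruth(
        brain_mask=MaskImage(mask.data, grid.affine, allow_empty=True),
        tissue_labels=labels,
        applied_transform=transform,
        bias_field=ground_truth.bias_field,
        motion_params=ground_truth.motion_params,
        t1_map=ground_truth.t1_map,
        m0_map=ground_truth.m0_map,
        cbf_map=ground_truth.cbf_map,
        warnings=warnings_list,
    )
    return warped, truth


def simulate_fair_series(t1_sel_map: VolumeImage, t1_ns_map: VolumeImage,
                         m0_map: VolumeImage,
                         inversion_times: Sequence[float],
                         inversion_efficiency: float = 1.0,
                         noise_sigma: float = 0.0, seed: int = 0):
    """Simulate paired FAIR inversion-recovery series.

    Each voxel/frame carries the magnitude inversion-recovery signal
    ``|M0 (1 - 2 a exp(-TI/T1))|`` (its own T1 per series) plus optional
    Gaussian noise.  Returns ``(selective, nonselective)`` FairSeries.
    """
    from .perfusion import FairSeries  # local import avoids a cycle

    tis = np.asarray(inversion_times, dtype=float)
    if tis.ndim != 1 or len(tis) < 3:
        raise ValueError("need at least 3 inversion times")
    if np.any(np.diff(tis) <= 0) or np.any(tis <= 0):
        raise ValueError("inversion times must be positive and increasing")
    if not 0.5 <= inversion_efficiency <= 1.0:
        raise ValueError("inversion efficiency must be in [0.5, 1]")
    m0 = m0_map.data
    brain = m0 > 0
    rng = np.random.default_rng(seed)
    out = []
    for tag, t1_map in (("selective", t1_sel_map), ("nonselective", t1_ns_map)):
        t1 = t1_map.data
        if np.any(t1[brain] <= 0):
            raise ValueError(f"nonpositive T1 inside the brain ({tag} series)")
        frames = np.zeros(m0.shape + (len(tis),))
        with np.errstate(divide="ignore", invalid="ignore"):
            for i, ti in enumerate(tis):
                decay = np.where(brain, np.exp(-ti / np.where(brain, t1, 1.0)),
                                 0.0)
                signal = np.abs(m0 * (1.0 - 2.0 * inversion_efficiency * decay))
                frames[..., i] = np.where(brain, signal, 0.0)
        if noise_sigma > 0:
            frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
        out.append(FairSeries(frames, m0_map.affine, list(tis), labeling_tag=tag))
    return out[0], out[1]


def simulate_bold_series(base_volume: VolumeImage, motion_params,
                         noise_sigma: float = 0.0, seed: int = 0
                         ) -> tuple[SeriesImage, GroundTruth]:
    """Motion-corrupted BOLD-like series from a base volume.

    ``motion_params`` is (T, 6): per-frame (rx, ry, rz) degrees and
    (tx, ty, tz) mm, applied about the grid centre.  Frame 0 must be the
    identity (all zeros), matching realignment-to-first-volume semantics.
    """
    params = np.asarray(motion_params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion_params must be (n_frames, 6)")
    if np.any(params[0] != 0):
        raise ValueError("frame-0 motion must be exactly zero")
    grid = base_volume.grid
    center = grid.world_center()
    rng = np.random.default_rng(seed)
    frames = []
    for t in range(params.shape[0]):
        if np.all(params[t] == 0):
            frame = base_volume.data.copy()
        else:
            transform = rigid_from_params(params[t], center=center)
            frame = resample(base_volume, grid, transform, "trilinear").data
        frames.append(frame)
    data = np.stack(frames, axis=-1)
    if noise_sigma > 0:
        data = data + rng.normal(0.0, noise_sigma, size=data.shape)
    series = SeriesImage(data, grid.affine)
    mask_data = (np.abs(base_volume.data)
                 > 0.5 * INTERIOR_INTENSITY).astype(np.uint8)
    truth = GroundTruth(
        brain_mask=MaskImage(mask_data, grid.affine, allow_empty=True),
        tissue_labels=LabelImage(mask_data.astype(np.int32), grid.affine),
        motion_params=params,
    )
    return series, truth


def make_slice_distortion(grid: Grid, max_voxels: float = 2.0,
                          axis: int = 0) -> SliceWarpStack:
    """Known quadratic in-plane EPI-like distortion, varying per slice.

    Displacement along ``axis`` grows quadratically from the slice centre,
    with per-slice amplitude ramping from half to full ``max_voxels``.
    """
    nx, ny, nz = grid.shape
    ii, jj = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    cu, cv = (nx - 1) / 2.0, (ny - 1) / 2.0
    u = (ii - cu) / cu
    v = (jj - cv) / cv
    inplane = np.zeros((nx, ny, nz, 2))
    for k in range(nz):
        amp = max_voxels * (0.5 + 0.5 * k / max(nz - 1, 1))
        base = u ** 2 - 0.5 * v ** 2  # smooth, quadratic, zero-ish mean
        inplane[:, :, k, axis] = amp * base / np.abs(base).max()
    return SliceWarpStack(inplane, grid.affine)


def make_perfusion_ground_truth(spec: PhantomSpec, t1_ns: float = 1.5,
                                m0: float = 1000.0,
                                cbf_values=(120.0, 300.0),
                                lambda_ml_per_g: float = 0.9):
    """Two-region CBF phantom: T1/M0/CBF maps plus a region label map.

    The brain is split into anterior/posterior halves carrying the two CBF
    values; the selective-inversion apparent T1 follows the FAIR
    difference-of-rates relation 1/T1_sel = 1/T1_ns + CBF / (6000 lambda).
    """
    _, truth = make_head_phantom(spec)
    brain = truth.brain_mask.data.astype(bool)
    shape = spec.grid_shape
    regions = np.zeros(shape, dtype=np.int32)
    half = shape[1] // 2
    regions[:, :half, :][brain[:, :half, :]] = 1
    regions[:, half:, :][brain[:, half:, :]] = 2
    cbf = np.zeros(shape)
    cbf[regions == 1] = cbf_values[0]
    cbf[regions == 2] = cbf_values[1]
    t1_ns_map = np.where(brain, t1_ns, 0.0)
    with np.errstate(divide="ignore"):
        inv_sel = np.where(brain, 1.0 / t1_ns + cbf / (6000.0 * lambda_ml_per_g),
                           0.0)
    t1_sel_map = np.where(brain, 1.0 / np.where(brain, inv_sel, 1.0), 0.0)
    m0_map = np.where(brain, m0, 0.0)
    aff = spec.affine
    return {
        "t1_sel_map": VolumeImage(t1_sel_map, aff),
        "t1_ns_map": VolumeImage(t1_ns_map, aff),
        "m0_map": VolumeImage(m0_map, aff),
        "cbf_map": VolumeImage(cbf, aff),
        "regions": LabelImage(regions, aff,
                              label_names={1: "anterior", 2: "posterior"}),
        "brain_mask": truth.brain_mask,
        "lambda_ml_per_g": lambda_ml_per_g,
    }
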