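"""Intensity-based spatial registration.

Rigid and full-affine registration maximise normalised mutual information
(NMI) over a three-level multiresolution pyramid with a derivative-free
Powell search per level, so results are deterministic — there is no
stochastic restart anywhere.  Nonlinear registration is a coarse-to-fine
cubic B-spline free-form deformation whose control-point displacements are
capped at 0.4 x the control spacing, the classic sufficient condition for
the deformation to stay diffeomorphic (positive Jacobian everywhere).  A
per-slice 2D variant of the same machinery corrects EPI distortion.

All returned transforms use the pull convention (reference world -> moving
world); see :mod:`rodentmri.transforms`.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, optimize

from .images import Grid, MaskImage, VolumeImage, resample
from .transforms import (
    AffineTransform,
    DisplacementField,
    SliceWarpStack,
    TransformChain,
    affine_from_params,
    compose,
    identity_transform,
    invert,
    rigid_from_params,
    rigid_params_from_matrix,
    transform_deviation,
)

__all__ = [
    "nmi",
    "register_rigid",
    "register_affine",
    "register_nonlinear",
    "register_slicewise",
    "apply_chain",
    "compose",
    "invert",
]


# ---------------------------------------------------------------------------
# Similarity metrics


def _entropy(p: np.ndarray) -> float:
    p = np.sort(p[p > 0])  # fixed summation order keeps nmi(A,B)==nmi(B,A)
    return float(-(p * np.log(p)).sum())


def _nmi_arrays(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    overlap = (a != 0) & (b != 0)
    if not overlap.any():
        raise ValueError("images have no overlapping nonzero support")
    av = a[overlap]
    bv = b[overlap]
    a_lim = np.percentile(av, [1, 99])
    b_lim = np.percentile(bv, [1, 99])
    if a_lim[0] == a_lim[1]:
        a_lim = (a_lim[0] - 0.5, a_lim[1] + 0.5)
    if b_lim[0] == b_lim[1]:
        b_lim = (b_lim[0] - 0.5, b_lim[1] + 0.5)
    hist, _, _ = np.histogram2d(
        np.clip(av, *a_lim), np.clip(bv, *b_lim), bins=bins,
        range=(tuple(a_lim), tuple(b_lim)),
    )
    total = hist.sum()
    if total == 0:
        raise ValueError("empty joint histogram")
    p_ab = hist / total
    h_a = _entropy(p_ab.sum(axis=1))
    h_b = _entropy(p_ab.sum(axis=0))
    h_ab = _entropy(p_ab.ravel())
    if h_ab == 0:
        return 2.0
    return (h_a + h_b) / h_ab


def nmi(image_a, image_b, bins: int = 32) -> float:
    """Normalised mutual information (H(A)+H(B))/H(A,B) in (0, 2].

    Computed from a joint histogram over the overlap of the two images'
    nonzero supports, with per-image intensity limits at the 1st-99th
    percentiles.  Accepts images on a shared grid or plain arrays of equal
    shape; higher means more similar, and NMI(X, X) = 2.
    """
    if bins < 8:
        raise ValueError("bins must be >= 8")
    a = image_a.data if hasattr(image_a, "affine") else np.asarray(image_a)
    b = image_b.data if hasattr(image_b, "affine") else np.asarray(image_b)
    if a.shape != b.shape:
        raise ValueError("nmi requires images on the same grid")
    return _nmi_arrays(a, b, bins)


def _ssd_score(a: np.ndarray, b: np.ndarray) -> float:
    overlap = (a != 0) | (b != 0)
    n = overlap.sum()
    if n == 0:
        raise ValueError("images have no nonzero support")
    diff = a[overlap] - b[overlap]
    return -float((diff ** 2).mean())


# ---------------------------------------------------------------------------
# Linear registration


def _downsample(data: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return data
    smoothed = ndimage.gaussian_filter(data, sigma=factor / 2.0)
    return smoothed[::factor, ::factor, ::factor]


def _level_image(image: VolumeImage, factor: int) -> VolumeImage:
    if factor == 1:
        return image
    data = _downsample(image.data, factor)
    affine = image.affine @ np.diag([factor, factor, factor, 1.0])
    return VolumeImage(data, affine)


def _masked(image: VolumeImage, mask: MaskImage | None) -> VolumeImage:
    if mask is None:
        return image
    return VolumeImage(image.data * mask.data, image.affine)


def _intensity_centroid(image: VolumeImage) -> np.ndarray:
    w = np.abs(image.data)
    total = w.sum()
    if total == 0:
        raise ValueError("cannot centre an all-zero image")
    com = np.array(ndimage.center_of_mass(w))
    return image.affine[:3, :3] @ com + image.affine[:3, 3]


def _centroid(image: VolumeImage, mask: MaskImage | None) -> np.ndarray:
    if mask is not None and mask.data.any():
        from .images import image_centroid
        return image_centroid(mask)
    return _intensity_centroid(image)


def _sample_through(source: VolumeImage, grid: Grid, transform,
                    world: np.ndarray | None = None) -> np.ndarray:
    if world is None:
        world = grid.world_grid()
    world = transform.apply(world)
    inv = np.linalg.inv(source.affine)
    coords = inv[:3, :3] @ world + inv[:3, 3:4]
    return ndimage.map_coordinates(source.data, coords, order=1,
                                   mode="constant", cval=0.0
                                   ).reshape(grid.shape)


def _register_linear(source, target, source_mask, target_mask, metric,
                     n_params, init_params, center, levels, maxiter):
    src = _masked(source, source_mask)
    tgt = _masked(target, target_mask)
    t0 = _centroid(src, source_mask) - _centroid(tgt, target_mask)

    def build(params):
        p = np.asarray(params, dtype=float)
        full = p.copy()
        full[3:6] = p[3:6] + t0
        if n_params == 6:
            return rigid_from_params(full, center=center)
        return affine_from_params(full, center=center)

    def score_fn(params, src_l, tgt_l, world=None):
        warped = _sample_through(src_l, tgt_l.grid, build(params), world)
        try:
            if metric == "nmi":
                return _nmi_arrays(warped, tgt_l.data, 32)
            return _ssd_score(warped, tgt_l.data)
        except ValueError:
            return -np.inf

    params = np.asarray(init_params, dtype=float)
    scales = np.ones(n_params)
    scales[:3] = 2.0  # degrees per unit step
    if n_params == 12:
        scales[6:] = 0.05  # log-scale / shear per unit step
    # drop pyramid levels that would leave fewer than ~8 voxels along an
    # axis — a 12-parameter search is unconstrained on such grids
    levels = [f for f in levels
              if f == 1 or min(tgt.shape) // f >= 8] or [1]
    finest = min(levels)
    for factor in levels:
        src_l = _level_image(src, factor)
        tgt_l = _level_image(tgt, factor)
        world_l = tgt_l.grid.world_grid()
        scales[3:6] = float(np.min(tgt_l.voxel_sizes))  # mm per unit step
        # the finest level only polishes the coarse solution
        level_maxiter = max(2, maxiter // 8) if factor == finest and \
            len(levels) > 1 else maxiter

        def neg(q):
            return -score_fn(q * scales, src_l, tgt_l, world_l)

        res = optimize.minimize(
            neg, params / scales, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": level_maxiter},
        )
        params = res.x * scales
    # a coarse level can drag the search away from an already-good
    # initialisation; never return something worse than the start point
    final_score = score_fn(params, src, tgt)
    init_score = score_fn(init_params, src, tgt)
    if init_score > final_score:
        params = np.asarray(init_params, dtype=float)
        final_score = init_score
    identity_score = score_fn(np.zeros(n_params), src, tgt)
    if final_score < identity_score - 1e-9:
        warnings.warn(
            "registration failed to improve over the centroid-aligned "
            "start; returning the best transform found",
            stacklevel=3,
        )
    return build(params)


def register_rigid(source: VolumeImage, target: VolumeImage,
                   source_mask: MaskImage | None = None,
                   target_mask: MaskImage | None = None,
                   metric: str = "nmi", levels=(4, 2, 1),
                   maxiter: int = 25) -> AffineTransform:
    """Rigid (6-dof) registration of ``source`` onto ``target``.

    The similarity metric (NMI by default; ``"ssd"`` for same-contrast
    data) is maximised over a multiresolution pyramid after centroid
    pre-alignment.  When masks are given the metric sees the masked
    ("brain extracted") images, but the returned transform applies to
    whole-head geometry: it maps target world coordinates to source world
    coordinates, ready for :func:`rodentmri.images.resample`.
    """
    center = target.grid.world_center()
    result = _register_linear(source, target, source_mask, target_mask,
                              metric, 6, np.zeros(6), center, levels, maxiter)
    # re-tag as rigid (construction guarantees orthonormality)
    return AffineTransform(result.matrix, "rigid6")


def register_affine(source: VolumeImage, target: VolumeImage,
                    source_mask: MaskImage | None = None,
                    target_mask: MaskImage | None = None,
                    metric: str = "nmi", levels=(4, 2, 1),
                    maxiter: int = 60,
                    init: AffineTransform | None = None) -> AffineTransform:
    """Full affine (12-dof) registration, initialised at the rigid solution.

    The 12-parameter search needs more line-search cycles than the rigid
    one to decouple rotation from shear, hence the larger default budget.
    """
    center = target.grid.world_center()
    if init is None:
        init = register_rigid(source, target, source_mask, target_mask,
                              metric, levels, min(maxiter, 25))
    src = _masked(source, source_mask)
    tgt = _masked(target, target_mask)
    t0 = _centroid(src, source_mask) - _centroid(tgt, target_mask)
    rigid_params = rigid_params_from_matrix(init, center=center)
    init_params = np.zeros(12)
    init_params[:6] = rigid_params
    init_params[3:6] -= t0
    return _register_linear(source, target, source_mask, target_mask,
                            metric, 12, init_params, center, levels, maxiter)


# ---------------------------------------------------------------------------
# Nonlinear registration (cubic B-spline free-form deformation)


def _bspline3(u: np.ndarray) -> np.ndarray:
    au = np.abs(u)
    out = np.zeros_like(au)
    inner = au <= 1
    outer = (au > 1) & (au < 2)
    out[inner] = 2.0 / 3.0 - au[inner] ** 2 + 0.5 * au[inner] ** 3
    out[outer] = (2.0 - au[outer]) ** 3 / 6.0
    return out


def _bspline_weight_matrix(n: int, spacing: float) -> np.ndarray:
    """(n x m) cubic B-spline weights of m control points at spacing voxels.

    Control point a sits at voxel position (a - 1) * spacing, giving one
    ring of points outside each edge of the grid.
    """
    m = int(np.ceil((n - 1) / spacing)) + 3
    i = np.arange(n, dtype=float)[:, None]
    a = np.arange(m, dtype=float)[None, :]
    return _bspline3(i / spacing - (a - 1))


def _dense_field_3d(coeffs: np.ndarray, Wx, Wy, Wz) -> np.ndarray:
    tmp = np.tensordot(Wx, coeffs, axes=([1], [0]))      # (nx, my, mz, 3)
    tmp = np.tensordot(Wy, tmp, axes=([1], [1]))         # (ny, nx, mz, 3)
    tmp = np.tensordot(Wz, tmp, axes=([1], [2]))         # (nz, ny, nx, 3)
    return np.transpose(tmp, (2, 1, 0, 3))


def _project_to_coeffs_3d(voxelwise: np.ndarray, Wx, Wy, Wz) -> np.ndarray:
    tmp = np.tensordot(Wx.T, voxelwise, axes=([1], [0]))
    tmp = np.tensordot(Wy.T, tmp, axes=([1], [1]))
    tmp = np.tensordot(Wz.T, tmp, axes=([1], [2]))
    return np.transpose(tmp, (2, 1, 0, 3))


def _normalize_to(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Scale source so its robust foreground level matches the target's."""
    s_fg = source[source > 0]
    t_fg = target[target > 0]
    if s_fg.size == 0 or t_fg.size == 0:
        return source
    s_med = np.median(s_fg)
    t_med = np.median(t_fg)
    if s_med <= 0:
        return source
    return source * (t_med / s_med)


def _ffd_level_3d(source_data: np.ndarray, target_data: np.ndarray,
                  spacing: np.ndarray, cap_ratio: float,
                  maxiter: int, reg_weight: float = 1e-3) -> np.ndarray:
    """Optimise one FFD level (SSD metric); returns dense voxel-unit field.

    A small L2 penalty on the displacement (``reg_weight`` x the target's
    mean squared intensity, per squared voxel) anchors the metric's null
    space: in textureless regions the image similarity cannot determine
    the warp, and without the penalty the field would drift freely there.
    """
    shape = target_data.shape
    Wx = _bspline_weight_matrix(shape[0], spacing[0])
    Wy = _bspline_weight_matrix(shape[1], spacing[1])
    Wz = _bspline_weight_matrix(shape[2], spacing[2])
    m_shape = (Wx.shape[1], Wy.shape[1], Wz.shape[1], 3)
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    grads = np.gradient(source_data)
    n_vox = idx.shape[1]
    lam = reg_weight * float((target_data ** 2).mean())

    def cost_grad(flat):
        coeffs = flat.reshape(m_shape)
        disp = _dense_field_3d(coeffs, Wx, Wy, Wz)
        coords = idx + disp.reshape(-1, 3).T
        warped = ndimage.map_coordinates(source_data, coords, order=1,
                                         mode="constant", cval=0.0)
        r = warped - target_data.ravel()
        cost = float((r ** 2).mean()) + lam * float((disp ** 2).mean())
        g = np.empty((n_vox, 3))
        for axis in range(3):
            g[:, axis] = ndimage.map_coordinates(grads[axis], coords, order=1,
                                                 mode="constant", cval=0.0)
        voxelwise = (2.0 / n_vox) * (r[:, None] * g
                                     + lam * disp.reshape(-1, 3))
        grad = _project_to_coeffs_3d(voxelwise.reshape(shape + (3,)),
                                     Wx, Wy, Wz)
        return cost, grad.ravel()

    bounds_per_axis = cap_ratio * spacing
    lower = np.tile(-bounds_per_axis, int(np.prod(m_shape[:3])))
    upper = -lower
    res = optimize.minimize(
        cost_grad, np.zeros(int(np.prod(m_shape))), jac=True,
        method="L-BFGS-B", bounds=np.column_stack([lower, upper]),
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
    )
    coeffs = res.x.reshape(m_shape)
    return _dense_field_3d(coeffs, Wx, Wy, Wz)


def _compose_voxel_fields(d_new: np.ndarray, d_prev: np.ndarray) -> np.ndarray:
    """d_total(x) = d_new(x) + d_prev(x + d_new(x)) (voxel units)."""
    shape = d_new.shape[:3]
    idx = np.indices(shape, dtype=float).reshape(3, -1)
    coords = idx + d_new.reshape(-1, 3).T
    out = d_new.copy().reshape(-1, 3)
    for axis in range(3):
        out[:, axis] += ndimage.map_coordinates(
            d_prev[..., axis], coords, order=1, mode="constant", cval=0.0
        )
    return out.reshape(shape + (3,))


def _apply_voxel_field(data: np.ndarray, d_vox: np.ndarray) -> np.ndarray:
    idx = np.indices(data.shape, dtype=float).reshape(3, -1)
    coords = idx + d_vox.reshape(-1, 3).T
    return ndimage.map_coordinates(data, coords, order=1, mode="constant",
                                   cval=0.0).reshape(data.shape)


def register_nonlinear(source: VolumeImage, target: VolumeImage,
                       max_level: int = 2, cap_ratio: float = 0.4,
                       maxiter: int = 80,
                       reg_weight: float = 1e-3) -> DisplacementField:
    """Multi-level nonlinear registration (cubic B-spline FFD).

    ``source`` must be affinely pre-aligned; it is resampled onto the
    target grid if necessary.  Control-grid spacing starts at a quarter of
    the field of view and halves at each of ``max_level`` levels; each
    level minimises the voxelwise squared-intensity difference (after
    robust intensity matching) with L-BFGS-B under the 0.4 x spacing
    displacement cap, and consecutive level fields are composed so the
    result stays a diffeomorphism.  The emitted field has strictly positive
    discrete Jacobian determinant at every interior voxel.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    if not source.grid.matches(target.grid):
        source = resample(source, target.grid, None, "trilinear")
    src = _normalize_to(source.data, target.data)
    tgt = target.data
    shape = np.asarray(tgt.shape, dtype=float)
    d_total = None
    level_history = []
    for level in range(1, max_level + 1):
        spacing = np.maximum(shape / 4.0 / (2 ** (level - 1)), 2.0)
        level_history.append(
            [float(s * v) for s, v in zip(spacing, target.voxel_sizes)]
        )
        src_level = src if d_total is None else _apply_voxel_field(src, d_total)
        d_new = _ffd_level_3d(src_level, tgt, spacing, cap_ratio, maxiter,
                              reg_weight)
        d_total = d_new if d_total is None else \
            _compose_voxel_fields(d_new, d_total)
    vectors = np.einsum("ab,ijkb->ijka", target.affine[:3, :3], d_total)
    field = DisplacementField(vectors, target.affine,
                              level_history=level_history)
    jac = field.jacobian_determinant()[1:-1, 1:-1, 1:-1]
    if np.any(jac <= 0):
        raise RuntimeError(
            f"nonlinear registration produced a folded field "
            f"({(jac <= 0).sum()} interior voxels with nonpositive Jacobian)"
        )
    return field


# ---------------------------------------------------------------------------
# Per-slice 2D nonlinear registration (EPI distortion correction)


def _dense_field_2d(coeffs, Wx, Wy):
    tmp = np.tensordot(Wx, coeffs, axes=([1], [0]))
    tmp = np.tensordot(Wy, tmp, axes=([1], [1]))
    return np.transpose(tmp, (1, 0, 2))


def _project_to_coeffs_2d(voxelwise, Wx, Wy):
    tmp = np.tensordot(Wx.T, voxelwise, axes=([1], [0]))
    tmp = np.tensordot(Wy.T, tmp, axes=([1], [1]))
    return np.transpose(tmp, (1, 0, 2))


def _ffd_level_2d(source_slice, target_slice, spacing, cap_ratio, maxiter,
                  reg_weight: float = 1e-3):
    shape = target_slice.shape
    Wx = _bspline_weight_matrix(shape[0], spacing[0])
    Wy = _bspline_weight_matrix(shape[1], spacing[1])
    m_shape = (Wx.shape[1], Wy.shape[1], 2)
    idx = np.indices(shape, dtype=float).reshape(2, -1)
    grads = np.gradient(source_slice)
    n_pix = idx.shape[1]
    lam = reg_weight * float((target_slice ** 2).mean())

    def cost_grad(flat):
        coeffs = flat.reshape(m_shape)
        disp = _dense_field_2d(coeffs, Wx, Wy)
        coords = idx + disp.reshape(-1, 2).T
        warped = ndimage.map_coordinates(source_slice, coords, order=1,
                                         mode="constant", cval=0.0)
        r = warped - target_slice.ravel()
        cost = float((r ** 2).mean()) + lam * float((disp ** 2).mean())
        g = np.empty((n_pix, 2))
        for axis in range(2):
            g[:, axis] = ndimage.map_coordinates(grads[axis], coords, order=1,
                                                 mode="constant", cval=0.0)
        voxelwise = (2.0 / n_pix) * (r[:, None] * g
                                     + lam * disp.reshape(-1, 2))
        grad = _project_to_coeffs_2d(voxelwise.reshape(shape + (2,)), Wx, Wy)
        return cost, grad.ravel()

    bounds_per_axis = cap_ratio * spacing
    lower = np.tile(-bounds_per_axis, int(np.prod(m_shape[:2])))
    res = optimize.minimize(
        cost_grad, np.zeros(int(np.prod(m_shape))), jac=True,
        method="L-BFGS-B", bounds=np.column_stack([lower, -lower]),
        options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-10},
    )
    coeffs = res.x.reshape(m_shape)
    return _dense_field_2d(coeffs, Wx, Wy)


def register_slicewise(epi_reference: VolumeImage,
                       anat_in_epi_space: VolumeImage,
                       max_level: int = 2, cap_ratio: float = 0.4,
                       min_tissue_fraction: float = 0.01,
                       maxiter: int = 60,
                       reg_weight: float = 0.0) -> SliceWarpStack:
    """Per-slice in-plane nonlinear registration of EPI to anatomy.

    Both images must share one grid (the anatomical already reoriented and
    resampled to the EPI geometry).  Each z-slice of the EPI is registered
    to the matching anatomical slice with the 2D FFD; slices with less than
    ``min_tissue_fraction`` nonzero voxels in either image keep identity
    warps.  The returned stack maps anatomical-space in-plane positions to
    distorted EPI positions (pull convention).
    """
    if epi_reference.shape[2] != anat_in_epi_space.shape[2]:
        raise ValueError("z-dimension mismatch between EPI and anatomical")
    if not epi_reference.grid.matches(anat_in_epi_space.grid):
        raise ValueError("EPI and anatomical must share one grid")
    nx, ny, nz = epi_reference.shape
    src = _normalize_to(epi_reference.data, anat_in_epi_space.data)
    tgt = anat_in_epi_space.data
    inplane = np.zeros((nx, ny, nz, 2))
    shape2 = np.array([float(nx), float(ny)])
    for k in range(nz):
        s = src[:, :, k]
        t = tgt[:, :, k]
        frac = min((s != 0).mean(), (t != 0).mean())
        if frac <= min_tissue_fraction:
            continue
        d_total = None
        for level in range(1, max_level + 1):
            spacing = np.maximum(shape2 / 4.0 / (2 ** (level - 1)), 2.0)
            if d_total is None:
                s_level = s
            else:
                idx = np.indices(s.shape, dtype=float).reshape(2, -1)
                coords = idx + d_total.reshape(-1, 2).T
                s_level = ndimage.map_coordinates(
                    s, coords, order=1, mode="constant", cval=0.0
                ).reshape(s.shape)
            d_new = _ffd_level_2d(s_level, t, spacing, cap_ratio, maxiter,
                                  reg_weight)
            if d_total is None:
                d_total = d_new
            else:
                idx = np.indices(s.shape, dtype=float).reshape(2, -1)
                coords = idx + d_new.reshape(-1, 2).T
                upd = d_new.copy().reshape(-1, 2)
                for axis in range(2):
                    upd[:, axis] += ndimage.map_coordinates(
                        d_total[..., axis], coords, order=1, mode="constant",
                        cval=0.0,
                    )
                d_total = upd.reshape(s.shape + (2,))
        inplane[:, :, k, :] = d_total
    stack = SliceWarpStack(inplane, epi_reference.affine)
    dets = stack.jacobian_determinant_2d()[1:-1, 1:-1, :]
    if np.any(dets <= 0):
        raise RuntimeError("per-slice registration produced a folded warp")
    return stack


# ---------------------------------------------------------------------------
# One-big-step application


def apply_chain(image, chain, reference, interpolation: str = "trilinear"):
    """Apply a transform chain with a single resampling.

    Every reference voxel is mapped through all chain elements in order and
    the source image is interpolated exactly once — the "one big step" that
    keeps interpolation error down compared with resampling after each
    transform.
    """
    if not isinstance(chain, TransformChain):
        chain = TransformChain(list(chain))
    composed = compose(chain)
    return resample(image, reference, composed, interpolation)
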