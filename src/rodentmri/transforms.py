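"""Spatial transforms and their algebra.

Every transform here is a *pull* mapping: it takes world coordinates in the
reference (fixed) space to world coordinates in the moving (source) space,
which is exactly what :func:`rodentmri.images.resample` needs.  Chains apply
their elements in order, so a chain resampling a functional image onto a
template grid starts with the template-to-anatomical warp and ends with the
per-slice distortion warp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .images import Grid

__all__ = [
    "AffineTransform",
    "DisplacementField",
    "SliceWarpStack",
    "TransformChain",
    "identity_transform",
    "rigid_from_params",
    "affine_from_params",
    "rigid_params_from_matrix",
    "compose",
    "invert",
    "transform_deviation",
]


@dataclass(frozen=True)
class AffineTransform:
    """World-to-world 4x4 affine with a degrees-of-freedom tag."""

    matrix: np.ndarray
    dof_tag: str = "affine12"

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError("AffineTransform matrix must be 4x4")
        if not np.all(np.isfinite(matrix)):
            raise ValueError("AffineTransform matrix must be finite")
        if abs(np.linalg.det(matrix[:3, :3])) <= 1e-12:
            raise ValueError("AffineTransform is singular")
        if self.dof_tag not in ("rigid6", "similarity7", "affine12"):
            raise ValueError(f"unknown dof_tag {self.dof_tag!r}")
        if self.dof_tag == "rigid6":
            rot = matrix[:3, :3]
            if (np.linalg.norm(rot.T @ rot - np.eye(3)) > 1e-6
                    or np.linalg.det(rot) < 0):
                raise ValueError("rigid6 transform must have orthonormal "
                                 "rotation with det +1")
        object.__setattr__(self, "matrix", matrix)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (3, N) world points."""
        return self.matrix[:3, :3] @ points + self.matrix[:3, 3:4]

    def invert(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.dof_tag)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        tag = "rigid6" if self.dof_tag == other.dof_tag == "rigid6" else "affine12"
        return AffineTransform(self.matrix @ other.matrix, tag)


def identity_transform() -> AffineTransform:
    return AffineTransform(np.eye(4), "rigid6")


def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """Rotation as Rz @ Ry @ Rx with angles in degrees."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def rigid_from_params(params, center=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Rigid transform from (rx, ry, rz [deg], tx, ty, tz [mm]).

    Rotation is about ``center`` (world mm): x -> R (x - c) + c + t.
    """
    rx, ry, rz, tx, ty, tz = [float(v) for v in params]
    center = np.asarray(center, dtype=float)
    R = _rotation_matrix(rx, ry, rz)
    m = np.eye(4)
    m[:3, :3] = R
    m[:3, 3] = center - R @ center + np.array([tx, ty, tz])
    return AffineTransform(m, "rigid6")


def rigid_params_from_matrix(transform: AffineTransform,
                             center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Inverse of :func:`rigid_from_params` (Rz·Ry·Rx Euler convention)."""
    R = transform.matrix[:3, :3]
    ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
    if abs(np.cos(ry)) > 1e-8:
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
    else:  # gimbal lock
        rx = np.arctan2(-R[1, 2], R[1, 1])
        rz = 0.0
    center = np.asarray(center, dtype=float)
    t = transform.matrix[:3, 3] - center + R @ center
    return np.array([np.rad2deg(rx), np.rad2deg(ry), np.rad2deg(rz), *t])


def affine_from_params(params, center=(0.0, 0.0, 0.0)) -> AffineTransform:
    """Full affine from 12 parameters.

    ``params`` = (rx, ry, rz [deg], tx, ty, tz [mm], log_sx, log_sy, log_sz,
    shear_xy, shear_xz, shear_yz); matrix = R · Shear · Scale about ``center``.
    """
    p = np.asarray(params, dtype=float)
    if p.size != 12:
        raise ValueError("affine_from_params needs 12 parameters")
    R = _rotation_matrix(*p[:3])
    scale = np.diag(np.exp(p[6:9]))
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = p[9], p[10], p[11]
    M = R @ shear @ scale
    center = np.asarray(center, dtype=float)
    m = np.eye(4)
    m[:3, :3] = M
    m[:3, 3] = center - M @ center + p[3:6]
    return AffineTransform(m, "affine12")


@dataclass
class DisplacementField:
    """Dense per-voxel world-mm displacement on a stated grid.

    Maps a world point w to w + d(w), where d is trilinearly interpolated
    from the per-voxel vectors (zero outside the field of view).
    """

    vectors: np.ndarray  # (X, Y, Z, 3) world-mm displacements
    affine: np.ndarray
    level_history: list = field(default_factory=list)

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DisplacementField vectors must be (X, Y, Z, 3)")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("DisplacementField must be finite")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid(self) -> Grid:
        return Grid(self.vectors.shape[:3], self.affine)

    def _sample(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        vox = inv[:3, :3] @ points + inv[:3, 3:4]
        out = np.empty_like(points)
        for axis in range(3):
            out[axis] = ndimage.map_coordinates(
                self.vectors[..., axis], vox, order=1, mode="constant", cval=0.0
            )
        return out

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points + self._sample(points)

    def jacobian_determinant(self) -> np.ndarray:
        """Discrete Jacobian determinant of the voxel-space mapping.

        Computed with central differences on interior voxels; the
        diffeomorphism contract requires it to be strictly positive there.
        """
        inv3 = np.linalg.inv(self.affine[:3, :3])
        dvox = np.einsum("ab,ijkb->ijka", inv3, self.vectors)
        J = np.empty(self.vectors.shape[:3] + (3, 3))
        for comp in range(3):
            grads = np.gradient(dvox[..., comp])
            for axis in range(3):
                J[..., comp, axis] = grads[axis]
        J += np.eye(3)
        return np.linalg.det(J)

    def invert(self, max_iter: int = 50, tol_voxels: float = 0.1
               ) -> "DisplacementField":
        """Fixed-point inversion: solve d_inv(w) = -d(w + d_inv(w))."""
        pts = self.grid.world_grid()
        d_inv = np.zeros_like(pts)
        voxel = float(np.min(self.grid.voxel_sizes))
        for _ in range(max_iter):
            # damped fixed point; the plain iteration can oscillate where
            # the field is sampled near the edge of its support
            new = 0.5 * (d_inv - self._sample(pts + d_inv))
            change = np.sqrt(((new - d_inv) ** 2).sum(axis=0)).max()
            d_inv = new
            if change < 1e-3 * voxel:
                break
        # round-trip residual T(T^-1(w)) - w, mean over the grid, in voxels
        res = self.apply(pts + d_inv) - pts
        mean_res = float(np.sqrt((res ** 2).sum(axis=0)).mean()) / voxel
        if mean_res > tol_voxels:
            raise RuntimeError(
                f"displacement-field inversion did not converge: mean "
                f"round-trip residual {mean_res:.3f} voxels > {tol_voxels}"
            )
        vecs = np.moveaxis(
            d_inv.reshape((3,) + self.vectors.shape[:3]), 0, -1
        )
        return DisplacementField(vecs, self.affine, list(self.level_history))


@dataclass
class SliceWarpStack:
    """Per-slice in-plane warps on a shared grid (EPI distortion model).

    ``inplane`` holds voxel-unit (i, j) displacements per voxel; the
    out-of-plane component is identically zero, so each z-slice maps onto
    itself.  Displacements are interpolated in-plane but looked up with
    nearest-neighbour in z, keeping slices independent.
    """

    inplane: np.ndarray  # (X, Y, Z, 2) voxel-unit in-plane displacements
    affine: np.ndarray

    def __post_init__(self):
        self.inplane = np.asarray(self.inplane, dtype=float)
        if self.inplane.ndim != 4 or self.inplane.shape[-1] != 2:
            raise ValueError("SliceWarpStack inplane must be (X, Y, Z, 2)")
        if not np.all(np.isfinite(self.inplane)):
            raise ValueError("SliceWarpStack must be finite")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def grid(self) -> Grid:
        return Grid(self.inplane.shape[:3], self.affine)

    @property
    def n_slices(self) -> int:
        return self.inplane.shape[2]

    def _sample_voxel_disp(self, vox: np.ndarray) -> np.ndarray:
        nz = self.inplane.shape[2]
        zs = np.clip(np.round(vox[2]), 0, nz - 1)
        coords = np.vstack([vox[0], vox[1], zs])
        disp = np.zeros((3, vox.shape[1]))
        for comp in range(2):
            disp[comp] = ndimage.map_coordinates(
                self.inplane[..., comp], coords, order=1, mode="constant",
                cval=0.0,
            )
        return disp

    def apply(self, points: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        vox = inv[:3, :3] @ points + inv[:3, 3:4]
        disp_vox = self._sample_voxel_disp(vox)
        return points + self.affine[:3, :3] @ disp_vox

    def jacobian_determinant_2d(self) -> np.ndarray:
        """Per-voxel 2D Jacobian determinant of each slice mapping."""
        dets = np.empty(self.inplane.shape[:3])
        for k in range(self.n_slices):
            du = self.inplane[:, :, k, 0]
            dv = self.inplane[:, :, k, 1]
            dux, duy = np.gradient(du)
            dvx, dvy = np.gradient(dv)
            dets[:, :, k] = (1 + dux) * (1 + dvy) - duy * dvx
        return dets

    def invert(self, max_iter: int = 50, tol_voxels: float = 0.1
               ) -> "SliceWarpStack":
        """Per-slice fixed-point inversion (in voxel units)."""
        nx, ny, nz, _ = self.inplane.shape
        ii, jj = np.meshgrid(np.arange(nx, dtype=float),
                             np.arange(ny, dtype=float), indexing="ij")
        out = np.zeros_like(self.inplane)
        for k in range(nz):
            d = self.inplane[:, :, k, :]
            if not d.any():
                continue
            dinv = np.zeros_like(d)
            for _ in range(max_iter):
                coords = np.array([ii + dinv[..., 0], jj + dinv[..., 1]])
                new = np.empty_like(dinv)
                for comp in range(2):
                    new[..., comp] = -ndimage.map_coordinates(
                        d[..., comp], coords, order=1, mode="constant", cval=0.0
                    )
                change = np.abs(new - dinv).max()
                dinv = new
                if change < 1e-3:
                    break
            coords = np.array([ii + dinv[..., 0], jj + dinv[..., 1]])
            fwd = np.empty_like(dinv)
            for comp in range(2):
                fwd[..., comp] = ndimage.map_coordinates(
                    d[..., comp], coords, order=1, mode="constant", cval=0.0
                )
            res = np.sqrt(((dinv + fwd) ** 2).sum(axis=-1)).mean()
            if res > tol_voxels:
                raise RuntimeError(
                    f"slice {k} warp inversion residual {res:.3f} voxels "
                    f"> {tol_voxels}"
                )
            out[:, :, k, :] = dinv
        return SliceWarpStack(out, self.affine)


@dataclass
class TransformChain:
    """Ordered list of transforms applied reference-to-moving."""

    elements: list

    def __post_init__(self):
        for el in self.elements:
            if not hasattr(el, "apply"):
                raise TypeError(f"chain element {type(el).__name__} has no apply()")

    def apply(self, points: np.ndarray) -> np.ndarray:
        # adjacent affines are merged first, so applying a chain is
        # bit-identical to applying its composed (one-big-step) form
        for el in compose(self).elements:
            points = el.apply(points)
        return points

    def invert(self) -> "TransformChain":
        return TransformChain([invert(el) for el in reversed(self.elements)])

    def __len__(self) -> int:
        return len(self.elements)


def compose(chain) -> TransformChain:
    """Flatten transforms into a single chain mapping (one resampling).

    Consecutive affines are multiplied analytically; other elements are kept
    as-is and evaluated pointwise when the chain is applied.
    """
    elements = list(chain.elements if isinstance(chain, TransformChain) else chain)
    if not elements:
        return TransformChain([identity_transform()])
    merged: list = []
    for el in elements:
        if (merged and isinstance(el, AffineTransform)
                and isinstance(merged[-1], AffineTransform)):
            # chain applies merged[-1] first, then el: x -> el(prev(x))
            merged[-1] = el @ merged[-1]
        else:
            merged.append(el)
    return TransformChain(merged)


def invert(transform):
    """Invert any supported transform (affine exactly, fields iteratively)."""
    if isinstance(transform, TransformChain):
        return transform.invert()
    return transform.invert()


def transform_deviation(t_a: AffineTransform, t_b: AffineTransform,
                        radius_mm: float, n_dirs: int = 64,
                        center=(0.0, 0.0, 0.0)) -> dict:
    """How far two affines disagree over a sphere of given radius.

    Returns the rotation-angle difference (degrees, from the polar
    decomposition of A_a^-1 A_b) and the maximum point displacement (mm)
    between the two mappings over points on the sphere — a direct way of
    saying "recovered within 0.5 degrees and a quarter voxel".
    """
    rel = np.linalg.inv(t_a.matrix) @ t_b.matrix
    M = rel[:3, :3]
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    angle = np.rad2deg(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0)))
    rng = np.random.default_rng(0)
    dirs = rng.normal(size=(3, n_dirs))
    dirs /= np.linalg.norm(dirs, axis=0)
    pts = np.asarray(center, dtype=float)[:, None] + radius_mm * dirs
    disp = t_a.apply(pts) - t_b.apply(pts)
    return {
        "rotation_deg": float(angle),
        "max_displacement_mm": float(np.linalg.norm(disp, axis=0).max()),
    }


# ---------------------------------------------------------------------------
# Serialization (text formats only: 4x4 matrices as whitespace tables,
# chains as JSON manifests, fields as NIfTI written elsewhere)


def save_affine(transform: AffineTransform, path) -> None:
    header = f"# dof: {transform.dof_tag}\n"
    Path(path).write_text(
        header + "\n".join(
            " ".join(f"{v:.17g}" for v in row) for row in transform.matrix
        ) + "\n"
    )


def load_affine(path) -> AffineTransform:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    tag = "affine12"
    if lines and lines[0].startswith("#"):
        if "dof:" in lines[0]:
            tag = lines[0].split("dof:")[1].strip()
        lines = lines[1:]
    matrix = np.array([[float(v) for v in ln.split()] for ln in lines])
    return AffineTransform(matrix, tag)


def save_chain_manifest(chain: TransformChain, directory, stem: str) -> Path:
    """Write chain elements to ``directory`` and a JSON manifest listing them."""
    from .images import VolumeImage, write_nifti  # local import, avoids cycle
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, el in enumerate(chain.elements):
        if isinstance(el, AffineTransform):
            fname = f"{stem}_{i:02d}_affine.txt"
            save_affine(el, directory / fname)
            entries.append({"type": "affine", "file": fname})
        elif isinstance(el, DisplacementField):
            fname = f"{stem}_{i:02d}_field.nii.gz"
            nib.save(nib.Nifti1Image(el.vectors[:, :, :, None, :], el.affine),
                     str(directory / fname))
            entries.append({"type": "field", "file": fname})
        elif isinstance(el, SliceWarpStack):
            fname = f"{stem}_{i:02d}_slicewarps.nii.gz"
            pad = np.zeros(el.inplane.shape[:3] + (3,))
            pad[..., :2] = el.inplane
            nib.save(nib.Nifti1Image(pad[:, :, :, None, :], el.affine),
                     str(directory / fname))
            entries.append({"type": "slicewarps", "file": fname})
        else:
            raise TypeError(f"cannot serialize {type(el).__name__}")
    manifest = directory / f"{stem}_chain.json"
    manifest.write_text(json.dumps({"elements": entries}, indent=2))
    return manifest


def load_chain_manifest(path) -> TransformChain:
    import nibabel as nib

    path = Path(path)
    spec = json.loads(path.read_text())
    elements = []
    for entry in spec["elements"]:
        fpath = path.parent / entry["file"]
        if entry["type"] == "affine":
            elements.append(load_affine(fpath))
        elif entry["type"] == "field":
            img = nib.load(str(fpath))
            vecs = np.squeeze(np.asanyarray(img.dataobj))
            elements.append(DisplacementField(vecs, img.affine))
        elif entry["type"] == "slicewarps":
            img = nib.load(str(fpath))
            vecs = np.squeeze(np.asanyarray(img.dataobj))
            elements.append(SliceWarpStack(vecs[..., :2], img.affine))
        else:
            raise ValueError(f"unknown chain element type {entry['type']!r}")
    return TransformChain(elements)
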