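"""Image data model, NIfTI-1 I/O, orientation handling, and resampling.

All geometry follows a single convention: voxel indices are 0-based, the
4x4 affine maps homogeneous index ``(i, j, k, 1)`` to world coordinates in
millimetres, and the world frame is RAS+ (+x right, +y anterior,
+z superior) once an image has been reoriented.  Intensities are held as
64-bit floats internally regardless of on-disk dtype; masks and label maps
are integer arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Grid",
    "VolumeImage",
    "SeriesImage",
    "MaskImage",
    "LabelImage",
    "read_nifti",
    "write_nifti",
    "reorient_to_ras",
    "reorient_like",
    "resample",
    "image_centroid",
]


class ImageIOError(IOError):
    """Raised when a NIfTI file cannot be read or written as requested."""


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if not np.all(np.isfinite(affine)):
        raise ValueError("affine contains non-finite entries")
    if abs(np.linalg.det(affine[:3, :3])) <= 1e-12:
        raise ValueError("affine 3x3 block is singular")
    return affine


@dataclass(frozen=True)
class Grid:
    """A sampling grid: array shape plus voxel-to-world affine."""

    shape: tuple
    affine: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", _check_affine(self.affine))

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_center(self) -> np.ndarray:
        """World coordinate of the grid's geometric centre."""
        center_idx = (np.asarray(self.shape, dtype=float) - 1.0) / 2.0
        return self.affine[:3, :3] @ center_idx + self.affine[:3, 3]

    def index_grid(self) -> np.ndarray:
        """Dense (3, N) array of voxel indices in C order."""
        idx = np.indices(self.shape, dtype=float)
        return idx.reshape(3, -1)

    def world_grid(self) -> np.ndarray:
        """Dense (3, N) array of world coordinates of every voxel centre."""
        return self.affine[:3, :3] @ self.index_grid() + self.affine[:3, 3:4]

    def matches(self, other: "Grid", tol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=tol
        )


class _SpatialImage:
    """Shared behaviour for all image types (data + affine)."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    @property
    def grid(self) -> Grid:
        return Grid(self.shape, self.affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Map (3, N) voxel indices to (3, N) world mm."""
        indices = np.atleast_2d(np.asarray(indices, dtype=float))
        if indices.shape[0] != 3:
            indices = indices.T
        return self.affine[:3, :3] @ indices + self.affine[:3, 3:4]

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if points.shape[0] != 3:
            points = points.T
        inv = np.linalg.inv(self.affine)
        return inv[:3, :3] @ points + inv[:3, 3:4]


@dataclass
class VolumeImage(_SpatialImage):
    """3D scalar volume with a voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeImage requires 3D data, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeImage intensities must be finite")
        self.affine = _check_affine(self.affine)


@dataclass
class MaskImage(_SpatialImage):
    """Binary mask on the same grid model as VolumeImage."""

    data: np.ndarray
    affine: np.ndarray
    allow_empty: bool = False

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"MaskImage requires 3D data, got {data.ndim}D")
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("MaskImage values must be 0 or 1")
        self.data = data.astype(np.uint8)
        self.affine = _check_affine(self.affine)
        if not self.allow_empty and not self.data.any():
            raise ValueError("MaskImage is empty (pass allow_empty=True to permit)")

    def count(self) -> int:
        return int(self.data.sum())


@dataclass
class LabelImage(_SpatialImage):
    """Integer region atlas; 0 is reserved for background."""

    data: np.ndarray
    affine: np.ndarray
    label_names: Mapping[int, str] | None = None

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"LabelImage requires 3D data, got {data.ndim}D")
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("LabelImage values must be integers")
            data = np.round(data)
        if data.min() < 0:
            raise ValueError("LabelImage labels must be nonnegative")
        self.data = data.astype(np.int32)
        self.affine = _check_affine(self.affine)

    def labels(self) -> np.ndarray:
        """Sorted nonzero label ids present in the image."""
        uniq = np.unique(self.data)
        return uniq[uniq != 0]


@dataclass
class SeriesImage(_SpatialImage):
    """4D series (x, y, z, t) sharing one grid, with per-frame metadata."""

    data: np.ndarray
    affine: np.ndarray
    frame_metadata: Sequence = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"SeriesImage requires 4D data, got {self.data.ndim}D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("SeriesImage intensities must be finite")
        self.affine = _check_affine(self.affine)
        if not self.frame_metadata:
            self.frame_metadata = list(range(self.data.shape[3]))
        if len(self.frame_metadata) != self.data.shape[3]:
            raise ValueError(
                f"frame_metadata length {len(self.frame_metadata)} != "
                f"number of frames {self.data.shape[3]}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> VolumeImage:
        return VolumeImage(self.data[..., t], self.affine)


# ---------------------------------------------------------------------------
# I/O


def read_nifti(path, kind: str = "auto"):
    """Read a NIfTI-1 file into the matching image type.

    Parameters
    ----------
    path : str or Path
        Readable ``.nii`` or ``.nii.gz`` file.
    kind : {"auto", "volume", "mask", "labels", "series"}
        Role to give a 3D file; 4D files always become :class:`SeriesImage`.
    """
    path = Path(path)
    if kind not in ("auto", "volume", "mask", "labels", "series"):
        raise ValueError(f"unknown kind {kind!r}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ImageIOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim > 4 else data
    if data.ndim not in (3, 4):
        raise ImageIOError(
            f"{path}: expected 3D or 4D data, got {data.ndim}D shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ImageIOError(f"{path}: data contains non-finite voxels")
    affine = img.affine  # nibabel prefers sform, falls back to qform
    try:
        _check_affine(affine)
    except ValueError as exc:
        raise ImageIOError(f"{path}: bad affine ({exc})") from exc
    if data.ndim == 4:
        return SeriesImage(data, affine)
    if kind == "series":
        return SeriesImage(data[..., None], affine)
    if kind == "mask":
        return MaskImage(data, affine, allow_empty=True)
    if kind == "labels":
        return LabelImage(data, affine)
    return VolumeImage(data, affine)


def write_nifti(image, path) -> None:
    """Write an image to NIfTI-1; masks as uint8, labels as int32, else float64."""
    path = Path(path)
    if isinstance(image, MaskImage):
        data = image.data.astype(np.uint8)
    elif isinstance(image, LabelImage):
        data = image.data.astype(np.int32)
    else:
        data = np.asarray(image.data, dtype=np.float64)
        if not np.all(np.isfinite(data)):
            raise ValueError("refusing to write non-finite voxel values")
    nifti = nib.Nifti1Image(data, image.affine)
    nifti.header.set_sform(image.affine, code=1)
    nifti.header.set_qform(image.affine, code=1)
    try:
        nib.save(nifti, str(path))
    except Exception as exc:
        raise ImageIOError(f"cannot write NIfTI file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Orientation


def _reorient(image, ornt: np.ndarray):
    """Apply a nibabel orientation transform, preserving world coordinates."""
    if np.array_equal(ornt, np.array([[0, 1], [1, 1], [2, 1]], dtype=float)):
        return image
    if isinstance(image, SeriesImage):
        frames = [nib.orientations.apply_orientation(image.data[..., t], ornt)
                  for t in range(image.n_frames)]
        data = np.stack(frames, axis=-1)
        shape3 = image.data.shape[:3]
    else:
        data = nib.orientations.apply_orientation(image.data, ornt)
        shape3 = image.data.shape
    affine = image.affine @ nib.orientations.inv_ornt_aff(ornt, shape3)
    out = replace(image, data=data, affine=affine)
    return out


def reorient_to_ras(image):
    """Permute/flip axes to the closest RAS+ orientation (lossless).

    Only the nearest axis permutation and flips are applied — no resampling —
    so every voxel keeps its world coordinate.  Oblique affines stay oblique;
    a warning is emitted when the rotation part is far from axis-aligned.
    """
    ornt = nib.orientations.io_orientation(image.affine)
    rot = image.affine[:3, :3] / np.linalg.norm(image.affine[:3, :3], axis=0)
    # obliquity: each column should be close to a signed unit vector
    if np.max(np.abs(rot)) < 0.999 or np.min(np.max(np.abs(rot), axis=0)) < 0.999:
        warnings.warn(
            "affine is oblique; reorientation picks the nearest axis "
            "permutation/flip and leaves the obliquity in place",
            stacklevel=2,
        )
    return _reorient(image, ornt)


def reorient_like(image, reference):
    """Reorient ``image`` so its axes run the same way as ``reference``'s.

    Both images are mapped to their nearest-canonical orientation and the
    reference's orientation is then imposed on the image, again without any
    resampling.
    """
    ras = reorient_to_ras(image)
    ref_ornt = nib.orientations.io_orientation(reference.affine)
    # ref_ornt maps reference axes -> RAS; invert it to go RAS -> reference axes
    inv = nib.orientations.ornt_transform(
        np.array([[0, 1], [1, 1], [2, 1]], dtype=float), ref_ornt
    )
    return _reorient(ras, inv)


# ---------------------------------------------------------------------------
# Resampling


def _interp_order(image, interpolation: str) -> int:
    if interpolation == "nearest":
        return 0
    if interpolation == "trilinear":
        if isinstance(image, (MaskImage, LabelImage)):
            raise ValueError(
                "trilinear interpolation is not allowed for mask/label images; "
                "use 'nearest'"
            )
        return 1
    raise ValueError(f"unknown interpolation {interpolation!r}")


def resample(image, reference, transform=None, interpolation: str = "trilinear"):
    """Resample ``image`` onto ``reference``'s grid through ``transform``.

    ``transform`` maps reference world coordinates into the image's world
    coordinates (pull convention); ``None`` means identity.  Out-of-field
    voxels are set to 0.  Masks and label maps require nearest-neighbour
    interpolation.
    """
    ref_grid = reference if isinstance(reference, Grid) else reference.grid
    order = _interp_order(image, interpolation)
    world = ref_grid.world_grid()
    if transform is not None:
        world = transform.apply(world)
    inv = np.linalg.inv(image.affine)
    coords = inv[:3, :3] @ world + inv[:3, 3:4]

    def _sample(vol, order):
        return ndimage.map_coordinates(
            vol, coords, order=order, mode="constant", cval=0.0
        ).reshape(ref_grid.shape)

    if isinstance(image, SeriesImage):
        frames = [_sample(image.data[..., t], order) for t in range(image.n_frames)]
        return SeriesImage(
            np.stack(frames, axis=-1), ref_grid.affine, list(image.frame_metadata)
        )
    out = _sample(np.asarray(image.data, dtype=float), order)
    if isinstance(image, MaskImage):
        return MaskImage(out.astype(np.uint8), ref_grid.affine, allow_empty=True)
    if isinstance(image, LabelImage):
        return LabelImage(
            out.astype(np.int32), ref_grid.affine, label_names=image.label_names
        )
    return VolumeImage(out, ref_grid.affine)


def image_centroid(mask: MaskImage) -> np.ndarray:
    """World-mm centroid (mean world coordinate) of a mask's foreground."""
    idx = np.array(np.nonzero(mask.data), dtype=float)
    if idx.size == 0:
        raise ValueError("cannot compute centroid of an empty mask")
    mean_idx = idx.mean(axis=1)
    return mask.affine[:3, :3] @ mean_idx + mask.affine[:3, 3]
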