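"""Volumetric containers and grid operations.

All grids are axis aligned: the world coordinate of voxel index ``i`` is
``origin + i * spacing`` (millimetres), with no direction matrix.  Array axes
are ordered (LR, AP, SI) — left-right, anterior-posterior, superior-inferior —
and displacements are stored in millimetres, never voxels, because clinical CT
spacing is anisotropic.

File I/O supports NIfTI-1 (``.nii``/``.nii.gz``) and MetaImage
(``.mha``/``.mhd``) through SimpleITK for scalar volumes, integer label masks
and 3-component displacement fields.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

__all__ = [
    "ScalarVolume",
    "VectorField",
    "LabelMask",
    "GeometryError",
    "FormatError",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_vector_field",
    "write_vector_field",
    "warp_volume",
    "warp_mask",
    "rigid_align",
    "crop_to_common_space",
]

AIR_HU = -1000.0

_VOLUME_EXTS = (".nii", ".nii.gz", ".mha", ".mhd")


class GeometryError(ValueError):
    """Two grids that must share geometry do not."""


class FormatError(ValueError):
    """A file is unreadable or not in a supported layout."""


class AlignmentError(RuntimeError):
    """Rigid alignment could not find any valid overlap."""


def _as_triple(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ScalarVolume:
    """3D intensity grid (HU-like) with spacing/origin metadata."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got {self.data.ndim}D")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.data.copy(), self.spacing, self.origin)


@dataclass
class VectorField:
    """Per-voxel 3-vector displacement field in mm, components (LR, AP, SI)."""

    dx: np.ndarray
    dy: np.ndarray
    dz: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.dz = np.asarray(self.dz, dtype=float)
        if not (self.dx.shape == self.dy.shape == self.dz.shape):
            raise ValueError("dx, dy, dz must share one shape")
        if self.dx.ndim != 3:
            raise ValueError("vector field components must be 3D")
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @classmethod
    def zeros(cls, shape, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> "VectorField":
        z = np.zeros(shape, dtype=float)
        return cls(z, z.copy(), z.copy(), spacing, origin)

    @classmethod
    def from_array(cls, arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> "VectorField":
        """Build from a (3, nx, ny, nz) component-first array."""
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 4 or arr.shape[0] != 3:
            raise ValueError(f"expected (3, nx, ny, nz) array, got {arr.shape}")
        return cls(arr[0], arr[1], arr[2], spacing, origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dx.shape

    def as_array(self) -> np.ndarray:
        """Stack components into a (3, nx, ny, nz) array."""
        return np.stack([self.dx, self.dy, self.dz])

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean displacement magnitude in mm."""
        return np.sqrt(self.dx**2 + self.dy**2 + self.dz**2)

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "VectorField":
        return VectorField(
            self.dx.copy(), self.dy.copy(), self.dz.copy(),
            self.spacing, self.origin, dict(self.meta),
        )

    def __add__(self, other: "VectorField") -> "VectorField":
        _check_geometry(self, other)
        return VectorField(
            self.dx + other.dx, self.dy + other.dy, self.dz + other.dz,
            self.spacing, self.origin,
        )

    def __mul__(self, scalar: float) -> "VectorField":
        s = float(scalar)
        return VectorField(self.dx * s, self.dy * s, self.dz * s, self.spacing, self.origin)

    __rmul__ = __mul__

    def __neg__(self) -> "VectorField":
        return self * -1.0


@dataclass
class LabelMask:
    """Integer-valued structure mask with a label → name table."""

    data: np.ndarray
    label_names: dict[int, str] = field(default_factory=dict)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("mask data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("mask labels must be non-negative")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        self.spacing = _as_triple(self.spacing, "spacing")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def labels(self) -> list[int]:
        present = np.unique(self.data)
        return [int(v) for v in present if v != 0]

    def binary(self, label: int) -> np.ndarray:
        return self.data == int(label)

    def same_geometry(self, other) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


def _check_geometry(a, b) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"grid geometry mismatch: shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing}, origin {a.origin} vs {b.origin}"
        )


# ---------------------------------------------------------------------------
# File I/O
#
# SimpleITK returns arrays in (SI, AP, LR) axis order; everything in this
# package is (LR, AP, SI), hence the transposes below.
# ---------------------------------------------------------------------------

def _check_extension(path: str) -> None:
    p = str(path).lower()
    if not p.endswith(_VOLUME_EXTS):
        raise FormatError(
            f"unsupported extension on {path!r}; expected one of {_VOLUME_EXTS}"
        )


def _read_sitk(path: str) -> sitk.Image:
    _check_extension(path)
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise FormatError(f"unreadable image file {path}: {exc}") from exc


def read_volume(path) -> ScalarVolume:
    """Read a 3D scalar volume from NIfTI or MetaImage.

    Integer-typed files are preserved bit-exact; geometry (spacing, origin)
    is taken from the header.
    """
    img = _read_sitk(path)
    if img.GetNumberOfComponentsPerPixel() != 1:
        raise FormatError(
            f"{path} holds {img.GetNumberOfComponentsPerPixel()}-component "
            "pixels; expected a scalar volume"
        )
    if img.GetDimension() != 3:
        raise FormatError(f"{path} is {img.GetDimension()}D; expected 3D")
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return ScalarVolume(data, img.GetSpacing(), img.GetOrigin())


def write_volume(vol: ScalarVolume, path) -> None:
    """Write a scalar volume; the extension selects the format."""
    _check_extension(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, str(path))


def read_mask(path) -> LabelMask:
    """Read an integer label mask; a sidecar ``<path>.labels.json`` (if
    present) supplies the label → structure-name table."""
    vol = read_volume(path)
    names = {}
    sidecar = str(path) + ".labels.json"
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            names = {int(k): v for k, v in json.load(fh).items()}
    return LabelMask(vol.data, names, vol.spacing, vol.origin)


def write_mask(mask: LabelMask, path) -> None:
    data = mask.data.astype(np.uint16 if mask.data.max() < 2**16 else np.int32)
    write_volume(ScalarVolume(data, mask.spacing, mask.origin), path)
    if mask.label_names:
        with open(str(path) + ".labels.json", "w") as fh:
            json.dump({str(k): v for k, v in mask.label_names.items()}, fh, indent=1)


def read_vector_field(path) -> VectorField:
    """Read a 3-component displacement field.

    Both vector-pixel images and 4D scalar images with a 3-long fourth axis
    are accepted; component order is (LR, AP, SI).
    """
    img = _read_sitk(path)
    ncomp = img.GetNumberOfComponentsPerPixel()
    if img.GetDimension() == 3 and ncomp == 3:
        arr = sitk.GetArrayFromImage(img)  # (z, y, x, 3)
        comps = arr.transpose(3, 2, 1, 0)
        spacing, origin = img.GetSpacing(), img.GetOrigin()
    elif img.GetDimension() == 4 and ncomp == 1:
        arr = sitk.GetArrayFromImage(img)  # (t, z, y, x)
        if arr.shape[0] != 3:
            raise FormatError(
                f"{path}: 4D field has {arr.shape[0]} channels, expected 3"
            )
        comps = arr.transpose(0, 3, 2, 1)
        spacing, origin = img.GetSpacing()[:3], img.GetOrigin()[:3]
    else:
        raise FormatError(
            f"{path}: expected a 3-component vector image, got "
            f"{img.GetDimension()}D with {ncomp} component(s)"
        )
    return VectorField(comps[0], comps[1], comps[2], spacing, origin)


def write_vector_field(fld: VectorField, path) -> None:
    """Write a displacement field as a vector-pixel image (32-bit floats)."""
    _check_extension(path)
    arr = np.stack([fld.dx, fld.dy, fld.dz], axis=-1).transpose(2, 1, 0, 3)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float32), isVector=True)
    img.SetSpacing(fld.spacing)
    img.SetOrigin(fld.origin)
    sitk.WriteImage(img, str(path))


# ---------------------------------------------------------------------------
# Resampling and warping
# ---------------------------------------------------------------------------

def _sample_at(data: np.ndarray, coords: np.ndarray, order: int,
               fill: float | None) -> np.ndarray:
    """Trilinear/nearest sampling at fractional voxel coordinates.

    ``fill=None`` clamps to the nearest edge value instead of padding.
    """
    if fill is None:
        return ndimage.map_coordinates(data, coords, order=order, mode="nearest")
    return ndimage.map_coordinates(
        data, coords, order=order, mode="constant", cval=fill
    )


def _pullback_coords(dvf: VectorField) -> np.ndarray:
    """Voxel coordinates of x + d(x) for every grid point x."""
    idx = np.indices(dvf.shape, dtype=float)
    sp = np.asarray(dvf.spacing).reshape(3, 1, 1, 1)
    return idx + dvf.as_array() / sp


def warp_volume(vol: ScalarVolume, dvf: VectorField, mode: str = "linear",
                fill: float = AIR_HU) -> ScalarVolume:
    """Warp ``vol`` by ``dvf`` under the pull-back convention.

    The output at grid point x is the input sampled at the world point
    x + d(x); a DVF produced by registering image t to a reference therefore
    deforms image t onto the reference grid.  Out-of-grid samples take
    ``fill`` (default −1000, air).  Use ``mode="nearest"`` for label data.
    """
    _check_geometry(vol, dvf)
    if mode not in ("linear", "nearest"):
        raise ValueError(f"mode must be 'linear' or 'nearest', got {mode!r}")
    order = 1 if mode == "linear" else 0
    coords = _pullback_coords(dvf)
    out = _sample_at(vol.data.astype(float), coords, order, fill)
    return ScalarVolume(out, vol.spacing, vol.origin)


def warp_mask(mask: LabelMask, dvf: VectorField) -> LabelMask:
    """Warp a label mask with nearest-neighbour sampling (fill = 0)."""
    vol = ScalarVolume(mask.data.astype(float), mask.spacing, mask.origin)
    warped = warp_volume(vol, dvf, mode="nearest", fill=0.0)
    return LabelMask(
        np.round(warped.data).astype(mask.data.dtype),
        mask.label_names, mask.spacing, mask.origin,
    )


# ---------------------------------------------------------------------------
# Rigid pre-alignment and common-space cropping
# ---------------------------------------------------------------------------

def _overlap_slices(shape_f, shape_m, t):
    """Index slices of the fixed/moving overlap for integer shift t."""
    sl_f, sl_m = [], []
    for k in range(3):
        lo = max(0, t[k])
        hi = min(shape_f[k], shape_m[k] + t[k])
        if hi <= lo:
            return None
        sl_f.append(slice(lo, hi))
        sl_m.append(slice(lo - t[k], hi - t[k]))
    return tuple(sl_f), tuple(sl_m)


def rigid_align(moving: ScalarVolume, fixed: ScalarVolume,
                search_radius: int = 5) -> tuple[int, int, int]:
    """Integer-voxel translation of ``moving`` that best matches ``fixed``.

    Exhaustively maximises the normalized cross-correlation coefficient over
    the overlap region for every shift within ``search_radius`` voxels per
    axis.  Ties are broken toward the smaller translation magnitude, then
    lexicographically.  The returned translation t means ``moving`` aligned
    to ``fixed`` is ``moving(i - t)``.
    """
    if not np.allclose(moving.spacing, fixed.spacing):
        raise GeometryError(
            f"rigid_align requires equal spacing: {moving.spacing} vs {fixed.spacing}"
        )
    r = int(search_radius)
    shifts = [
        (i, j, k)
        for i in range(-r, r + 1)
        for j in range(-r, r + 1)
        for k in range(-r, r + 1)
    ]
    shifts.sort(key=lambda t: (t[0] ** 2 + t[1] ** 2 + t[2] ** 2, t))
    f = fixed.data.astype(float)
    m = moving.data.astype(float)
    best_t, best_ncc = None, -np.inf
    for t in shifts:
        sl = _overlap_slices(fixed.shape, moving.shape, t)
        if sl is None:
            continue
        a = f[sl[0]].ravel()
        b = m[sl[1]].ravel()
        if a.size < 2:
            continue
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a @ a) * (b @ b))
        if denom == 0:
            continue
        ncc = (a @ b) / denom
        if ncc > best_ncc + 1e-12:
            best_ncc, best_t = ncc, t
    if best_t is None:
        raise AlignmentError("no candidate shift produced a valid overlap")
    return best_t


def crop_to_common_space(volumes: list[ScalarVolume],
                         translations: list[tuple[int, int, int]]
                         ) -> list[ScalarVolume]:
    """Crop aligned volumes to their common (intersection) bounding box.

    ``translations[k]`` places volume k in the shared reference frame: its
    voxel i sits at reference index i + t_k.  All outputs share one grid
    geometry (the intersection box), with the origin expressed in the frame
    of the first volume.
    """
    if len(volumes) != len(translations):
        raise ValueError("one translation per volume required")
    spacing = volumes[0].spacing
    for v in volumes[1:]:
        if not np.allclose(v.spacing, spacing):
            raise GeometryError("all volumes must share spacing")
    ts = [np.asarray(t, dtype=int) for t in translations]
    lo = np.max([t for t in ts], axis=0)
    hi = np.min([t + np.asarray(v.shape) for v, t in zip(volumes, ts)], axis=0)
    if np.any(hi <= lo):
        raise GeometryError(
            f"aligned volumes have empty intersection (lo={lo}, hi={hi})"
        )
    origin = tuple(
        np.asarray(volumes[0].origin) + (lo - ts[0]) * np.asarray(spacing)
    )
    out = []
    for v, t in zip(volumes, ts):
        a, b = lo - t, hi - t
        out.append(ScalarVolume(
            v.data[a[0]:b[0], a[1]:b[1], a[2]:b[2]].copy(), spacing, origin
        ))
    return out
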