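"""Volume containers, preprocessing and peritumoral ring geometry.

The unit of analysis is a 3-D scalar :class:`Volume` with physical voxel
spacing, paired with binary :class:`RegionMask` objects on the same grid
(tumor, peritumoral rings, habitat subregions).  Preprocessing follows the
fixed order bias correction -> isotropic resampling -> intensity
normalization; all geometry (ring distances, shape descriptors) is computed
in physical millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


class GridError(ValueError):
    """Raised for degenerate or mismatched image grids."""


@dataclass(frozen=True)
class Volume:
    """3-D scalar image with physical spacing and origin (mm)."""

    array: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=np.float64)
        if arr.ndim != 3:
            raise GridError(f"expected a 3-D array, got ndim={arr.ndim}")
        if arr.size == 0:
            raise GridError("zero-extent volume")
        if not np.all(np.isfinite(arr)):
            raise GridError("volume contains non-finite intensities")
        if any(s <= 0 for s in self.spacing_mm):
            raise GridError(f"spacing must be strictly positive: {self.spacing_mm}")
        object.__setattr__(self, "array", arr)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def same_grid(self, other: "Volume | RegionMask") -> bool:
        return (
            self.array.shape == other.array.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )


@dataclass(frozen=True)
class RegionMask:
    """Binary mask on a Volume's grid.

    ``role`` tags the region (``tumor``, ``ring_1mm`` .. ``ring_5mm``,
    ``h1`` .. ``hk``, ``body``); it is carried into feature names.
    """

    array: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    role: str = "tumor"

    def __post_init__(self) -> None:
        arr = np.asarray(self.array)
        if arr.ndim != 3:
            raise GridError(f"expected a 3-D mask, got ndim={arr.ndim}")
        object.__setattr__(self, "array", arr.astype(bool))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(s) for s in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_count(self) -> int:
        return int(self.array.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def with_role(self, role: str) -> "RegionMask":
        return replace(self, role=role)


# --------------------------------------------------------------------------
# NIfTI I/O (affine preserved as diag(spacing) + origin translation)
# --------------------------------------------------------------------------

def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def save_volume(vol: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(vol.array.astype(np.float32), _affine(vol.spacing_mm, vol.origin_mm))
    nib.save(img, str(path))


def save_mask(mask: RegionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.array.astype(np.uint8), _affine(mask.spacing_mm, mask.origin_mm))
    nib.save(img, str(path))


def save_labelmap(labels: np.ndarray, like: Volume | RegionMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        np.asarray(labels).astype(np.int16), _affine(like.spacing_mm, like.origin_mm)
    )
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return Volume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path: str | Path, role: str = "tumor") -> RegionMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in np.asarray(img.affine)[:3, 3])
    return RegionMask(np.asarray(img.dataobj) > 0.5, spacing, origin, role=role)


# --------------------------------------------------------------------------
# Resampling
# --------------------------------------------------------------------------

def resample_isotropic(
    volume: Volume,
    masks: list[RegionMask] | None = None,
    target_spacing_mm: float = 1.0,
) -> tuple[Volume, list[RegionMask]]:
    """Resample image and masks to an isotropic grid.

    The image is interpolated linearly, masks with nearest neighbour so they
    stay binary.  Output grid covers the same physical extent; origin is
    preserved.
    """
    if target_spacing_mm <= 0:
        raise GridError("target spacing must be positive")
    masks = list(masks) if masks else []
    for m in masks:
        if not volume.same_grid(m):
            raise GridError("mask grid does not match volume grid")

    src = np.asarray(volume.spacing_mm)
    if np.allclose(src, target_spacing_mm):
        return volume, masks

    new_shape = tuple(
        max(1, int(round(n * s / target_spacing_mm))) for n, s in zip(volume.shape, src)
    )
    # physical coordinate of each new voxel centre, mapped back to source index
    coords = np.meshgrid(
        *[
            (np.arange(n) * target_spacing_mm) / s
            for n, s in zip(new_shape, src)
        ],
        indexing="ij",
    )
    out = ndimage.map_coordinates(volume.array, coords, order=1, mode="nearest")
    new_spacing = (target_spacing_mm,) * 3
    out_vol = Volume(out, new_spacing, volume.origin_mm)
    out_masks = [
        RegionMask(
            ndimage.map_coordinates(
                m.array.astype(np.uint8), coords, order=0, mode="constant", cval=0
            ).astype(bool),
            new_spacing,
            volume.origin_mm,
            role=m.role,
        )
        for m in masks
    ]
    return out_vol, out_masks


# --------------------------------------------------------------------------
# Bias-field correction
# --------------------------------------------------------------------------

def _poly_design(shape: tuple[int, int, int], degree: int) -> np.ndarray:
    """Monomial basis of total degree <= degree on coords normalized to [-1, 1]."""
    ax = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(n) for n in shape]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append((X**i) * (Y**j) * (Z**k))
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_bias(
    volume: Volume,
    mask: RegionMask,
    degree: int = 3,
    backend: str = "polynomial",
    max_fit_voxels: int = 50_000,
    seed: int = 0,
) -> Volume:
    """Remove a smooth multiplicative intensity field.

    Default backend fits a low-order (``degree`` <= 3) polynomial to the log
    intensities over the body ``mask`` and divides the fitted field out
    (normalized to unit geometric mean, so overall intensity scale is kept).
    ``backend='n4'`` delegates to SimpleITK's N4 implementation if installed.
    """
    if mask.voxel_count == 0:
        raise GridError("bias correction requires a nonempty mask")
    if not volume.same_grid(mask):
        raise GridError("mask grid does not match volume grid")
    if backend == "n4":
        return _correct_bias_n4(volume, mask)
    if backend != "polynomial":
        raise ValueError(f"unknown bias backend: {backend}")
    if degree > 3:
        raise ValueError("polynomial backend supports degree <= 3")

    arr = volume.array
    shift = 0.0
    vals = arr[mask.array]
    lo = vals.min()
    if lo <= 0:
        shift = float(1e-3 * (vals.max() - lo + 1.0) - lo)
        warnings.warn(
            "non-positive intensities in mask; shifting before log-domain fit",
            stacklevel=2,
        )
    logim = np.log(arr + shift, where=(arr + shift) > 0, out=np.zeros_like(arr))

    design = _poly_design(volume.shape, degree)
    flat_idx = np.flatnonzero(mask.array.ravel())
    if flat_idx.size > max_fit_voxels:
        rng = np.random.default_rng(seed)
        flat_idx = rng.choice(flat_idx, size=max_fit_voxels, replace=False)
    coef, *_ = np.linalg.lstsq(design[flat_idx], logim.ravel()[flat_idx], rcond=None)
    log_field = design @ coef
    log_field -= log_field[np.flatnonzero(mask.array.ravel())].mean()  # unit geo-mean
    fieldvol = np.exp(log_field.reshape(volume.shape))
    corrected = (arr + shift) / fieldvol - shift
    return Volume(corrected, volume.spacing_mm, volume.origin_mm)


def _correct_bias_n4(volume: Volume, mask: RegionMask) -> Volume:
    import SimpleITK as sitk  # optional backend

    img = sitk.GetImageFromArray(volume.array.astype(np.float32))
    img.SetSpacing(volume.spacing_mm[::-1])
    msk = sitk.GetImageFromArray(mask.array.astype(np.uint8))
    msk.SetSpacing(volume.spacing_mm[::-1])
    out = sitk.N4BiasFieldCorrection(img, msk)
    return Volume(
        sitk.GetArrayFromImage(out).astype(np.float64),
        volume.spacing_mm,
        volume.origin_mm,
    )


# --------------------------------------------------------------------------
# Intensity normalization
# --------------------------------------------------------------------------

def normalize_intensity(volume: Volume, mask: RegionMask) -> Volume:
    """Z-score the image using mean/SD computed over ``mask`` (body region).

    Normalizing over the whole body region (rather than tumor-only) keeps
    habitat intensity contrasts comparable across patients.
    """
    if mask.voxel_count == 0:
        raise GridError("normalization region is empty")
    vals = volume.array[mask.array]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0:
        raise GridError(f"zero intensity SD over region '{mask.role}'")
    return Volume((volume.array - mu) / sd, volume.spacing_mm, volume.origin_mm)


# --------------------------------------------------------------------------
# Peritumoral rings
# --------------------------------------------------------------------------

def peritumoral_ring(
    tumor_mask: RegionMask,
    distance_mm: float,
    body_mask: RegionMask | None = None,
) -> RegionMask:
    """Shell of voxels outside the tumor within ``distance_mm`` of it.

    Distance is voxel-centre to nearest tumor voxel-centre, Euclidean in
    physical mm (exact distance transform); voxels at exactly ``distance_mm``
    are included.  The ring is disjoint from the tumor and clipped at the
    image boundary; ``body_mask`` optionally clips it to the body.
    """
    if distance_mm <= 0:
        raise ValueError("ring distance must be positive")
    if tumor_mask.voxel_count == 0:
        raise GridError("tumor mask is empty")
    dist = ndimage.distance_transform_edt(
        ~tumor_mask.array, sampling=tumor_mask.spacing_mm
    )
    ring = (dist > 0) & (dist <= distance_mm + 1e-9)
    if body_mask is not None:
        ring &= body_mask.array
    return RegionMask(
        ring,
        tumor_mask.spacing_mm,
        tumor_mask.origin_mm,
        role=f"ring_{distance_mm:g}mm",
    )


def peritumoral_rings(
    tumor_mask: RegionMask,
    distances_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0),
    body_mask: RegionMask | None = None,
) -> dict[float, RegionMask]:
    """Rings at several distances from one shared distance transform."""
    out = {}
    for d in distances_mm:
        out[d] = peritumoral_ring(tumor_mask, d, body_mask=body_mask)
    return out
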