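"""Volume/mask I/O and network-input preparation.

Axial slices (the last array axis) are the working unit for per-slice
clustering and for the deep-feature input.  ``crop_resize_input`` implements
the "background removed, resized to 224 x 224" contract: intensities outside
the ROI are zeroed, the mask bounding box is cropped, padded to a square with
zeros (aspect preserved) and bilinearly resized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from skimage.transform import resize


class AlignmentError(ValueError):
    """Mask and volume grids do not agree."""


class EmptyMaskError(ValueError):
    """An operation requiring ROI voxels received an empty mask."""


@dataclass
class ImageVolume:
    """A 3-D scalar intensity grid with voxel spacing in millimetres."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        if self.affine is None:
            self.affine = np.diag(list(self.spacing_mm) + [1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class RoiMask:
    """Binary ROI grid aligned to an :class:`ImageVolume`."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = (np.asarray(self.data) != 0).astype(np.uint8)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def write_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: RoiMask, path, spacing_mm=(1.0, 1.0, 1.0), affine=None) -> None:
    if affine is None:
        affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def write_labelmap(labels: np.ndarray, path, spacing_mm=(1.0, 1.0, 1.0), affine=None) -> None:
    """Write an integer label map (0 background, 1=S1, 2=S2, ...) as NIfTI."""
    if affine is None:
        affine = np.diag(list(spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(labels).astype(np.uint8), affine)
    img.header.set_zooms(spacing_mm)
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(data=data, spacing_mm=zooms, affine=img.affine)


def read_mask(path, volume: ImageVolume) -> RoiMask:
    """Read a NIfTI label map and binarize it (any nonzero voxel -> 1)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.shape != volume.shape:
        raise AlignmentError(
            f"mask shape {data.shape} does not match volume shape {volume.shape}"
        )
    mask = RoiMask(data=data)
    if mask.n_voxels == 0:
        raise EmptyMaskError(f"mask at {path} has no positive voxels")
    return mask


def export_png(image: np.ndarray, path) -> None:
    """Diagnostic PNG export of a 2-D image (min-max scaled to 8-bit)."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=np.float64)
    lo, hi = img.min(), img.max()
    scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    iio.imwrite(str(path), (scaled * 255).astype(np.uint8))


def largest_roi_slice(mask: RoiMask) -> int:
    """Index of the axial slice with the largest in-slice ROI area.

    Ties are broken toward the lowest slice index (``np.argmax`` semantics).
    """
    counts = mask.data.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise EmptyMaskError("cannot select a slice from an empty mask")
    return int(np.argmax(counts))


def crop_resize_input(
    slice_image: np.ndarray, slice_mask: np.ndarray, side: int = 224
) -> np.ndarray:
    """Masked, cropped, square-padded, bilinearly resized network input.

    Pixels outside the mask are set to zero before cropping so that no
    background intensity leaks into the network input.  The mask bounding box
    is padded symmetrically with zeros to a square (preserving the ROI aspect
    ratio) and resized to ``side x side`` with bilinear interpolation.
    """
    slice_image = np.asarray(slice_image, dtype=np.float64)
    slice_mask = np.asarray(slice_mask) != 0
    if slice_image.shape != slice_mask.shape:
        raise AlignmentError("slice image and mask shapes differ")
    if not slice_mask.any():
        raise EmptyMaskError("slice mask is empty")

    masked = np.where(slice_mask, slice_image, 0.0)
    rows = np.flatnonzero(slice_mask.any(axis=1))
    cols = np.flatnonzero(slice_mask.any(axis=0))
    crop = masked[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]

    h, w = crop.shape
    size = max(h, w)
    padded = np.zeros((size, size), dtype=np.float64)
    r0 = (size - h) // 2
    c0 = (size - w) // 2
    padded[r0 : r0 + h, c0 : c0 + w] = crop

    if padded.shape == (side, side):
        return padded
    return resize(
        padded,
        (side, side),
        order=1,
        mode="constant",
        cval=0.0,
        anti_aliasing=False,
        preserve_range=True,
    )
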