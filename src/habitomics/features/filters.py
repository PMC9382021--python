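"""Image filters applied before feature extraction.

Supported filter identifiers (the prefix of a canonical feature name):

- ``original``: the unfiltered volume;
- ``wavelet-XYZ`` with X,Y,Z in {L,H}: one sub-band of a one-level stationary
  (undecimated) 3-D wavelet decomposition, coiflet-1 kernel, L = approximation
  and H = detail along each axis;
- ``log-sigma-<s>-mm-3D``: Laplacian of Gaussian, sigma given in millimetres
  and converted per-axis through the voxel spacing;
- ``square``: intensities squared, linearly rescaled back to the original
  maximum absolute intensity;
- ``squareroot``: sqrt(|x|) * sign(x), rescaled likewise;
- ``lbp-3D-m1`` / ``lbp-3D-m2`` / ``lbp-3D-k``: 3-D local binary pattern
  moment maps (first and second moments of the binary spherical pattern) and
  the kurtosis map of the sampled spherical neighborhood.
"""

from __future__ import annotations

import re

import numpy as np
import pywt
from scipy import ndimage

_WAVELET = "coif1"


def _pad_to_even(volume: np.ndarray):
    pads = [(0, n % 2) for n in volume.shape]
    return np.pad(volume, pads, mode="edge"), pads


def wavelet_bands(volume: np.ndarray) -> dict:
    """All 8 sub-bands of a one-level stationary 3-D wavelet transform.

    Keys are 'LLL'..'HHH', letter order following the array axes.  The
    undecimated transform keeps every band at the input shape.
    """
    padded, pads = _pad_to_even(volume.astype(np.float64))
    coeffs = pywt.swtn(padded, _WAVELET, level=1)[0]
    out = {}
    for key, band in coeffs.items():
        label = "".join("L" if c == "a" else "H" for c in key)
        crop = tuple(slice(0, band.shape[i] - pads[i][1]) for i in range(band.ndim))
        out[label] = band[crop]
    return out


def log_filter(volume: np.ndarray, sigma_mm: float, spacing_mm) -> np.ndarray:
    """Laplacian of Gaussian with physical (mm) sigma."""
    sigma_vox = [sigma_mm / s for s in spacing_mm]
    # truncate=8: the default 4-sigma kernel truncation leaves a small DC
    # residual (a constant input maps to ~1e-3, not 0); 8 sigma is exact to
    # float precision.
    return ndimage.gaussian_laplace(volume.astype(np.float64), sigma=sigma_vox, truncate=8.0)


def square_filter(volume: np.ndarray) -> np.ndarray:
    """Intensities squared, rescaled so max |output| equals max |input|."""
    v = volume.astype(np.float64)
    out = v**2
    peak = np.abs(out).max()
    return out * (np.abs(v).max() / peak) if peak > 0 else out


def squareroot_filter(volume: np.ndarray) -> np.ndarray:
    """Signed square root, rescaled so max |output| equals max |input|."""
    v = volume.astype(np.float64)
    out = np.sqrt(np.abs(v)) * np.sign(v)
    peak = np.abs(out).max()
    return out * (np.abs(v).max() / peak) if peak > 0 else out


def _icosphere_directions(subdivisions: int = 1) -> np.ndarray:
    """Unit vectors of an icosahedron subdivided ``subdivisions`` times."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    for _ in range(subdivisions):
        mids = {}
        new_faces = []
        vlist = list(verts)

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in mids:
                m = (vlist[i] + vlist[j]) / 2.0
                m /= np.linalg.norm(m)
                mids[key] = len(vlist)
                vlist.append(m)
            return mids[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    return verts


def lbp3d_maps(
    volume: np.ndarray,
    radius_vox: float = 1.0,
    subdivisions: int = 1,
    mask: np.ndarray | None = None,
) -> dict:
    """3-D local binary pattern moment maps.

    For each voxel, the intensity is sampled (trilinear) at points of a
    subdivided icosahedron of radius ``radius_vox``; with the binary pattern
    b_k = [sample_k >= center]:

    - m1: first moment of the pattern (fraction of brighter neighbors);
    - m2: second central moment of the pattern;
    - k: excess kurtosis of the raw sampled neighborhood values (0 where the
      neighborhood is constant).

    With ``mask`` given, maps are computed only at mask voxels (0 elsewhere).
    """
    v = volume.astype(np.float64)
    dirs = _icosphere_directions(subdivisions) * radius_vox
    if mask is not None:
        coords = np.argwhere(np.asarray(mask) != 0).T.astype(np.float64)
    else:
        grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in v.shape], indexing="ij")
        coords = np.stack([g.ravel() for g in grids])
    samples = np.empty((len(dirs), coords.shape[1]))
    for i, d in enumerate(dirs):
        samples[i] = ndimage.map_coordinates(v, coords + d[:, None], order=1, mode="nearest")
    center = v[tuple(coords.astype(int))] if mask is not None else v.ravel()

    b = (samples >= center).astype(np.float64)
    m1 = b.mean(axis=0)
    m2 = ((b - m1) ** 2).mean(axis=0)
    mu = samples.mean(axis=0)
    d2 = (samples - mu) ** 2
    v2 = d2.mean(axis=0)
    v4 = (d2**2).mean(axis=0)
    scale = np.maximum(np.abs(samples).max(axis=0), 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(v2 > (1e-9 * scale) ** 2, v4 / v2**2 - 3.0, 0.0)

    def as_map(flat):
        if mask is None:
            return flat.reshape(v.shape)
        out = np.zeros(v.shape)
        idx = coords.astype(int)
        out[idx[0], idx[1], idx[2]] = flat
        return out

    return {"m1": as_map(m1), "m2": as_map(m2), "k": as_map(k)}


_LOG_RE = re.compile(r"^log-sigma-(\d+(?:\.\d+)?)-mm-3D$")


def apply_filter(volume: np.ndarray, spacing_mm, filter_id: str) -> np.ndarray:
    """Dispatch a canonical filter identifier to its implementation."""
    if filter_id == "original":
        return volume.astype(np.float64)
    if filter_id.startswith("wavelet-"):
        label = filter_id.split("-", 1)[1]
        bands = wavelet_bands(volume)
        if label not in bands:
            raise ValueError(f"unknown wavelet sub-band {label!r}")
        return bands[label]
    m = _LOG_RE.match(filter_id)
    if m:
        return log_filter(volume, float(m.group(1)), spacing_mm)
    if filter_id == "square":
        return square_filter(volume)
    if filter_id == "squareroot":
        return squareroot_filter(volume)
    if filter_id.startswith("lbp-3D-"):
        kind = filter_id.rsplit("-", 1)[1]
        maps = lbp3d_maps(volume)
        if kind not in maps:
            raise ValueError(f"unknown lbp-3D map {kind!r}")
        return maps[kind]
    raise ValueError(f"unknown filter {filter_id!r}")
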