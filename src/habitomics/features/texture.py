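"""IBSI-style texture matrices and features.

All four families operate on a gray-level-discretized image restricted to a
binary mask.  Inputs may be 2-D or 3-D; 2-D inputs (or 3-D masks confined to
a single slice) use the in-plane direction/connectivity sets (4 directions,
8-connectivity), full 3-D inputs use 13 unique distance-1 directions and
26-connectivity.  GLCM and GLRLM features are averaged over directions.
Degenerate inputs take their conventional values (constant ROI: GLCM Imc1 =
0, NGTDM Contrast = Busyness = 0) instead of raising.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class DiscretizationSettings:
    """Gray-level discretization: fixed bin count over the ROI range, or
    fixed bin width anchored at the ROI minimum."""

    mode: str = "fixed-bin-count"  # or "fixed-bin-width"
    value: float = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed-bin-count", "fixed-bin-width"):
            raise ValueError(f"unknown discretization mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("discretization value must be positive")


def discretize(image: np.ndarray, mask: np.ndarray, settings: DiscretizationSettings):
    """Integer gray levels 1..Ng on mask voxels (0 outside the mask)."""
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask) != 0
    if not msk.any():
        raise ValueError("discretization requires a non-empty mask")
    vals = img[msk]
    lo = float(vals.min())
    if settings.mode == "fixed-bin-count":
        n = int(settings.value)
        hi = float(vals.max())
        if hi == lo:
            levels = np.ones_like(img, dtype=np.int64)
        else:
            levels = np.clip(((img - lo) / (hi - lo) * n).astype(np.int64), 0, n - 1) + 1
    else:
        w = float(settings.value)
        levels = np.floor(img / w).astype(np.int64) - int(np.floor(lo / w)) + 1
    levels = np.where(msk, levels, 0)
    return levels, int(levels.max())


def _as3d(arr: np.ndarray) -> np.ndarray:
    return arr[:, :, None] if arr.ndim == 2 else arr


def _directions(mask3d: np.ndarray) -> list:
    """Unique distance-1 directions: in-plane only for single-slice masks."""
    single_slice = int((mask3d.any(axis=(0, 1))).sum()) <= 1
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        if single_slice and d[2] != 0:
            continue
        first = next(x for x in d if x != 0)
        if first > 0:
            dirs.append(d)
    return dirs


def _shift(arr: np.ndarray, d, fill=0) -> np.ndarray:
    """Array shifted by -d (value at v becomes value previously at v+d)."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for n, di in zip(arr.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _shift2d(plane: np.ndarray, d) -> np.ndarray:
    """2-D variant of :func:`_shift` used inside the run-length sweep."""
    out = np.zeros_like(plane)
    src = []
    dst = []
    for n, di in zip(plane.shape, d):
        if di >= 0:
            src.append(slice(di, n))
            dst.append(slice(0, n - di))
        else:
            src.append(slice(0, n + di))
            dst.append(slice(-di, n))
    out[tuple(dst)] = plane[tuple(src)]
    return out


def _prep(image, mask):
    levels_in = np.asarray(image)
    msk = _as3d(np.asarray(mask) != 0)
    lv = _as3d(levels_in).astype(np.int64)
    if not msk.any():
        raise ValueError("texture features require a non-empty mask")
    return lv, msk


# ---------------------------------------------------------------- GLCM


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix for one direction."""
    ng = int(levels.max())
    a = levels
    b = _shift(levels, direction)
    valid = mask & _shift(mask, direction)
    pairs_a = a[valid]
    pairs_b = b[valid]
    C = np.zeros((ng, ng), dtype=np.float64)
    np.add.at(C, (pairs_a - 1, pairs_b - 1), 1.0)
    C = C + C.T
    total = C.sum()
    return C / total if total > 0 else C


def _glcm_single(P: np.ndarray, features) -> dict:
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    out = {}
    for feat in features:
        if feat == "InverseVariance":
            off = ii != jj
            with np.errstate(divide="ignore"):
                out[feat] = float((P[off] / (ii[off] - jj[off]) ** 2).sum())
        elif feat == "Contrast":
            out[feat] = float((P * (ii - jj) ** 2).sum())
        elif feat == "Imc1":
            nz = P > 0
            hxy = float(-(P[nz] * np.log2(P[nz])).sum())
            pxy = np.outer(px, py)
            nz1 = (P > 0) & (pxy > 0)
            hxy1 = float(-(P[nz1] * np.log2(pxy[nz1])).sum())
            hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
            hy = float(-(py[py > 0] * np.log2(py[py > 0])).sum())
            denom = max(hx, hy)
            out[feat] = (hxy - hxy1) / denom if denom > 0 else 0.0
        else:
            raise ValueError(f"unknown GLCM feature {feat!r}")
    return out


GLCM_FEATURES = ("InverseVariance", "Imc1", "Contrast")


def glcm_features(image, mask, settings=None, features=GLCM_FEATURES, directions=None) -> dict:
    """Direction-averaged GLCM features on the discretized ROI.

    ``image`` may be raw intensities (discretized via ``settings``) or an
    already-discretized integer level map when ``settings`` is None.
    """
    if settings is not None:
        levels, _ = discretize(image, mask, settings)
    else:
        levels = image
    lv, msk = _prep(levels, mask)
    dirs = directions if directions is not None else _directions(msk)
    acc = {f: 0.0 for f in features}
    for d in dirs:
        vals = _glcm_single(glcm_matrix(lv, msk, d), features)
        for f in features:
            acc[f] += vals[f]
    return {f: acc[f] / len(dirs) for f in features}


# ---------------------------------------------------------------- GLRLM


def glrlm_matrix(levels: np.ndarray, mask: np.ndarray, direction) -> np.ndarray:
    """Run-length matrix r(gray level, run length) for one direction.

    Runs are maximal in-mask sequences of equal gray level along the
    direction, found by an iterative plane sweep: the run length ending at a
    voxel extends the run at its predecessor when both are in the mask and
    share the level.
    """
    ng = int(levels.max())
    neg = tuple(-x for x in direction)
    same_prev = mask & _shift(mask, neg) & (levels == _shift(levels, neg))

    axis = next(i for i, x in enumerate(direction) if x != 0)
    step = direction[axis]
    order = range(levels.shape[axis]) if step > 0 else range(levels.shape[axis] - 1, -1, -1)
    rest = tuple(-x for i, x in enumerate(direction) if i != axis)

    R = np.where(mask, 1, 0).astype(np.int64)
    R = np.moveaxis(R, axis, 0)
    sp = np.moveaxis(same_prev, axis, 0)
    for t in order:
        pt = t - step
        if pt < 0 or pt >= R.shape[0]:
            continue
        prev_plane = _shift2d(R[pt], rest)
        R[t] = np.where(sp[t], prev_plane + 1, R[t])
    R = np.moveaxis(R, 0, axis)

    next_mask = _shift(mask, direction)
    next_lv = _shift(levels, direction)
    run_end = mask & ~(next_mask & (levels == next_lv))
    g = levels[run_end]
    ln = R[run_end]
    max_len = int(ln.max()) if ln.size else 1
    M = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(M, (g - 1, ln - 1), 1.0)
    return M


def _glrlm_single(M: np.ndarray, features) -> dict:
    nr = M.sum()
    i = np.arange(1, M.shape[0] + 1)[:, None]
    j = np.arange(1, M.shape[1] + 1)[None, :]
    out = {}
    for feat in features:
        if feat == "LongRunEmphasis":
            out[feat] = float((M * j**2).sum() / nr)
        elif feat == "ShortRunEmphasis":
            out[feat] = float((M / j**2).sum() / nr)
        elif feat == "LongRunLowGrayLevelEmphasis":
            out[feat] = float((M * j**2 / i**2).sum() / nr)
        else:
            raise ValueError(f"unknown GLRLM feature {feat!r}")
    return out


GLRLM_FEATURES = ("LongRunEmphasis", "ShortRunEmphasis", "LongRunLowGrayLevelEmphasis")


def glrlm_features(image, mask, settings=None, features=GLRLM_FEATURES, directions=None) -> dict:
    """Direction-averaged run-length features on the discretized ROI."""
    if settings is not None:
        levels, _ = discretize(image, mask, settings)
    else:
        levels = image
    lv, msk = _prep(levels, mask)
    dirs = directions if directions is not None else _directions(msk)
    acc = {f: 0.0 for f in features}
    for d in dirs:
        vals = _glrlm_single(glrlm_matrix(lv, msk, d), features)
        for f in features:
            acc[f] += vals[f]
    return {f: acc[f] / len(dirs) for f in features}


# ---------------------------------------------------------------- GLSZM


def glszm_zones(levels: np.ndarray, mask: np.ndarray) -> list:
    """(gray level, zone size) for every connected equal-level zone.

    26-connectivity in 3-D, 8-connectivity for single-slice masks.
    """
    single_slice = int((mask.any(axis=(0, 1))).sum()) <= 1
    if single_slice:
        structure = np.zeros((3, 3, 3), dtype=bool)
        structure[:, :, 1] = True
    else:
        structure = np.ones((3, 3, 3), dtype=bool)
    zones = []
    for g in np.unique(levels[mask]):
        lab, n = ndimage.label((levels == g) & mask, structure=structure)
        sizes = np.bincount(lab.ravel())[1:]
        zones += [(int(g), int(s)) for s in sizes]
    return zones


GLSZM_FEATURES = (
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "GrayLevelVariance",
)


def glszm_features(image, mask, settings=None, features=GLSZM_FEATURES) -> dict:
    """Size-zone features from connected equal-level zones."""
    if settings is not None:
        levels, _ = discretize(image, mask, settings)
    else:
        levels = image
    lv, msk = _prep(levels, mask)
    zones = glszm_zones(lv, msk)
    g = np.array([z[0] for z in zones], dtype=np.float64)
    s = np.array([z[1] for z in zones], dtype=np.float64)
    nz = len(zones)
    out = {}
    for feat in features:
        if feat == "SmallAreaHighGrayLevelEmphasis":
            out[feat] = float((g**2 / s**2).sum() / nz)
        elif feat == "LargeAreaHighGrayLevelEmphasis":
            out[feat] = float((g**2 * s**2).sum() / nz)
        elif feat == "GrayLevelVariance":
            p = 1.0 / nz
            mu = float((g * p).sum())
            out[feat] = float((p * (g - mu) ** 2).sum())
        else:
            raise ValueError(f"unknown GLSZM feature {feat!r}")
    return out


# ---------------------------------------------------------------- NGTDM


NGTDM_FEATURES = ("Contrast", "Busyness")


def ngtdm_features(image, mask, settings=None, features=NGTDM_FEATURES) -> dict:
    """Neighbourhood gray-tone difference features.

    For each in-mask voxel, the absolute difference between its level and the
    mean level of its in-mask neighbors (full 26/8-neighborhood excluding the
    center, clipped at image edges) accumulates into s_i.  A single occupied
    gray level yields Contrast = Busyness = 0 by convention.
    """
    if settings is not None:
        levels, _ = discretize(image, mask, settings)
    else:
        levels = image
    lv, msk = _prep(levels, mask)
    single_slice = int((msk.any(axis=(0, 1))).sum()) <= 1
    kernel = np.ones((3, 3, 1) if single_slice else (3, 3, 3), dtype=np.float64)

    mask_f = msk.astype(np.float64)
    lv_f = lv.astype(np.float64) * mask_f
    neigh_sum = ndimage.correlate(lv_f, kernel, mode="constant", cval=0.0) - lv_f
    neigh_cnt = ndimage.correlate(mask_f, kernel, mode="constant", cval=0.0) - mask_f

    valid = msk & (neigh_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        diff = np.abs(lv_f - neigh_sum / neigh_cnt)
    g = lv[valid]
    ng = int(lv.max())
    s = np.zeros(ng + 1)
    n = np.zeros(ng + 1)
    np.add.at(s, g, diff[valid])
    np.add.at(n, g, 1.0)
    s, n = s[1:], n[1:]
    N = n.sum()
    p = n / N
    occupied = p > 0
    ngp = int(occupied.sum())
    i = np.arange(1, ng + 1, dtype=np.float64)

    out = {}
    for feat in features:
        if feat == "Contrast":
            if ngp < 2:
                out[feat] = 0.0
            else:
                pij = np.outer(p, p) * (i[:, None] - i[None, :]) ** 2
                out[feat] = float(pij.sum() / (ngp * (ngp - 1)) * (s.sum() / N))
        elif feat == "Busyness":
            ipi = i * p
            grid = np.abs(ipi[:, None] - ipi[None, :])
            denom = float(grid[np.ix_(occupied, occupied)].sum())
            out[feat] = float((p * s).sum() / denom) if denom > 0 else 0.0
        else:
            raise ValueError(f"unknown NGTDM feature {feat!r}")
    return out
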