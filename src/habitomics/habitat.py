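"""Intratumor subregion ("habitat") partitioning.

Three-stage procedure:

1. per-slice local Shannon entropy of the ROI intensities in a sliding
   window (default 9 x 9), a texture/heterogeneity map;
2. patient-level k-means on (z-scored intensity, z-scored entropy) pixel
   pairs, producing "superpixels" — clusters of phenotypically similar ROI
   pixels within one slice;
3. population-level agglomerative (Ward) clustering of all superpixels'
   (mean intensity, mean entropy) descriptors, with the number of clusters k
   chosen by the Calinski-Harabasz index over k = 2..10.

Cluster labels are mapped back to pixels and named S1, S2, ... in order of
decreasing population mean entropy, so S1 is always the most heterogeneous
(in practice the marginal) subregion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import AgglomerativeClustering, KMeans

from habitomics.imaging_io import EmptyMaskError
from habitomics.phantom import PhantomCase


@dataclass
class EntropyMap:
    """Per-pixel local entropy (bits) on the mask-positive pixels of a slice."""

    values: np.ndarray  # 2-D, zero outside the mask
    mask: np.ndarray
    n_bins: int


@dataclass
class SuperpixelRecord:
    """One patient-level cluster of ROI pixels in a single slice."""

    case_id: str
    slice_index: int
    pixel_coords: np.ndarray  # (n, 2) row/col indices
    mean_intensity: float
    mean_entropy: float

    @property
    def n_pixels(self) -> int:
        return len(self.pixel_coords)


@dataclass
class HabitatPartition:
    """Population-level subregion partition of a cohort."""

    k: int
    labels: dict  # case_id -> int array (0 background, 1=S1, 2=S2, ...)
    subregion_identity: dict  # population cluster id -> "S1", "S2", ...
    ch_by_k: dict  # k -> Calinski-Harabasz value
    entropy_maps: dict = field(default_factory=dict)  # case_id -> 3-D entropy array


def local_entropy(
    slice_image: np.ndarray,
    slice_mask: np.ndarray,
    window: int = 9,
    n_bins: int = 32,
    restrict_to_mask: bool = True,
) -> EntropyMap:
    """Local Shannon entropy (bits) of windowed intensity histograms.

    For each mask pixel, intensities inside a ``window x window`` neighborhood
    (clipped at the image edge) are binned into ``n_bins`` equal-width bins
    spanning the slice's ROI intensity range; the entropy of the occupancy
    distribution is -sum p log2 p.  With ``restrict_to_mask`` (default) only
    in-mask neighbors contribute, so the map measures intratumoral texture
    rather than the tumor/background interface.  A constant ROI yields zero
    everywhere; values are bounded by log2(n_bins).
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    img = np.asarray(slice_image, dtype=np.float64)
    mask = np.asarray(slice_mask) != 0
    if not mask.any():
        raise EmptyMaskError("entropy map requires a non-empty slice mask")

    vals = img[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        idx = np.clip(((img - lo) / (hi - lo) * n_bins).astype(int), 0, n_bins - 1)
    else:
        idx = np.zeros_like(img, dtype=int)

    support = mask if restrict_to_mask else np.ones_like(mask)
    half = window // 2
    h, w = img.shape

    # Per-bin window counts via 2-D integral images (exact edge clipping).
    counts = np.zeros((n_bins, h, w), dtype=np.float64)
    for b in range(n_bins):
        member = ((idx == b) & support).astype(np.float64)
        ii = np.zeros((h + 1, w + 1))
        np.cumsum(np.cumsum(member, axis=0), axis=1, out=ii[1:, 1:])
        r0 = np.clip(np.arange(h) - half, 0, h)
        r1 = np.clip(np.arange(h) + half + 1, 0, h)
        c0 = np.clip(np.arange(w) - half, 0, w)
        c1 = np.clip(np.arange(w) + half + 1, 0, w)
        counts[b] = (
            ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
        )

    total = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    ent = np.where(mask & (total > 0), terms.sum(axis=0), 0.0)
    return EntropyMap(values=ent, mask=mask, n_bins=n_bins)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def default_n_superpixels(n_pixels: int, pixels_per_superpixel: int = 1000) -> int:
    """Density-based superpixel count: one per ~1000 ROI pixels, in [2, 20].

    Superpixels must average over enough pixels that their (mean intensity,
    mean entropy) descriptors concentrate near compartment-level phenotypes
    rather than tiling the per-pixel noise distribution; at sub-millimetre
    in-plane spacing a tumor cross-section holds thousands of pixels, so one
    superpixel per ~1000 pixels still yields several per slice and tens per
    patient.
    """
    return int(np.clip(math.ceil(n_pixels / pixels_per_superpixel), 2, 20))


def patient_superpixels(
    slice_image: np.ndarray,
    entropy: EntropyMap,
    slice_mask: np.ndarray,
    n_superpixels: int,
    seed: int = 0,
    case_id: str = "case",
    slice_index: int = 0,
) -> list[SuperpixelRecord]:
    """Patient-level k-means superpixels on (intensity, entropy) pixel pairs.

    Both coordinates are z-scored over the slice ROI so that the Euclidean
    metric weighs them comparably; reported superpixel means are computed on
    the raw values.  Deterministic given the seed (k-means++ init, single
    initialization).
    """
    img = np.asarray(slice_image, dtype=np.float64)
    mask = np.asarray(slice_mask) != 0
    coords = np.argwhere(mask)
    if len(coords) < n_superpixels:
        raise ValueError(
            f"slice has {len(coords)} ROI pixels, fewer than {n_superpixels} superpixels"
        )
    intens = img[mask]
    ent = entropy.values[mask]
    X = np.column_stack([_zscore(intens), _zscore(ent)])

    km = KMeans(
        n_clusters=n_superpixels,
        init="k-means++",
        n_init=10,
        max_iter=300,
        tol=1e-6,
        random_state=seed,
    )
    labels = km.fit_predict(X)

    records = []
    for lab in range(n_superpixels):
        member = labels == lab
        if not member.any():
            warnings.warn(f"empty superpixel {lab} dropped", stacklevel=2)
            continue
        records.append(
            SuperpixelRecord(
                case_id=case_id,
                slice_index=slice_index,
                pixel_coords=coords[member],
                mean_intensity=float(intens[member].mean()),
                mean_entropy=float(ent[member].mean()),
            )
        )
    return records


def _record_points(records: list[SuperpixelRecord]) -> np.ndarray:
    pts = np.array([[r.mean_intensity, r.mean_entropy] for r in records])
    return np.column_stack([_zscore(pts[:, 0]), _zscore(pts[:, 1])])


def population_clustering(records: list[SuperpixelRecord], k: int) -> np.ndarray:
    """Ward-linkage agglomerative clustering of superpixel descriptors.

    Operates on the population-z-scored (mean intensity, mean entropy) points;
    returns one integer label per record.
    """
    if k > len(records):
        raise ValueError(f"k={k} exceeds the number of superpixel records ({len(records)})")
    X = _record_points(records)
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    return model.fit_predict(X)


def ch_index(points: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz index: [B/(k-1)] / [W/(n-k)].

    B is the between-cluster sum of squared distances of cluster means to the
    grand mean (weighted by cluster size); W is the pooled within-cluster sum
    of squares.  W = 0 (perfectly tight clusters) returns +inf.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] == 1:
        points = points.T
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, k = len(points), len(uniq)
    if k < 2:
        raise ValueError("CH index requires at least 2 clusters")
    if n <= k:
        raise ValueError("CH index requires more points than clusters")
    grand = points.mean(axis=0)
    B = 0.0
    W = 0.0
    for u in uniq:
        member = points[labels == u]
        if len(member) == 0:
            raise ValueError(f"cluster {u} is empty")
        m = member.mean(axis=0)
        B += len(member) * float(((m - grand) ** 2).sum())
        W += float(((member - m) ** 2).sum())
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def select_k(
    records: list[SuperpixelRecord], k_min: int = 2, k_max: int = 10
) -> tuple[int, dict]:
    """Choose the cluster count maximizing the CH index over k_min..k_max.

    The CH index is evaluated on the same z-scored superpixel descriptors that
    are clustered.  Ties (including multiple +inf) resolve to the smaller k.
    """
    if len(records) <= k_max:
        new_max = len(records) - 1
        warnings.warn(
            f"only {len(records)} records; lowering k_max from {k_max} to {new_max}",
            stacklevel=2,
        )
        k_max = new_max
    if k_max < k_min:
        raise ValueError("not enough superpixel records to cluster")
    X = _record_points(records)
    ch_by_k = {}
    for k in range(k_min, k_max + 1):
        labels = population_clustering(records, k)
        ch_by_k[k] = ch_index(X, labels)
    best = max(ch_by_k, key=lambda k: (ch_by_k[k], -k))
    return best, ch_by_k


def build_partition(
    cases: list[PhantomCase],
    window: int = 9,
    n_bins: int = 32,
    pixels_per_superpixel: int = 1000,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    min_slice_pixels: int = 10,
) -> HabitatPartition:
    """End-to-end cohort partition: entropy -> superpixels -> Ward + CH.

    Each case contributes superpixels from every axial slice with at least
    ``min_slice_pixels`` ROI pixels.  Population labels are mapped back to
    member pixels; subregions are named S1, S2, ... by decreasing population
    mean entropy (S1 = most heterogeneous).
    """
    if len(cases) < 2:
        raise ValueError("partition requires at least 2 cases")
    rng = np.random.default_rng(seed)
    all_records: list[SuperpixelRecord] = []
    entropy_maps: dict = {}
    for case in cases:
        vol = case.volume.data
        msk = case.mask.data
        ent3d = np.zeros_like(vol)
        for z in range(vol.shape[2]):
            sl_mask = msk[:, :, z]
            npix = int(sl_mask.sum())
            if npix < min_slice_pixels:
                continue
            emap = local_entropy(vol[:, :, z], sl_mask, window=window, n_bins=n_bins)
            ent3d[:, :, z] = emap.values
            n_sp = default_n_superpixels(npix, pixels_per_superpixel)
            n_sp = min(n_sp, npix)
            all_records.extend(
                patient_superpixels(
                    vol[:, :, z],
                    emap,
                    sl_mask,
                    n_superpixels=n_sp,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    case_id=case.case_id,
                    slice_index=z,
                )
            )
        entropy_maps[case.case_id] = ent3d

    k_star, ch_by_k = select_k(all_records, k_min=k_min, k_max=k_max)
    pop_labels = population_clustering(all_records, k_star)

    # Rank clusters by pixel-weighted population mean entropy, descending.
    sums = {}
    for rec, lab in zip(all_records, pop_labels):
        s, n = sums.get(lab, (0.0, 0))
        sums[lab] = (s + rec.mean_entropy * rec.n_pixels, n + rec.n_pixels)
    order = sorted(sums, key=lambda lab: -(sums[lab][0] / sums[lab][1]))
    identity = {lab: f"S{rank + 1}" for rank, lab in enumerate(order)}
    rank_of = {lab: rank + 1 for rank, lab in enumerate(order)}

    labels_by_case: dict = {}
    for case in cases:
        labels_by_case[case.case_id] = np.zeros(case.mask.shape, dtype=np.uint8)
    for rec, lab in zip(all_records, pop_labels):
        arr = labels_by_case[rec.case_id]
        rr, cc = rec.pixel_coords[:, 0], rec.pixel_coords[:, 1]
        arr[rr, cc, rec.slice_index] = rank_of[lab]

    return HabitatPartition(
        k=k_star,
        labels=labels_by_case,
        subregion_identity=identity,
        ch_by_k=ch_by_k,
        entropy_maps=entropy_maps,
    )


def subregion_mask(partition: HabitatPartition, case_id: str, subregion: str = "S1") -> np.ndarray:
    """Binary mask of one named subregion for one case."""
    rank = int(subregion[1:])
    return partition.labels[case_id] == rank


def compare_subregions(
    partition: HabitatPartition, cases: list[PhantomCase], s_a: str = "S1", s_b: str = "S2"
):
    """Per-case subregion summaries and Welch t-tests between two subregions.

    Returns a dict with per-case mean intensity and mean entropy for each
    subregion and two-sided Welch t-test results across cases.  Cases where
    either subregion is absent are omitted with a warning.
    """
    int_a, int_b, ent_a, ent_b = [], [], [], []
    for case in cases:
        lab = partition.labels[case.case_id]
        ent = partition.entropy_maps[case.case_id]
        ma = lab == int(s_a[1:])
        mb = lab == int(s_b[1:])
        if not ma.any() or not mb.any():
            warnings.warn(f"{case.case_id}: subregion missing, case omitted", stacklevel=2)
            continue
        vol = case.volume.data
        int_a.append(float(vol[ma].mean()))
        int_b.append(float(vol[mb].mean()))
        ent_a.append(float(ent[ma].mean()))
        ent_b.append(float(ent[mb].mean()))
    if not int_a:
        raise ValueError("no case has both subregions")
    t_int = stats.ttest_ind(int_a, int_b, equal_var=False)
    t_ent = stats.ttest_ind(ent_a, ent_b, equal_var=False)
    return {
        "per_case": {
            f"{s_a}_intensity": np.array(int_a),
            f"{s_b}_intensity": np.array(int_b),
            f"{s_a}_entropy": np.array(ent_a),
            f"{s_b}_entropy": np.array(ent_b),
        },
        "intensity_t": float(t_int.statistic),
        "intensity_p": float(t_int.pvalue),
        "entropy_t": float(t_ent.statistic),
        "entropy_p": float(t_ent.pvalue),
    }
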