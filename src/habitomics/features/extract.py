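"""Feature-vector assembly: filter x family x statistic with canonical names.

Canonical feature names follow the ``<filter>_<family>_<Statistic>``
convention, e.g. ``wavelet-HLH_glrlm_LongRunEmphasis`` or
``original_firstorder_Mean``; deep features are named ``DL_<i>`` elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from habitomics.features.filters import apply_filter, wavelet_bands
from habitomics.features.firstorder import FIRSTORDER_STATS, firstorder_features
from habitomics.features.texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    DiscretizationSettings,
    discretize,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

DEFAULT_FILTERS = (
    "original",
    "wavelet-LLL",
    "wavelet-LLH",
    "wavelet-LHL",
    "wavelet-LHH",
    "wavelet-HLL",
    "wavelet-HLH",
    "wavelet-HHL",
    "wavelet-HHH",
    "log-sigma-3-mm-3D",
    "log-sigma-5-mm-3D",
    "square",
    "squareroot",
    "lbp-3D-m1",
    "lbp-3D-m2",
    "lbp-3D-k",
)


@dataclass
class FeatureConfig:
    """Which filters, families and statistics to extract, and how to
    discretize gray levels (fixed bin width on the original image, fixed bin
    count on filtered images, both configurable)."""

    filters: tuple = DEFAULT_FILTERS
    firstorder_stats: tuple = FIRSTORDER_STATS
    glcm: tuple = GLCM_FEATURES
    glrlm: tuple = GLRLM_FEATURES
    glszm: tuple = GLSZM_FEATURES
    ngtdm: tuple = NGTDM_FEATURES
    discretization_original: DiscretizationSettings = field(
        default_factory=lambda: DiscretizationSettings("fixed-bin-width", 25.0)
    )
    discretization_filtered: DiscretizationSettings = field(
        default_factory=lambda: DiscretizationSettings("fixed-bin-count", 32)
    )

    def n_features(self) -> int:
        per_filter = (
            len(self.firstorder_stats)
            + len(self.glcm)
            + len(self.glrlm)
            + len(self.glszm)
            + len(self.ngtdm)
        )
        return len(self.filters) * per_filter


def extract_all(volume, mask: np.ndarray, config: FeatureConfig | None = None) -> dict:
    """Handcrafted feature vector for one (volume, ROI/subregion mask) pair.

    ``volume`` is an :class:`~habitomics.imaging_io.ImageVolume`; ``mask`` a
    boolean array of the same shape (typically one subregion of a habitat
    partition).  Returns ``{canonical_name: value}``.  An empty mask returns
    an empty vector with a warning.
    """
    if config is None:
        config = FeatureConfig()
    mask = np.asarray(mask) != 0
    if not mask.any():
        warnings.warn("empty (sub)region mask: returning empty feature vector", stacklevel=2)
        return {}

    data = volume.data
    spacing = volume.spacing_mm

    # Crop to a padded bounding box: all filters and texture neighborhoods are
    # local, and this keeps large-volume extraction tractable.
    pad = 16
    idx = np.argwhere(mask)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + pad + 1, mask.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    data = data[box]
    mask = mask[box]

    bands = wavelet_bands(data) if any(f.startswith("wavelet-") for f in config.filters) else {}
    lbp_maps = {}
    if any(f.startswith("lbp-3D-") for f in config.filters):
        from habitomics.features.filters import lbp3d_maps

        lbp_maps = lbp3d_maps(data, mask=mask)

    out = {}
    for filt in config.filters:
        if filt.startswith("wavelet-"):
            img = bands[filt.split("-", 1)[1]]
        elif filt.startswith("lbp-3D-"):
            img = lbp_maps[filt.rsplit("-", 1)[1]]
        else:
            img = apply_filter(data, spacing, filt)
        disc = (
            config.discretization_original
            if filt == "original"
            else config.discretization_filtered
        )
        levels, _ = discretize(img, mask, disc)

        for stat, val in firstorder_features(img[mask], config.firstorder_stats).items():
            out[f"{filt}_firstorder_{stat}"] = val
        if config.glcm:
            for stat, val in glcm_features(levels, mask, None, config.glcm).items():
                out[f"{filt}_glcm_{stat}"] = val
        if config.glrlm:
            for stat, val in glrlm_features(levels, mask, None, config.glrlm).items():
                out[f"{filt}_glrlm_{stat}"] = val
        if config.glszm:
            for stat, val in glszm_features(levels, mask, None, config.glszm).items():
                out[f"{filt}_glszm_{stat}"] = val
        if config.ngtdm:
            for stat, val in ngtdm_features(levels, mask, None, config.ngtdm).items():
                out[f"{filt}_ngtdm_{stat}"] = val
    return out
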