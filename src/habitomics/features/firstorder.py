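"""First-order (histogram) statistics of an ROI intensity sample."""

from __future__ import annotations

import numpy as np

FIRSTORDER_STATS = (
    "Mean",
    "Median",
    "RootMeanSquared",
    "10Percentile",
    "90Percentile",
    "InterquartileRange",
    "Skewness",
    "MeanAbsoluteDeviation",
    "Variance",
)


def firstorder_features(values: np.ndarray, stats: tuple = FIRSTORDER_STATS) -> dict:
    """First-order statistics of a 1-D intensity sample.

    Percentiles use linear interpolation; skewness and variance are the
    population (biased) versions; skewness of a (near-)constant sample is 0 by
    convention; MAD is the mean absolute deviation about the mean.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("first-order features require at least one value")
    mean = float(x.mean())
    out = {}
    for stat in stats:
        if stat == "Mean":
            out[stat] = mean
        elif stat == "Median":
            out[stat] = float(np.median(x))
        elif stat == "RootMeanSquared":
            out[stat] = float(np.sqrt(np.mean(x**2)))
        elif stat == "10Percentile":
            out[stat] = float(np.percentile(x, 10))
        elif stat == "90Percentile":
            out[stat] = float(np.percentile(x, 90))
        elif stat == "InterquartileRange":
            out[stat] = float(np.percentile(x, 75) - np.percentile(x, 25))
        elif stat == "Skewness":
            m2 = float(np.mean((x - mean) ** 2))
            m3 = float(np.mean((x - mean) ** 3))
            denom = m2**1.5
            out[stat] = m3 / denom if denom > 0 else 0.0
        elif stat == "MeanAbsoluteDeviation":
            out[stat] = float(np.mean(np.abs(x - mean)))
        elif stat == "Variance":
            out[stat] = float(np.mean((x - mean) ** 2))
        else:
            raise ValueError(f"unknown first-order statistic {stat!r}")
    return out
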