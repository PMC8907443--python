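"""First-order (statistical) features over ROI voxel intensities."""

from __future__ import annotations

import numpy as np

from .texture import DiscretizationParams, discretize

FIRSTORDER_FEATURES = (
    "Mean",
    "Variance",
    "StdDev",
    "Skewness",
    "Kurtosis",
    "Minimum",
    "Maximum",
    "Range",
    "P10",
    "P25",
    "Median",
    "P75",
    "P90",
    "IQR",
    "Energy",
    "TotalEnergy",
    "RMS",
    "MeanAbsDeviation",
    "MedianAbsDeviation",
    "Uniformity",
    "Entropy",
    "CoeffVariation",
)


def firstorder_features(
    volume: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizationParams = DiscretizationParams(),
    voxel_volume: float = 1.0,
) -> dict[str, float]:
    """First-order statistics of the intensities inside the ROI.

    Moments are computed over ROI voxels only. ``Entropy`` and ``Uniformity``
    are computed on the discretized grey levels (``-sum p log2 p`` and
    ``sum p^2``). Skewness/kurtosis of a constant ROI are NaN by convention;
    kurtosis is the Pearson (non-excess) form, 3 for a normal distribution.
    """
    m = np.asarray(mask) > 0
    if not m.any():
        raise ValueError("empty mask")
    x = np.asarray(volume, dtype=np.float64)[m]

    mean = float(np.mean(x))
    var = float(np.var(x))
    sd = float(np.sqrt(var))
    if var > 0:
        z = x - mean
        skew = float(np.mean(z ** 3) / var ** 1.5)
        kurt = float(np.mean(z ** 4) / var ** 2)
    else:
        skew = np.nan
        kurt = np.nan

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    energy = float(np.sum(x ** 2))

    levels = discretize(x, disc)
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / levels.size
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p ** 2))

    return {
        "Mean": mean,
        "Variance": var,
        "StdDev": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Minimum": float(np.min(x)),
        "Maximum": float(np.max(x)),
        "Range": float(np.max(x) - np.min(x)),
        "P10": float(p10),
        "P25": float(p25),
        "Median": float(p50),
        "P75": float(p75),
        "P90": float(p90),
        "IQR": float(p75 - p25),
        "Energy": energy,
        "TotalEnergy": energy * float(voxel_volume),
        "RMS": float(np.sqrt(np.mean(x ** 2))),
        "MeanAbsDeviation": float(np.mean(np.abs(x - mean))),
        "MedianAbsDeviation": float(np.median(np.abs(x - np.median(x)))),
        "Uniformity": uniformity,
        "Entropy": entropy,
        "CoeffVariation": sd / mean if mean != 0 else np.nan,
    }
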