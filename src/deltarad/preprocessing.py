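"""Intensity normalization applied to each volume before feature extraction."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class NormalizationParams:
    """How to normalize a volume's intensities.

    method : {'zscore', 'none'}
    reference_region : {'whole_volume', 'roi_dilated'}
        Region over which the mean/sd are estimated. ``roi_dilated`` uses the
        ROI mask dilated by ``dilate_voxels`` (requires a mask at call time).
    clip_sd : float or None
        If set, clip the z-scored output symmetrically at ``+/- clip_sd``.
    """

    method: str = "zscore"
    reference_region: str = "whole_volume"
    clip_sd: float | None = None
    dilate_voxels: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("zscore", "none"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        if self.reference_region not in ("whole_volume", "roi_dilated"):
            raise ValueError(f"unknown reference_region {self.reference_region!r}")
        if self.clip_sd is not None and self.clip_sd <= 0:
            raise ValueError("clip_sd must be > 0 when present")


def normalize(
    volume: np.ndarray,
    params: NormalizationParams = NormalizationParams(),
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Return the normalized volume (float64); ``method='none'`` is identity.

    z-score: ``(x - mean_ref) / sd_ref`` with the reference statistics taken
    over ``params.reference_region``. A constant reference region is an error.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    if params.method == "none":
        return volume.copy()

    if params.reference_region == "whole_volume":
        ref = volume
    else:
        if mask is None:
            raise ValueError("reference_region='roi_dilated' requires a mask")
        from scipy import ndimage

        dilated = ndimage.binary_dilation(
            np.asarray(mask) > 0, iterations=params.dilate_voxels
        )
        if not dilated.any():
            raise ValueError("reference region is empty")
        ref = volume[dilated]

    mu = float(np.mean(ref))
    sd = float(np.std(ref))
    if sd == 0.0:
        raise ValueError("constant reference region: sd is zero")
    out = (volume - mu) / sd
    if params.clip_sd is not None:
        np.clip(out, -params.clip_sd, params.clip_sd, out=out)
    return out
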