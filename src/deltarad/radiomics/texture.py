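"""Grey-level discretization and textural features (GLCM, GLRLM).

Co-occurrence and run-length matrices are built over the 13 unique 3D
directions (26-connectivity halved by symmetry), restricted to voxel pairs
inside the ROI, and features are averaged over directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: The 13 unique direction vectors of a 3D 26-neighbourhood (one per +/- pair).
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

GLCM_FEATURES = (
    "JointMaximum",
    "JointAverage",
    "JointVariance",
    "JointEntropy",
    "DifferenceAverage",
    "DifferenceVariance",
    "DifferenceEntropy",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "JointEnergy",
    "Contrast",
    "Dissimilarity",
    "InverseDifference",
    "InverseDifferenceNorm",
    "InverseDifferenceMoment",
    "InverseDifferenceMomentNorm",
    "InverseVariance",
    "Correlation",
    "Autocorrelation",
    "ClusterTendency",
    "ClusterShade",
    "ClusterProminence",
    "InfoMeasureCorr1",
    "InfoMeasureCorr2",
)

GLRLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonUniformity",
    "RunLengthNonUniformity",
    "RunPercentage",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
)


@dataclass(frozen=True)
class DiscretizationParams:
    """Grey-level discretization applied before histogram/texture features.

    ``fixed_bin_count`` maps the reference range onto ``n_bins`` equal bins
    (robust to normalization scale, the default); ``fixed_bin_size`` uses
    bins of width ``bin_width`` anchored at the reference minimum.
    """

    strategy: str = "fixed_bin_count"
    n_bins: int = 32
    bin_width: float | None = None
    range_policy: str = "roi_min_max"
    fixed_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.strategy not in ("fixed_bin_count", "fixed_bin_size"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "fixed_bin_count" and self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy == "fixed_bin_size" and (
            self.bin_width is None or self.bin_width <= 0
        ):
            raise ValueError("bin_width must be > 0 for fixed_bin_size")
        if self.range_policy not in ("roi_min_max", "fixed_bounds"):
            raise ValueError(f"unknown range_policy {self.range_policy!r}")
        if self.range_policy == "fixed_bounds" and self.fixed_bounds is None:
            raise ValueError("fixed_bounds required with range_policy='fixed_bounds'")


def discretize(values: np.ndarray, params: DiscretizationParams) -> np.ndarray:
    """Map intensities to integer grey levels ``1..n_levels`` (same shape).

    A constant input maps everything to level 1.
    """
    x = np.asarray(values, dtype=np.float64)
    if params.range_policy == "fixed_bounds":
        lo, hi = params.fixed_bounds  # type: ignore[misc]
    else:
        lo, hi = float(x.min()), float(x.max())
    if params.strategy == "fixed_bin_count":
        if hi == lo:
            return np.ones(x.shape, dtype=np.int64)
        lev = np.floor((x - lo) / (hi - lo) * params.n_bins).astype(np.int64) + 1
        return np.clip(lev, 1, params.n_bins)
    lev = np.floor((x - lo) / params.bin_width).astype(np.int64) + 1  # type: ignore[operator]
    return np.clip(lev, 1, None)


def _level_volume(volume: np.ndarray, mask: np.ndarray, disc: DiscretizationParams):
    """Cropped grey-level volume with 0 outside the ROI, plus level count."""
    m = np.asarray(mask) > 0
    idx = np.nonzero(m)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    m = m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    v = np.asarray(volume, dtype=np.float64)[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    roi_levels = discretize(v[m], disc)
    L = np.zeros(m.shape, dtype=np.int64)
    L[m] = roi_levels
    return L, int(roi_levels.max())


def _offset_slices(shape, offset):
    core, shifted = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            core.append(slice(0, n - o))
            shifted.append(slice(o, n))
        else:
            core.append(slice(-o, n))
            shifted.append(slice(0, n + o))
    return tuple(core), tuple(shifted)


def glcm_matrix(levels: np.ndarray, offset, n_levels: int) -> np.ndarray:
    """Symmetric co-occurrence count matrix for one offset (not normalized)."""
    a, b = _offset_slices(levels.shape, offset)
    l1, l2 = levels[a].ravel(), levels[b].ravel()
    keep = (l1 > 0) & (l2 > 0)
    l1, l2 = l1[keep], l2[keep]
    M = np.bincount((l1 - 1) * n_levels + (l2 - 1), minlength=n_levels * n_levels)
    M = M.reshape(n_levels, n_levels).astype(np.float64)
    return M + M.T


def glcm_features_from_matrix(M: np.ndarray) -> dict[str, float]:
    """IBSI-style GLCM features from one (symmetric) count or probability matrix.

    Single-occupied-level matrices yield Correlation/InfoMeasureCorr1 = NaN
    (undefined by convention), JointEnergy 1 and Contrast 0.
    """
    total = M.sum()
    if total == 0:
        return {name: np.nan for name in GLCM_FEATURES}
    P = M / total
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float(np.sum(i * px))
    var = float(np.sum((i - mu) ** 2 * px))

    nz = P > 0
    joint_entropy = float(-np.sum(P[nz] * np.log2(P[nz])))

    # difference |i-j| and sum i+j distributions
    k_diff = np.arange(ng, dtype=np.float64)
    p_diff = np.bincount(
        np.abs(ii - jj).astype(np.int64).ravel(), weights=P.ravel(), minlength=ng
    )
    diff_avg = float(np.sum(k_diff * p_diff))
    diff_var = float(np.sum((k_diff - diff_avg) ** 2 * p_diff))
    nzd = p_diff > 0
    diff_ent = float(-np.sum(p_diff[nzd] * np.log2(p_diff[nzd])))

    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.bincount(
        (ii + jj).astype(np.int64).ravel(), weights=P.ravel(), minlength=2 * ng + 1
    )[2:]
    sum_avg = float(np.sum(k_sum * p_sum))
    sum_var = float(np.sum((k_sum - sum_avg) ** 2 * p_sum))
    nzs = p_sum > 0
    sum_ent = float(-np.sum(p_sum[nzs] * np.log2(p_sum[nzs])))

    contrast = float(np.sum((ii - jj) ** 2 * P))
    dissim = float(np.sum(np.abs(ii - jj) * P))
    autocorr = float(np.sum(ii * jj * P))
    if var > 0:
        correlation = (autocorr - mu * mu) / var
    else:
        correlation = np.nan

    off = np.abs(ii - jj) > 0
    inv_var = float(np.sum(P[off] / (ii - jj)[off] ** 2))

    # information measures of correlation
    px_nz = px[px > 0]
    hx = float(-np.sum(px_nz * np.log2(px_nz)))
    pxpy = np.outer(px, px)
    nzj = pxpy > 0
    hxy1 = float(-np.sum(P[nzj] * np.log2(pxpy[nzj])))
    hxy2 = float(-np.sum(pxpy[nzj] * np.log2(pxpy[nzj])))
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else np.nan
    arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(arg, 0.0)))

    spread = ii + jj - 2.0 * mu
    return {
        "JointMaximum": float(P.max()),
        "JointAverage": mu,
        "JointVariance": var,
        "JointEntropy": joint_entropy,
        "DifferenceAverage": diff_avg,
        "DifferenceVariance": diff_var,
        "DifferenceEntropy": diff_ent,
        "SumAverage": sum_avg,
        "SumVariance": sum_var,
        "SumEntropy": sum_ent,
        "JointEnergy": float(np.sum(P ** 2)),
        "Contrast": contrast,
        "Dissimilarity": dissim,
        "InverseDifference": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "InverseDifferenceNorm": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "InverseDifferenceMoment": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "InverseDifferenceMomentNorm": float(
            np.sum(P / (1.0 + (ii - jj) ** 2 / ng ** 2))
        ),
        "InverseVariance": inv_var,
        "Correlation": float(correlation),
        "Autocorrelation": autocorr,
        "ClusterTendency": float(np.sum(spread ** 2 * P)),
        "ClusterShade": float(np.sum(spread ** 3 * P)),
        "ClusterProminence": float(np.sum(spread ** 4 * P)),
        "InfoMeasureCorr1": float(imc1),
        "InfoMeasureCorr2": imc2,
    }


def glcm_features(
    volume: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizationParams = DiscretizationParams(),
    distance: int = 1,
    aggregation: str = "average_over_directions",
) -> dict[str, float]:
    """GLCM features at a Chebyshev ``distance``, averaged over 13 directions.

    Per-direction matrices are symmetric by construction; directions whose
    offset produces no in-ROI pair are skipped in the average.
    """
    if aggregation != "average_over_directions":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if int(np.count_nonzero(np.asarray(mask))) < 2:
        raise ValueError("GLCM needs at least 2 ROI voxels")
    L, n_levels = _level_volume(volume, mask, disc)
    per_dir = []
    for direction in DIRECTIONS_13:
        offset = tuple(distance * d for d in direction)
        M = glcm_matrix(L, offset, n_levels)
        if M.sum() > 0:
            per_dir.append(glcm_features_from_matrix(M))
    if not per_dir:
        return {name: np.nan for name in GLCM_FEATURES}
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_FEATURES
    }


def glrlm_matrix(levels: np.ndarray, direction, n_levels: int) -> np.ndarray:
    """Run-length count matrix R[g-1, l-1] along one direction."""
    shape = levels.shape
    o = np.asarray(direction)
    # a run starts where the predecessor (v - o) is out of ROI or differs
    prev_same = np.zeros(shape, dtype=bool)
    a, b = _offset_slices(shape, tuple(-x for x in o))
    prev_same[a] = (levels[a] == levels[b]) & (levels[b] > 0)
    starts = (levels > 0) & ~prev_same

    coords = np.argwhere(starts)
    if coords.size == 0:
        return np.zeros((n_levels, 1))
    run_level = levels[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    cur = coords + o
    alive = np.ones(len(coords), dtype=bool)
    while True:
        inb = alive.copy()
        idx = np.nonzero(inb)[0]
        pos = cur[idx]
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        idx = idx[ok]
        if idx.size == 0:
            break
        pos = cur[idx]
        same = levels[pos[:, 0], pos[:, 1], pos[:, 2]] == run_level[idx]
        idx = idx[same]
        alive[:] = False
        if idx.size == 0:
            break
        alive[idx] = True
        lengths[idx] += 1
        cur[idx] += o

    lmax = int(lengths.max())
    R = np.zeros((n_levels, lmax))
    np.add.at(R, (run_level - 1, lengths - 1), 1.0)
    return R


def glrlm_features_from_matrix(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    n_runs = R.sum()
    if n_runs == 0:
        return {name: np.nan for name in GLRLM_FEATURES}
    g = np.arange(1, R.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, R.shape[1] + 1, dtype=np.float64)[None, :]
    rg = R.sum(axis=1)
    rl = R.sum(axis=0)
    return {
        "ShortRunEmphasis": float(np.sum(R / l ** 2) / n_runs),
        "LongRunEmphasis": float(np.sum(R * l ** 2) / n_runs),
        "GreyLevelNonUniformity": float(np.sum(rg ** 2) / n_runs),
        "RunLengthNonUniformity": float(np.sum(rl ** 2) / n_runs),
        "RunPercentage": float(n_runs / n_voxels),
        "LowGreyLevelRunEmphasis": float(np.sum(R / g ** 2) / n_runs),
        "HighGreyLevelRunEmphasis": float(np.sum(R * g ** 2) / n_runs),
        "ShortRunLowGreyLevelEmphasis": float(np.sum(R / (g ** 2 * l ** 2)) / n_runs),
        "ShortRunHighGreyLevelEmphasis": float(np.sum(R * g ** 2 / l ** 2) / n_runs),
        "LongRunHighGreyLevelEmphasis": float(np.sum(R * g ** 2 * l ** 2) / n_runs),
    }


def glrlm_features(
    volume: np.ndarray,
    mask: np.ndarray,
    disc: DiscretizationParams = DiscretizationParams(),
) -> dict[str, float]:
    """Run-length features averaged over the 13 directions."""
    n_vox = int(np.count_nonzero(np.asarray(mask)))
    if n_vox < 1:
        raise ValueError("empty mask")
    L, n_levels = _level_volume(volume, mask, disc)
    per_dir = [
        glrlm_features_from_matrix(glrlm_matrix(L, d, n_levels), n_vox)
        for d in DIRECTIONS_13
    ]
    return {
        name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_FEATURES
    }
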