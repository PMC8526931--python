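"""Voxel-wise distribution diagnostics across a subject population.

For every voxel of an aligned population stack the subject axis is an
ordered sample x_1..x_n.  The diagnostics characterise its shape:

* skewness  S = (1/n) sum (x_i - mu)^3 / sigma^3
* kurtosis  K = (1/n) sum (x_i - mu)^4 / sigma^4 - 3   (Fisher/excess)
* the Shapiro-Wilk normality p-value

with sigma the population (n-denominator) standard deviation, so both
S and K are 0 for a Gaussian in the large-sample limit.  Constant
samples take S = K = 0 by convention and a NaN sentinel for the
Shapiro-Wilk p; such voxels are excluded by the content mask anyway.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import MaskMap, PopulationStack, StatMap

__all__ = [
    "sample_skewness",
    "sample_kurtosis",
    "shapiro_wilk_p",
    "stat_map",
    "content_mask",
    "distribution_summary",
    "violin_export",
]

#: below this, a sample's n-denominator sigma counts as zero (constant input)
_SIGMA_FLOOR = 0.0


def _moments(x: np.ndarray, axis: int = 0):
    n = x.shape[axis]
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    mu = x.mean(axis=axis, keepdims=True)
    d = x - mu
    m2 = np.mean(d * d, axis=axis)
    m3 = np.mean(d**3, axis=axis)
    m4 = np.mean(d**4, axis=axis)
    return m2, m3, m4


def sample_skewness(values: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Third standardized moment with the n-denominator sigma.

    Returns 0 for constant input (sigma = 0) by convention.  Negative
    values indicate a left tail, positive a right tail.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim == 1:
        axis = 0
    m2, m3, _ = _moments(x, axis=axis)
    nonzero = m2 > _SIGMA_FLOOR
    denom = np.where(nonzero, m2, 1.0) ** 1.5
    s = np.where(nonzero, m3 / denom, 0.0)
    return float(s) if np.ndim(s) == 0 else s


def sample_kurtosis(values: np.ndarray, axis: int = 0) -> np.ndarray | float:
    """Fisher (excess) kurtosis: fourth standardized moment minus 3.

    Uses the n-denominator sigma; 0 for a Gaussian in the large-sample
    limit and 0 for constant input by convention.
    """
    x = np.asarray(values, dtype=np.float64)
    if x.ndim == 1:
        axis = 0
    m2, _, m4 = _moments(x, axis=axis)
    nonzero = m2 > _SIGMA_FLOOR
    denom = np.where(nonzero, m2, 1.0) ** 2
    k = np.where(nonzero, m4 / denom - 3.0, 0.0)
    return float(k) if np.ndim(k) == 0 else k


def shapiro_wilk_p(values: np.ndarray) -> float:
    """Two-sided Shapiro-Wilk normality p-value for one sample.

    Valid for 3 <= n <= 5000 (Royston's AS R94 approximation).  A small
    p signals departure from Gaussianity.  Constant input is degenerate:
    returns NaN (the sentinel excluded from downstream maps).
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if not 3 <= n <= 5000:
        raise ValueError(f"Shapiro-Wilk valid for 3 <= n <= 5000, got {n}")
    if np.ptp(x) == 0.0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(x).pvalue)


def _sw_p_over_stack(data4d: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    n = data4d.shape[0]
    flat = data4d.reshape(n, -1)
    out = np.full(flat.shape[1], np.nan)
    idx = np.flatnonzero(mask.ravel()) if mask is not None else np.arange(flat.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in idx:
            col = flat[:, i]
            if np.ptp(col) > 0.0:
                out[i] = stats.shapiro(col).pvalue
    return out.reshape(data4d.shape[1:])


def stat_map(
    stack: PopulationStack,
    statistic: str,
    mask: MaskMap | None = None,
) -> StatMap:
    """Apply a scalar diagnostic voxel-wise across the subject axis.

    ``statistic`` is one of skewness, kurtosis, sw_p, mean.  Out-of-mask
    voxels carry NaN; provenance (tissue, n, statistic) is recorded.
    """
    if mask is not None and mask.data.shape != stack.grid_shape:
        raise ValueError("mask shape does not match stack grid")
    if statistic == "skewness":
        data = sample_skewness(stack.data, axis=0)
    elif statistic == "kurtosis":
        data = sample_kurtosis(stack.data, axis=0)
    elif statistic == "mean":
        data = stack.data.mean(axis=0)
    elif statistic == "sw_p":
        data = _sw_p_over_stack(stack.data, mask.data if mask is not None else None)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    data = np.asarray(data, dtype=np.float64)
    if mask is not None and statistic != "sw_p":
        data = data.copy()
        data[~mask.data] = np.nan
    return StatMap(
        statistic=statistic,
        data=data,
        affine=stack.affine,
        mask=mask,
        provenance={"tissue": stack.tissue, "n": stack.n, "statistic": statistic},
    )


def content_mask(central_map: StatMap, threshold: float = 0.05) -> MaskMap:
    """Mask of voxels whose central proportion strictly exceeds ``threshold``.

    The 5% default restricts maps to where the structure actually
    exists; ties at exactly the threshold are excluded.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    with np.errstate(invalid="ignore"):
        m = central_map.data > threshold
    if not m.any():
        warnings.warn("content mask is empty", stacklevel=2)
    return MaskMap(data=m, threshold=threshold, source=central_map.statistic)


def distribution_summary(
    maps: dict[str, StatMap],
    mask: MaskMap,
    label: str = "",
    tissue: str = "",
) -> pd.DataFrame:
    """One-row table of in-mask medians of the shape diagnostics.

    ``maps`` holds StatMaps keyed by statistic name (typically kurtosis,
    skewness, sw_p); NaN sentinels are dropped before the median.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    row: dict[str, object] = {"group": label, "tissue": tissue, "n_voxels": mask.n_voxels}
    for name, m in maps.items():
        if m.data.shape != mask.data.shape:
            raise ValueError(f"map {name!r} shape does not match mask")
        vals = m.data[mask.data]
        vals = vals[np.isfinite(vals)]
        row[f"median_{name}"] = float(np.median(vals)) if vals.size else float("nan")
    return pd.DataFrame([row])


def violin_export(map_: StatMap, mask: MaskMap, path=None) -> np.ndarray:
    """Flat multiset of in-mask values, for external density plotting.

    Written to ``path`` as a one-column TSV (header ``value``) at full
    precision when a path is given.
    """
    if map_.data.shape != mask.data.shape:
        raise ValueError("map shape does not match mask")
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    values = map_.data[mask.data]
    if path is not None:
        # default float formatting writes the shortest round-trip repr
        pd.DataFrame({"value": values}).to_csv(path, sep="\t", index=False)
    return values
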