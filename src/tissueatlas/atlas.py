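"""Order-based (percentile) and mean tissue-proportion atlases.

The t-th percentile of the ordered per-voxel sample x_1 <= ... <= x_n
follows the averaged-inverse-CDF rule (Hyndman-Fan definition 2): with
n*t/100 = j + g (j integer part, g fractional part),

    y = (x_j + x_{j+1}) / 2   if g = 0
    y = x_{j+1}               if g > 0

indices clamped to [1, n].  The t=50 map is the median atlas, the
non-parametric alternative to the mean atlas; p75 - p25 gives the IQR
spread map.  Tissue volumes are obtained by summing the proportion over
voxels ("counting the probability") times the voxel volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .io import MaskMap, PopulationStack, ProportionMap, StatMap, voxel_volume_ml

__all__ = [
    "percentile_value",
    "percentile_indices",
    "build_percentile_atlas",
    "build_mean_atlas",
    "iqr_map",
    "tpm_volume",
    "PercentileAtlas",
    "VolumeReport",
]

DEFAULT_LEVELS: tuple[float, ...] = (5.0, 25.0, 50.0, 75.0, 95.0)


def percentile_indices(n: int, t: float) -> tuple[int, bool]:
    """Resolve the order-statistic rule for sample size n and level t.

    Returns ``(j, average)`` where j is the 1-based lower index and
    ``average`` is True when y = (x_j + x_{j+1})/2 (the g = 0 branch).
    Whether g = 0 is decided in exact rational arithmetic (n*t mod 100),
    never by floating-point equality.
    """
    if not 0.0 < t < 100.0:
        raise ValueError(f"percentile level must be in (0, 100), got {t}")
    if n < 1:
        raise ValueError("need at least one observation")
    q = n * Fraction(str(t)) / 100  # exact j + g
    j = int(q)  # floor for positive q
    g_zero = q == j
    j = min(max(j, 0), n)
    return j, g_zero


def percentile_value(values: np.ndarray, t: float) -> float:
    """The t-th percentile of a 1D sample (sorted internally)."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    j, g_zero = percentile_indices(n, t)
    if g_zero:
        if j == 0:  # unreachable for t > 0, kept for safety
            return float(x[0])
        hi = min(j + 1, n)
        return float(0.5 * (x[j - 1] + x[hi - 1]))
    return float(x[min(j + 1, n) - 1])


@dataclass
class PercentileAtlas:
    """The family of percentile-level maps for one tissue class."""

    tissue: str
    levels: list[float]
    maps: dict[float, StatMap] = field(default_factory=dict)
    n: int = 0
    group_label: str = "All"

    def __getitem__(self, t: float) -> StatMap:
        if t not in self.maps:
            raise KeyError(f"level {t} not in atlas (have {sorted(self.maps)})")
        return self.maps[t]

    @property
    def median(self) -> StatMap:
        return self[50.0]


@dataclass
class VolumeReport:
    """A single tissue volume measurement in ml."""

    group_label: str
    tissue: str
    measure: str  # "mean", "median", or "percentile-<t>"
    volume_ml: float

    def __post_init__(self) -> None:
        if self.volume_ml < 0:
            raise ValueError("volume cannot be negative")


def build_percentile_atlas(
    stack: PopulationStack,
    levels=DEFAULT_LEVELS,
    group_label: str = "All",
) -> PercentileAtlas:
    """Per-voxel percentile maps of a population stack.

    The subject axis is sorted once; each level is then a pick (or an
    average of two picks) of order-statistic slices, so maps are
    voxel-wise non-decreasing in t by construction.
    """
    levels = [float(t) for t in levels]
    if not levels:
        raise ValueError("need at least one percentile level")
    sorted_data = np.sort(stack.data, axis=0)
    n = stack.n
    atlas = PercentileAtlas(
        tissue=stack.tissue, levels=levels, n=n, group_label=group_label
    )
    for t in levels:
        j, g_zero = percentile_indices(n, t)
        if g_zero:
            hi = min(j + 1, n)
            data = 0.5 * (sorted_data[j - 1] + sorted_data[hi - 1]) if j >= 1 \
                else sorted_data[0].copy()
        else:
            data = sorted_data[min(j + 1, n) - 1].copy()
        atlas.maps[t] = StatMap(
            statistic="percentile",
            level=t,
            data=data,
            affine=stack.affine,
            provenance={
                "tissue": stack.tissue,
                "n": n,
                "t": t,
                "group": group_label,
            },
        )
    return atlas


def build_mean_atlas(stack: PopulationStack, group_label: str = "All") -> StatMap:
    """Parametric (arithmetic-mean) tissue proportion map."""
    return StatMap(
        statistic="mean",
        data=stack.data.mean(axis=0),
        affine=stack.affine,
        provenance={"tissue": stack.tissue, "n": stack.n, "group": group_label},
    )


def iqr_map(atlas: PercentileAtlas) -> StatMap:
    """Voxel-wise interquartile range: p75 - p25 (non-negative)."""
    for t in (25.0, 75.0):
        if t not in atlas.maps:
            raise ValueError(f"atlas lacks the level {t} required for the IQR")
    data = atlas[75.0].data - atlas[25.0].data
    return StatMap(
        statistic="iqr",
        data=data,
        affine=atlas[25.0].affine,
        provenance={"tissue": atlas.tissue, "n": atlas.n, "group": atlas.group_label},
    )


def tpm_volume(
    vol: StatMap | ProportionMap,
    affine: np.ndarray | None = None,
    group_label: str = "All",
    measure: str | None = None,
) -> VolumeReport:
    """Tissue volume in ml by counting the probability in the voxels.

    volume = (sum of proportion values) * voxel volume.  NaN (masked)
    voxels contribute 0; negative values are an error.
    """
    aff = affine if affine is not None else vol.affine
    data = vol.data
    finite = data[np.isfinite(data)]
    if (finite < 0).any():
        raise ValueError("negative proportion values present")
    total = float(np.nansum(data))
    if measure is None:
        if isinstance(vol, StatMap):
            measure = (
                f"percentile-{vol.level:g}"
                if vol.statistic == "percentile"
                else vol.statistic
            )
        else:
            measure = "subject"
    tissue = (
        vol.tissue
        if isinstance(vol, ProportionMap)
        else str(vol.provenance.get("tissue", ""))
    )
    return VolumeReport(
        group_label=group_label,
        tissue=tissue,
        measure=measure,
        volume_ml=total * voxel_volume_ml(aff),
    )
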