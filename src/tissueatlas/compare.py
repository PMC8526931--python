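"""Paired comparison of tissue maps and volume sets.

Mean vs. median atlases (and group vs. group atlases) are compared with

* the Wilcoxon signed-rank test — null: the paired voxel differences
  are symmetric about zero.  Zero differences are discarded (Wilcoxon's
  original policy), ties are mid-ranked; the p-value is exact (full
  enumeration of sign assignments via a rank-sum convolution) for up to
  25 informative pairs and a tie- and continuity-corrected normal
  approximation above;
* the two-sample Kolmogorov-Smirnov test — null: the two in-mask value
  samples come from the same distribution (asymptotic p; the sample
  here is the pooled voxel values, with no spatial information);
* percentage-difference maps 100*|mean - median|/median, which blow up
  near structure borders where the median approaches the mask floor.

Voxels are treated as independent observations; spatial autocorrelation
is deliberately not modeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MaskMap, StatMap

__all__ = [
    "ComparisonResult",
    "PctDiffMap",
    "percentage_difference_map",
    "wilcoxon_signed_rank",
    "wilcoxon_from_differences",
    "ks_two_sample",
    "compare_volume_sets",
]

#: largest number of informative pairs handled by exact enumeration
EXACT_LIMIT = 25

PCT_DIFF_FORMULA = "100 * |mean - median| / median"


@dataclass
class ComparisonResult:
    """Outcome of one paired-map or volume-set comparison."""

    test: str  # "wilcoxon_signed_rank" | "ks_two_sample"
    statistic: float
    p_value: float
    n_pairs: int | None = None
    n_a: int | None = None
    n_b: int | None = None
    mask_provenance: str = ""
    alpha: float = 0.05
    degenerate: bool = False
    method: str = ""
    direction: int = 0  # sign of the median paired difference (a - b)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def as_row(self) -> dict:
        n = self.n_pairs if self.n_pairs is not None else f"{self.n_a}/{self.n_b}"
        return {
            "test": self.test,
            "statistic": self.statistic,
            "p_value": max(self.p_value, 1e-308),  # display floor only
            "n": n,
            "mask": self.mask_provenance,
            "alpha": self.alpha,
            "verdict": "significant" if self.significant else "ns",
        }


@dataclass
class PctDiffMap:
    """Voxel-wise percentage difference between two central maps."""

    data: np.ndarray
    mask: MaskMap
    definition: str = PCT_DIFF_FORMULA
    n_zero_median: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def masked_values(self) -> np.ndarray:
        vals = self.data[self.mask.data]
        return vals[np.isfinite(vals)]


def percentage_difference_map(
    mean_map: StatMap,
    median_map: StatMap,
    mask: MaskMap,
    fill: float = np.nan,
) -> PctDiffMap:
    """100 * |mean - median| / median per in-mask voxel.

    Voxels with a zero median are set to ``fill`` and counted in a
    warning; out-of-mask voxels carry ``fill``.
    """
    if mean_map.data.shape != median_map.data.shape != mask.data.shape:
        raise ValueError("map/mask shapes disagree")
    out = np.full(mean_map.data.shape, fill, dtype=np.float64)
    m = mask.data
    med = median_map.data[m]
    mean = mean_map.data[m]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * np.abs(mean - med) / med
    zero = med == 0.0
    pct[zero] = fill
    n_zero = int(zero.sum())
    if n_zero:
        warnings.warn(
            f"{n_zero} in-mask voxel(s) with zero median set to fill", stacklevel=2
        )
    out[m] = pct
    return PctDiffMap(
        data=out,
        mask=mask,
        n_zero_median=n_zero,
        affine=mean_map.affine,
    )


def _exact_signed_rank_p(ranks: np.ndarray, w_small: float) -> float:
    """Two-sided exact p by enumerating all 2^n sign assignments.

    Equivalent to full enumeration: the distribution of W+ over the 2^n
    equiprobable assignments is built by convolving over the (doubled,
    hence integer even with mid-ranks) ranks.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.rint(2.0 * w_small))
    p_le = counts[: w2 + 1].sum() / counts.sum()
    return min(1.0, 2.0 * p_le)


def wilcoxon_from_differences(
    diffs: np.ndarray,
    alpha: float = 0.05,
    mask_provenance: str = "",
) -> ComparisonResult:
    """Wilcoxon signed-rank test on paired differences.

    Reports W- (the smaller signed-rank sum side is used for the exact
    tail) as the statistic; all-zero differences are degenerate and
    give p = 1.
    """
    d = np.asarray(diffs, dtype=np.float64)
    if d.ndim != 1:
        d = d.ravel()
    if d.size == 0:
        raise ValueError("no paired observations")
    d = d[d != 0.0]  # Wilcoxon's discard policy for zero differences
    n = d.size
    if n == 0:
        return ComparisonResult(
            test="wilcoxon_signed_rank",
            statistic=0.0,
            p_value=1.0,
            n_pairs=0,
            mask_provenance=mask_provenance,
            alpha=alpha,
            degenerate=True,
            method="degenerate",
        )
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_small = min(w_plus, w_minus)
    direction = int(np.sign(w_plus - w_minus))
    if n <= EXACT_LIMIT:
        p = _exact_signed_rank_p(ranks, w_small)
        method = "exact"
    else:
        _, counts = np.unique(ranks, return_counts=True)
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
        if var <= 0:
            return ComparisonResult(
                test="wilcoxon_signed_rank",
                statistic=w_minus,
                p_value=1.0,
                n_pairs=n,
                mask_provenance=mask_provenance,
                alpha=alpha,
                degenerate=True,
                method="degenerate",
            )
        # continuity-corrected z; correction matters up to n ~ 50
        z = (abs(w_plus - mu) - 0.5) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "normal-approx"
    return ComparisonResult(
        test="wilcoxon_signed_rank",
        statistic=w_minus,
        p_value=p,
        n_pairs=n,
        mask_provenance=mask_provenance,
        alpha=alpha,
        method=method,
        direction=direction,
    )


def wilcoxon_signed_rank(
    a: StatMap,
    b: StatMap,
    mask: MaskMap,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Paired Wilcoxon signed-rank test over the in-mask voxels of a, b."""
    if a.data.shape != b.data.shape or a.data.shape != mask.data.shape:
        raise ValueError("map/mask shapes disagree")
    diffs = a.data[mask.data] - b.data[mask.data]
    diffs = diffs[np.isfinite(diffs)]
    return wilcoxon_from_differences(
        diffs,
        alpha=alpha,
        mask_provenance=f"content-mask({mask.source}>{mask.threshold:g})",
    )


def ks_two_sample(
    a: StatMap,
    b: StatMap,
    mask: MaskMap,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-sample Kolmogorov-Smirnov test on pooled in-mask values.

    D = sup |F_a - F_b| with the asymptotic two-sided p-value; the test
    uses only the value distributions, not voxel locations.
    """
    if a.data.shape != mask.data.shape or b.data.shape != mask.data.shape:
        raise ValueError("map/mask shapes disagree")
    va = a.data[mask.data]
    vb = b.data[mask.data]
    va = va[np.isfinite(va)]
    vb = vb[np.isfinite(vb)]
    if va.size == 0 or vb.size == 0:
        raise ValueError("empty mask or all-NaN values")
    res = stats.ks_2samp(va, vb, method="asymp")
    return ComparisonResult(
        test="ks_two_sample",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=va.size,
        n_b=vb.size,
        mask_provenance=f"content-mask({mask.source}>{mask.threshold:g})",
        alpha=alpha,
        method="asymptotic",
    )


def compare_volume_sets(
    vols_a,
    vols_b,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Paired Wilcoxon test of two per-subject volume lists (ml)."""
    a = np.asarray(vols_a, dtype=np.float64)
    b = np.asarray(vols_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    return wilcoxon_from_differences(
        a - b, alpha=alpha, mask_provenance="paired-volumes"
    )
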