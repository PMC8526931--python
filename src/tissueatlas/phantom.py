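"""Synthetic phantom populations of aligned tissue-proportion maps.

The phantom stands in for a real cohort of spatially normalized GM/WM/
CSF proportion maps.  Geometry is three nested ellipsoids — a WM core,
a GM shell around it, and a CSF outer shell — whose blurred indicator
functions emulate partial-volume mixing at structure borders.  Within
its region each tissue's proportion is drawn voxel-wise from a scaled
Beta distribution:

* GM   Beta(8, 3)   mildly left-skewed (negative skewness),
* WM   Beta(3, 8)   moderately right-skewed,
* CSF  Beta(1.5, 8) strongly right-skewed and leptokurtic,

matching the qualitative skewness/kurtosis pattern of population
proportion data (the exact magnitudes of real cohorts are not targets).
A per-subject log-normal global factor emulates residual head-size /
segmentation variability.  At partial-volume voxels the within-voxel
averaging over mixed micro-compartments tightens and symmetrizes the
content distribution, so the Beta precision (both shape parameters)
is scaled up — mean-preserving — as the region weight drops below
purity: border voxels come out far more Gaussian than region cores,
the border-normality feature of real population maps.  Beta gives
closed-form moments and quantiles, so the generator carries its own
analytic ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .io import PopulationStack, ProportionMap, StatMap, Tissue, TISSUES

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_phantom_regions",
    "sample_subject",
    "generate_population",
    "true_percentile_map",
    "gaussian_population",
]


@dataclass
class PhantomSpec:
    """Full parametric description of the synthetic population generator.

    Semi-axes are in voxels and must nest (WM inside GM inside CSF) and
    fit the grid.  ``partial_volume_blur`` is the Gaussian sigma (in
    voxels) applied to the region indicators; ``subject_scale_sd`` the
    log-sd of the per-subject global factor (truncated at 2 sd);
    ``voxel_noise_sd`` an optional additive residual segmentation noise
    inside the structures (proportion units, off by default);
    ``border_precision`` the factor by which both Beta shape parameters
    grow at fully mixed voxels (mean-preserving symmetrization).
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: float = 1.0
    wm_semi_axes: tuple[float, float, float] = (10.0, 9.0, 8.0)
    gm_semi_axes: tuple[float, float, float] = (16.0, 15.0, 13.0)
    csf_semi_axes: tuple[float, float, float] = (20.0, 19.0, 17.0)
    beta_params: dict = field(
        default_factory=lambda: {
            "GM": (8.0, 3.0),
            "WM": (3.0, 8.0),
            "CSF": (1.5, 8.0),
        }
    )
    partial_volume_blur: float = 1.0
    subject_scale_sd: float = 0.02
    voxel_noise_sd: float = 0.0
    border_precision: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for tissue, (a, b) in self.beta_params.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"{tissue}: Beta parameters must be positive")
        if self.partial_volume_blur < 0:
            raise ValueError("blur width must be >= 0")
        axes = [self.wm_semi_axes, self.gm_semi_axes, self.csf_semi_axes]
        for inner, outer in zip(axes, axes[1:]):
            if not all(i < o for i, o in zip(inner, outer)):
                raise ValueError("ellipsoids must be strictly nested (WM < GM < CSF)")
        half = [s / 2.0 for s in self.grid_shape]
        if not all(a < h for a, h in zip(self.csf_semi_axes, half)):
            raise ValueError("outer ellipsoid exceeds the grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    def to_dict(self) -> dict:
        return {
            "grid_shape": list(self.grid_shape),
            "voxel_size_mm": self.voxel_size_mm,
            "wm_semi_axes": list(self.wm_semi_axes),
            "gm_semi_axes": list(self.gm_semi_axes),
            "csf_semi_axes": list(self.csf_semi_axes),
            "beta_params": {k: list(v) for k, v in self.beta_params.items()},
            "partial_volume_blur": self.partial_volume_blur,
            "subject_scale_sd": self.subject_scale_sd,
            "voxel_noise_sd": self.voxel_noise_sd,
            "border_precision": self.border_precision,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("grid_shape", "wm_semi_axes", "gm_semi_axes", "csf_semi_axes"):
            if key in d:
                d[key] = tuple(d[key])
        if "beta_params" in d:
            d["beta_params"] = {k: tuple(v) for k, v in d["beta_params"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic description of the generated population.

    ``weights`` are the (blurred, renormalized) region mixing maps;
    ``core_masks`` mark voxels whose weight is essentially pure tissue,
    where the analytic Beta quantiles are exact up to the subject
    factor.  Quantile maps are monotone in t by construction.
    """

    spec: PhantomSpec
    weights: dict[Tissue, np.ndarray]
    core_masks: dict[Tissue, np.ndarray]
    affine: np.ndarray


def _ellipsoid_mask(shape, semi_axes) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes)
    )
    return r2 <= 1.0


def make_phantom_regions(spec: PhantomSpec) -> dict[Tissue, np.ndarray]:
    """Per-tissue mixing-weight maps in [0, 1] with GM+WM+CSF <= 1.

    Crisp nested-ellipsoid indicators are blurred (partial-volume
    emulation) and jointly renormalized wherever the blur pushes the
    sum above 1; the remainder 1 - sum is background.
    """
    shape = spec.grid_shape
    wm_in = _ellipsoid_mask(shape, spec.wm_semi_axes)
    gm_in = _ellipsoid_mask(shape, spec.gm_semi_axes)
    csf_in = _ellipsoid_mask(shape, spec.csf_semi_axes)
    indicators = {
        "WM": wm_in.astype(np.float64),
        "GM": (gm_in & ~wm_in).astype(np.float64),
        "CSF": (csf_in & ~gm_in).astype(np.float64),
    }
    if spec.partial_volume_blur > 0:
        indicators = {
            t: ndimage.gaussian_filter(ind, spec.partial_volume_blur)
            for t, ind in indicators.items()
        }
    total = sum(indicators.values())
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    return {t: np.clip(ind * scale, 0.0, 1.0) for t, ind in indicators.items()}


#: weight above which a voxel counts as pure tissue (Beta precision = 1)
W_PURE = 0.9
#: weight below which partial-volume mixing is considered complete
W_MIXED = 0.6


def _precision_factor(weights: np.ndarray, border_precision: float) -> np.ndarray:
    """Mean-preserving Beta precision multiplier: 1 in pure-tissue
    voxels, ``border_precision`` in fully mixed ones, linear ramp in
    between (partial-volume averaging symmetrizes the distribution)."""
    mixing = np.clip((W_PURE - weights) / (W_PURE - W_MIXED), 0.0, 1.0)
    return 1.0 + (border_precision - 1.0) * mixing


def _subject_rng(seed: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(subject_index)]))


def sample_subject(
    spec: PhantomSpec,
    rng: np.random.Generator,
    weights: dict[Tissue, np.ndarray] | None = None,
    subject_id: str = "sub-000",
) -> dict[Tissue, ProportionMap]:
    """Draw one subject's three proportion maps.

    Per voxel: proportion = region weight x Beta draw x subject factor,
    then jointly renormalized so GM+WM+CSF <= 1 (which also bounds each
    proportion by 1).
    """
    if weights is None:
        weights = make_phantom_regions(spec)
    shape = spec.grid_shape
    log_f = rng.normal(0.0, spec.subject_scale_sd) if spec.subject_scale_sd > 0 else 0.0
    cap = 2.0 * spec.subject_scale_sd
    factor = float(np.exp(np.clip(log_f, -cap, cap)))
    raw: dict[Tissue, np.ndarray] = {}
    for tissue in TISSUES:
        a, b = spec.beta_params[tissue]
        w = weights[tissue]
        c = _precision_factor(w, spec.border_precision)
        draw = rng.beta(a * c, b * c)
        vals = w * draw * factor
        if spec.voxel_noise_sd > 0:
            # residual segmentation noise, confined to the structure
            noise = rng.normal(0.0, spec.voxel_noise_sd, size=shape)
            vals = np.clip(vals + np.where(w > 1e-6, noise, 0.0), 0.0, None)
        raw[tissue] = vals
    total = raw["GM"] + raw["WM"] + raw["CSF"]
    scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
    return {
        tissue: ProportionMap(
            subject_id=subject_id,
            tissue=tissue,
            data=raw[tissue] * scale,
            affine=spec.affine,
        )
        for tissue in TISSUES
    }


def generate_population(
    spec: PhantomSpec,
    n: int,
    seed: int | None = None,
) -> tuple[dict[Tissue, PopulationStack], GroundTruth]:
    """Generate an n-subject phantom population plus its ground truth.

    Reproducible given (spec, n, seed): each subject draws from a
    substream derived from (seed, subject index), so any subject can be
    re-derived in isolation.  ``seed=None`` uses ``spec.seed``.
    """
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    seed = spec.seed if seed is None else int(seed)
    weights = make_phantom_regions(spec)
    shape = spec.grid_shape
    data = {t: np.empty((n, *shape), dtype=np.float64) for t in TISSUES}
    subject_ids = [f"sub-{i:03d}" for i in range(n)]
    for i, sid in enumerate(subject_ids):
        maps = sample_subject(spec, _subject_rng(seed, i), weights, subject_id=sid)
        for t in TISSUES:
            data[t][i] = maps[t].data
    stacks = {
        t: PopulationStack(
            tissue=t, subject_ids=list(subject_ids), data=data[t], affine=spec.affine
        )
        for t in TISSUES
    }
    core_masks = {t: weights[t] >= W_PURE for t in TISSUES}
    gt = GroundTruth(
        spec=spec, weights=weights, core_masks=core_masks, affine=spec.affine
    )
    return stacks, gt


def true_percentile_map(gt: GroundTruth, tissue: Tissue, t: float) -> StatMap:
    """Analytic t-th percentile of the generating distribution per voxel.

    quantile = region weight x Beta^{-1}(t/100; alpha, beta).  Exact
    for core voxels (weight above the purity threshold, where the Beta
    precision multiplier is 1); at mixed border voxels the generator
    tightens the distribution, so this map is an envelope there.  The
    log-normal subject factor has median 1 and is ignored; within cores
    its effect on low/mid percentiles is far below the Beta spread for
    the default log-sd.
    """
    if not 0.0 < t < 100.0:
        raise ValueError(f"percentile level must be in (0, 100), got {t}")
    a, b = gt.spec.beta_params[tissue]
    q = float(stats.beta.ppf(t / 100.0, a, b))
    return StatMap(
        statistic="percentile",
        level=float(t),
        data=gt.weights[tissue] * q,
        affine=gt.affine,
        provenance={"tissue": tissue, "t": t, "analytic": True},
    )


def gaussian_population(
    n_subjects: int,
    n_voxels: int,
    seed: int,
    mean: float = 0.5,
    sd: float = 0.1,
) -> PopulationStack:
    """An i.i.d. Gaussian population (no spatial structure).

    Used to calibrate the normality diagnostics: every voxel's subject
    sample is N(mean, sd^2), so the Shapiro-Wilk rejection rate should
    match the nominal level.  Laid out as an (n_voxels, 1, 1) grid.
    """
    rng = np.random.default_rng(seed)
    data = rng.normal(mean, sd, size=(n_subjects, n_voxels, 1, 1))
    return PopulationStack(
        tissue="GM",
        subject_ids=[f"sub-{i:03d}" for i in range(n_subjects)],
        data=data,
        affine=np.eye(4),
    )
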