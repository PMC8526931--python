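# Methods

## Scope and data model

The pipeline operates downstream of segmentation and spatial
normalization: its inputs are per-subject 3D tissue-proportion maps
(GM, WM, CSF; values in [0, 1]) already resampled to one grid.
Registration, bias correction and segmentation are out of scope. Maps
are stacked into a 4D population array (subjects × voxels); every
statistic is computed independently per voxel across the subject axis,
treating subjects as i.i.d. draws and voxels as independent — spatial
autocorrelation is deliberately not modeled, matching how such
voxel-wise batteries are conventionally run.

Consistency rules: at least 3 subjects per stack (the minimum for the
Shapiro–Wilk test and the shape statistics); identical grid shapes;
affines equal element-wise within 1e-4 (normalized maps resampled to
one grid should agree to write precision). Proportions outside [0, 1]
are clipped with a warning by default ("reject" is available), since
segmentation outputs occasionally overshoot by rounding.

## Distribution diagnostics

Skewness and excess kurtosis use the population (n-denominator) σ, so
both converge to 0 for Gaussian data; they are computed by direct
central-moment accumulation in float64. Constant voxel samples take
S = K = 0 and a NaN sentinel for the Shapiro–Wilk p (avoiding
division-by-zero propagation); such voxels are excluded by the content
mask in practice. The Shapiro–Wilk p-value is delegated to
`scipy.stats.shapiro` (Royston's AS R94 approximation, valid for
3 ≤ n ≤ 5000); its calibration on this pipeline's data layout is part
of the test suite (rejection rate within [0.03, 0.07] at α = 0.05 on a
96 × 10,000 Gaussian population).

The content mask keeps voxels whose central proportion strictly
exceeds 5 %. The central map is the median (50th-percentile) atlas by
default — consistent with the non-parametric framing — with the mean
map available by configuration; ties at exactly the threshold are
excluded.

## Percentile atlases

The t-th percentile uses the averaged-inverse-CDF order-statistic rule
(Hyndman–Fan definition 2): with n·t/100 = j + g, y is the average of
x₍ⱼ₎ and x₍ⱼ₊₁₎ when g = 0 and x₍ⱼ₊₁₎ otherwise, indices clamped to
[1, n]. Whether g = 0 is decided in exact rational arithmetic
(`fractions.Fraction`), never by floating-point equality, so the
averaging branch cannot be misclassified. At t = 50 the rule reduces to
the classical median. Atlases sort the subject axis once and pick
order-statistic slices, which makes the maps non-decreasing in t by
construction. Default levels are {5, 25, 50, 75, 95}; the IQR map is
p75 − p25. Tissue volume "counts the probability in the voxels":
Σ value × |det A₃ₓ₃|/1000 ml, with the voxel volume taken from the
input affine rather than assumed isotropic; NaN (masked) voxels
contribute 0. Volumes are computed whole-grid by default; masking
changes volumes and is left to the caller.

## Map and volume comparisons

*Wilcoxon signed-rank* (paired, two-sided): zero differences are
discarded (Wilcoxon's original policy, the mainstream package default),
absolute differences are mid-ranked. For up to 25 informative pairs the
p-value is exact — the null distribution of the rank sum is built by
convolution over the (doubled, hence integer) ranks, equivalent to full
enumeration of the 2ⁿ sign assignments and valid under ties. Above 25
pairs a normal approximation with tie correction
(var −= Σ(t³ − t)/48) and continuity correction is used; the two
engines agree within 0.02 on random inputs in the 10–25 pair range.
All differences zero is reported as a degenerate result with p = 1.
P-values are reported as computed; only display is floored at 1e-308.

*Kolmogorov–Smirnov* (two-sample, two-sided): D = sup |F_a − F_b| over
pooled in-mask values with the asymptotic p-value — in-mask voxel
counts here are in the 10³–10⁵ range, where the asymptotic form is
accurate and exact small-sample computation is pointless. The test uses
value distributions only, no spatial information.

*Percentage-difference maps*: the comparison of mean and median
templates uses 100 × |mean − median| / median restricted to the content
mask, with the formula string recorded in the output. Zero-median
voxels are set to the fill value and counted in a warning. Division by
the median makes values blow up where the median approaches the mask
floor — the characteristic border amplification this diagnostic is
meant to show.

Both map tests default to content-masked voxel sets (configurable to
whole-grid).

## Synthetic phantom population

The generator emulates a cohort of aligned proportion maps at the level
where the statistics live; it makes no attempt at realistic anatomy,
MR contrast, scanner noise or bias fields.

**Geometry.** Three nested ellipsoids on a 48³ grid at 1 mm isotropic
(defaults): WM core (semi-axes 10, 9, 8 voxels), GM shell (16, 15, 13),
CSF outer shell (20, 19, 17). Region indicators are blurred with a
Gaussian of σ = 1 voxel (partial-volume emulation) and jointly
renormalized so GM + WM + CSF ≤ 1 per voxel.

**Content distributions.** Within its region each tissue draws
voxel-wise from a Beta law: GM Beta(8, 3) (left-skewed, ≈ −0.37), WM
Beta(3, 8) (right-skewed, ≈ +0.60), CSF Beta(1.5, 8) (strongly
right-skewed ≈ +1.25 and leptokurtic, excess kurtosis ≈ +1.06). Beta
was chosen because proportions are bounded in [0, 1] and both skew
directions come with closed-form moments and quantiles for oracles.
The skewness *sign pattern* (GM negative; WM, CSF positive) is the
target; real-cohort magnitudes are not.

**Border symmetrization.** A voxel sample equal to weight × Beta would
have the same distributional shape at borders as in cores (the
normality test is scale-invariant), which contradicts the empirical
fact that border voxels of population proportion maps look far more
Gaussian than region cores. Physically, a mixed voxel averages over
many micro-compartments, which tightens and symmetrizes its content
distribution. The generator models this by scaling *both* Beta shape
parameters (mean-preserving precision increase) as the region weight
drops below purity: the multiplier ramps linearly from 1 at weight
≥ 0.9 to `border_precision` (default 20, shrinking skewness by ≈ √20)
at weight ≤ 0.6. With this mechanism the CSF Shapiro–Wilk rejection
rate at n = 96 falls from ≈ 1.0 in cores to ≈ 0.2 at borders.

**Subject variability.** Each subject carries a global multiplicative
factor exp(ε), ε ~ N(0, 0.02²) truncated at ±2 sd — residual head-size
and segmentation variability that survives spatial normalization. The
sd is kept small both because normalization removes most global scale
and because the factor's log-normal right skew would otherwise mask the
weak negative GM skewness at symmetrized border voxels, breaking the
sign pattern the generator is built to show. An optional additive
voxel noise (`voxel_noise_sd`, default 0) is available but off: with
clipping at 0 it creates a point mass that distorts normality at the
outer fade.

**Reproducibility and ground truth.** Each subject draws from an RNG
substream seeded by (seed, subject index), so populations are bit
reproducible and any subject re-derivable in isolation. The ground
truth carries the weight maps, core masks (weight ≥ 0.9, exactly where
the precision multiplier is 1) and analytic quantile maps
weight × Beta⁻¹(t/100); these are exact in cores up to the subject
factor (median 1, quantile perturbation well below the Beta spread at
the default sd).

**What passing tests do and do not show.** The phantom shares with real
data the bounded skewed voxel distributions, partial-volume borders,
subject-level global variability and the border-normality contrast; it
lacks anatomy, spatially correlated noise, registration error and
demographic structure. Tests passing on it validate the statistical
machinery and its calibration, not claims about any particular cohort.

## Validation problem sizes

The suite and the acceptance script use: 10⁵-draw Gaussian samples for
the moment limits; all n ≤ 12 × all integer t ∈ 1…99 × ~100 random
vectors for the percentile oracle; 1,000 random vectors for the moment
oracles; a 96 × 10,000 Gaussian population for Shapiro–Wilk
calibration; 40- and 96-subject default phantoms for volume linearity
and the mean-vs-median direction pattern; a 500-subject phantom for
percentile recovery (observed RMS ≈ 0.01 against the 0.02 contract);
and two full 40-subject pipeline runs for byte-level reproducibility.

## Known limitations

* Voxel-wise p-values are not corrected for multiple comparisons, by
  design (the comparison battery replicates the conventional
  uncorrected presentation).
* The KS p-value is asymptotic; for in-mask counts below ~50 it is
  approximate.
* Volumes are whole-grid; a caller who wants mask-restricted volumes
  must apply the mask first.
* The phantom's ground-truth quantiles are envelopes, not exact values,
  at mixed border voxels.
* NIfTI-1 only; qform/sform disagreements resolve to sform (nibabel's
  convention), and headers are not repaired.
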