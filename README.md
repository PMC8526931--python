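# tissueatlas

Non-parametric (percentile) brain tissue-probability-map atlases and
voxel-wise population distribution diagnostics.

## The problem

A population brain template is usually built by averaging spatially
normalized per-subject tissue proportion maps (gray matter, white
matter, cerebrospinal fluid) voxel by voxel. The arithmetic mean,
however, is only a faithful central measure when the per-voxel sample
across subjects is symmetric — and tissue proportions, being bounded in
[0, 1] and driven by anatomy, are typically skewed: GM mildly
left-skewed, WM and CSF right-skewed, CSF strongly so. A mean template
then systematically overstates CSF and understates GM.

`tissueatlas` is for neuroimaging researchers who build or evaluate
tissue probability maps (TPMs). It takes a population of aligned
proportion maps and produces:

* **order-based (percentile) atlases** — per-voxel order statistics at
  chosen levels t (the t = 50 map is the median template), plus the
  parametric mean atlas and the IQR spread map;
* **distribution diagnostic maps** — voxel-wise skewness, excess
  (Fisher) kurtosis and Shapiro–Wilk normality p-values, with 5 %
  content masking and table-style median summaries;
* **a comparison battery** — paired Wilcoxon signed-rank and two-sample
  Kolmogorov–Smirnov tests between maps, percentage-difference maps,
  and TPM volumes obtained by counting the probability in the voxels;
* **a synthetic phantom population** with analytic Beta ground truth,
  for validating the whole pipeline without a real cohort.

## The statistics

For the per-voxel sample x₁ … xₙ across n subjects, with μ the mean and
σ the standard deviation computed with **n** (not n − 1) in the
denominator:

* skewness S = (1/n) Σᵢ (xᵢ − μ)³ / σ³
* excess kurtosis K = (1/n) Σᵢ (xᵢ − μ)⁴ / σ⁴ − 3

so both are 0 in the Gaussian limit. The t-th percentile of the ordered
sample x₍₁₎ ≤ … ≤ x₍ₙ₎ uses the averaged-inverse-CDF rule: writing
n·t/100 = j + g (j integer part, g fractional part),

* y = ½ (x₍ⱼ₎ + x₍ⱼ₊₁₎)  if g = 0
* y = x₍ⱼ₊₁₎            if g > 0

with indices clamped to [1, n]. Tissue volume is
V = Σ voxels value × voxel volume (|det A₃ₓ₃| mm³ / 1000 ml from the
NIfTI affine A). Normality is assessed per voxel with the Shapiro–Wilk
test; mean vs. median templates are compared with the paired Wilcoxon
signed-rank test (exact enumeration up to 25 informative pairs,
tie/continuity-corrected normal approximation above) and the
Kolmogorov–Smirnov test on pooled in-mask values.

## Worked example

```python
import numpy as np
from tissueatlas import (PhantomSpec, generate_population, build_percentile_atlas,
                         build_mean_atlas, tpm_volume, content_mask,
                         wilcoxon_signed_rank, stat_map, distribution_summary)

spec = PhantomSpec()                      # 48^3 grid, 1 mm voxels
stacks, truth = generate_population(spec, n=96, seed=42)

gm = stacks["GM"]
atlas = build_percentile_atlas(gm, levels=(5, 25, 50, 75, 95))
mean_map = build_mean_atlas(gm)
mask = content_mask(atlas[50.0], threshold=0.05)

print("GM median-atlas volume: %.2f ml" % tpm_volume(atlas[50.0]).volume_ml)
print("GM mean-atlas volume:   %.2f ml" % tpm_volume(mean_map).volume_ml)

res = wilcoxon_signed_rank(mean_map, atlas[50.0], mask)
print("Wilcoxon mean vs median: W- = %.0f, p = %.3g (n = %d voxels)"
      % (res.statistic, res.p_value, res.n_pairs))

diag = {s: stat_map(gm, s, mask=mask) for s in ("skewness", "kurtosis", "sw_p")}
print(distribution_summary(diag, mask, label="All", tissue="GM").to_string(index=False))
```

prints

```
GM median-atlas volume: 7.38 ml
GM mean-atlas volume:   7.30 ml
Wilcoxon mean vs median: W- = 94335587, p = 0 (n = 15468 voxels)
group tissue  n_voxels  median_skewness  median_kurtosis  median_sw_p
  All     GM     15468        -0.220435        -0.150068     0.253454
```

The GM phantom population is left-skewed, so its median template is
*larger* than the mean template (here by about 1 %), the paired
Wilcoxon test rejects equality decisively (p underflows to 0), and the
in-mask median skewness is negative — the direction pattern expected
for gray matter. For right-skewed WM/CSF the inequality reverses.

## Command line

```sh
tissueatlas simulate   --outdir phantom --n 40 --seed 1   # write a phantom cohort
tissueatlas diagnose   --manifest phantom/manifest.tsv --outdir maps
tissueatlas build-atlas --manifest phantom/manifest.tsv --outdir atlas
tissueatlas compare    --rundir atlas                     # mean vs median tests
tissueatlas volumes    --manifest phantom/manifest.tsv --outdir vols
tissueatlas run-all    --outdir out --seed 1              # everything at once
```

Inputs are NIfTI-1 proportion maps listed in a TSV manifest
(`subject_id`, `tissue`, `path`, optional `group`); all outputs are
NIfTI maps plus TSV tables and a JSON run manifest that makes every run
reproducible from (config, seed).

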