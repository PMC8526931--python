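"""End-to-end orchestration: simulate -> diagnose -> atlas -> compare.

A run is fully described by a :class:`RunConfig` (deserializable from a
YAML file) plus a seed; every product is derivable from those alone and
the run manifest written alongside the outputs records the config hash
and library versions needed to reproduce it.

Products per tissue and group (NIfTI unless noted):
percentile atlas maps, mean map, IQR map, skewness/kurtosis/sw_p maps,
content mask, percentage-difference map, violin value exports (TSV),
volumes.tsv, comparisons.tsv, summary.tsv, run_manifest.json.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import (
    DEFAULT_LEVELS,
    PercentileAtlas,
    build_mean_atlas,
    build_percentile_atlas,
    iqr_map,
    tpm_volume,
)
from .compare import ks_two_sample, percentage_difference_map, wilcoxon_signed_rank
from .io import (
    MaskMap,
    PopulationStack,
    ProportionMap,
    StatMap,
    Tissue,
    TISSUES,
    load_stacks_from_manifest,
    write_map,
)
from .phantom import PhantomSpec, generate_population, true_percentile_map
from .voxelwise import content_mask, distribution_summary, stat_map, violin_export

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    Exactly one of ``manifest`` (subject TSV) or ``phantom`` (synthetic
    spec + n_subjects) provides the input population.  ``mask_source``
    chooses the central map thresholded at ``mask_threshold`` (median,
    the non-parametric default, or mean).
    """

    outdir: str = "out"
    seed: int = 0
    tissues: tuple[Tissue, ...] = TISSUES
    levels: tuple[float, ...] = DEFAULT_LEVELS
    mask_threshold: float = 0.05
    alpha: float = 0.05
    mask_source: str = "median"
    range_policy: str = "clip"
    group_label: str = "All"
    manifest: str | None = None
    phantom: PhantomSpec | None = None
    n_subjects: int = 40
    write_volumes: bool = True

    def __post_init__(self) -> None:
        self.levels = tuple(float(t) for t in self.levels)
        for t in self.levels:
            if not 0.0 < t < 100.0:
                raise ValueError(f"percentile level {t} outside (0, 100)")
        if self.mask_source not in ("median", "mean"):
            raise ValueError("mask_source must be 'median' or 'mean'")

    def to_dict(self) -> dict:
        # outdir is deliberately omitted: the manifest and its hash
        # describe the computation, not where it landed on disk
        d = {
            "seed": self.seed,
            "tissues": list(self.tissues),
            "levels": list(self.levels),
            "mask_threshold": self.mask_threshold,
            "alpha": self.alpha,
            "mask_source": self.mask_source,
            "range_policy": self.range_policy,
            "group_label": self.group_label,
            "manifest": self.manifest,
            "n_subjects": self.n_subjects,
        }
        if self.phantom is not None:
            d["phantom"] = self.phantom.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("phantom") is not None:
            d["phantom"] = PhantomSpec.from_dict(d["phantom"])
        if "tissues" in d:
            d["tissues"] = tuple(d["tissues"])
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class TissueProducts:
    """In-memory handles to one tissue's maps from a run."""

    tissue: Tissue
    atlas: PercentileAtlas
    mean_map: StatMap
    mask: MaskMap
    n_subjects: int


@dataclass
class RunReport:
    """What one pipeline run produced, with paths for downstream stages."""

    config: RunConfig
    outdir: Path
    products: dict[Tissue, TissueProducts] = field(default_factory=dict)
    volumes: pd.DataFrame | None = None
    comparisons: pd.DataFrame | None = None
    summary: pd.DataFrame | None = None
    files: list[str] = field(default_factory=list)
    warnings_count: int = 0


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_input_stacks(config: RunConfig) -> dict[Tissue, PopulationStack]:
    """Resolve the run's input population (manifest or phantom)."""
    if config.manifest is not None:
        return load_stacks_from_manifest(
            config.manifest,
            tissues=config.tissues,
            range_policy=config.range_policy,
        )
    spec = config.phantom if config.phantom is not None else PhantomSpec()
    stacks, _ = generate_population(spec, config.n_subjects, seed=config.seed)
    return {t: stacks[t] for t in config.tissues}


def _name(outdir: Path, group: str, tissue: str, suffix: str) -> Path:
    return outdir / f"{group}_{tissue}_{suffix}.nii.gz"


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full per-group workflow and write all products."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    group = config.group_label
    logger.info("run start: group=%s outdir=%s seed=%d", group, outdir, config.seed)

    stacks = load_input_stacks(config)
    report = RunReport(config=config, outdir=outdir)
    vol_rows: list[dict] = []
    cmp_rows: list[dict] = []
    sum_rows: list[pd.DataFrame] = []

    for tissue in config.tissues:
        stack = stacks[tissue]
        atlas = build_percentile_atlas(stack, config.levels, group_label=group)
        mean_map = build_mean_atlas(stack, group_label=group)

        central = atlas[50.0] if config.mask_source == "median" and 50.0 in atlas.maps \
            else mean_map
        mask = content_mask(central, config.mask_threshold)
        mask.source = config.mask_source

        for t, m in atlas.maps.items():
            p = _name(outdir, group, tissue, f"p{t:g}")
            write_map(m, p)
            report.files.append(str(p))
        p = _name(outdir, group, tissue, "mean")
        write_map(mean_map, p)
        report.files.append(str(p))

        if 25.0 in atlas.maps and 75.0 in atlas.maps:
            iqr = iqr_map(atlas)
            p = _name(outdir, group, tissue, "iqr")
            write_map(iqr, p)
            report.files.append(str(p))
        else:
            logger.info("%s/%s: IQR stage skipped (levels 25/75 absent)", group, tissue)

        diag = {
            name: stat_map(stack, name, mask=mask)
            for name in ("skewness", "kurtosis", "sw_p")
        }
        for name, m in diag.items():
            p = _name(outdir, group, tissue, name)
            write_map(m, p)
            report.files.append(str(p))
            vpath = outdir / f"{group}_{tissue}_{name}_violin.tsv"
            violin_export(m, mask, path=vpath)
            report.files.append(str(vpath))
        p = _name(outdir, group, tissue, "mask")
        write_map(mask, p, affine=stack.affine)
        report.files.append(str(p))

        sum_rows.append(distribution_summary(diag, mask, label=group, tissue=tissue))

        if 50.0 in atlas.maps:
            pct = percentage_difference_map(mean_map, atlas[50.0], mask)
            pmap = StatMap(
                statistic="pct_diff", data=pct.data, affine=stack.affine, mask=mask
            )
            p = _name(outdir, group, tissue, "pctdiff")
            write_map(pmap, p)
            report.files.append(str(p))

            wres = wilcoxon_signed_rank(mean_map, atlas[50.0], mask, alpha=config.alpha)
            row = wres.as_row()
            row.update(group=group, tissue=tissue, contrast="mean-vs-median")
            cmp_rows.append(row)
            kres = ks_two_sample(mean_map, atlas[50.0], mask, alpha=config.alpha)
            row = kres.as_row()
            row.update(group=group, tissue=tissue, contrast="mean-vs-median")
            cmp_rows.append(row)

        if config.write_volumes:
            vol_rows.append(
                tpm_volume(mean_map, group_label=group, measure="mean").__dict__
            )
            for t, m in atlas.maps.items():
                measure = "median" if t == 50.0 else f"percentile-{t:g}"
                vol_rows.append(
                    tpm_volume(m, group_label=group, measure=measure).__dict__
                )

        report.products[tissue] = TissueProducts(
            tissue=tissue,
            atlas=atlas,
            mean_map=mean_map,
            mask=mask,
            n_subjects=stack.n,
        )

    if vol_rows:
        report.volumes = pd.DataFrame(vol_rows).rename(
            columns={"group_label": "group"}
        )[["group", "tissue", "measure", "volume_ml"]]
        vpath = outdir / "volumes.tsv"
        report.volumes.to_csv(vpath, sep="\t", index=False, float_format="%.6f")
        report.files.append(str(vpath))
    if cmp_rows:
        report.comparisons = pd.DataFrame(cmp_rows)
        cpath = outdir / "comparisons.tsv"
        report.comparisons.to_csv(cpath, sep="\t", index=False)
        report.files.append(str(cpath))
    if sum_rows:
        report.summary = pd.concat(sum_rows, ignore_index=True)
        spath = outdir / "summary.tsv"
        report.summary.to_csv(spath, sep="\t", index=False, float_format="%.6g")
        report.files.append(str(spath))

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "versions": _library_versions(),
        "products": sorted(Path(f).name for f in report.files),
    }
    mpath = outdir / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    report.files.append(str(mpath))
    logger.info("run complete: %d files in %s", len(report.files), outdir)
    return report


def _library_versions() -> dict:
    import nibabel
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
        "pandas": pd.__version__,
    }


def simulate_to_disk(
    spec: PhantomSpec,
    n: int,
    outdir: str | Path,
    seed: int | None = None,
    gt_levels: tuple[float, ...] = (25.0, 50.0, 75.0),
) -> Path:
    """Write a phantom population as per-subject NIfTI maps + manifest.

    Emits ``sub-XXX_<tissue>.nii.gz`` per subject/tissue, ground-truth
    analytic quantile maps, the serialized generator spec, and a
    ``manifest.tsv`` consumable by the analysis stages.  Returns the
    manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stacks, gt = generate_population(spec, n, seed=seed)
    rows = []
    for tissue in TISSUES:
        stack = stacks[tissue]
        for i, sid in enumerate(stack.subject_ids):
            fname = f"{sid}_{tissue}.nii.gz"
            write_map(
                ProportionMap(sid, tissue, stack.data[i], stack.affine),
                outdir / fname,
            )
            rows.append({"subject_id": sid, "tissue": tissue, "path": fname})
        for t in gt_levels:
            gmap = true_percentile_map(gt, tissue, t)
            write_map(gmap, outdir / f"groundtruth_{tissue}_p{t:g}.nii.gz")
    manifest_path = outdir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)
    with open(outdir / "phantom_spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=True)
    return manifest_path


def summarize_groups(reports: list[RunReport], outdir: str | Path | None = None):
    """Cross-group volume table plus pairwise KS atlas comparisons.

    Compares the groups' non-parametric (median) maps per tissue on the
    union of their content masks; all groups must share a grid.
    """
    if len(reports) < 2:
        raise ValueError("need at least two group reports")
    tissues = list(reports[0].products)
    grid = reports[0].products[tissues[0]].mean_map.data.shape
    for rep in reports[1:]:
        for t in tissues:
            if rep.products[t].mean_map.data.shape != grid:
                raise ValueError(
                    f"grid mismatch between groups "
                    f"({rep.config.group_label}, tissue {t})"
                )
    vol_tables = [r.volumes for r in reports if r.volumes is not None]
    volumes = pd.concat(vol_tables, ignore_index=True) if vol_tables else None
    rows = []
    for i, ra in enumerate(reports):
        for rb in reports[i + 1 :]:
            for tissue in tissues:
                pa, pb = ra.products[tissue], rb.products[tissue]
                union = MaskMap(
                    data=pa.mask.data | pb.mask.data,
                    threshold=pa.mask.threshold,
                    source=f"union({pa.mask.source})",
                )
                res = ks_two_sample(
                    pa.atlas[50.0], pb.atlas[50.0], union, alpha=ra.config.alpha
                )
                row = res.as_row()
                row.update(
                    group_a=ra.config.group_label,
                    group_b=rb.config.group_label,
                    tissue=tissue,
                    contrast="median-atlas",
                )
                rows.append(row)
    comparisons = pd.DataFrame(rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if volumes is not None:
            volumes.to_csv(
                outdir / "group_volumes.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
        comparisons.to_csv(outdir / "group_comparisons.tsv", sep="\t", index=False)
    return volumes, comparisons
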