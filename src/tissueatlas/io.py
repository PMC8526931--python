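"""NIfTI ingestion, population stacks, and voxel geometry.

All volumes are tissue-proportion maps: 3D arrays of values in [0, 1]
giving the fraction of a tissue class (GM, WM or CSF) at each voxel,
already resampled to a common grid.  This module reads and writes them,
assembles aligned 4D population stacks (subjects x voxels), and derives
the voxel volume used to convert probability counts into millilitres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Tissue = Literal["GM", "WM", "CSF"]
TISSUES: tuple[Tissue, ...] = ("GM", "WM", "CSF")

#: element-wise absolute tolerance for affine agreement across subjects
AFFINE_ATOL = 1e-4

#: minimum population size for any distributional statistic
MIN_SUBJECTS = 3


class RangePolicyError(ValueError):
    """Raised when proportions fall outside [0, 1] under the 'reject' policy."""


def _validate_range(data: np.ndarray, policy: str, context: str) -> np.ndarray:
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{context}: non-finite values present")
    lo, hi = float(data.min()), float(data.max())
    if lo >= 0.0 and hi <= 1.0:
        return data
    if policy == "reject":
        raise RangePolicyError(
            f"{context}: values outside [0, 1] (min={lo:.6g}, max={hi:.6g})"
        )
    if policy == "clip":
        n_out = int(np.count_nonzero((data < 0.0) | (data > 1.0)))
        warnings.warn(
            f"{context}: clipped {n_out} voxel(s) outside [0, 1] "
            f"(min={lo:.6g}, max={hi:.6g})",
            stacklevel=3,
        )
        logger.warning("%s: clipped %d out-of-range voxel(s)", context, n_out)
        return np.clip(data, 0.0, 1.0)
    raise ValueError(f"unknown out-of-range policy {policy!r}")


def _check_affine(affine: np.ndarray, context: str) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"{context}: affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{context}: singular affine (non-invertible 3x3 part)")
    return affine


@dataclass
class ProportionMap:
    """One subject's 3D tissue-proportion volume.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the map belongs to.
    tissue : {"GM", "WM", "CSF"}
        Tissue class of the proportions.
    data : ndarray, shape (nx, ny, nz)
        Proportion values in [0, 1].
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform in mm.
    """

    subject_id: str
    tissue: Tissue
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.data.ndim}D for {self.subject_id}"
            )
        self.affine = _check_affine(self.affine, f"subject {self.subject_id}")
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class MaskMap:
    """Boolean content mask derived from a central (mean/median) map."""

    data: np.ndarray
    threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass
class StatMap:
    """A 3D map of a named voxel-wise statistic with provenance.

    ``statistic`` is one of skewness, kurtosis, sw_p, mean, percentile,
    iqr, pct_diff; ``level`` is the percentile level t (percentile maps
    only).  ``provenance`` records tissue, subject count and parameters.
    """

    statistic: str
    data: np.ndarray
    affine: np.ndarray
    level: float | None = None
    mask: MaskMap | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("StatMap data must be 3D")
        self.affine = _check_affine(self.affine, f"StatMap[{self.statistic}]")

    def masked_values(self, mask: MaskMap | None = None) -> np.ndarray:
        """Flat array of in-mask values (all finite voxels if no mask)."""
        m = mask if mask is not None else self.mask
        if m is None:
            return self.data[np.isfinite(self.data)]
        if m.data.shape != self.data.shape:
            raise ValueError("mask shape does not match map shape")
        return self.data[m.data]


@dataclass
class PopulationStack:
    """Aligned 4D collection (subjects x voxels) of one tissue class."""

    tissue: Tissue
    subject_ids: list[str]
    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError("stack data must be 4D (subjects x nx x ny x nz)")
        if self.data.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match stack size")
        if self.n < MIN_SUBJECTS:
            raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {self.n}")
        self.affine = _check_affine(self.affine, f"stack[{self.tissue}]")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]  # type: ignore[return-value]


def read_proportion_map(
    path: str | Path,
    tissue: Tissue,
    subject_id: str,
    range_policy: str = "clip",
) -> ProportionMap:
    """Read one subject's proportion map from a NIfTI-1 file.

    The affine is taken from the header (sform preferred over qform when
    both are set, nibabel's default); scaling slope/intercept are honored.
    ``range_policy`` is "clip" (clip to [0, 1] with a warning, default)
    or "reject" (raise on out-of-range values).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    data = _validate_range(data, range_policy, f"{path.name} ({subject_id}/{tissue})")
    return ProportionMap(
        subject_id=subject_id, tissue=tissue, data=data, affine=img.affine
    )


def assemble_stack(maps: Sequence[ProportionMap]) -> PopulationStack:
    """Stack aligned per-subject maps of one tissue into a 4D population.

    Subject order is preserved; the shared affine is the first map's.
    Raises on mixed tissues, shape mismatch, fewer than 3 maps, or
    affines differing beyond ``AFFINE_ATOL`` element-wise.
    """
    maps = list(maps)
    if len(maps) < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {len(maps)}")
    tissue = maps[0].tissue
    shape = maps[0].shape
    affine = maps[0].affine
    for m in maps[1:]:
        if m.tissue != tissue:
            raise ValueError(
                f"mixed tissues: {tissue} vs {m.tissue} (subject {m.subject_id})"
            )
        if m.shape != shape:
            raise ValueError(
                f"shape mismatch for subject {m.subject_id}: {m.shape} vs {shape}"
            )
        if not np.allclose(m.affine, affine, rtol=0.0, atol=AFFINE_ATOL):
            raise ValueError(
                f"affine mismatch for subject {m.subject_id} "
                f"(beyond {AFFINE_ATOL} element-wise)"
            )
    data = np.stack([m.data for m in maps], axis=0)
    return PopulationStack(
        tissue=tissue,
        subject_ids=[m.subject_id for m in maps],
        data=data,
        affine=affine,
    )


def voxel_volume_ml(affine: np.ndarray) -> float:
    """Voxel volume in ml: ``|det| mm^3 / 1000`` of the affine's 3x3 part.

    Invariant under rotation of the grid; raises on a singular affine.
    """
    affine = _check_affine(affine, "voxel_volume_ml")
    return abs(float(np.linalg.det(affine[:3, :3]))) / 1000.0


def write_map(
    vol: ProportionMap | StatMap | MaskMap,
    path: str | Path,
    affine: np.ndarray | None = None,
    mask_fill: float = np.nan,
) -> None:
    """Write a volume as NIfTI-1 (gzip if the path ends in .gz).

    Float maps are stored as float32 (>= 32-bit precision); masks as
    uint8.  For a masked :class:`StatMap` the out-of-mask voxels carry
    ``mask_fill`` (NaN by default, distinguishing "no data" from 0).
    """
    path = Path(path)
    if isinstance(vol, MaskMap):
        data = vol.data.astype(np.uint8)
        if affine is None:
            raise ValueError("writing a MaskMap requires an explicit affine")
        aff = affine
    else:
        data = vol.data.astype(np.float32)
        aff = vol.affine if affine is None else affine
        if isinstance(vol, StatMap) and vol.mask is not None:
            data = data.copy()
            data[~vol.mask.data] = mask_fill
    img = nib.Nifti1Image(data, np.asarray(aff, dtype=float))
    nib.save(img, str(path))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a subject manifest TSV with columns subject_id, tissue, path.

    An optional ``group`` column carries group labels (defaults to "All").
    Paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "tissue", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if "group" not in df.columns:
        df["group"] = "All"
    df["path"] = [
        str((path.parent / p).resolve()) if not Path(p).is_absolute() else p
        for p in df["path"]
    ]
    bad = set(df["tissue"]) - set(TISSUES)
    if bad:
        raise ValueError(f"manifest {path}: unknown tissue labels {sorted(bad)}")
    return df


def load_stacks_from_manifest(
    path: str | Path,
    tissues: Iterable[Tissue] = TISSUES,
    group: str | None = None,
    range_policy: str = "clip",
) -> dict[Tissue, PopulationStack]:
    """Load per-tissue population stacks for one group from a manifest."""
    df = read_manifest(path)
    if group is not None:
        df = df[df["group"] == group]
        if df.empty:
            raise ValueError(f"no manifest rows for group {group!r}")
    stacks: dict[Tissue, PopulationStack] = {}
    for tissue in tissues:
        sub = df[df["tissue"] == tissue]
        maps = [
            read_proportion_map(row["path"], tissue, row["subject_id"], range_policy)
            for _, row in sub.iterrows()
        ]
        stacks[tissue] = assemble_stack(maps)
    return stacks
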