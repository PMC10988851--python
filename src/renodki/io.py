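"""File I/O: NIfTI volumes, FSL-dialect bval/bvec tables, metric CSV tables.

NIfTI affines are carried through untouched; ``.nii.gz`` outputs are
gzipped with a zeroed timestamp so byte-identical inputs produce
byte-identical files (checksum-stable pipelines).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import GradientScheme
from .errors import FormatError
from .metrics import ParameterMaps

__all__ = [
    "DWIVolume",
    "LabelMap",
    "REGION_LEGEND",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "read_dwi",
    "write_dwi",
    "read_labels",
    "write_labels",
    "write_maps",
    "read_maps",
    "read_roi_table",
    "write_roi_table",
    "validate_roi_table",
]

REGION_LEGEND = {0: "background", 1: "CO", 2: "OS", 3: "IS"}

ROI_REQUIRED_COLUMNS = ("subject", "group", "timepoint", "region", "metric", "value")
ROI_KEY_COLUMNS = ("subject", "group", "timepoint", "region", "metric", "rater")

_BVEC_RENORM_TOL = 1e-3


@dataclass(frozen=True)
class DWIVolume:
    """4D diffusion-weighted signal array with its acquisition scheme."""

    data: np.ndarray  # (x, y, z, volume), signal >= 0
    scheme: GradientScheme
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise FormatError(f"DWI data must be 4D, got shape {data.shape}")
        if data.shape[3] != self.scheme.n_volumes:
            raise FormatError(
                f"image holds {data.shape[3]} volumes but the scheme "
                f"describes {self.scheme.n_volumes}"
            )
        if np.any(data < 0):
            raise FormatError("signal values must be nonnegative")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass(frozen=True)
class LabelMap:
    """Integer region labels aligned with a companion DWI grid."""

    labels: np.ndarray
    legend: dict = field(default_factory=lambda: dict(REGION_LEGEND))
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise FormatError("labels must be integer-typed")
        codes = set(np.unique(labels).tolist())
        unknown = codes - set(self.legend)
        if unknown:
            raise FormatError(f"label codes {sorted(unknown)} missing from legend")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    def region_mask(self, region: str) -> np.ndarray:
        code = {v: k for k, v in self.legend.items()}[region]
        return self.labels == code


def _save_nifti(img: nib.Nifti1Image, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.name.endswith(".nii.gz"):
        path.write_bytes(gzip.compress(img.to_bytes(), mtime=0))
    else:
        nib.save(img, str(path))


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-dialect tables: bvals one row, bvecs 3 rows x N columns."""
    bvals = np.loadtxt(bval_path, dtype=float).reshape(-1)
    bvecs = np.atleast_2d(np.loadtxt(bvec_path, dtype=float))
    if bvecs.shape[0] != 3:
        raise FormatError(f"bvec file must have 3 rows, got {bvecs.shape[0]}")
    bvecs = bvecs.T  # (n, 3)
    if bvecs.shape[0] != bvals.shape[0]:
        raise FormatError(
            f"bval ({bvals.shape[0]}) and bvec ({bvecs.shape[0]}) entries disagree"
        )
    return bvals, bvecs


def write_bvals_bvecs(scheme: GradientScheme, bval_path, bvec_path) -> None:
    Path(bval_path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.17g")


def _scheme_from_tables(bvals: np.ndarray, bvecs: np.ndarray) -> GradientScheme:
    norms = np.linalg.norm(bvecs, axis=1)
    weighted = bvals > 0
    bad = weighted & (np.abs(norms - 1.0) >= _BVEC_RENORM_TOL)
    if np.any(bad):
        raise FormatError(
            f"{int(bad.sum())} weighted directions deviate from unit length "
            f"by >= {_BVEC_RENORM_TOL} and cannot be renormalized"
        )
    bvecs = bvecs.copy()
    renorm = weighted & (norms > 0)
    bvecs[renorm] /= norms[renorm, None]
    if np.any(weighted & (norms == 0)):
        raise FormatError("zero direction vector on a weighted volume")
    return GradientScheme(bvals, bvecs)


def read_dwi(nifti_path, bval_path, bvec_path) -> DWIVolume:
    """Load a 4D NIfTI with its gradient tables; renormalizes near-unit bvecs."""
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected a 4D image, got shape {data.shape}")
    bvals, bvecs = read_bvals_bvecs(bval_path, bvec_path)
    if bvals.shape[0] != data.shape[3]:
        raise FormatError(
            f"image holds {data.shape[3]} volumes but tables describe {bvals.shape[0]}"
        )
    return DWIVolume(data, _scheme_from_tables(bvals, bvecs), img.affine)


def write_dwi(dwi: DWIVolume, nifti_path, bval_path, bvec_path) -> None:
    img = nib.Nifti1Image(dwi.data.astype(np.float64), dwi.affine)
    _save_nifti(img, Path(nifti_path))
    write_bvals_bvecs(dwi.scheme, bval_path, bvec_path)


def read_labels(path, legend: dict | None = None) -> LabelMap:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int16)
    return LabelMap(labels, legend or dict(REGION_LEGEND), img.affine)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), labels.affine)
    _save_nifti(img, Path(path))


def write_maps(maps: ParameterMaps, directory) -> dict[str, Path]:
    """Write one float32 NIfTI per metric; returns metric -> path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in ("mk", "fa", "md", "s0"):
        arr = getattr(maps, name).astype(np.float32)
        path = directory / f"{name}.nii.gz"
        _save_nifti(nib.Nifti1Image(arr, maps.affine), path)
        out[name] = path
    return out


def read_maps(directory) -> ParameterMaps:
    directory = Path(directory)
    arrays = {}
    affine = None
    for name in ("mk", "fa", "md", "s0"):
        path = directory / f"{name}.nii.gz"
        if not path.exists():
            raise FormatError(f"missing metric map {path}")
        img = nib.load(str(path))
        arrays[name] = np.asarray(img.dataobj, dtype=float)
        affine = img.affine
    return ParameterMaps(affine=affine, **arrays)


def validate_roi_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and key uniqueness of a tidy metrics table."""
    missing = [c for c in ROI_REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"ROI table lacks required column(s): {missing}")
    key_cols = [c for c in ROI_KEY_COLUMNS if c in table.columns]
    dup = table.duplicated(subset=key_cols)
    if dup.any():
        raise FormatError(
            f"{int(dup.sum())} duplicate (subject, region, metric, timepoint"
            + (", rater" if "rater" in key_cols else "")
            + ") rows"
        )
    if not np.issubdtype(table["value"].dtype, np.number):
        raise FormatError("ROI table 'value' column must be numeric")
    return table


def read_roi_table(path) -> pd.DataFrame:
    # round_trip parsing: written values must survive the text format exactly
    return validate_roi_table(pd.read_csv(path, float_precision="round_trip"))


def write_roi_table(table: pd.DataFrame, path) -> None:
    validate_roi_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.17g")
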