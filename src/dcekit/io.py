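"""NIfTI reading/writing and result serialization shared by all stages."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .calibration import ProbabilityMap
from .tic import DCESeries, TissueMask

__all__ = [
    "read_volume",
    "read_series",
    "read_mask",
    "read_binary_mask",
    "read_probability_map",
    "write_volume",
    "write_series",
    "write_phantom",
]

logger = logging.getLogger(__name__)


def _load(path) -> tuple[np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    logger.info("read %s: shape=%s", path.name, data.shape)
    return data, img.affine


def _spacing_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


def read_series(path) -> DCESeries:
    """Read a 4D dynamic series; rejects non-4D volumes."""
    data, affine = _load(path)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D DCE series, got {data.ndim}D")
    return DCESeries(data.astype(float), voxel_spacing=_spacing_from_affine(affine))


def read_mask(path, label_map: dict[str, int] | None = None) -> TissueMask:
    """Read a 3D integer tissue-label volume; logs the label histogram."""
    data, _ = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D label mask, got {data.ndim}D")
    labels = np.rint(data).astype(np.int16)
    values, counts = np.unique(labels, return_counts=True)
    logger.info("labels in %s: %s", path, dict(zip(values.tolist(), counts.tolist())))
    if label_map is None:
        return TissueMask(labels)
    return TissueMask(labels, label_map)


def read_binary_mask(path) -> np.ndarray:
    data, _ = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D binary mask, got {data.ndim}D")
    return data > 0


def read_probability_map(path, prostate_mask_path=None) -> ProbabilityMap:
    data, _ = _load(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D probability map, got {data.ndim}D")
    mask = read_binary_mask(prostate_mask_path) if prostate_mask_path else None
    return ProbabilityMap(data.astype(float), prostate_mask=mask)


def read_volume(path, kind: str):
    """Dispatch reader: ``series`` | ``mask`` | ``binary`` | ``probability``."""
    readers = {
        "series": read_series,
        "mask": read_mask,
        "binary": read_binary_mask,
        "probability": read_probability_map,
    }
    if kind not in readers:
        raise ValueError(f"unknown volume kind {kind!r}; choose from {sorted(readers)}")
    return readers[kind](path)


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_volume(path, array: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _affine(spacing)), str(path))
    return path


def write_series(path, series: DCESeries) -> Path:
    return write_volume(path, series.data, series.voxel_spacing)


def write_phantom(out_dir, series: DCESeries, mask: TissueMask, ground_truth: dict) -> dict:
    """Write a phantom as dce.nii.gz + mask.nii.gz + ground_truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dce": write_series(out_dir / "dce.nii.gz", series),
        "mask": write_volume(out_dir / "mask.nii.gz", mask.labels, series.voxel_spacing),
    }
    gt = {
        tissue: dataclasses.asdict(spec) for tissue, spec in ground_truth.items()
    }
    gt_path = out_dir / "ground_truth.json"
    gt_path.write_text(json.dumps(gt, indent=2))
    paths["ground_truth"] = gt_path
    return paths
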