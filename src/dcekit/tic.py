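"""Time-intensity curve (TIC) extraction from 4D DCE series.

A dynamic contrast-enhanced (DCE) acquisition is a 4D stack of T1-weighted
volumes acquired while a gadolinium bolus passes through the tissue.  Given
integer label masks for the three segmented compartments — tumor-suspicious
lesion (TSL), perilesional tissue (PLT, the shell directly adjacent to the
lesion) and normal-appearing tissue (NAT, a peripheral-zone reference) —
this module averages the voxel intensities of each compartment at every
frame and normalizes the resulting curve to its pre-contrast baseline, so
that downstream slope and fitted-maximum features are dimensionless and
comparable across tissues and patients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DCESeries",
    "TissueMask",
    "TimeIntensityCurve",
    "TISSUES",
    "extract_curve",
    "normalize_baseline",
]

logger = logging.getLogger(__name__)

#: Canonical tissue names used throughout the pipeline.
TISSUES = ("TSL", "PLT", "NAT")


@dataclass(frozen=True)
class DCESeries:
    """A 4D dynamic series with frame timing.

    Parameters
    ----------
    data
        Raw signal intensities, axes ``(x, y, z, t)``.
    frame_times
        Acquisition time of each frame.  When no timing metadata is
        available this defaults to the frame index, in which case every
        slope downstream carries per-frame units.
    voxel_spacing
        Voxel edge lengths in mm, ``(dx, dy, dz)``.
    """

    data: np.ndarray
    frame_times: np.ndarray = None  # type: ignore[assignment]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise ValueError(f"DCE series must be 4D (x,y,z,t); got {data.ndim}D")
        if data.shape[3] < 4:
            raise ValueError(f"DCE series needs >= 4 frames; got {data.shape[3]}")
        if self.frame_times is None:
            times = np.arange(data.shape[3], dtype=float)
        else:
            times = np.asarray(self.frame_times, dtype=float)
        if times.shape != (data.shape[3],):
            raise ValueError("frame_times length must match the t axis")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "frame_times", times)

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass(frozen=True)
class TissueMask:
    """Integer label volume plus the mapping tissue-name -> label code."""

    labels: np.ndarray
    label_map: dict[str, int] = field(
        default_factory=lambda: {"TSL": 1, "PLT": 2, "NAT": 3}
    )

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"tissue mask must be 3D; got {labels.ndim}D")
        if not np.issubdtype(labels.dtype, np.integer):
            labels = labels.astype(np.int16)
        object.__setattr__(self, "labels", labels)

    def voxels(self, tissue: str) -> np.ndarray:
        """Boolean mask of the named tissue; raises if absent or empty."""
        if tissue not in self.label_map:
            raise KeyError(
                f"tissue {tissue!r} not in label map {sorted(self.label_map)}"
            )
        sel = self.labels == self.label_map[tissue]
        if not sel.any():
            raise ValueError(f"tissue {tissue!r} has no voxels in the mask")
        return sel

    def voxel_counts(self) -> dict[str, int]:
        return {
            t: int((self.labels == code).sum()) for t, code in self.label_map.items()
        }


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Per-tissue averaged intensity versus time.

    ``baseline_frames`` is ``None`` for a raw (un-normalized) curve; after
    :func:`normalize_baseline` it records how many leading frames were
    averaged to define the baseline, and the mean of those frames equals 1.
    """

    tissue: str
    times: np.ndarray
    values: np.ndarray
    baseline_frames: int | None = None
    n_voxels: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if times.shape != values.shape or times.ndim != 1:
            raise ValueError("times and values must be equal-length 1D arrays")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def is_normalized(self) -> bool:
        return self.baseline_frames is not None


def extract_curve(series: DCESeries, mask: TissueMask, tissue: str) -> TimeIntensityCurve:
    """Average the voxel trajectories of one tissue into a raw curve.

    The value at frame *t* is the arithmetic mean over all voxels carrying
    the tissue's label.  NaN voxels (signal voids) are excluded from the
    mean per frame, with the count logged; an all-NaN tissue is an error.
    """
    sel = mask.voxels(tissue)
    if sel.shape != series.grid_shape:
        raise ValueError(
            f"mask grid {sel.shape} does not match series grid {series.grid_shape}"
        )
    voxels = series.data[sel]  # (n_voxels, t)
    n_nan = int(np.isnan(voxels).sum())
    if n_nan:
        logger.info("extract_curve(%s): excluding %d NaN voxel samples", tissue, n_nan)
    if np.isnan(voxels).all(axis=0).any():
        raise ValueError(f"tissue {tissue!r} is all-NaN in at least one frame")
    with np.errstate(invalid="ignore"):
        values = np.nanmean(voxels, axis=0)
    return TimeIntensityCurve(
        tissue=tissue,
        times=series.frame_times,
        values=values,
        baseline_frames=None,
        n_voxels=int(sel.sum()),
    )


def normalize_baseline(curve: TimeIntensityCurve, baseline_frames: int = 2) -> TimeIntensityCurve:
    """Divide a raw curve by the mean of its first ``baseline_frames`` values.

    Normalization makes the curve dimensionless with baseline ~= 1, so that
    the reference tissue's fitted maximum lands near 1.0 and ratios between
    tissues are scale-free.  Raises on a non-positive baseline mean, which
    indicates a signal void (air) rather than tissue.
    """
    if not 1 <= baseline_frames < len(curve):
        raise ValueError(
            f"baseline_frames must be in [1, {len(curve) - 1}]; got {baseline_frames}"
        )
    base = float(np.mean(curve.values[:baseline_frames]))
    if not base > 0:
        raise ValueError(
            f"non-positive baseline mean ({base:g}) for tissue {curve.tissue!r}: "
            "signal void or air in the segmentation"
        )
    return replace(
        curve, values=curve.values / base, baseline_frames=baseline_frames
    )
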