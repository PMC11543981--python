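"""Mapping deep-learning lesion-probability predictions to DL-PIRADS categories.

A voxelwise tumor-probability map (values in [0, 1], produced upstream by a
segmentation network; inference itself is out of scope here) is reduced to
one scalar per patient — the maximum voxel probability within the
evaluation region — and thresholded at calibrated operating points to yield
a PI-RADS-equivalent category ("DL-PIRADS").  The default operating points
ship with the package: 0.033 -> category 2, 0.074 -> 3, 0.186 -> 4,
0.646 -> 5, with inclusive lower bounds.  Predictions below the lowest
cut-off fall into a sentinel category 1 ("below DL-PIRADS 2"), which the
calibration itself does not define.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProbabilityMap",
    "CalibrationTable",
    "PatientScore",
    "AgreementSummary",
    "default_calibration",
    "patient_prediction",
    "assign_dl_pirads",
    "agreement_table",
]

#: Calibrated operating points: probability cut-off -> DL-PIRADS category.
DEFAULT_CUT_OFFS: tuple[tuple[float, int], ...] = (
    (0.033, 2),
    (0.074, 3),
    (0.186, 4),
    (0.646, 5),
)

#: Sentinel category for predictions below the lowest cut-off.
FLOOR_CATEGORY = 1


@dataclass(frozen=True)
class ProbabilityMap:
    """3D voxelwise lesion probabilities, optionally restricted to a mask."""

    values: np.ndarray
    prostate_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"probability map must be 3D; got {values.ndim}D")
        if values.size and (np.nanmin(values) < 0 or np.nanmax(values) > 1):
            raise ValueError("probability values must lie in [0, 1]")
        object.__setattr__(self, "values", values)
        if self.prostate_mask is not None:
            mask = np.asarray(self.prostate_mask, dtype=bool)
            if mask.shape != values.shape:
                raise ValueError("prostate mask grid must match the map")
            object.__setattr__(self, "prostate_mask", mask)


@dataclass(frozen=True)
class CalibrationTable:
    """Ordered probability cut-offs mapping predictions to categories."""

    cut_offs: tuple[tuple[float, int], ...] = DEFAULT_CUT_OFFS
    floor_category: int = FLOOR_CATEGORY

    def __post_init__(self) -> None:
        cut_offs = tuple((float(t), int(c)) for t, c in self.cut_offs)
        thresholds = [t for t, _ in cut_offs]
        categories = [c for _, c in cut_offs]
        if not cut_offs:
            raise ValueError("calibration table needs at least one cut-off")
        if any(not 0 <= t <= 1 for t in thresholds):
            raise ValueError("thresholds must lie in [0, 1]")
        if np.any(np.diff(thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any(np.diff(categories) <= 0):
            raise ValueError("categories must be strictly increasing")
        if self.floor_category >= categories[0]:
            raise ValueError("floor category must lie below the first category")
        object.__setattr__(self, "cut_offs", cut_offs)


@dataclass(frozen=True)
class PatientScore:
    patient_id: str
    prediction: float
    dl_pirads: int
    visual_pirads: int | None = None

    @property
    def agreement(self) -> bool | None:
        if self.visual_pirads is None:
            return None
        return self.dl_pirads == self.visual_pirads


@dataclass(frozen=True)
class AgreementSummary:
    n_agree: int
    n_dl_lower: int
    n_dl_higher: int
    excluded: tuple[str, ...] = field(default=())

    @property
    def n_compared(self) -> int:
        return self.n_agree + self.n_dl_lower + self.n_dl_higher


def default_calibration() -> CalibrationTable:
    """The packaged calibration operating points."""
    return CalibrationTable()


def patient_prediction(prob_map: ProbabilityMap) -> float:
    """Patient-level scalar prediction: the maximum voxel probability.

    Evaluated within ``prostate_mask`` when one is attached to the map.
    """
    values = prob_map.values
    if prob_map.prostate_mask is not None:
        values = values[prob_map.prostate_mask]
    if values.size == 0:
        raise ValueError("empty evaluation region: no voxels to aggregate")
    return float(np.nanmax(values))


def assign_dl_pirads(prediction: float, table: CalibrationTable | None = None) -> int:
    """Category of the highest cut-off <= prediction (inclusive lower bound).

    A prediction exactly on a cut-off receives that cut-off's category;
    predictions below the lowest cut-off receive ``table.floor_category``.
    """
    if table is None:
        table = default_calibration()
    if not 0 <= prediction <= 1:
        raise ValueError(f"prediction {prediction!r} outside [0, 1]")
    category = table.floor_category
    for threshold, cat in table.cut_offs:
        if prediction >= threshold:
            category = cat
    return category


def agreement_table(scores: list[PatientScore]) -> AgreementSummary:
    """Counts of patients with equal, DL-lower and DL-higher categories.

    Patients without a visual score are excluded and listed by id.
    """
    n_agree = n_lower = n_higher = 0
    excluded: list[str] = []
    for score in scores:
        if score.visual_pirads is None:
            excluded.append(score.patient_id)
            continue
        diff = score.dl_pirads - score.visual_pirads
        if diff == 0:
            n_agree += 1
        elif diff < 0:
            n_lower += 1
        else:
            n_higher += 1
    return AgreementSummary(n_agree, n_lower, n_higher, tuple(excluded))
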