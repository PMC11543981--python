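"""Segmentation agreement (DICE) and cohort-level reporting.

The DICE coefficient ``2|A∩B| / (|A| + |B|)`` quantifies voxel overlap
between a manual and an automatic lesion segmentation.  Manual T2w and
manual ADC lesion masks are OR-combined ("union mask") before comparison
with the automatic mask.  Cohort reporting aggregates the per-patient DCE
features, contrast ratios, DL-PIRADS scores and DICE values, checks the
internal consistency of fitted maxima versus fMCR cells, and flags the
discrimination property (fMCR > 1 for every lesion-bearing patient).

The package ships two reference cohort tables as CSV fixtures
(:func:`load_table1`, :func:`load_table2`) used by the consistency checks
and the worked examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import PatientScore, agreement_table, assign_dl_pirads, default_calibration

__all__ = [
    "DiceResult",
    "dice",
    "union_mask",
    "load_table1",
    "load_table2",
    "fmcr_consistency",
    "mean_dice",
    "cohort_report",
]

#: fMCR pairs reported per patient, as (column prefix, numerator, denominator).
FMCR_PAIRS = (("tsl_nat", "tsl", "nat"), ("tsl_plt", "tsl", "plt"))


@dataclass(frozen=True)
class DiceResult:
    dice: float
    n_a: int
    n_b: int
    n_intersection: int
    both_empty: bool = False


def _as_bool(mask) -> np.ndarray:
    arr = np.asarray(getattr(mask, "values", mask))
    if arr.ndim != 3:
        raise ValueError(f"binary mask must be 3D; got {arr.ndim}D")
    return arr.astype(bool)


def dice(a, b) -> DiceResult:
    """DICE overlap of two binary masks on the same grid.

    Two empty masks are defined to have DICE 0 with ``both_empty`` set,
    avoiding the 0/0 division while still flagging the pathology.
    """
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    n_a, n_b = int(a.sum()), int(b.sum())
    n_int = int((a & b).sum())
    if n_a + n_b == 0:
        return DiceResult(0.0, 0, 0, 0, both_empty=True)
    return DiceResult(2.0 * n_int / (n_a + n_b), n_a, n_b, n_int)


def union_mask(masks: list) -> np.ndarray:
    """Voxelwise logical OR of one or more binary masks (order-independent)."""
    if not masks:
        raise ValueError("union_mask needs at least one mask")
    arrays = [_as_bool(m) for m in masks]
    shape = arrays[0].shape
    for arr in arrays[1:]:
        if arr.shape != shape:
            raise ValueError(f"mask grids differ: {shape} vs {arr.shape}")
    out = arrays[0].copy()
    for arr in arrays[1:]:
        out |= arr
    return out


def _load_fixture(name: str) -> pd.DataFrame:
    with resources.files("dcekit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Cohort score table: predictions, PI-RADS categories, DICE values."""
    return _load_fixture("table1.csv")


def load_table2() -> pd.DataFrame:
    """Cohort DCE feature table: slopes ratios, fitted maxima, fMCR."""
    return _load_fixture("table2.csv")


def fmcr_consistency(table2: pd.DataFrame, tol: float = 0.005) -> pd.DataFrame:
    """Recompute fMCR cells from printed fitted maxima and flag deviations.

    For each patient and tissue pair, the ratio of the reported fitted
    maxima is compared against the reported fMCR cell.  ``tol`` defaults to
    half a unit in the last printed decimal (0.005 at two decimals); cells
    deviating beyond it are flagged, never silently absorbed — deviations
    indicate the source table carried more internal precision than it
    prints.
    """
    rows = []
    for _, rec in table2.iterrows():
        for suffix, num, den in FMCR_PAIRS:
            recomputed = rec[f"fitted_max_{num}"] / rec[f"fitted_max_{den}"]
            printed = rec[f"fmcr_{suffix}"]
            rows.append(
                {
                    "patient_id": rec["patient_id"],
                    "pair": suffix.upper().replace("_", "/"),
                    "recomputed": recomputed,
                    "printed": printed,
                    "abs_deviation": abs(recomputed - printed),
                    "consistent": abs(recomputed - printed) <= tol,
                }
            )
    return pd.DataFrame(rows)


def mean_dice(dice_values) -> float:
    """Mean DICE over patients that have a value (missing entries excluded)."""
    values = pd.Series(dice_values, dtype=float).dropna()
    if values.empty:
        raise ValueError("no DICE values to average")
    return float(values.mean())


def cohort_report(
    table1: pd.DataFrame | None = None, table2: pd.DataFrame | None = None
) -> dict:
    """Cohort summary mirroring the reference score and feature tables.

    Returns a dict with the mean DICE (patients lacking an automatic
    segmentation excluded), visual-versus-DL agreement counts, recomputed
    DL-PIRADS categories, per-patient fMCR discrimination flags and the
    fitted-maximum/fMCR consistency table.
    """
    if table1 is None:
        table1 = load_table1()
    if table2 is None:
        table2 = load_table2()
    cal = default_calibration()
    scores = [
        PatientScore(
            patient_id=str(rec["patient_id"]),
            prediction=float(rec["prediction"]),
            dl_pirads=assign_dl_pirads(float(rec["prediction"]), cal),
            visual_pirads=int(rec["visual_pirads"])
            if pd.notna(rec["visual_pirads"])
            else None,
        )
        for _, rec in table1.iterrows()
    ]
    dl_matches_printed = all(
        s.dl_pirads == int(rec["dl_pirads"])
        for s, (_, rec) in zip(scores, table1.iterrows())
    )
    discrimination = {
        f"fmcr_{suffix}": bool((table2[f"fmcr_{suffix}"] > 1).all())
        for suffix, _, _ in FMCR_PAIRS
    }
    consistency = fmcr_consistency(table2)
    return {
        "n_patients": len(table1),
        "mean_dice": mean_dice(table1["dice"]),
        "n_dice": int(table1["dice"].notna().sum()),
        "agreement": agreement_table(scores),
        "scores": scores,
        "dl_matches_printed": dl_matches_printed,
        "discrimination": discrimination,
        "fmcr_consistency": consistency,
        "n_consistent_fmcr_cells": int(consistency["consistent"].sum()),
    }
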