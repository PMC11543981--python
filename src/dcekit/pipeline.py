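"""End-to-end per-patient analysis: curves -> features -> ratios -> scores.

Ties the stages together for one patient: extract and normalize the three
tissue curves, compute their semi-quantitative features and pairwise
contrast ratios, optionally assign a DL-PIRADS category from a probability
map, and optionally evaluate DICE agreement between the manual (T2w + ADC
union) and automatic lesion masks.  Any stage failure is re-raised naming
the stage and patient, so small-cohort analyses stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict

import numpy as np
import pandas as pd

from .calibration import ProbabilityMap, assign_dl_pirads, patient_prediction
from .config import PipelineConfig
from .evaluation import dice, union_mask
from .features import compute_features, contrast_ratios
from .tic import DCESeries, TissueMask, TISSUES, extract_curve, normalize_baseline

__all__ = ["PipelineError", "analyze_patient", "curves_to_frame", "features_to_frame"]

logger = logging.getLogger(__name__)

PAIRS = (("TSL", "NAT"), ("TSL", "PLT"), ("PLT", "NAT"))


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and patient id."""

    def __init__(self, stage: str, patient_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for patient {patient_id!r}: {cause}")
        self.stage = stage
        self.patient_id = patient_id


def analyze_patient(
    series: DCESeries,
    mask: TissueMask,
    config: PipelineConfig | None = None,
    prob_map: ProbabilityMap | None = None,
    manual_masks: list | None = None,
    auto_mask=None,
    visual_pirads: int | None = None,
    patient_id: str = "phantom",
) -> dict:
    """Run the full chain for one patient; returns a nested result dict."""
    if config is None:
        config = PipelineConfig()
    result: dict = {"patient_id": patient_id, "config": config.to_dict()}

    try:
        curves = {}
        for tissue in TISSUES:
            raw = extract_curve(series, mask, tissue)
            curves[tissue] = normalize_baseline(raw, config.baseline_frames)
        result["n_voxels"] = {t: c.n_voxels for t, c in curves.items()}
        logger.info("patient %s voxel counts: %s", patient_id, result["n_voxels"])
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError("tic_extraction", patient_id, exc) from exc

    try:
        feats = {
            t: compute_features(
                c,
                smooth_window=config.smooth_window,
                epsilon=config.plateau_epsilon,
            )
            for t, c in curves.items()
        }
        ratios = {pair: contrast_ratios(feats, pair) for pair in PAIRS}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("dce_features", patient_id, exc) from exc
    result["curves"] = curves
    result["features"] = feats
    result["ratios"] = ratios

    if prob_map is not None:
        try:
            pred = patient_prediction(prob_map)
            result["prediction"] = pred
            result["dl_pirads"] = assign_dl_pirads(pred, config.calibration)
            result["visual_pirads"] = visual_pirads
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("dl_calibration", patient_id, exc) from exc

    if manual_masks and auto_mask is not None:
        try:
            manual = union_mask(manual_masks)
            result["dice"] = dice(manual, auto_mask)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("evaluation", patient_id, exc) from exc

    return result


def curves_to_frame(curves: dict) -> pd.DataFrame:
    """Tidy long-format table: tissue, frame, time, value, n_voxels."""
    rows = []
    for tissue, curve in curves.items():
        for frame, (t, v) in enumerate(zip(curve.times, curve.values)):
            rows.append(
                {
                    "tissue": tissue,
                    "frame": frame,
                    "time": t,
                    "value": v,
                    "n_voxels": curve.n_voxels,
                }
            )
    return pd.DataFrame(rows)


def features_to_frame(result: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-tissue features and per-pair ratios as flat tables."""
    feat_rows = []
    for tissue, f in result["features"].items():
        row = asdict(f)
        row["fit_window_in"] = str(row["fit_window_in"])
        row["fit_window_out"] = str(row["fit_window_out"])
        feat_rows.append(row)
    ratio_rows = [
        {
            "pair": contrast.name,
            "wash_in_ratio": contrast.wash_in_ratio,
            "wash_out_ratio": contrast.wash_out_ratio,
            "fmcr": contrast.fmcr,
        }
        for contrast in result["ratios"].values()
    ]
    return pd.DataFrame(feat_rows), pd.DataFrame(ratio_rows)


def frame_to_curves(df: pd.DataFrame, baseline_frames: int = 2) -> dict:
    """Inverse of :func:`curves_to_frame`, for the CSV-based CLI stages."""
    from .tic import TimeIntensityCurve

    curves = {}
    for tissue, grp in df.groupby("tissue"):
        grp = grp.sort_values("frame")
        curves[str(tissue)] = TimeIntensityCurve(
            tissue=str(tissue),
            times=grp["time"].to_numpy(float),
            values=grp["value"].to_numpy(float),
            baseline_frames=baseline_frames,
            n_voxels=int(grp["n_voxels"].iloc[0]),
        )
    return curves


def plot_curves(curves: dict, features: dict | None = None, path=None):
    """Annotated time-intensity curve figure (wash-in/wash-out schematic)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"TSL": "tab:red", "PLT": "tab:orange", "NAT": "tab:green"}
    fig, ax = plt.subplots(figsize=(6, 4))
    for tissue, curve in curves.items():
        ax.plot(curve.times, curve.values, "o-", ms=3,
                color=colors.get(tissue, None), label=tissue)
        if features and tissue in features:
            f = features[tissue]
            t_peak = curve.times[0] + f.time_to_peak
            ax.plot([t_peak], [f.fitted_maximum], "*", ms=12,
                    color=colors.get(tissue, None))
    ax.set_xlabel("time")
    ax.set_ylabel("normalized intensity")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
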