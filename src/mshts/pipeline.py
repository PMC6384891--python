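"""End-to-end plumbing: quantify image sets, assemble dose-response curves
from a plate's SD table, fit every sample, and screen libraries.

These functions back the CLI but are the natural library entry points for
scripted analyses.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .doseresponse import (
    ControlFailureError,
    DoseResponseCurve,
    FitResult,
    InsufficientDataError,
    fit_ec50,
    screen_library,
)
from .plate import PlateLayout
from .quantify import Micrograph, ROISpec, read_micrograph, well_sd

logger = logging.getLogger(__name__)

__all__ = [
    "quantify_images",
    "quantify_directory",
    "build_curves",
    "fit_plate",
    "results_table",
    "screen_to_files",
]

_IMAGE_RE = re.compile(r"(?P<plate>.+)_(?P<well>[A-Z]{1,2}\d{1,2})_(?P<tp>t0|t24)\.tiff?$")


def quantify_images(
    images: dict[tuple[str, str], Micrograph],
    config: RunConfig = RunConfig(),
    plate_id: str = "plate1",
) -> pd.DataFrame:
    """SD table for an in-memory image set keyed by (well_name, timepoint)."""
    acq = config.acquisition
    rows = []
    for (well, tp), micro in sorted(images.items()):
        res = well_sd(micro, ROISpec(acq.roi_size), acq.target_fraction, acq.qc,
                      well=well, timepoint=tp)
        rows.append({
            "plate_id": plate_id, "well": well, "timepoint": tp,
            "sd_value": res.sd_value, "mean_fraction": res.qc.mean_fraction,
            "saturated_fraction": res.qc.saturated_fraction,
            "verdict": res.qc.verdict,
        })
    return pd.DataFrame(rows)


def quantify_directory(image_dir: str | Path, config: RunConfig = RunConfig()) -> pd.DataFrame:
    """SD table for every ``{plate}_{well}_{t0|t24}.tif`` in a directory.

    Non-TIFF files and files not matching the naming convention are skipped
    with a log line.
    """
    image_dir = Path(image_dir)
    rows = []
    acq = config.acquisition
    for path in sorted(image_dir.iterdir()):
        m = _IMAGE_RE.match(path.name)
        if not m:
            if path.suffix.lower() in (".tif", ".tiff"):
                logger.warning("skipping unrecognised image name: %s", path.name)
            elif path.is_file() and path.name not in ("truth.csv", "manifest.json"):
                logger.info("skipping non-TIFF file: %s", path.name)
            continue
        micro = read_micrograph(path, channel=acq.channel)
        res = well_sd(micro, ROISpec(acq.roi_size), acq.target_fraction, acq.qc,
                      well=m["well"], timepoint=m["tp"])
        rows.append({
            "plate_id": m["plate"], "well": m["well"], "timepoint": m["tp"],
            "sd_value": res.sd_value, "mean_fraction": res.qc.mean_fraction,
            "saturated_fraction": res.qc.saturated_fraction,
            "verdict": res.qc.verdict,
        })
    return pd.DataFrame(rows)


def _control_sds(sd_df: pd.DataFrame, layout: PlateLayout) -> tuple[float, float]:
    """(sd_pos, sd_neg): mean no-inhibitor 24 h SD and mean 0 h SD of the
    same control wells."""
    controls = {a.name for a in layout.control_wells("positive_control_no_inhibitor")}
    if not controls:
        raise ControlFailureError("layout has no no-inhibitor control wells")
    sub = sd_df[sd_df["well"].isin(controls)]
    pos = sub.loc[sub["timepoint"] == "t24", "sd_value"]
    neg = sub.loc[sub["timepoint"] == "t0", "sd_value"]
    if pos.empty or neg.empty:
        raise ControlFailureError("missing control images for 0 h or 24 h")
    return float(pos.mean()), float(neg.mean())


def build_curves(
    sd_df: pd.DataFrame, layout: PlateLayout, unit: str = "uM"
) -> dict[str, DoseResponseCurve]:
    """Assemble one dose-response curve per test sample from the SD table."""
    sd_pos, sd_neg = _control_sds(sd_df, layout)
    t24 = sd_df[sd_df["timepoint"] == "t24"].set_index("well")
    curves: dict[str, DoseResponseCurve] = {}
    for sample_id in layout.sample_ids():
        points = []
        for addr, a in layout.wells_for_sample(sample_id):
            if addr.name not in t24.index:
                logger.warning("sample %s: no 24 h image for well %s",
                               sample_id, addr.name)
                continue
            row = t24.loc[addr.name]
            points.append((a.final_conc, float(row["sd_value"]), str(row["verdict"])))
        curves[sample_id] = DoseResponseCurve(
            sample_id=sample_id, points=points, sd_pos=sd_pos, sd_neg=sd_neg,
            unit=unit,
        )
    return curves


def fit_plate(
    sd_df: pd.DataFrame, layout: PlateLayout, config: RunConfig = RunConfig()
) -> list[FitResult]:
    """Fit EC50 for every test sample on a plate; samples whose curves cannot
    be fitted are carried through with a failure status rather than dropped."""
    fit_cfg = config.fitting
    results: list[FitResult] = []
    try:
        curves = build_curves(sd_df, layout)
    except ControlFailureError as exc:
        logger.warning("plate %s: %s", layout.plate_id, exc)
        return [
            FitResult(sample_id=sid, ec50=None, hill=np.nan, top=np.nan,
                      bottom=np.nan, rmse=np.nan, method=fit_cfg.method,
                      status="control_failure")
            for sid in layout.sample_ids()
        ]
    for sample_id, curve in curves.items():
        try:
            results.append(
                fit_ec50(curve, method=fit_cfg.method,
                         exclude_flagged=fit_cfg.exclude_flagged,
                         free_asymptotes=fit_cfg.free_asymptotes)
            )
        except InsufficientDataError as exc:
            logger.warning("%s", exc)
            results.append(
                FitResult(sample_id=sample_id, ec50=None, hill=np.nan,
                          top=np.nan, bottom=np.nan, rmse=np.nan,
                          method=fit_cfg.method, status="insufficient_data")
            )
    return results


def results_table(fits: list[FitResult]) -> pd.DataFrame:
    """Flatten fit results into the results-CSV schema."""
    return pd.DataFrame([
        {
            "sample_id": f.sample_id, "n_points": f.n_points, "method": f.method,
            "status": f.status, "ec50": f.ec50 if f.ec50 is not None else np.nan,
            "unit": f.unit, "hill": f.hill, "rmse": f.rmse,
        }
        for f in fits
    ])


def screen_to_files(
    fit_table: pd.DataFrame,
    out_dir: str | Path,
    domain: str = "extract",
    group_labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Rank + tier a fit table and write results.csv / summary.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranked, counts, group_fraction = screen_library(fit_table, group_labels, domain)
    ranked.to_csv(out / "results.csv", index=False)
    summary = {"tier_counts": counts, "group_high_activity_fraction": group_fraction,
               "n_samples": int(len(ranked))}
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return ranked, summary
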