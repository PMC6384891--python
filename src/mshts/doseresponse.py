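"""EC50 estimation from SD-vs-concentration series, activity tiers, and
library-level screening summaries.

The per-well SD values are first converted to percent inhibition against the
plate's own controls (no-inhibitor 24 h SD = 0% inhibition, 0 h background
SD = 100%), which makes plates with different absolute SD scales directly
comparable. EC50 is then the concentration at half-maximal inhibition,
estimated by a four-parameter logistic (4PL) fit in log-concentration with
the asymptotes fixed at 0 and 100 by default, or by monotone log-linear
interpolation of the 50% crossing.

Activity tiers for plant extracts follow the screening convention
(EC50 <= 0.018 mg/ml high / red; 0.018–0.05 yellow; 0.05–0.1 listed; else
inactive); single-compound screens use a 200 µM cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseCurve",
    "FitResult",
    "ReplicateSummary",
    "ControlFailureError",
    "InsufficientDataError",
    "EXTRACT_TIERS",
    "COMPOUND_CUT",
    "percent_inhibition",
    "fit_ec50",
    "four_pl",
    "classify_activity",
    "summarize_replicates",
    "screen_library",
    "tier_counts",
]

#: extract tier boundaries in mg/ml: (high_red, active_yellow, listed)
EXTRACT_TIERS = (0.018, 0.05, 0.1)
#: compound-screen activity cut in µM
COMPOUND_CUT = 200.0


class ControlFailureError(ValueError):
    """Plate controls are unusable (positive-control SD <= background SD)."""


class InsufficientDataError(ValueError):
    """Fewer than three usable dose-response points."""


@dataclass
class DoseResponseCurve:
    """One sample's SD readings across its dilution series plus the plate
    controls used for percent-inhibition normalization."""

    sample_id: str
    points: list[tuple[float, float, str]]  # (final_conc, sd_value, qc_verdict)
    sd_pos: float  # no-inhibitor 24 h control SD
    sd_neg: float  # 0 h / background control SD
    unit: str = "uM"

    def usable_points(self, exclude_flagged: bool = True) -> np.ndarray:
        """(conc, sd) pairs, QC-flagged wells dropped by default."""
        pts = [
            (c, sd)
            for c, sd, verdict in self.points
            if (verdict == "pass" or not exclude_flagged) and c > 0
        ]
        return np.asarray(sorted(pts), dtype=np.float64).reshape(-1, 2)


@dataclass(frozen=True)
class FitResult:
    sample_id: str
    ec50: float | None
    hill: float
    top: float
    bottom: float
    rmse: float
    method: str  # fourPL | interpolation
    status: str  # determinable | below_range | above_range | not_active | control_failure
    n_points: int = 0
    unit: str = "uM"

    @property
    def determinable(self) -> bool:
        return self.status == "determinable"


@dataclass(frozen=True)
class ReplicateSummary:
    n: int
    mean_ec50: float
    sd_ec50: float  # sample SD (ddof=1); NaN when n == 1


def percent_inhibition(sd: float, sd_pos: float, sd_neg: float):
    """Percent inhibition of aggregation relative to plate controls.

    100 * (sd_pos - sd) / (sd_pos - sd_neg); 0% at the no-inhibitor control,
    100% at the 0 h background. Not clipped: noisy wells may fall outside
    [0, 100].
    """
    if sd_pos <= sd_neg:
        raise ControlFailureError(
            f"positive-control SD ({sd_pos}) must exceed background SD ({sd_neg})"
        )
    return 100.0 * (sd_pos - np.asarray(sd, dtype=np.float64)) / (sd_pos - sd_neg)


def four_pl(conc, ec50: float, hill: float, bottom: float = 0.0, top: float = 100.0):
    """Four-parameter logistic inhibition curve, rising with concentration."""
    conc = np.asarray(conc, dtype=np.float64)
    return bottom + (top - bottom) * conc**hill / (ec50**hill + conc**hill)


def _interpolate_crossing(log_c: np.ndarray, y: np.ndarray) -> float | None:
    """First 50% crossing of the (log conc, inhibition) polyline, scanning
    from low to high concentration; None when the curve never crosses."""
    for i in range(len(y) - 1):
        y0, y1 = y[i], y[i + 1]
        if (y0 - 50.0) * (y1 - 50.0) <= 0 and y0 != y1:
            frac = (50.0 - y0) / (y1 - y0)
            return float(log_c[i] + frac * (log_c[i + 1] - log_c[i]))
        if y0 == 50.0:
            return float(log_c[i])
    return None


def _fit_four_pl(
    log_c: np.ndarray, y: np.ndarray, free_asymptotes: bool
) -> tuple[float, float, float, float, float]:
    """Least-squares 4PL in log10-concentration; returns
    (log_ec50, hill, bottom, top, rmse). Raises RuntimeError on failure."""
    guess_log_e = _interpolate_crossing(log_c, y)
    if guess_log_e is None:
        guess_log_e = float(np.median(log_c))

    if free_asymptotes:
        def resid(p):
            return four_pl(10.0**log_c, 10.0 ** p[0], p[1], p[2], p[3]) - y
        x0 = [guess_log_e, 1.0, 0.0, 100.0]
        lb = [log_c.min() - 6, 0.05, -50.0, 50.0]
        ub = [log_c.max() + 6, 20.0, 50.0, 200.0]
    else:
        def resid(p):
            return four_pl(10.0**log_c, 10.0 ** p[0], p[1]) - y
        x0 = [guess_log_e, 1.0]
        lb = [log_c.min() - 6, 0.05]
        ub = [log_c.max() + 6, 20.0]

    sol = least_squares(resid, x0, bounds=(lb, ub), method="trf")
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise RuntimeError("4PL fit did not converge")
    rmse = float(np.sqrt(np.mean(sol.fun**2)))
    if free_asymptotes:
        log_e, hill, bottom, top = sol.x
    else:
        (log_e, hill), bottom, top = sol.x, 0.0, 100.0
    return float(log_e), float(hill), float(bottom), float(top), rmse


def fit_ec50(
    curve: DoseResponseCurve,
    method: str = "fourPL",
    exclude_flagged: bool = True,
    free_asymptotes: bool = False,
) -> FitResult:
    """Estimate EC50 from one dose-response curve.

    ``fourPL`` performs a least-squares logistic fit of percent inhibition vs
    log10 concentration (asymptotes fixed at 0/100 unless ``free_asymptotes``);
    ``interpolation`` takes the monotone log-linear 50% crossing. Status is
    ``not_active`` when inhibition never reaches 50% over the tested range,
    ``below_range``/``above_range`` when the crossing falls outside it; EC50 is
    reported only when ``determinable``.
    """
    if method not in ("fourPL", "interpolation"):
        raise ValueError(f"unknown method {method!r}")
    pts = curve.usable_points(exclude_flagged)
    if len(pts) < 3:
        raise InsufficientDataError(
            f"sample {curve.sample_id}: {len(pts)} usable points (need >= 3)"
        )
    conc, sd = pts[:, 0], pts[:, 1]
    y = percent_inhibition(sd, curve.sd_pos, curve.sd_neg)
    log_c = np.log10(conc)
    n = len(pts)

    def result(ec50, hill, bottom, top, rmse, used_method, status):
        return FitResult(
            sample_id=curve.sample_id, ec50=ec50, hill=hill, top=top,
            bottom=bottom, rmse=rmse, method=used_method, status=status,
            n_points=n, unit=curve.unit,
        )

    if float(np.max(y)) < 50.0:
        return result(None, np.nan, 0.0, 100.0, np.nan, method, "not_active")

    if method == "fourPL":
        try:
            log_e, hill, bottom, top, rmse = _fit_four_pl(log_c, y, free_asymptotes)
            used = "fourPL"
        except RuntimeError as exc:
            logger.warning("sample %s: %s; falling back to interpolation",
                           curve.sample_id, exc)
            method = "interpolation"

    if method == "interpolation":
        log_e = _interpolate_crossing(log_c, y)
        hill, bottom, top = np.nan, 0.0, 100.0
        rmse = np.nan
        used = "interpolation"
        if log_e is None:
            # reaches 50% only via non-monotone noise; treat crossing at the
            # lowest concentration whose inhibition exceeds 50%
            above = log_c[y >= 50.0]
            log_e = float(above.min()) if above.size else None
        if log_e is None:
            return result(None, np.nan, 0.0, 100.0, np.nan, used, "not_active")

    ec50 = 10.0**log_e
    if ec50 < conc.min() * (1 - 1e-9):
        return result(None, hill, bottom, top, rmse, used, "below_range")
    if ec50 > conc.max() * (1 + 1e-9):
        return result(None, hill, bottom, top, rmse, used, "above_range")
    return result(float(ec50), hill, bottom, top, rmse, used, "determinable")


def classify_activity(fit: FitResult | float | None, domain: str = "extract") -> str:
    """Map an EC50 (or FitResult) to its activity tier.

    Extracts: <=0.018 mg/ml -> high_red; (0.018, 0.05] -> active_yellow;
    (0.05, 0.1] -> listed; otherwise (or not determinable) -> inactive.
    Compounds: <=200 µM -> active, else inactive. Boundaries are closed on the
    more-active side.
    """
    if isinstance(fit, FitResult):
        ec50 = fit.ec50 if fit.determinable else None
    else:
        ec50 = fit
    if ec50 is not None and (np.isnan(ec50) or ec50 <= 0):
        ec50 = None

    if domain == "extract":
        t_red, t_yellow, t_listed = EXTRACT_TIERS
        if ec50 is None:
            return "inactive"
        if ec50 <= t_red:
            return "high_red"
        if ec50 <= t_yellow:
            return "active_yellow"
        if ec50 <= t_listed:
            return "listed"
        return "inactive"
    if domain == "compound":
        return "active" if ec50 is not None and ec50 <= COMPOUND_CUT else "inactive"
    raise ValueError(f"unknown domain {domain!r}")


def summarize_replicates(ec50_list) -> ReplicateSummary:
    """Arithmetic mean and sample SD (ddof=1) of replicate EC50 estimates."""
    arr = np.asarray(list(ec50_list), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty replicate list")
    if np.any(~np.isfinite(arr)):
        raise ValueError("all replicate EC50s must be finite (determinable)")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else float("nan")
    return ReplicateSummary(n=int(arr.size), mean_ec50=float(arr.mean()), sd_ec50=sd)


def tier_counts(ec50_values, domain: str = "extract") -> dict[str, int]:
    """Count samples in each activity tier of a per-sample EC50 table."""
    tiers = [classify_activity(None if v is None or not np.isfinite(v) else float(v),
                               domain)
             for v in ec50_values]
    order = (
        ("high_red", "active_yellow", "listed", "inactive")
        if domain == "extract" else ("active", "inactive")
    )
    return {t: sum(x == t for x in tiers) for t in order}


def screen_library(
    fit_table: pd.DataFrame, group_labels: dict[str, str] | None = None,
    domain: str = "extract",
) -> tuple[pd.DataFrame, dict[str, int], dict[str, float]]:
    """Rank a screened library and summarise tiers and group activity.

    ``fit_table`` needs columns ``sample_id``, ``ec50``, ``status`` (extra
    columns pass through). Samples are ranked by ascending EC50 with
    non-determinable samples last; ties break lexicographically on sample_id.
    Returns (ranked table with ``tier``/``rank`` columns, tier counts,
    per-group highly-active fraction).
    """
    df = fit_table.copy()
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id(s): {dups}")
    determinable = df["status"].eq("determinable") & df["ec50"].notna()
    df["tier"] = [
        classify_activity(float(e) if ok else None, domain)
        for e, ok in zip(df["ec50"], determinable)
    ]
    sort_key = np.where(determinable, df["ec50"].astype(float), np.inf)
    df = (
        df.assign(_key=sort_key)
        .sort_values(["_key", "sample_id"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    df["rank"] = np.arange(1, len(df) + 1)

    counts = tier_counts(
        [e if ok else None for e, ok in zip(df["ec50"], determinable)], domain
    )
    top_tier = "high_red" if domain == "extract" else "active"
    group_fraction: dict[str, float] = {}
    if group_labels is not None:
        df["group"] = df["sample_id"].map(group_labels)
    if "group" in df.columns:
        for grp, sub in df.groupby("group", dropna=True):
            group_fraction[str(grp)] = float((sub["tier"] == top_tier).mean())
    return df, counts, group_fraction
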