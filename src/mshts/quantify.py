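"""Micrograph -> QC-gated SD value.

The assay's readout for aggregate amount is the population standard deviation
of per-pixel brightness in a centered 432 x 432 pixel region (800 x 800 µm at
4x), computed after the acquisition macro has rescaled the frame so its mean
intensity sits at 50% of the camera full scale. Frames that are over- or
under-exposed, or whose brightness histogram is far from normal, are flagged:
the SD of a saturated or empty frame no longer tracks aggregate amount.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "Micrograph",
    "ROISpec",
    "QCThresholds",
    "QCReport",
    "SDResult",
    "NormalizationError",
    "read_micrograph",
    "normalize_intensity",
    "extract_center_roi",
    "compute_sd",
    "qc_image",
    "well_sd",
    "percent_sd_trace",
]


class NormalizationError(ValueError):
    """Raised for frames that cannot be normalized (e.g. all-zero rasters)."""


@dataclass
class Micrograph:
    """Single-channel intensity raster with acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 16
    exposure_ms: float | None = None
    gain: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2D raster")
        if self.pixels.max(initial=0) > self.full_scale:
            raise ValueError(f"pixel values exceed {self.bit_depth}-bit full scale")
        if self.pixels.min(initial=0) < 0:
            raise ValueError("pixel values must be non-negative")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class ROISpec:
    """Centered square analysis region; default 432 px = 800 µm at 4x."""

    size: int = 432

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("ROI size must be positive")


@dataclass(frozen=True)
class QCThresholds:
    sat_max: float = 0.01
    bright_max: float = 0.85
    dark_min: float = 0.05
    skew_max: float = 1.0
    kurt_max: float = 2.0
    clip_max: float = 0.005


@dataclass(frozen=True)
class QCReport:
    mean_fraction: float
    saturated_fraction: float
    dark_fraction: float
    skewness: float
    excess_kurtosis: float
    verdict: str  # pass | fail_bright | fail_dark | fail_nonnormal

    @property
    def passed(self) -> bool:
        return self.verdict == "pass"


@dataclass(frozen=True)
class SDResult:
    sd_value: float
    qc: QCReport
    well: str | None = None
    timepoint: str | None = None


def read_micrograph(path: str | Path, channel: str = "luminance") -> Micrograph:
    """Read an 8/16-bit single-channel or RGB TIFF.

    RGB frames (the original system used a color CCD) are reduced to one
    channel: ``luminance`` averages the channels; ``r``/``g``/``b`` select one.
    """
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 3:
        if channel == "luminance":
            arr = np.rint(arr.mean(axis=-1))
        elif channel in ("r", "g", "b"):
            arr = arr[..., "rgb".index(channel)]
        else:
            raise ValueError(f"unknown channel {channel!r}")
    bit_depth = 16 if arr.dtype.itemsize > 1 else 8
    return Micrograph(pixels=arr.astype(np.uint16 if bit_depth == 16 else np.uint8),
                      bit_depth=bit_depth)


def normalize_intensity(image: Micrograph, target_fraction: float = 0.5) -> Micrograph:
    """Rescale so the mean intensity equals ``target_fraction`` of full scale.

    Emulates the acquisition macro that adjusts every frame to 50% mean
    intensity before analysis, which makes the downstream SD insensitive to
    exposure-time and camera-gain differences. The fraction of pixels clipped
    at full scale is recorded in ``meta['norm_clipped_fraction']``.
    """
    if not (0 < target_fraction < 1):
        raise ValueError("target_fraction must be in (0, 1)")
    mean = float(image.pixels.mean())
    if mean <= 0:
        raise NormalizationError("all-zero image: empty or failed acquisition")
    scale = target_fraction * image.full_scale / mean
    scaled = image.pixels.astype(np.float64) * scale
    clipped_fraction = float((scaled > image.full_scale).mean())
    pixels = np.clip(np.rint(scaled), 0, image.full_scale).astype(image.pixels.dtype)
    meta = dict(image.meta)
    meta["norm_clipped_fraction"] = clipped_fraction
    return Micrograph(pixels=pixels, bit_depth=image.bit_depth,
                      exposure_ms=image.exposure_ms, gain=image.gain, meta=meta)


def extract_center_roi(image: Micrograph, roi: ROISpec | int = ROISpec()) -> Micrograph:
    """Crop the centered square ROI; odd margins drop the extra pixel from the
    high-index side (floor offsets)."""
    if isinstance(roi, int):
        roi = ROISpec(roi)
    h, w = image.shape
    if roi.size > h or roi.size > w:
        raise ValueError(f"ROI size {roi.size} exceeds image dims {image.shape}")
    r0 = (h - roi.size) // 2
    c0 = (w - roi.size) // 2
    return Micrograph(
        pixels=image.pixels[r0 : r0 + roi.size, c0 : c0 + roi.size],
        bit_depth=image.bit_depth, exposure_ms=image.exposure_ms,
        gain=image.gain, meta=dict(image.meta),
    )


def compute_sd(image: Micrograph | np.ndarray) -> float:
    """Population standard deviation (divisor N) of all pixel intensities."""
    pixels = image.pixels if isinstance(image, Micrograph) else np.asarray(image)
    if pixels.size == 0:
        raise ValueError("empty raster")
    return float(np.std(pixels.astype(np.float64), ddof=0))


def qc_image(image: Micrograph, thresholds: QCThresholds = QCThresholds()) -> QCReport:
    """Exposure and histogram-normality quality control.

    Over-exposure (saturated pixels or very high mean) and under-exposure are
    failed first; otherwise the brightness histogram must be near-normal,
    enforced as moment bounds on skewness and excess kurtosis.
    """
    px = image.pixels.astype(np.float64).ravel()
    full = image.full_scale
    mean_fraction = float(px.mean() / full)
    saturated_fraction = float((image.pixels == full).mean())
    dark_fraction = float((image.pixels == 0).mean())
    if px.std() == 0:
        skewness, kurt = 0.0, 0.0
    else:
        skewness = float(stats.skew(px))
        kurt = float(stats.kurtosis(px))  # Fisher: excess kurtosis

    if saturated_fraction > thresholds.sat_max or mean_fraction > thresholds.bright_max:
        verdict = "fail_bright"
    elif mean_fraction < thresholds.dark_min:
        verdict = "fail_dark"
    elif abs(skewness) > thresholds.skew_max or abs(kurt) > thresholds.kurt_max:
        verdict = "fail_nonnormal"
    else:
        verdict = "pass"
    return QCReport(mean_fraction, saturated_fraction, dark_fraction,
                    skewness, kurt, verdict)


def well_sd(
    image: Micrograph,
    roi: ROISpec | int = ROISpec(),
    target_fraction: float = 0.5,
    thresholds: QCThresholds = QCThresholds(),
    well: str | None = None,
    timepoint: str | None = None,
) -> SDResult:
    """Full per-well pipeline: normalize -> crop ROI -> QC -> SD.

    Exposure metrics (mean/saturated/dark fractions) are taken from the raw
    frame — normalization would otherwise hide over/under-exposure — while the
    normality moments are taken from the normalized ROI actually analysed. A
    QC failure does not null the SD: the value is reported with the verdict
    attached, and downstream fitting excludes flagged wells by default.
    """
    raw_qc = qc_image(image, thresholds)
    normalized = normalize_intensity(image, target_fraction)
    cropped = extract_center_roi(normalized, roi)
    norm_qc = qc_image(cropped, thresholds)

    if raw_qc.verdict in ("fail_bright", "fail_dark"):
        verdict = raw_qc.verdict
    elif cropped.meta.get("norm_clipped_fraction", 0.0) > thresholds.clip_max:
        verdict = "fail_bright"
    elif norm_qc.verdict == "fail_nonnormal":
        verdict = "fail_nonnormal"
    else:
        verdict = "pass"
    qc = QCReport(
        mean_fraction=raw_qc.mean_fraction,
        saturated_fraction=raw_qc.saturated_fraction,
        dark_fraction=raw_qc.dark_fraction,
        skewness=norm_qc.skewness,
        excess_kurtosis=norm_qc.excess_kurtosis,
        verdict=verdict,
    )
    return SDResult(sd_value=compute_sd(cropped), qc=qc, well=well, timepoint=timepoint)


def percent_sd_trace(sd_series) -> np.ndarray:
    """Normalize an SD time series to percent of its maximum (max -> 100)."""
    arr = np.asarray(sd_series, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty series")
    peak = arr.max()
    if peak <= 0:
        raise ValueError("series maximum must be positive")
    return arr * 100.0 / peak
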