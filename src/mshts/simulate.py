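"""Forward model for quantum-dot-labelled aggregate micrographs.

The assay images QD-nanoprobe fluorescence of amyloid aggregates in 1536-well
plates; the amount of aggregate in a well is read out downstream as the
per-pixel brightness SD of the micrograph. This module generates seeded
synthetic micrographs with a known ground-truth "aggregate load" so the whole
analysis chain can be exercised and validated without a microscope.

Generative model
----------------
A single scalar load in [0, ~1.2] controls the image:

* ``round(load * filament_scale)`` filamentous aggregates are drawn as
  persistent random-walk polylines of bright intensity on a uniform
  background,
* the frame is convolved with a Gaussian PSF; when the load exceeds
  ``dof_load_threshold`` the aggregates grow thicker than the depth of focus,
  so only a ``threshold/load`` fraction of each filament's mass stays in
  sharp focus while the excess becomes heavily defocused haze — light is
  conserved but contrast collapses, reproducing the rise-then-fall of SD
  versus amyloid concentration,
* zero-mean read noise is added and the frame is quantised to the camera bit
  depth.

Inhibition follows a Hill law with a known true EC50, and aggregation
kinetics follow a lag-then-saturating rise, with protein-specific lag time
(amyloid-beta shows a lag of a few hours; the tau fragment aggregates with
essentially no lag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line

from .plate import PlateLayout, WellAddress
from .quantify import Micrograph

__all__ = [
    "SimulationParams",
    "InhibitionModel",
    "KineticModel",
    "GroundTruthRecord",
    "inhibited_load",
    "kinetic_load",
    "render_micrograph",
    "simulate_well_pair",
    "simulate_plate",
    "well_seed",
]


@dataclass(frozen=True)
class SimulationParams:
    """Acquisition + rendering parameters for synthetic micrographs.

    Geometry defaults to the analysis ROI: 432 x 432 pixels covering
    800 x 800 µm (1.852 µm/pixel). Intensity parameters are fractions of the
    camera full scale.
    """

    image_size: tuple[int, int] = (432, 432)
    pixel_size: float = 800.0 / 432.0
    bit_depth: int = 16
    background_level: float = 0.30
    noise_sd: float = 0.015
    filament_scale: int = 220
    filament_amplitude: float = 0.16
    filament_step_length: float = 4.0
    filament_n_steps: int = 60
    psf_sigma: float = 2.0
    # Filament brightness grows with load (aggregates thicken as well as
    # multiply); the sqrt((load+offset)/(1+offset)) amplitude law is
    # calibrated so the image SD is approximately affine in load below the
    # depth-of-focus threshold — the regime in which the assay reads SD as a
    # proxy for aggregate amount.
    amplitude_load_offset: float = 0.7
    dof_load_threshold: float = 1.0
    dof_blur_gain: float = 30.0
    gain: float = 1.0
    gain_noise_coeff: float = 0.0
    poisson_noise: bool = False

    def __post_init__(self) -> None:
        if min(self.image_size) < 8:
            raise ValueError("image_size too small")
        if not (0 < self.background_level < 1):
            raise ValueError("background_level must be in (0, 1)")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be non-negative")
        if self.filament_scale < 1 or self.filament_n_steps < 1:
            raise ValueError("filament parameters must be positive")
        if self.dof_load_threshold <= 0 or self.dof_blur_gain < 0:
            raise ValueError("depth-of-focus parameters must be positive")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError("bit_depth must be 8, 12 or 16")


@dataclass(frozen=True)
class InhibitionModel:
    """Hill-type inhibition with a known half-maximal concentration."""

    ec50_true: float
    hill: float = 1.0
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.ec50_true <= 0:
            raise ValueError("ec50_true must be positive")
        if self.hill <= 0:
            raise ValueError("hill must be positive")


@dataclass(frozen=True)
class KineticModel:
    """Lag-phase aggregation kinetics: flat until ``lag_time``, then a
    saturating rise at ``rate`` (1/h) toward ``plateau_load``."""

    lag_time: float = 4.0
    rate: float = 0.5
    plateau_load: float = 1.0

    def __post_init__(self) -> None:
        if self.lag_time < 0:
            raise ValueError("lag_time must be >= 0")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if not (0 < self.plateau_load <= 1.2):
            raise ValueError("plateau_load must be in (0, 1.2]")


@dataclass(frozen=True)
class GroundTruthRecord:
    well: WellAddress | None
    sample_id: str
    load: float
    concentration: float
    timepoint: float
    seed: int


def inhibited_load(conc: float, model: InhibitionModel) -> float:
    """Remaining aggregate load at inhibitor concentration ``conc``.

    load = ec50^h / (ec50^h + conc^h): 1 with no inhibitor, exactly 0.5 at
    the true EC50, strictly decreasing in concentration.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if conc == 0:
        return 1.0
    e, h = model.ec50_true, model.hill
    return float(e**h / (e**h + conc**h))


def kinetic_load(t: float, model: KineticModel) -> float:
    """Aggregate load at time ``t`` hours: 0 through the lag phase, then a
    continuous monotone rise to the plateau."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t <= model.lag_time:
        return 0.0
    return float(model.plateau_load * (1.0 - np.exp(-model.rate * (t - model.lag_time))))


def well_seed(master_seed: int, row: int, col: int, timepoint_tag: int = 0) -> int:
    """Deterministic per-well seed mixed from (master_seed, row, col, tag).

    Uses numpy's SeedSequence entropy spawning so any single well can be
    re-rendered in isolation; returned value fits in 31 bits.
    """
    ss = np.random.SeedSequence([int(master_seed), int(row), int(col), int(timepoint_tag)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def _draw_filaments(
    canvas: np.ndarray,
    n_filaments: int,
    params: SimulationParams,
    rng: np.random.Generator,
    amp_scale: float = 1.0,
) -> None:
    """Additively draw persistent random-walk polylines onto ``canvas``."""
    h, w = canvas.shape
    for _ in range(n_filaments):
        r = rng.uniform(0, h - 1)
        c = rng.uniform(0, w - 1)
        theta = rng.uniform(0, 2 * np.pi)
        amp = amp_scale * params.filament_amplitude * rng.uniform(0.6, 1.0)
        for _ in range(params.filament_n_steps):
            theta += rng.normal(0.0, 0.35)  # persistence: small angular diffusion
            r2 = r + params.filament_step_length * np.sin(theta)
            c2 = c + params.filament_step_length * np.cos(theta)
            # reflect at the borders so mass does not pile up along the edges
            if r2 < 0 or r2 > h - 1:
                theta = -theta
                r2 = np.clip(-r2 if r2 < 0 else 2 * (h - 1) - r2, 0, h - 1)
            if c2 < 0 or c2 > w - 1:
                theta = np.pi - theta
                c2 = np.clip(-c2 if c2 < 0 else 2 * (w - 1) - c2, 0, w - 1)
            rr, cc = _draw_line(
                int(round(r)), int(round(c)), int(round(r2)), int(round(c2))
            )
            canvas[rr, cc] += amp
            r, c = r2, c2


def render_micrograph(
    load: float,
    params: SimulationParams | None = None,
    seed: int = 0,
    timepoint: float = 24.0,
) -> tuple[Micrograph, GroundTruthRecord]:
    """Render one synthetic micrograph at the given aggregate load.

    Deterministic per (load, params, seed): identical calls return
    bit-identical rasters.
    """
    if load < 0:
        raise ValueError("load must be non-negative")
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)

    canvas = np.zeros(params.image_size, dtype=np.float64)
    n_filaments = int(round(load * params.filament_scale))
    if n_filaments:
        # thickening law: per-filament brightness grows with total load so
        # that the image SD tracks load approximately linearly (see
        # SimulationParams.amplitude_load_offset)
        off = params.amplitude_load_offset
        amp_scale = float(np.sqrt((load + off) / (1.0 + off)))
        _draw_filaments(canvas, n_filaments, params, rng, amp_scale)

    # Depth-of-focus model: aggregate mass within the focal slab images
    # sharply; once the load exceeds dof_load_threshold the aggregates grow
    # thicker than the depth of focus, so only a thr/load fraction of each
    # filament's mass stays in focus while the excess contributes a heavily
    # defocused haze. Total emitted light is conserved, so contrast (not
    # brightness) collapses — SD stops tracking aggregate amount.
    thr = params.dof_load_threshold
    if load <= thr or n_filaments == 0:
        img = ndimage.gaussian_filter(canvas, params.psf_sigma, mode="wrap")
    else:
        in_focus = thr / load
        haze_sigma = params.psf_sigma + params.dof_blur_gain * (load - thr)
        img = ndimage.gaussian_filter(canvas * in_focus, params.psf_sigma, mode="wrap")
        img += ndimage.gaussian_filter(canvas * (1.0 - in_focus), haze_sigma, mode="wrap")
    img += params.background_level

    full_scale = 2**params.bit_depth - 1
    if params.poisson_noise:
        # shot noise: variance proportional to signal, scaled so the
        # background-level noise floor matches noise_sd
        lam = np.clip(img, 0, None) / max(params.noise_sd**2, 1e-12) * params.background_level
        img = rng.poisson(lam) * (params.noise_sd**2) / params.background_level
    else:
        read_sd = params.noise_sd + params.gain_noise_coeff * max(params.gain - 1.0, 0.0)
        img = img + rng.normal(0.0, read_sd, params.image_size)
    img = img * params.gain

    pixels = np.clip(np.rint(img * full_scale), 0, full_scale)
    dtype = np.uint8 if params.bit_depth == 8 else np.uint16
    micro = Micrograph(pixels=pixels.astype(dtype), bit_depth=params.bit_depth)
    truth = GroundTruthRecord(
        well=None, sample_id="", load=float(load), concentration=np.nan,
        timepoint=timepoint, seed=int(seed),
    )
    return micro, truth


def simulate_well_pair(
    load_24h: float, params: SimulationParams | None = None, seed: int = 0
) -> tuple[Micrograph, Micrograph]:
    """Render the 0 h (dispersed monomer/probe, load 0) and 24 h images of a
    well; the two timepoints use distinct seeds."""
    img0, _ = render_micrograph(0.0, params, well_seed(seed, 0, 0, 0), timepoint=0.0)
    img24, _ = render_micrograph(load_24h, params, well_seed(seed, 0, 0, 24), timepoint=24.0)
    return img0, img24


class ConfigurationError(ValueError):
    """A simulation request referenced a sample with no inhibition model."""


def simulate_plate(
    layout: PlateLayout,
    inhibition_models: dict[str, InhibitionModel],
    params: SimulationParams | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[dict[tuple[str, str], Micrograph], pd.DataFrame]:
    """Simulate the 0 h and 24 h micrographs of every assigned well.

    Per-well seeds are mixed deterministically from (master_seed, row, col,
    timepoint), so re-running with the same master seed reproduces the image
    set bit for bit. Returns ``{(well_name, 't0'|'t24'): Micrograph}`` plus a
    ground-truth table; when ``out_dir`` is given, images are also written as
    ``{plate_id}_{well}_{t0|t24}.tif`` with a ``truth.csv`` alongside.
    """
    params = params or SimulationParams()
    layout.validate()
    for sid in layout.sample_ids():
        if sid not in inhibition_models:
            raise ConfigurationError(f"no inhibition model for sample {sid!r}")

    images: dict[tuple[str, str], Micrograph] = {}
    records = []
    for addr, a in sorted(layout.wells.items()):
        if a.role == "test":
            load = inhibited_load(a.final_conc, inhibition_models[a.sample_id])
        elif a.role == "positive_control_no_inhibitor":
            load = 1.0
        else:  # background_0h, blank
            load = 0.0
        for tag, tp, ld in ((0, 0.0, 0.0), (24, 24.0, load)):
            seed = well_seed(master_seed, addr.row, addr.col, tag)
            micro, _ = render_micrograph(ld, params, seed, timepoint=tp)
            images[(addr.name, f"t{tag}")] = micro
            records.append(
                {
                    "plate_id": layout.plate_id,
                    "well": addr.name,
                    "sample_id": a.sample_id,
                    "role": a.role,
                    "final_conc": a.final_conc,
                    "timepoint": tp,
                    "load": ld,
                    "seed": seed,
                }
            )
    truth = pd.DataFrame.from_records(records)

    if out_dir is not None:
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for (well, tp), micro in images.items():
            tifffile.imwrite(out / f"{layout.plate_id}_{well}_{tp}.tif", micro.pixels)
        truth.to_csv(out / "truth.csv", index=False)
    return images, truth
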