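"""Desk-scale validation experiments for the whole analysis chain.

Each function runs a self-contained, seeded experiment on synthetic data and
returns plain numbers; they back both the validation test suite and the
``scripts/acceptance.py`` report. Problem sizes are chosen to finish in a few
minutes on one CPU.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .doseresponse import DoseResponseCurve, fit_ec50, four_pl, summarize_replicates
from .plate import PLATE_FORMATS, PlateLayout, WellAddress, WellAssignment
from .quantify import Micrograph, ROISpec, compute_sd, well_sd
from .simulate import (
    InhibitionModel,
    SimulationParams,
    inhibited_load,
    render_micrograph,
    simulate_plate,
    well_seed,
)

__all__ = [
    "sd_oracle_max_rel_err",
    "ec50_image_recovery",
    "ec50_noiseless_recovery",
    "sd_load_profile",
    "exposure_invariance_max_drift",
    "plate_timepoint_separation",
    "replicate_reference_recovery",
]


def sd_oracle_max_rel_err(n_rasters: int = 1000, seed: int = 0) -> float:
    """Largest relative disagreement between the pipeline SD and a direct
    two-pass oracle over random small rasters."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_rasters):
        shape = (int(rng.integers(2, 40)), int(rng.integers(2, 40)))
        arr = rng.uniform(0, 65535, shape)
        mean = arr.sum() / arr.size
        oracle = float(np.sqrt(((arr - mean) ** 2).sum() / arr.size))
        got = compute_sd(arr)
        if oracle > 0:
            worst = max(worst, abs(got - oracle) / oracle)
    return worst


def _control_sd(
    params: SimulationParams, load: float, seeds: list[int], roi: ROISpec
) -> float:
    return float(
        np.mean([well_sd(render_micrograph(load, params, s)[0], roi).sd_value
                 for s in seeds])
    )


def ec50_image_recovery(
    n_series: int = 100,
    seed: int = 0,
    params: SimulationParams | None = None,
    n_points: int = 8,
    top_conc: float = 600.0,
    factor: float = 5.0,
) -> dict:
    """Full-pipeline EC50 recovery: render -> normalize -> ROI -> SD -> fit.

    Each series is an ``n_points``-step ``factor``-fold dilution with a true
    Hill-1 EC50 drawn log-uniformly within the tested range; plate controls
    (no-inhibitor and background) are rendered and quantified the same way.
    Returns per-series relative errors and their median.
    """
    params = params or SimulationParams()
    rng = np.random.default_rng(seed)
    roi = ROISpec(min(432, min(params.image_size)))
    concs = top_conc / factor ** np.arange(n_points)

    ctrl_seeds = [well_seed(seed, 0, c, 99) for c in range(6)]
    sd_pos = _control_sd(params, 1.0, ctrl_seeds, roi)
    sd_neg = _control_sd(params, 0.0, [s + 1 for s in ctrl_seeds], roi)

    rel_errors = []
    for i in range(n_series):
        true_ec50 = float(10 ** rng.uniform(np.log10(5.0), np.log10(100.0)))
        model = InhibitionModel(ec50_true=true_ec50)
        points = []
        for j, conc in enumerate(concs):
            img, _ = render_micrograph(
                inhibited_load(float(conc), model), params, well_seed(seed, i, j, 24)
            )
            res = well_sd(img, roi)
            points.append((float(conc), res.sd_value, res.qc.verdict))
        curve = DoseResponseCurve(f"series{i}", points, sd_pos=sd_pos, sd_neg=sd_neg)
        fit = fit_ec50(curve)
        if fit.status == "determinable":
            rel_errors.append(abs(fit.ec50 - true_ec50) / true_ec50)
    return {
        "n": len(rel_errors),
        "median_rel_err": float(np.median(rel_errors)),
        "rel_errors": rel_errors,
    }


def ec50_noiseless_recovery(n_series: int = 100, seed: int = 0) -> dict:
    """EC50 recovery on noiseless SD-level curves (ideal affine SD readout)."""
    rng = np.random.default_rng(seed)
    concs = 600.0 / 5.0 ** np.arange(8)
    sd_pos, sd_neg = 3000.0, 1600.0
    rel_errors = []
    for i in range(n_series):
        true_ec50 = float(10 ** rng.uniform(np.log10(5.0), np.log10(100.0)))
        inhibition = four_pl(concs, true_ec50, 1.0)
        sd = sd_pos - (sd_pos - sd_neg) * inhibition / 100.0
        curve = DoseResponseCurve(
            f"clean{i}", [(float(c), float(s), "pass") for c, s in zip(concs, sd)],
            sd_pos=sd_pos, sd_neg=sd_neg,
        )
        fit = fit_ec50(curve)
        rel_errors.append(abs(fit.ec50 - true_ec50) / true_ec50)
    return {"n": n_series, "median_rel_err": float(np.median(rel_errors))}


def sd_load_profile(
    loads=(0.0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.2),
    n_seeds: int = 20,
    seed: int = 0,
    params: SimulationParams | None = None,
) -> dict:
    """Mean pipeline SD per ground-truth load; used to check that contrast
    rises with aggregate load up to the depth-of-focus threshold and collapses
    beyond it (the rise-then-fall of SD vs amyloid concentration)."""
    params = params or dataclasses.replace(SimulationParams(), dof_load_threshold=0.8)
    roi = ROISpec(min(432, min(params.image_size)))
    means = {}
    for load in loads:
        sds = [
            well_sd(render_micrograph(float(load), params, well_seed(seed, k, 0, 7))[0],
                    roi).sd_value
            for k in range(n_seeds)
        ]
        means[float(load)] = float(np.mean(sds))
    return {"mean_sd": means, "threshold": params.dof_load_threshold}


def exposure_invariance_max_drift(
    factors=(0.5, 0.8, 1.25, 2.0), seed: int = 0,
    params: SimulationParams | None = None,
) -> float:
    """Worst relative drift (fraction) of the pipeline SD under clip-free
    exposure-like rescaling of the raw frame."""
    params = params or SimulationParams()
    rendered, _ = render_micrograph(0.5, params, seed)
    # leave headroom so a 2x rescale stays clip-free
    base = np.rint(rendered.pixels.astype(np.float64) / 2.2).astype(np.uint16)
    roi = ROISpec(min(432, min(params.image_size)))
    baseline = well_sd(Micrograph(pixels=base, bit_depth=params.bit_depth), roi).sd_value
    worst = 0.0
    for k in factors:
        scaled = np.rint(base.astype(np.float64) * k)
        if scaled.max() > 2**params.bit_depth - 1:
            raise RuntimeError("rescaling clipped; experiment misconfigured")
        sd = well_sd(
            Micrograph(pixels=scaled.astype(np.uint16), bit_depth=params.bit_depth), roi
        ).sd_value
        worst = max(worst, abs(sd - baseline) / baseline)
    return worst


def plate_timepoint_separation(
    seed: int = 0, params: SimulationParams | None = None
) -> dict:
    """Simulate a full no-inhibitor plate (96-well scale-down of the 1536
    validation run) and compare every well's 24 h SD with its own 0 h SD."""
    params = params or SimulationParams()
    layout = PlateLayout(plate_format=96, plate_id="val96")
    nrow, ncol = PLATE_FORMATS[96]
    for r in range(nrow):
        for c in range(ncol):
            layout.assign(
                WellAddress(r, c, 96),
                WellAssignment("__positive__", 0, 0.0, "positive_control_no_inhibitor"),
            )
    images, truth = simulate_plate(layout, {}, params, master_seed=seed)
    roi = ROISpec(min(432, min(params.image_size)))
    n_greater = 0
    wells = sorted({w for w, _ in images})
    for well in wells:
        sd0 = well_sd(images[(well, "t0")], roi).sd_value
        sd24 = well_sd(images[(well, "t24")], roi).sd_value
        n_greater += sd24 > sd0
    return {"n_wells": len(wells), "n_24h_greater": n_greater,
            "fraction": n_greater / len(wells)}


def replicate_reference_recovery(
    n_replicates: int = 61, true_ec50: float = 26.9, noise_frac: float = 0.10,
    seed: int = 0,
) -> dict:
    """Replicate EC50 estimation at the reference-inhibitor activity level
    (SD-level curves with proportional noise), summarised as mean ± SD."""
    rng = np.random.default_rng(seed)
    concs = 600.0 / 5.0 ** np.arange(8)
    sd_pos, sd_neg = 3000.0, 1600.0
    estimates = []
    for i in range(n_replicates):
        inhibition = four_pl(concs, true_ec50, 1.0)
        sd = sd_pos - (sd_pos - sd_neg) * inhibition / 100.0
        sd = sd + rng.normal(0, noise_frac * (sd_pos - sd_neg), sd.shape)
        curve = DoseResponseCurve(
            f"rep{i}", [(float(c), float(s), "pass") for c, s in zip(concs, sd)],
            sd_pos=sd_pos, sd_neg=sd_neg,
        )
        fit = fit_ec50(curve)
        if fit.status == "determinable":
            estimates.append(fit.ec50)
    summary = summarize_replicates(estimates)
    return {"n": summary.n, "mean_ec50": summary.mean_ec50,
            "sd_ec50": summary.sd_ec50, "true_ec50": true_ec50}
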