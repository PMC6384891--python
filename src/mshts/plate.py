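"""Plate geometry, dilution series, and mixing arithmetic.

Models the physical bookkeeping of the screening assay: samples are serially
diluted in a 384-well source plate, stamped into a 1536-well assay plate at
2.5 µl per well, and mixed 1:1 with 2.5 µl of amyloid/probe working solution,
so every in-well concentration is the pre-mix concentration halved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "PLATE_FORMATS",
    "WellAddress",
    "DilutionSeries",
    "MixSpec",
    "WellAssignment",
    "PlateLayout",
    "LayoutError",
    "make_dilution_series",
    "final_concentration",
    "build_plate_layout",
    "lookup_well",
    "read_plate_map",
    "write_plate_map",
]

#: plate format -> (rows, cols)
PLATE_FORMATS: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}

#: well roles recognised in plate maps
ROLES = ("test", "positive_control_no_inhibitor", "background_0h", "blank")


class LayoutError(ValueError):
    """Raised for invalid plate layouts, addresses, or capacity overflows."""


def _row_letters(row: int) -> str:
    # A..Z then AA..AF (1536 plates have 32 rows)
    if row < 26:
        return chr(ord("A") + row)
    return "A" + chr(ord("A") + row - 26)


def _parse_row_letters(s: str) -> int:
    if len(s) == 1:
        return ord(s) - ord("A")
    if len(s) == 2 and s[0] == "A":
        return 26 + ord(s[1]) - ord("A")
    raise LayoutError(f"cannot parse row label {s!r}")


@dataclass(frozen=True, order=True)
class WellAddress:
    """0-based (row, col) address on a plate of a given format."""

    row: int
    col: int
    plate_format: int = 1536

    def __post_init__(self) -> None:
        if self.plate_format not in PLATE_FORMATS:
            raise LayoutError(f"unknown plate format {self.plate_format}")
        nrow, ncol = PLATE_FORMATS[self.plate_format]
        if not (0 <= self.row < nrow and 0 <= self.col < ncol):
            raise LayoutError(
                f"address ({self.row}, {self.col}) outside {self.plate_format}-well bounds"
            )

    @property
    def name(self) -> str:
        """Letter+number rendering, e.g. A1, P24, AF48."""
        return f"{_row_letters(self.row)}{self.col + 1}"

    @classmethod
    def from_name(cls, name: str, plate_format: int = 1536) -> "WellAddress":
        m = re.fullmatch(r"([A-Z]{1,2})(\d{1,2})", name.strip().upper())
        if not m:
            raise LayoutError(f"cannot parse well name {name!r}")
        return cls(_parse_row_letters(m.group(1)), int(m.group(2)) - 1, plate_format)


@dataclass(frozen=True)
class DilutionSeries:
    """A stepwise serial dilution of one sample (pre-mix concentrations)."""

    sample_id: str
    stock_conc: float
    dilution_factor: float
    n_steps: int
    unit: str = "uM"

    def __post_init__(self) -> None:
        if self.stock_conc <= 0:
            raise ValueError("stock_conc must be positive")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    def concentrations(self) -> np.ndarray:
        return make_dilution_series(self.stock_conc, self.dilution_factor, self.n_steps)


@dataclass(frozen=True)
class MixSpec:
    """1:1 mixing of diluted sample with amyloid/probe working solution.

    Defaults follow the assay protocol: 2.5 µl sample + 2.5 µl of 50 µM
    amyloid / 50 nM QD probe, giving 25 µM amyloid and 25 nM probe in-well.
    """

    sample_volume: float = 2.5
    reagent_volume: float = 2.5
    reagent_stock_conc: float = 50.0
    probe_stock_conc: float = 50.0
    pipetting_count: int = 3

    def __post_init__(self) -> None:
        if self.sample_volume <= 0 or self.reagent_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.pipetting_count < 0:
            raise ValueError("pipetting_count must be >= 0")

    @property
    def final_reagent_conc(self) -> float:
        return final_concentration(
            self.reagent_stock_conc, self.reagent_volume, self.sample_volume
        )

    @property
    def final_probe_conc(self) -> float:
        return final_concentration(
            self.probe_stock_conc, self.reagent_volume, self.sample_volume
        )

    def final_sample_conc(self, pre_mix_conc: float) -> float:
        return final_concentration(pre_mix_conc, self.sample_volume, self.reagent_volume)


@dataclass(frozen=True)
class WellAssignment:
    sample_id: str
    step_index: int
    final_conc: float
    role: str
    unit: str = "uM"


@dataclass
class PlateLayout:
    """Mapping of well addresses to sample assignments on one plate."""

    plate_format: int = 1536
    plate_id: str = "plate1"
    wells: dict[WellAddress, WellAssignment] = field(default_factory=dict)

    def assign(self, address: WellAddress, assignment: WellAssignment) -> None:
        if address in self.wells:
            raise LayoutError(f"well {address.name} assigned twice")
        if address.plate_format != self.plate_format:
            raise LayoutError("address format does not match plate format")
        if assignment.role not in ROLES:
            raise LayoutError(f"unknown role {assignment.role!r}")
        self.wells[address] = assignment

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.wells.values():
            if a.role == "test":
                seen.setdefault(a.sample_id, None)
        return list(seen)

    def wells_for_sample(self, sample_id: str) -> list[tuple[WellAddress, WellAssignment]]:
        return [
            (addr, a)
            for addr, a in sorted(self.wells.items())
            if a.sample_id == sample_id and a.role == "test"
        ]

    def control_wells(self, role: str) -> list[WellAddress]:
        return [addr for addr, a in sorted(self.wells.items()) if a.role == role]

    def validate(self) -> None:
        """Check layout invariants: series with test wells need a no-inhibitor control."""
        if self.sample_ids() and not self.control_wells("positive_control_no_inhibitor"):
            raise LayoutError("layout has test series but no no-inhibitor control well")


def make_dilution_series(
    stock_conc: float, dilution_factor: float, n_steps: int
) -> np.ndarray:
    """Stepwise serial dilution: concentration at step i is stock / factor**i.

    A factor of exactly 1 yields a constant series (used for controls run at a
    single concentration). Factors below 1 are rejected.
    """
    if stock_conc <= 0:
        raise ValueError("stock_conc must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    return stock_conc / dilution_factor ** np.arange(n_steps, dtype=float)


def final_concentration(
    pre_mix_conc: float, sample_volume: float, reagent_volume: float
) -> float:
    """In-well concentration after mixing ``sample_volume`` of sample with
    ``reagent_volume`` of diluent/reagent: c * v_s / (v_s + v_r)."""
    if pre_mix_conc < 0:
        raise ValueError("concentration must be non-negative")
    if sample_volume <= 0 or reagent_volume < 0:
        raise ValueError("volumes must be positive (reagent may be zero)")
    total = sample_volume + reagent_volume
    if total <= 0:
        raise ValueError("total volume must be positive")
    return pre_mix_conc * sample_volume / total


def build_plate_layout(
    series_list: Iterable[DilutionSeries],
    replicates: int = 1,
    plate_format: int = 1536,
    mix: MixSpec | None = None,
    n_positive_controls: int = 4,
    n_blanks: int = 0,
    plate_id: str = "plate1",
) -> PlateLayout:
    """Deterministic row-major placement of dilution series and controls.

    Controls are placed first (no-inhibitor wells, then blanks), then each
    series' steps in order, repeated ``replicates`` times. Raises
    :class:`LayoutError` when the plate capacity is exceeded, reporting the
    overflow count.
    """
    series_list = list(series_list)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    mix = mix or MixSpec()
    nrow, ncol = PLATE_FORMATS[plate_format]
    capacity = nrow * ncol
    need = n_positive_controls + n_blanks + replicates * sum(
        s.n_steps for s in series_list
    )
    if need > capacity:
        raise LayoutError(
            f"layout needs {need} wells but a {plate_format}-well plate holds "
            f"{capacity} ({need - capacity} over capacity)"
        )

    layout = PlateLayout(plate_format=plate_format, plate_id=plate_id)
    cursor = 0

    def next_addr() -> WellAddress:
        nonlocal cursor
        addr = WellAddress(cursor // ncol, cursor % ncol, plate_format)
        cursor += 1
        return addr

    for _ in range(n_positive_controls):
        layout.assign(
            next_addr(),
            WellAssignment("__positive__", 0, 0.0, "positive_control_no_inhibitor"),
        )
    for _ in range(n_blanks):
        layout.assign(next_addr(), WellAssignment("__blank__", 0, 0.0, "blank"))
    for series in series_list:
        concs = series.concentrations()
        for _rep in range(replicates):
            for step, pre_mix in enumerate(concs):
                layout.assign(
                    next_addr(),
                    WellAssignment(
                        series.sample_id,
                        step,
                        mix.final_sample_conc(float(pre_mix)),
                        "test",
                        unit=series.unit,
                    ),
                )
    if series_list and n_positive_controls < 1:
        raise LayoutError("series require at least one no-inhibitor control well")
    return layout


def lookup_well(layout: PlateLayout, address: WellAddress) -> WellAssignment:
    """Return the assignment stored at ``address``; raise on unassigned wells."""
    try:
        return layout.wells[address]
    except KeyError:
        raise LayoutError(f"well {address.name} is unassigned") from None


# ---------------------------------------------------------------------------
# plate-map CSV IO (columns: plate_id, well, sample_id, step_index, final_conc,
# unit, role)

def write_plate_map(layout: PlateLayout, path) -> None:
    rows = [
        {
            "plate_id": layout.plate_id,
            "well": addr.name,
            "sample_id": a.sample_id,
            "step_index": a.step_index,
            "final_conc": a.final_conc,
            "unit": a.unit,
            "role": a.role,
        }
        for addr, a in sorted(layout.wells.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_map(path, plate_format: int = 1536) -> PlateLayout:
    df = pd.read_csv(path)
    required = {"plate_id", "well", "sample_id", "step_index", "final_conc", "unit", "role"}
    missing = required - set(df.columns)
    if missing:
        raise LayoutError(f"plate map missing columns: {sorted(missing)}")
    plate_ids = df["plate_id"].unique()
    layout = PlateLayout(plate_format=plate_format, plate_id=str(plate_ids[0]))
    for i, row in df.iterrows():
        try:
            addr = WellAddress.from_name(str(row["well"]), plate_format)
            layout.assign(
                addr,
                WellAssignment(
                    str(row["sample_id"]),
                    int(row["step_index"]),
                    float(row["final_conc"]),
                    str(row["role"]),
                    unit=str(row["unit"]),
                ),
            )
        except (LayoutError, ValueError) as exc:
            raise LayoutError(f"plate map row {i + 2}: {exc}") from exc
    return layout
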