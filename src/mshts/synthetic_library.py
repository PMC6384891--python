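"""Synthetic screening-library tables (stand-ins for real screen results).

The published screen's per-sample EC50 tables live in supplementary material
that is not redistributable here, but their headline structure is: of 504
plant extracts, 139 had EC50 <= 0.1 mg/ml, 55 <= 0.05 mg/ml, and 20 <= 0.018
mg/ml (19 of those 20 eudicots, with Geraniales and Myrtales enriched); of 98
aromatic compounds, 13 were active with 7 tropolone derivatives among them;
of 36 further tropolone derivatives, 25 were active. These generators emit
SYNTHETIC per-sample tables whose EC50 values are drawn deterministically
within each published band, so tiering, ranking, and group summaries can be
exercised and checked against the published counts. Individual EC50 values
are invented; only the band structure is real.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "make_extract_library",
    "make_compound_screen",
    "make_tropolone_screen",
]

#: published band structure of the 504-extract screen: (lo, hi] mg/ml -> count
_EXTRACT_BANDS = [
    (0.004, 0.018, 20),   # more active than spearmint (red tier)
    (0.018, 0.05, 35),    # yellow tier (55 cumulative <= 0.05)
    (0.05, 0.1, 84),      # listed (139 cumulative <= 0.1)
]
_N_EXTRACTS = 504

# active compounds named in the initial 98-compound screen; 7 are tropolones
_MO_ACTIVE = ["MO-001", "MO-003", "MO-004", "MO-007", "MO-009", "MO-010",
              "MO-011", "MO-012", "MO-016", "MO-020", "MO-038", "MO-074",
              "MO-100"]
_MO_TROPOLONE_ACTIVE = ["MO-003", "MO-009", "MO-010", "MO-011",
                        "MO-012", "MO-016", "MO-020"]

_GROUPS_HIGH = ["Geraniales", "Myrtales"]
_GROUPS_EUDICOT = ["Rosales", "Fabales", "Sapindales", "Asterales",
                   "Lamiales", "Ericales"]
_GROUPS_OTHER = ["Poales", "Asparagales", "Pinales", "Polypodiales"]


def _loguniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), n)


def make_extract_library(seed: int = 0) -> pd.DataFrame:
    """Synthetic 504-extract screen table.

    Columns: sample_id, group, eudicot, ec50 (mg/ml; NaN when not
    determinable at <= 0.1 mg/ml), status.
    """
    rng = np.random.default_rng(seed)
    records = []
    idx = 0
    for band_i, (lo, hi, count) in enumerate(_EXTRACT_BANDS):
        vals = np.sort(_loguniform(rng, lo * 1.0001, hi, count))
        for v in vals:
            if band_i == 0:
                # 19 of the 20 top extracts are eudicots, enriched in
                # Geraniales/Myrtales (Geranium species dominate the top)
                pos = len([r for r in records if r["ec50"] is not None])
                if pos < 8:
                    group = _GROUPS_HIGH[pos % 2]
                elif pos < 19:
                    group = _GROUPS_EUDICOT[pos % len(_GROUPS_EUDICOT)]
                else:
                    group = _GROUPS_OTHER[0]
            else:
                group = rng.choice(_GROUPS_EUDICOT + _GROUPS_OTHER)
            records.append({"sample_id": f"EX-{idx + 1:03d}", "group": str(group),
                            "ec50": float(v), "status": "determinable"})
            idx += 1
    while idx < _N_EXTRACTS:
        group = rng.choice(_GROUPS_EUDICOT + _GROUPS_OTHER)
        records.append({"sample_id": f"EX-{idx + 1:03d}", "group": str(group),
                        "ec50": None, "status": "not_active"})
        idx += 1
    df = pd.DataFrame.from_records(records)
    df["eudicot"] = ~df["group"].isin(_GROUPS_OTHER)
    df["unit"] = "mg/ml"
    return df


def make_compound_screen(seed: int = 1) -> pd.DataFrame:
    """Synthetic initial screen of 98 aromatic low-molecular-weight compounds.

    13 actives (EC50 <= 200 µM), 7 of them tropolone derivatives; MO-009 is
    the most active, below the rosmarinic-acid reference of 26.9 µM.
    """
    rng = np.random.default_rng(seed)
    ids = [f"MO-{i:03d}" for i in range(1, 101) if i not in (97, 99)]
    assert len(ids) == 98
    tropolones = set(_MO_TROPOLONE_ACTIVE) | {"MO-050", "MO-051", "MO-052"}
    records = []
    for sid in ids:
        active = sid in _MO_ACTIVE
        if sid == "MO-009":
            ec50 = float(rng.uniform(8.0, 20.0))  # more active than RA
        elif active:
            ec50 = float(_loguniform(rng, 30.0, 200.0, 1)[0])
        else:
            ec50 = None
        records.append({
            "sample_id": sid, "tropolone": sid in tropolones, "ec50": ec50,
            "status": "determinable" if active else "not_active", "unit": "uM",
        })
    return pd.DataFrame.from_records(records)


def make_tropolone_screen(seed: int = 2) -> pd.DataFrame:
    """Synthetic second screen of 36 tropolone derivatives, 25 active;
    TR-003 most active, TR-004 inactive."""
    rng = np.random.default_rng(seed)
    inactive = {"TR-004"} | {f"TR-{i:03d}" for i in range(27, 37)}  # 11 inactive
    records = []
    for i in range(1, 37):
        sid = f"TR-{i:03d}"
        if sid == "TR-003":
            ec50 = float(rng.uniform(3.0, 8.0))
        elif sid not in inactive:
            ec50 = float(_loguniform(rng, 10.0, 200.0, 1)[0])
        else:
            ec50 = None
        records.append({
            "sample_id": sid, "tropolone": True, "ec50": ec50,
            "status": "determinable" if ec50 is not None else "not_active",
            "unit": "uM",
        })
    df = pd.DataFrame.from_records(records)
    assert int(df["ec50"].notna().sum()) == 25
    return df
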