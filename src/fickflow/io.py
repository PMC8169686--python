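"""Tabular data contract tying the modules together.

One CSV row per protocol step (RFC 4180, header row).  Units are fixed
by the schema: blood and sweep flows in ml/min, gas contents in
ml/100 ml, pressures in mmHg, temperature in deg C, fractions
dimensionless.  Floats are written with a fixed significant-digit
policy so that write -> read -> write round-trips byte-identically.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from .circuit_simulator import PORTS

__all__ = [
    "MEASUREMENT_COLUMNS",
    "REQUIRED_MEASUREMENT_COLUMNS",
    "FLOAT_FORMAT",
    "write_records",
    "read_records",
    "config_hash",
]

#: Fixed float formatting for CSV output.  12 significant digits keep
#: the noiseless simulator's closure properties intact through a file
#: round trip while remaining a stable canonical text form.
FLOAT_FORMAT = "%.12g"

_META_COLUMNS = [
    "step_id", "q_total", "q_ecmo", "q_lung", "shunt_set",
    "v_ecmo", "v_lung", "fio2", "transfer_fraction", "barometric",
    "hb", "temp", "exhaust_pco2_ecmo", "exhaust_pco2_lung",
    "chamber_vco2", "chamber_vo2",
]
_PANEL_COLUMNS = [f"{port}_{var}" for port in PORTS
                  for var in ("pco2", "po2", "so2", "ph")]
MEASUREMENT_COLUMNS = _META_COLUMNS + _PANEL_COLUMNS + ["noise", "seed"]

#: Columns every record must carry; port panels may be null when a
#: port was not sampled (blood-side methods will then raise).
REQUIRED_MEASUREMENT_COLUMNS = [
    "step_id", "q_ecmo", "q_lung", "shunt_set", "v_ecmo", "v_lung",
    "exhaust_pco2_ecmo", "exhaust_pco2_lung", "hb", "temp", "venous_ph",
]

_UNIT_BOUNDS = {
    # column -> (lo, hi): coarse plausibility checks that catch unit slips
    "q_ecmo": (0.0, 20_000.0),
    "q_lung": (0.0, 20_000.0),
    "v_ecmo": (1.0, 20_000.0),       # ml/min -- an L/min value would fail
    "v_lung": (1.0, 20_000.0),
    "shunt_set": (0.0, 1.0),
    "exhaust_pco2_ecmo": (0.0, 150.0),
    "exhaust_pco2_lung": (0.0, 150.0),
    "hb": (1.0, 25.0),
    "temp": (30.0, 42.0),
}


def write_records(records: pd.DataFrame, path: str | Path) -> None:
    """Write measurement (or estimate) records as canonical CSV."""
    ordered = [c for c in MEASUREMENT_COLUMNS if c in records.columns]
    ordered += [c for c in records.columns if c not in ordered]
    records[ordered].to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_records(path: str | Path, validate: bool = True) -> pd.DataFrame:
    """Read a measurement CSV, validating schema and unit plausibility."""
    df = pd.read_csv(path)
    if validate:
        missing = [c for c in REQUIRED_MEASUREMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"{path}: missing required columns: {', '.join(missing)}"
            )
        for col, (lo, hi) in _UNIT_BOUNDS.items():
            if col not in df.columns:
                continue
            bad = df[(df[col] < lo) | (df[col] > hi)]
            if not bad.empty:
                raise ValueError(
                    f"{path}: column '{col}' outside [{lo}, {hi}] in "
                    f"{len(bad)} row(s) (row {bad.index[0]}: "
                    f"{bad[col].iloc[0]}); check units "
                    "(flows/sweeps ml/min, pressures mmHg)"
                )
    return df


def config_hash(payload: str | bytes) -> str:
    """Short SHA-256 digest used in provenance log lines."""
    if isinstance(payload, str):
        payload = payload.encode()
    return hashlib.sha256(payload).hexdigest()[:12]
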