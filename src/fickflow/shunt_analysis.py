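"""Berggren shunt fraction and the flow-estimation error it causes.

Shunted blood bypasses the lung oxygenator and exchanges no gas, so a
gas-exchange-based flow estimate misses exactly the shunted fraction.
The classical Berggren (venous admixture) equation recovers the shunt
fraction from post-oxygenator, left-atrial and venous gas contents and
works with either O2 or CO2 contents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ShuntEstimate",
    "ShuntErrorFit",
    "berggren_shunt",
    "flow_error",
    "shunt_error_regression",
    "filter_by_shunt",
]


@dataclass(frozen=True)
class ShuntEstimate:
    """A shunt fraction Qs/Qt with a range-quality flag.

    Noise can push the content-based estimate outside [0, 1]; it is
    flagged (``in_range``) rather than clamped so that downstream
    agreement statistics see the raw estimator.
    """

    fraction: float
    species: str           # "o2" | "co2"

    @property
    def in_range(self) -> bool:
        return 0.0 <= self.fraction <= 1.0


def berggren_shunt(c_post_lung: float, c_la: float, c_venous: float,
                   species: str = "o2") -> ShuntEstimate:
    """Qs/Qt = (c_postLung - c_LA) / (c_postLung - c_venous).

    Contents in ml/100 ml; the same expression serves O2 (post-lung
    above venous) and CO2 (post-lung below venous) contents.
    """
    denom = c_post_lung - c_venous
    if denom == 0:
        raise ZeroDivisionError(
            "post-lung and venous contents are equal; shunt is undefined"
        )
    return ShuntEstimate(fraction=(c_post_lung - c_la) / denom, species=species)


def flow_error(q_measured: float, q_calculated: float) -> float:
    """Relative error (q_measured - q_calculated) / q_measured."""
    if q_measured <= 0:
        raise ValueError("measured flow must be positive")
    return (q_measured - q_calculated) / q_measured


@dataclass(frozen=True)
class ShuntErrorFit:
    """Least-squares fit of flow error on set shunt fraction."""

    slope: float
    intercept: float
    r2: float
    n: int

    def predict(self, shunt: float) -> float:
        """Predicted flow error at a shunt fraction (both as fractions)."""
        return self.slope * shunt + self.intercept


def shunt_error_regression(shunts: Sequence[float],
                           errors: Sequence[float]) -> ShuntErrorFit:
    """Fit error = slope x shunt + intercept by ordinary least squares."""
    x = np.asarray(shunts, dtype=float)
    y = np.asarray(errors, dtype=float)
    if x.size != y.size:
        raise ValueError("shunts and errors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 records for the regression")
    if np.ptp(x) == 0:
        raise ValueError("set shunt has no variance; slope is unidentifiable")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return ShuntErrorFit(slope=float(slope), intercept=float(intercept),
                         r2=r2, n=int(x.size))


def filter_by_shunt(records: pd.DataFrame, max_shunt: float = 0.01,
                    column: str = "shunt_set") -> pd.DataFrame:
    """Drop records whose shunt exceeds ``max_shunt`` (default 1 %)."""
    if column not in records.columns:
        raise KeyError(f"records lack a '{column}' column")
    return records.loc[records[column] <= max_shunt].copy()
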