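"""Normalization of CO2 elimination toward a V/Q ratio of 1.

CO2 elimination across a membrane lung depends on both the blood flow
delivering CO2 and the sweep-gas flow removing it.  When the
ventilation/perfusion ratio V/Q differs from 1, the measured VCO2 no
longer tracks blood flow.  The correction factor

    f(V, Q) = ((V/Q + c) / (1 + c)) * (Q / V)

rescales a gas-side VCO2 measured at an arbitrary V/Q to the value it
would take at V/Q = 1, where c is the blood CO2 capacitance constant
from :func:`fickflow.gas_content.normalization_constant`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["VqPoint", "vq_correction_factor", "normalize_vco2"]


@dataclass(frozen=True)
class VqPoint:
    """A gas-exchange unit's operating point.

    v and q must be in identical units (ml/min throughout the package);
    c is the dimensionless capacitance constant.
    """

    v: float
    q: float
    c: float

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("sweep gas flow v must be positive")
        if self.q <= 0:
            raise ValueError("blood flow q must be positive")
        if self.c <= 0:
            raise ValueError("normalization constant c must be positive")

    @property
    def ratio(self) -> float:
        return self.v / self.q


def vq_correction_factor(p: VqPoint) -> float:
    """Multiplicative factor mapping VCO2 at p.ratio to V/Q = 1.

    Equals 1 when v = q, falls below 1 for V/Q > 1 (over-ventilated
    units eliminate more CO2 than blood flow warrants) and rises above
    1 for V/Q < 1; strictly decreasing in V/Q.
    """
    r = p.ratio
    return (r + p.c) / (1.0 + p.c) / r


def normalize_vco2(vco2_gas: float, p: VqPoint) -> float:
    """Gas-side VCO2 [ml/min] corrected to V/Q = 1.

    Identity when v = q.  ``vco2_gas`` must be non-negative (use the
    package's absolute-value convention upstream).
    """
    if vco2_gas < 0:
        raise ValueError("vco2_gas must be non-negative; take the magnitude first")
    return vco2_gas * vq_correction_factor(p)
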