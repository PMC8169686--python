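"""Modified-Fick estimation of native pulmonary blood flow on VA-ECMO.

With the ECMO circuit and the native lung in parallel, mass balance of
CO2 (or O2) gives

    Q_lung = Q_ecmo * |Vx_lung| / |Vx_ecmo|

where Vx is the gas-exchange rate of the unit, measured either on the
gas side (exhaust fraction x sweep flow, optionally normalized to
V/Q = 1) or on the blood side (content difference x blood flow).  The
content-difference form

    Q_lung = Q_ecmo * (d_v-pm - d_v-ao) / (d_v-ao - d_v-LA)

uses only port CO2 contents.  Absolute values make the estimate
invariant to the sign convention of production vs elimination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .gas_content import (
    BloodGas,
    co2_content,
    normalization_constant,
    o2_content,
)
from .vq_normalization import VqPoint, normalize_vco2

__all__ = [
    "GasExchange",
    "ContentDifference",
    "FlowEstimate",
    "MissingFieldError",
    "vco2_from_gas",
    "exhaust_fraction_from_pco2",
    "exchange_from_blood",
    "estimate_qlung_ratio",
    "estimate_qlung_contents",
    "estimate_all_methods",
    "METHODS",
]

#: The four flow-calculation methods compared throughout the study.
METHODS = ("vo2_blood", "vco2_gas", "vco2_gasnorm", "vco2_blood")

#: Standard water vapor pressure at body temperature [mmHg].
PH2O_BODY = 47.0


class MissingFieldError(KeyError):
    """A measurement record lacks a column required by a method."""


@dataclass(frozen=True)
class GasExchange:
    """A gas-exchange rate [ml/min] with its provenance."""

    value: float
    species: str          # "co2" | "o2"
    source: str           # "gas" | "gas_normalized" | "blood"
    site: str             # "lung" | "ecmo" | "total"


@dataclass(frozen=True)
class ContentDifference:
    """A blood gas-content difference [ml/100 ml] between two ports."""

    delta: float
    segment: str          # e.g. "v-ao", "v-LA", "v-pm", "pL-LA", "pL-v"


@dataclass(frozen=True)
class FlowEstimate:
    """An estimated lung-circuit blood flow [ml/min]."""

    q_lung_hat: float
    method: str


def vco2_from_gas(exhaust_co2_fraction: float, sweep_flow: float,
                  site: str = "ecmo") -> GasExchange:
    """Gas-side VCO2 [ml/min] = exhaust CO2 fraction x sweep gas flow [ml/min]."""
    if not 0.0 <= exhaust_co2_fraction < 0.2:
        raise ValueError(
            f"exhaust CO2 fraction {exhaust_co2_fraction} outside [0, 0.2)"
        )
    if sweep_flow <= 0:
        raise ValueError("sweep gas flow must be positive")
    return GasExchange(value=exhaust_co2_fraction * sweep_flow,
                       species="co2", source="gas", site=site)


def exhaust_fraction_from_pco2(exhaust_pco2: float, barometric: float = 760.0,
                               water_vapor: bool = False,
                               ph2o: float = PH2O_BODY) -> float:
    """Convert a capnometer exhaust pCO2 [mmHg] to a dry-gas fraction.

    Default treats the exhaust as dry gas (fraction = pCO2/Pbar); with
    ``water_vapor=True`` the denominator is Pbar - pH2O.
    """
    if barometric <= 0:
        raise ValueError("barometric pressure must be positive")
    denom = barometric - ph2o if water_vapor else barometric
    if not 0.0 <= exhaust_pco2 < denom:
        raise ValueError(f"exhaust pCO2 {exhaust_pco2} outside [0, {denom})")
    return exhaust_pco2 / denom


def exchange_from_blood(q: float, delta: ContentDifference,
                        species: str = "co2", site: str = "ecmo") -> GasExchange:
    """Blood-side exchange [ml/min] = flow x content difference / 100."""
    if q < 0:
        raise ValueError("blood flow must be non-negative")
    return GasExchange(value=q * delta.delta / 100.0,
                       species=species, source="blood", site=site)


def estimate_qlung_ratio(q_ecmo: float, vx_lung: GasExchange,
                         vx_ecmo: GasExchange) -> FlowEstimate:
    """Q_lung from the ratio of lung to ECMO exchange (absolute values)."""
    if vx_lung.species != vx_ecmo.species:
        raise ValueError(
            f"species mismatch: {vx_lung.species} vs {vx_ecmo.species}"
        )
    if vx_ecmo.value == 0:
        raise ZeroDivisionError(
            "ECMO gas exchange is zero: the flow ratio is undefined"
        )
    method = {"gas": "vco2_gas", "gas_normalized": "vco2_gasnorm",
              "blood": f"v{vx_lung.species}_blood"}[vx_lung.source]
    return FlowEstimate(
        q_lung_hat=q_ecmo * abs(vx_lung.value) / abs(vx_ecmo.value),
        method=method,
    )


def estimate_qlung_contents(q_ecmo: float, d_v_pm: ContentDifference,
                            d_v_ao: ContentDifference,
                            d_v_la: ContentDifference) -> FlowEstimate:
    """Q_lung from port CO2 content differences alone.

    Degenerate when the aortic difference equals the left-atrial one
    (no information separates lung flow from total flow).
    """
    denom = d_v_ao.delta - d_v_la.delta
    if denom == 0:
        raise ZeroDivisionError(
            "degenerate content differences: d(v-ao) == d(v-LA) "
            f"({d_v_ao.delta} ml/100 ml); lung flow is unidentifiable"
        )
    return FlowEstimate(
        q_lung_hat=q_ecmo * (d_v_pm.delta - d_v_ao.delta) / denom,
        method="contents",
    )


# --- record-level driver ---------------------------------------------

_PORTS = ("venous", "post_membrane", "post_lung", "left_atrium", "aorta")


def _get(record: Mapping[str, float], key: str, method: str) -> float:
    try:
        value = record[key]
    except KeyError as exc:
        raise MissingFieldError(
            f"method '{method}' requires column '{key}'"
        ) from exc
    if value is None:
        raise MissingFieldError(f"method '{method}' requires column '{key}'")
    return value


def _port_bg(record: Mapping[str, float], port: str, method: str) -> BloodGas:
    return BloodGas(
        pco2=_get(record, f"{port}_pco2", method),
        po2=_get(record, f"{port}_po2", method),
        so2=_get(record, f"{port}_so2", method),
        ph=_get(record, f"{port}_ph", method),
        hb=_get(record, "hb", method),
        temp=_get(record, "temp", method),
    )


def _gas_vco2(record: Mapping[str, float], unit: str, method: str) -> float:
    pco2 = _get(record, f"exhaust_pco2_{unit}", method)
    baro = record.get("barometric", 760.0)
    sweep = _get(record, f"v_{unit}", method)
    if pco2 == 0.0:
        return 0.0
    return vco2_from_gas(exhaust_fraction_from_pco2(pco2, baro), sweep).value


def estimate_all_methods(record: Mapping[str, float],
                         methods: tuple[str, ...] = METHODS,
                         normalize_ecmo: bool = True,
                         ) -> dict[str, FlowEstimate]:
    """All requested flow estimates for one measurement record.

    ``record`` is a mapping with the CSV schema of
    :mod:`fickflow.io` (flows and sweeps in ml/min, exhaust pCO2 in
    mmHg, one blood-gas panel per port).  The ECMO-side VCO2 is
    normalized to V/Q = 1 whenever ``normalize_ecmo`` (the V/Q at the
    ECMO is always known); the lung side is normalized only for the
    ``vco2_gasnorm`` method.  The lung normalization uses the
    oxygenator blood flow, i.e. lung flow reduced by the set shunt
    fraction, as only that flow participates in gas exchange.

    Raises :class:`MissingFieldError` naming the first missing column.
    """
    out: dict[str, FlowEstimate] = {}
    q_ecmo = _get(record, "q_ecmo", "all")
    q_lung = _get(record, "q_lung", "all")
    shunt = record.get("shunt_set", 0.0) or 0.0

    needs_gas = {"vco2_gas", "vco2_gasnorm"} & set(methods)
    if needs_gas:
        c = normalization_constant(
            _get(record, "venous_ph", "vco2_gas"),
            _get(record, "temp", "vco2_gas"),
        ).c
        vco2_e = _gas_vco2(record, "ecmo", "vco2_gas")
        vco2_l = _gas_vco2(record, "lung", "vco2_gas")
        if normalize_ecmo:
            vco2_e = normalize_vco2(
                abs(vco2_e), VqPoint(v=record["v_ecmo"], q=q_ecmo, c=c))
        if vco2_e == 0:
            raise ZeroDivisionError("ECMO VCO2 is zero; ratio undefined")

        if "vco2_gas" in methods:
            out["vco2_gas"] = FlowEstimate(
                q_lung_hat=q_ecmo * abs(vco2_l) / vco2_e, method="vco2_gas")
        if "vco2_gasnorm" in methods:
            q_oxy = q_lung * (1.0 - shunt)
            if vco2_l == 0.0 or q_oxy == 0.0:
                vco2_l_norm = 0.0
            else:
                vco2_l_norm = normalize_vco2(
                    abs(vco2_l), VqPoint(v=record["v_lung"], q=q_oxy, c=c))
            out["vco2_gasnorm"] = FlowEstimate(
                q_lung_hat=q_ecmo * vco2_l_norm / vco2_e, method="vco2_gasnorm")

    needs_blood = {"vo2_blood", "vco2_blood"} & set(methods)
    if needs_blood:
        method = sorted(needs_blood)[0]
        bg = {p: _port_bg(record, p, method) for p in _PORTS}
        if "vco2_blood" in methods:
            cco2 = {p: co2_content(b) for p, b in bg.items()}
            lung = exchange_from_blood(
                q_lung, ContentDifference(cco2["venous"] - cco2["left_atrium"], "v-LA"),
                site="lung")
            ecmo = exchange_from_blood(
                q_ecmo, ContentDifference(cco2["venous"] - cco2["post_membrane"], "v-pm"),
                site="ecmo")
            out["vco2_blood"] = estimate_qlung_ratio(q_ecmo, lung, ecmo)
        if "vo2_blood" in methods:
            co2c = {p: o2_content(b) for p, b in bg.items()}
            lung = exchange_from_blood(
                q_lung, ContentDifference(co2c["left_atrium"] - co2c["venous"], "LA-v"),
                species="o2", site="lung")
            ecmo = exchange_from_blood(
                q_ecmo, ContentDifference(co2c["post_membrane"] - co2c["venous"], "pm-v"),
                species="o2", site="ecmo")
            out["vo2_blood"] = estimate_qlung_ratio(q_ecmo, lung, ecmo)

    return out
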