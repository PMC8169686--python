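"""In-silico twin of the two-circuit VA-ECMO bench simulator.

Topology: a venous reservoir feeds two parallel circuits -- an ECMO
circuit (pump + membrane oxygenator) and a lung circuit (pump +
oxygenator with an adjustable shunt bypass).  Their outflows merge in
an "aorta" and pass a metabolic chamber that adds CO2 and removes O2
at configured rates, closing the loop back to the venous side.
Sampling ports: venous, post-membrane (after the ECMO oxygenator),
post-lung (after the lung oxygenator), left atrium (post-lung mixed
with the shunted blood), aorta.

Forward gas-exchange model
--------------------------
Each oxygenator's CO2 elimination at V/Q = 1 is a flow-proportional
content drop; at other V/Q ratios the measured elimination is the
V/Q = 1 reference divided by the Eq-5-type correction factor f(V, Q),
so the downstream normalization recovers the reference exactly.  The
common per-flow drop is scaled so that total elimination balances the
metabolic chamber's CO2 input -- the steady-state condition of the
closed loop.  O2: oxygenator outflow is fully saturated at a
configured post-oxygenator pO2; venous saturation then follows from
the chamber's O2 removal.  Measurement noise replicates the
side-stream capnometer specification (+-3.3 mmHg + 8 % relative as a
95 % bound).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gas_content import (
    BloodGas,
    GasContents,
    normalization_constant,
    o2_content,
    pco2_from_content,
    po2_from_o2_content,
    co2_content,
)
from .vq_normalization import VqPoint, vq_correction_factor

__all__ = [
    "CircuitConfig",
    "SteadyState",
    "ProtocolStep",
    "ConvergenceError",
    "OverVentilationError",
    "oxygenator_exchange",
    "solve_steady_state",
    "run_protocol",
    "measurement_record",
    "apply_measurement_noise",
    "records_from_protocol",
    "PORTS",
]

PORTS = ("venous", "post_membrane", "post_lung", "left_atrium", "aorta")

#: Wean schedule of ECMO blood flow [ml/min] (baseline first).
WEAN_FLOWS = (2000.0, 1500.0, 1000.0, 500.0)


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the content tolerance."""


class OverVentilationError(ValueError):
    """A port content was driven negative (ventilation exceeds supply)."""


@dataclass(frozen=True)
class CircuitConfig:
    """Flows, sweep settings and perfusate properties for one step.

    Flows and sweeps in ml/min, contents in ml/100 ml, pressures in
    mmHg, temperature in deg C.  ``chamber_vco2``/``chamber_vo2`` are
    the metabolic chamber's CO2 addition and O2 removal rates
    [ml/min]; if ``chamber_vco2`` is None it is derived from
    ``exchange_delta_ref`` (the reference veno-arterial CO2 content
    drop at V/Q = 1) and the circulating flows.
    """

    q_ecmo: float = 2000.0
    q_lung: float = 500.0
    shunt: float = 0.0
    v_ecmo: float = 2000.0
    v_lung: float = 1500.0
    fio2: float = 0.5
    chamber_vco2: float | None = 130.0
    chamber_vo2: float = 45.0
    hb: float = 9.0
    temp: float = 36.8
    ph_venous: float = 7.28
    ph_arterial: float = 7.39
    venous_pco2_target: float = 50.0
    exchange_delta_ref: float = 5.0
    post_oxygenator_po2: float = 200.0
    barometric: float = 760.0
    # optional extra noise terms (SDs; 0 disables)
    blood_gas_pco2_sd: float = 0.0
    flow_rel_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.q_ecmo <= 0 or self.q_lung < 0:
            raise ValueError("q_ecmo must be positive and q_lung non-negative")
        if not 0.0 <= self.shunt <= 1.0:
            raise ValueError(f"shunt fraction {self.shunt} outside [0, 1]")
        if self.v_ecmo <= 0 or self.v_lung <= 0:
            raise ValueError("sweep gas flows must be positive")
        if self.chamber_vco2 is not None and self.chamber_vco2 < 0:
            raise ValueError("chamber_vco2 must be non-negative")
        if self.chamber_vo2 < 0:
            raise ValueError("chamber_vo2 must be non-negative")

    @property
    def q_total(self) -> float:
        """Systemic flow [ml/min]; the circuits merge, so it is the sum."""
        return self.q_ecmo + self.q_lung

    @property
    def q_lung_oxy(self) -> float:
        """Lung-circuit flow actually passing the oxygenator [ml/min]."""
        return self.q_lung * (1.0 - self.shunt)

    def resolved_chamber_vco2(self) -> float:
        if self.chamber_vco2 is not None:
            return self.chamber_vco2
        return self.exchange_delta_ref / 100.0 * (self.q_ecmo + self.q_lung_oxy)


@dataclass(frozen=True)
class SteadyState:
    """Converged port contents and per-unit exchange rates for one step."""

    contents: dict[str, GasContents]
    vco2_lung: float
    vco2_ecmo: float
    vco2_total: float
    vo2_lung: float
    vo2_ecmo: float
    vco2_ref_lung: float
    vco2_ref_ecmo: float
    f_lung: float
    f_ecmo: float
    delta_eff: float
    c_norm: float
    converged: bool
    iterations: int


@dataclass(frozen=True)
class ProtocolStep:
    """One configured maneuver of the weaning protocol."""

    step_id: str
    q_ecmo: float
    q_lung: float
    shunt: float
    vq_ecmo: float
    transfer_fraction: float | None = None


def oxygenator_exchange(q: float, v: float, c_in: GasContents,
                        cfg: CircuitConfig,
                        delta_ref: float | None = None,
                        ) -> tuple[GasContents, float, float]:
    """Forward model of one membrane oxygenator.

    Returns (outflow contents, measured VCO2 [ml/min], VO2 [ml/min]).
    The V/Q = 1 reference elimination is ``q x delta_ref / 100``; the
    measured elimination is the reference divided by the correction
    factor f(v, q), so normalizing the measurement recovers the
    reference exactly.  The outflow is fully saturated with O2.
    """
    if q <= 0 or v <= 0:
        raise ValueError("oxygenator flows must be positive")
    if delta_ref is None:
        delta_ref = cfg.exchange_delta_ref
    c = normalization_constant(cfg.ph_venous, cfg.temp).c
    f = vq_correction_factor(VqPoint(v=v, q=q, c=c))
    vco2_ref = q * delta_ref / 100.0
    vco2_meas = vco2_ref / f
    cco2_out = c_in.cco2 - 100.0 * vco2_meas / q
    if cco2_out < 0:
        raise OverVentilationError(
            f"CO2 content driven to {cco2_out:.2f} ml/100 ml: sweep flow {v} "
            f"ml/min over-ventilates the available CO2 at q={q} ml/min"
        )
    co2_out = o2_content(BloodGas(pco2=40.0, po2=cfg.post_oxygenator_po2,
                                  so2=1.0, ph=cfg.ph_arterial, hb=cfg.hb, temp=cfg.temp))
    vo2 = q * (co2_out - c_in.co2) / 100.0
    return GasContents(cco2=cco2_out, co2=co2_out), vco2_meas, vo2


def solve_steady_state(cfg: CircuitConfig, tol: float = 1e-9,
                       max_iter: int = 10_000) -> SteadyState:
    """Closed-loop steady state of the two-circuit rig.

    Fixed-point iteration on the venous contents: the lung inflow
    splits (1 - shunt) through the oxygenator and shunt past it, the
    left atrium mixes the two, the aorta mixes lung and ECMO outflows
    by flow, and the metabolic chamber adds CO2 / removes O2 at its
    configured rates.  Per-unit CO2 elimination partitions the chamber
    input with weights q_i / f_i so the loop is mass-balanced (see the
    module docstring).
    """
    s = cfg.shunt
    q_e, q_l, q_t = cfg.q_ecmo, cfg.q_lung, cfg.q_total
    q_lo = cfg.q_lung_oxy
    chamber_vco2 = cfg.resolved_chamber_vco2()
    c_norm = normalization_constant(cfg.ph_venous, cfg.temp).c

    # V/Q correction factors of the two exchange units
    f_e = vq_correction_factor(VqPoint(v=cfg.v_ecmo, q=q_e, c=c_norm))
    f_l = (vq_correction_factor(VqPoint(v=cfg.v_lung, q=q_lo, c=c_norm))
           if q_lo > 0 else math.inf)

    # chamber CO2 partitions over the units with weights q/f
    w_e = q_e / f_e
    w_l = q_lo / f_l if q_lo > 0 else 0.0
    delta_eff = 100.0 * chamber_vco2 / (w_e + w_l)
    vco2_e = w_e * delta_eff / 100.0
    vco2_l = w_l * delta_eff / 100.0
    ref_e = q_e * delta_eff / 100.0
    ref_l = q_lo * delta_eff / 100.0

    c_sat = o2_content(BloodGas(pco2=40.0, po2=cfg.post_oxygenator_po2, so2=1.0,
                                ph=cfg.ph_arterial, hb=cfg.hb, temp=cfg.temp))

    # --- O2 loop: venous content is the only unknown ----------------
    o2_drop = 100.0 * cfg.chamber_vo2 / q_t
    o2_v = c_sat - o2_drop                      # initial guess
    it_o2 = 0
    converged = False
    for it_o2 in range(1, max_iter + 1):
        o2_la = (1.0 - s) * c_sat + s * o2_v
        o2_ao = (q_l * o2_la + q_e * c_sat) / q_t
        o2_v_new = o2_ao - o2_drop
        if o2_v_new < 0:
            raise OverVentilationError(
                "chamber O2 demand exceeds delivery: venous O2 content < 0"
            )
        if abs(o2_v_new - o2_v) < tol:
            o2_v = o2_v_new
            converged = True
            break
        o2_v = o2_v_new
    if not converged:
        raise ConvergenceError(f"O2 loop did not converge in {max_iter} iterations")
    o2_la = (1.0 - s) * c_sat + s * o2_v
    o2_ao = (q_l * o2_la + q_e * c_sat) / q_t

    # --- CO2 loop ----------------------------------------------------
    _, so2_v = po2_from_o2_content(o2_v, cfg.hb)
    cco2_v = co2_content(BloodGas(pco2=cfg.venous_pco2_target, po2=0.0, so2=so2_v,
                                  ph=cfg.ph_venous, hb=cfg.hb, temp=cfg.temp))
    drop_e = 100.0 * vco2_e / q_e
    # zero-flow limit: stagnant blood equilibrates with the CO2-free
    # sweep gas, so the post-lung sample content goes to 0
    drop_l = 100.0 * vco2_l / q_lo if q_lo > 0 else None

    it_co2 = 0
    converged = False
    for it_co2 in range(1, max_iter + 1):
        c_pm = cco2_v - drop_e
        c_pl = cco2_v - drop_l if drop_l is not None else 0.0
        if c_pm < 0 or c_pl < 0:
            raise OverVentilationError(
                "oxygenator CO2 elimination drives a port content negative"
            )
        c_la = (1.0 - s) * c_pl + s * cco2_v
        c_ao = (q_l * c_la + q_e * c_pm) / q_t
        cco2_v_new = c_ao + 100.0 * chamber_vco2 / q_t
        if abs(cco2_v_new - cco2_v) < tol:
            cco2_v = cco2_v_new
            converged = True
            break
        cco2_v = cco2_v_new
    if not converged:
        raise ConvergenceError(f"CO2 loop did not converge in {max_iter} iterations")
    c_pm = cco2_v - drop_e
    c_pl = cco2_v - drop_l if drop_l is not None else 0.0
    c_la = (1.0 - s) * c_pl + s * cco2_v
    c_ao = (q_l * c_la + q_e * c_pm) / q_t

    contents = {
        "venous": GasContents(cco2=cco2_v, co2=o2_v),
        "post_membrane": GasContents(cco2=c_pm, co2=c_sat),
        "post_lung": GasContents(cco2=c_pl, co2=c_sat),
        "left_atrium": GasContents(cco2=c_la, co2=o2_la),
        "aorta": GasContents(cco2=c_ao, co2=o2_ao),
    }
    vo2_e = q_e * (c_sat - o2_v) / 100.0
    vo2_l = q_lo * (c_sat - o2_v) / 100.0
    return SteadyState(
        contents=contents,
        vco2_lung=vco2_l, vco2_ecmo=vco2_e, vco2_total=vco2_l + vco2_e,
        vo2_lung=vo2_l, vo2_ecmo=vo2_e,
        vco2_ref_lung=ref_l, vco2_ref_ecmo=ref_e,
        f_lung=f_l, f_ecmo=f_e, delta_eff=delta_eff, c_norm=c_norm,
        converged=True, iterations=max(it_o2, it_co2),
    )


# --- protocol ---------------------------------------------------------

DEFAULT_SHUNT_LEVELS = (0.0, 0.2, 0.4)
TRANSFER_FRACTIONS = (0.75, 0.5)


def run_protocol(step_id: str,
                 shunt_levels: Sequence[float] | None = None,
                 cfg: CircuitConfig | None = None,
                 ) -> list[tuple[ProtocolStep, SteadyState]]:
    """Run one experimental maneuver of the weaning protocol.

    * ``1a`` -- ECMO flow 2000 -> 500 ml/min in 500-ml steps, lung flow
      rising to keep the 2500 ml/min total, ECMO sweep matched to blood
      flow (V/Q = 1); repeated per shunt level.
    * ``1b`` -- same flow schedule, ECMO sweep fixed at 1500 ml/min
      (V/Q traverses 0.75, 1, 1.5, 3); repeated per shunt level.
    * ``2a`` -- limited venous return: only a fraction (0.75, 0.5) of
      each weaned 500 ml reaches the lung circuit, total flow falls;
      shunt fixed at 0.
    * ``2b`` -- limited pump function: lung flow held at its baseline
      value across the wean (constant-RPM proxy); shunt fixed at 0.
    """
    if cfg is None:
        cfg = CircuitConfig()
    if step_id in ("1a", "1b"):
        shunts = DEFAULT_SHUNT_LEVELS if shunt_levels is None else tuple(shunt_levels)
    elif step_id in ("2a", "2b"):
        shunts = (0.0,)
    else:
        raise ValueError(f"unknown protocol step '{step_id}'; use 1a, 1b, 2a or 2b")

    base_q_e = cfg.q_ecmo
    base_q_l = cfg.q_lung
    total = cfg.q_total
    out: list[tuple[ProtocolStep, SteadyState]] = []
    for shunt in shunts:
        for q_e in WEAN_FLOWS:
            if step_id in ("1a", "1b"):
                schedule: list[tuple[float, float | None]] = [(total - q_e, None)]
            elif step_id == "2a":
                schedule = [(base_q_l + tf * (base_q_e - q_e), tf)
                            for tf in TRANSFER_FRACTIONS]
            else:  # 2b
                schedule = [(base_q_l, None)]
            v_e = 1500.0 if step_id == "1b" else q_e
            for q_l, tf in schedule:
                step_cfg = replace(cfg, q_ecmo=q_e, q_lung=q_l,
                                   shunt=shunt, v_ecmo=v_e)
                step = ProtocolStep(step_id=step_id, q_ecmo=q_e, q_lung=q_l,
                                    shunt=shunt, vq_ecmo=v_e / q_e,
                                    transfer_fraction=tf)
                out.append((step, solve_steady_state(step_cfg)))
    return out


# --- measurement records ---------------------------------------------

def _port_panel(port: str, contents: GasContents, cfg: CircuitConfig) -> dict[str, float]:
    """Recover a reportable blood-gas panel from port contents."""
    if port == "venous":
        ph = cfg.ph_venous
    elif port == "left_atrium":
        ph = cfg.shunt * cfg.ph_venous + (1.0 - cfg.shunt) * cfg.ph_arterial
    else:
        ph = cfg.ph_arterial
    po2, so2 = po2_from_o2_content(contents.co2, cfg.hb)
    pco2 = pco2_from_content(contents.cco2, ph=ph, hb=cfg.hb, so2=so2,
                             temp=cfg.temp)
    return {f"{port}_pco2": pco2, f"{port}_po2": po2,
            f"{port}_so2": so2, f"{port}_ph": ph}


def measurement_record(step: ProtocolStep, state: SteadyState,
                       cfg: CircuitConfig) -> dict[str, float]:
    """Noise-free measurement record (one CSV row) for a protocol step."""
    rec: dict[str, float] = {
        "step_id": step.step_id,
        "q_total": cfg.q_total,
        "q_ecmo": cfg.q_ecmo,
        "q_lung": cfg.q_lung,
        "shunt_set": cfg.shunt,
        "v_ecmo": cfg.v_ecmo,
        "v_lung": cfg.v_lung,
        "fio2": cfg.fio2,
        "transfer_fraction": (math.nan if step.transfer_fraction is None
                              else step.transfer_fraction),
        "barometric": cfg.barometric,
        "hb": cfg.hb,
        "temp": cfg.temp,
        "exhaust_pco2_ecmo": state.vco2_ecmo / cfg.v_ecmo * cfg.barometric,
        "exhaust_pco2_lung": state.vco2_lung / cfg.v_lung * cfg.barometric,
        "chamber_vco2": cfg.resolved_chamber_vco2(),
        "chamber_vo2": cfg.chamber_vo2,
    }
    for port in PORTS:
        rec.update(_port_panel(port, state.contents[port], cfg))
    return rec


def capnometer_sd(value: float, accuracy_abs: float = 3.3,
                  accuracy_rel: float = 0.08) -> float:
    """Gaussian SD of the exhaust pCO2 reading at a true value [mmHg].

    The manufacturer accuracy (+-3.3 mmHg + 8 % relative) is read as a
    95 % bound, hence SD = (3.3 + 0.08 x value) / 1.96.
    """
    return (accuracy_abs + accuracy_rel * value) / 1.96


def apply_measurement_noise(record: Mapping[str, float],
                            rng: np.random.Generator | int,
                            cfg: CircuitConfig | None = None) -> dict[str, float]:
    """Perturb a record with seeded measurement noise.

    Always perturbs the two exhaust pCO2 readings with the capnometer
    noise model; blood-gas pCO2 and flow-meter noise are added only if
    the config carries non-zero SDs.  Deterministic for a fixed seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    noisy = dict(record)
    for key in ("exhaust_pco2_ecmo", "exhaust_pco2_lung"):
        val = noisy[key]
        noisy[key] = max(0.0, val + rng.normal(0.0, capnometer_sd(val)))
    if cfg is not None and cfg.blood_gas_pco2_sd > 0:
        for port in PORTS:
            noisy[f"{port}_pco2"] = max(
                0.0, noisy[f"{port}_pco2"] + rng.normal(0.0, cfg.blood_gas_pco2_sd))
    if cfg is not None and cfg.flow_rel_sd > 0:
        for key in ("q_ecmo", "q_lung", "q_total"):
            noisy[key] = max(0.0, noisy[key] * (1.0 + rng.normal(0.0, cfg.flow_rel_sd)))
    return noisy


def records_from_protocol(step_id: str,
                          cfg: CircuitConfig | None = None,
                          shunt_levels: Sequence[float] | None = None,
                          noise: bool = False,
                          seed: int | None = None) -> pd.DataFrame:
    """Simulate a maneuver and return its measurement records as a table.

    Reproducible bit-for-bit from (config, seed).
    """
    if cfg is None:
        cfg = CircuitConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for step, state in run_protocol(step_id, shunt_levels, cfg):
        step_cfg = replace(cfg, q_ecmo=step.q_ecmo, q_lung=step.q_lung,
                           shunt=step.shunt,
                           v_ecmo=1500.0 if step_id == "1b" else step.q_ecmo)
        rec = measurement_record(step, state, step_cfg)
        if noise:
            rec = apply_measurement_noise(rec, rng, cfg)
        rec["noise"] = noise
        rec["seed"] = math.nan if seed is None else seed
        rows.append(rec)
    return pd.DataFrame(rows)
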