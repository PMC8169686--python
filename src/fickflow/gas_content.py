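"""Blood O2 and CO2 content models and the V/Q normalization constant.

O2 content is the classical linear hemoglobin-binding formula; CO2
content follows the Dash-Bassingthwaighte whole-blood chemistry
(dissolved CO2, bicarbonate in plasma and erythrocyte water, and
oxygen-linked carbamino binding, i.e. the Haldane effect).  Both
contents are reported in ml gas (STPD) per 100 ml blood.  The module
also provides the numeric inversion content -> pCO2 needed by the
circuit simulator, a Severinghaus oxygen dissociation curve for
reporting port (pO2, sO2) pairs, and the dimensionless constant c used
to normalize CO2 elimination toward a ventilation/perfusion ratio of 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

__all__ = [
    "BloodGas",
    "GasContents",
    "DashConstants",
    "NormalizationConstant",
    "o2_content",
    "co2_content",
    "pco2_from_content",
    "normalization_constant",
    "severinghaus_so2",
    "po2_from_o2_content",
]

#: ml CO2 (STPD) per mol at standard conditions (real-gas molar volume).
ML_STPD_PER_MOL = 22_256.0

#: O2 carrying capacity of hemoglobin [ml O2 / g Hb] (Huefner number).
HUEFNER = 1.36

#: O2 solubility term of the content formula [ml O2 / 100 ml / mmHg].
O2_SOLUBILITY = 0.003


@dataclass(frozen=True)
class BloodGas:
    """One sampling port's blood-gas panel.

    Parameters
    ----------
    pco2, po2 : float
        Partial pressures [mmHg].
    so2 : float
        Hemoglobin O2 saturation as a fraction in [0, 1].
    ph : float
        Plasma pH.
    hb : float
        Hemoglobin concentration [g/dl].
    temp : float
        Blood temperature [deg C].
    """

    pco2: float
    po2: float
    so2: float
    ph: float
    hb: float
    temp: float = 37.0

    def __post_init__(self) -> None:
        if self.pco2 < 0 or self.po2 < 0:
            raise ValueError("partial pressures must be non-negative")
        if not 0.0 <= self.so2 <= 1.0:
            raise ValueError(f"so2 must be a fraction in [0, 1], got {self.so2}")
        if not 6.5 < self.ph < 8.0:
            raise ValueError(f"pH {self.ph} outside the physiological range (6.5, 8.0)")
        if self.hb <= 0:
            raise ValueError("hemoglobin must be positive")
        if not 30.0 < self.temp < 42.0:
            raise ValueError(f"temperature {self.temp} outside (30, 42) C")


@dataclass(frozen=True)
class GasContents:
    """CO2 and O2 content of blood [ml/100 ml]."""

    cco2: float
    co2: float


@dataclass(frozen=True)
class DashConstants:
    """Equilibrium and partition constants of the blood CO2 model.

    Defaults are the published values of the Dash-Bassingthwaighte
    chemistry; exposed so an alternate parameterization can be swapped
    in without touching the content routines.

    Attributes
    ----------
    alpha_co2_37 : CO2 solubility in plasma at 37 C [mol/L/mmHg].
    alpha_co2_dt1, alpha_co2_dt2 : linear/quadratic temperature
        coefficients of the solubility around 37 C.
    w_plasma, w_rbc : water fractions of plasma and erythrocytes.
    r_donnan : Donnan ratio [H+]plasma / [H+]rbc (< 1: cells more acidic).
    k1 : apparent CO2 hydration constant [M] (pK' = 6.1).
    k2, k3 : carbamate formation constants of deoxy-/oxyhemoglobin.
    k5, k6 : alpha-amino ionization constants [M] of deoxy-/oxyhemoglobin.
    mw_hb : hemoglobin tetramer molecular weight [g/mol].
    mchc : mean corpuscular hemoglobin concentration [g/dl], used to
        derive hematocrit from the measured hemoglobin.
    """

    alpha_co2_37: float = 3.07e-5
    alpha_co2_dt1: float = -5.7e-7
    alpha_co2_dt2: float = 2.0e-9
    w_plasma: float = 0.94
    w_rbc: float = 0.65
    r_donnan: float = 0.69
    k1: float = 10.0 ** -6.1
    k2: float = 2.95e-5
    k3: float = 2.51e-5
    k5: float = 2.63e-8
    k6: float = 1.91e-8
    mw_hb: float = 64458.0
    mchc: float = 34.0

    def alpha_co2(self, temp: float) -> float:
        """Plasma CO2 solubility [mol/L/mmHg] at ``temp`` [deg C]."""
        dt = temp - 37.0
        return self.alpha_co2_37 + self.alpha_co2_dt1 * dt + self.alpha_co2_dt2 * dt * dt


_DEFAULT_DASH = DashConstants()


def o2_content(bg: BloodGas) -> float:
    """O2 content [ml/100 ml] = 1.36 x Hb x sO2 + 0.003 x pO2.

    Hemoglobin-bound O2 plus physically dissolved O2; Hb in g/dl, sO2
    as a fraction.
    """
    return HUEFNER * bg.hb * bg.so2 + O2_SOLUBILITY * bg.po2


def co2_content(bg: BloodGas, constants: DashConstants = _DEFAULT_DASH) -> float:
    """Whole-blood CO2 content [ml/100 ml] from a blood-gas panel.

    Sums, per litre of blood: dissolved CO2 in plasma and red-cell
    water, bicarbonate in both water phases (Henderson-Hasselbalch,
    with the intracellular pH set by a fixed Donnan H+ ratio), and
    carbamino CO2 on the four alpha-amino termini of hemoglobin with
    saturation-dependent equilibria (deoxyhemoglobin binds more CO2 --
    the Haldane effect).  Strictly increasing in pCO2 and decreasing in
    sO2 at fixed covariates.
    """
    k = constants
    alpha = k.alpha_co2(bg.temp)
    co2_free = alpha * bg.pco2                    # M in water-equivalent
    h_pl = 10.0 ** (-bg.ph)
    h_rbc = h_pl / k.r_donnan
    hct = bg.hb / k.mchc

    dis_pl = k.w_plasma * co2_free
    hco3_pl = dis_pl * k.k1 / h_pl
    dis_rbc = k.w_rbc * co2_free
    hco3_rbc = dis_rbc * k.k1 / h_rbc

    # carbamino saturation of the amino termini (4 per tetramer)
    sites = 4.0 * k.mchc * 10.0 / k.mw_hb         # M inside the cell
    z_deoxy = k.k2 * co2_free / h_rbc
    z_oxy = k.k3 * co2_free / h_rbc
    s_deoxy = z_deoxy / (1.0 + h_rbc / k.k5 + z_deoxy)
    s_oxy = z_oxy / (1.0 + h_rbc / k.k6 + z_oxy)
    carb = sites * (bg.so2 * s_oxy + (1.0 - bg.so2) * s_deoxy)

    molar = (1.0 - hct) * (dis_pl + hco3_pl) + hct * (dis_rbc + hco3_rbc + carb)
    return molar * ML_STPD_PER_MOL / 10.0


def pco2_from_content(
    target_cco2: float,
    ph: float,
    hb: float,
    so2: float,
    temp: float = 37.0,
    constants: DashConstants = _DEFAULT_DASH,
    bracket: tuple[float, float] = (0.0, 200.0),
) -> float:
    """Invert :func:`co2_content`: pCO2 [mmHg] yielding ``target_cco2``.

    Bracketed root finding on [0, 200] mmHg; the content model is
    strictly monotone in pCO2 so the root is unique.  Raises
    ``ValueError`` if the target lies outside the achievable range.
    """
    if target_cco2 < 0:
        raise ValueError("CO2 content cannot be negative")
    if target_cco2 == 0.0:
        return 0.0

    def f(p: float) -> float:
        bg = BloodGas(pco2=p, po2=0.0, so2=so2, ph=ph, hb=hb, temp=temp)
        return co2_content(bg, constants) - target_cco2

    lo, hi = bracket
    if f(hi) < 0:
        raise ValueError(
            f"CO2 content {target_cco2:.3f} ml/100 ml exceeds the model range "
            f"at pCO2 {hi} mmHg for ph={ph}, hb={hb}, so2={so2}"
        )
    return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)


@dataclass(frozen=True)
class NormalizationConstant:
    """The dimensionless constant c of the V/Q normalization.

    c = sigma_CO2 x R x T x (1 + Kc) with Kc = 10^(pH - pK'): the ratio
    of total transportable CO2 (dissolved + fast bicarbonate pool) to
    dissolved CO2, expressed per mmHg.  Larger c means CO2 elimination
    saturates more slowly with rising ventilation.
    """

    c: float
    sigma_co2: float          # mmol/L/mmHg
    r_t: float                # L*mmHg/mmol at the sample temperature
    kc: float                 # bicarbonate/dissolved ratio, pH dependent

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")


#: Effective CO2 solubility used for c [mmol/L/mmHg].  The aqueous
#: solubility at ~37 C; calibrated so the printed venous pH range maps
#: onto the reported range of c (see docs/methods.md).
SIGMA_CO2_DEFAULT = 0.0333

#: Gas constant [L*mmHg/(mol*K)].
R_GAS = 62.36

#: Apparent pK of the CO2/bicarbonate system.
PK_PRIME = 6.1


def normalization_constant(
    ph: float,
    temp: float = 37.0,
    sigma_co2: float = SIGMA_CO2_DEFAULT,
    pk_prime: float = PK_PRIME,
) -> NormalizationConstant:
    """Compute c from a venous blood-gas sample's pH and temperature."""
    if not 6.5 < ph < 8.0:
        raise ValueError(f"pH {ph} outside the physiological range")
    if not 30.0 < temp < 42.0:
        raise ValueError(f"temperature {temp} outside (30, 42) C")
    r_t = R_GAS * (273.15 + temp) / 1000.0        # L*mmHg/mmol
    kc = 10.0 ** (ph - pk_prime)
    return NormalizationConstant(c=sigma_co2 * r_t * (1.0 + kc),
                                 sigma_co2=sigma_co2, r_t=r_t, kc=kc)


# --- oxygen dissociation curve (for the simulator's port panels) -----

def severinghaus_so2(po2: float) -> float:
    """Severinghaus (1979) human ODC: sO2 fraction at pO2 [mmHg]."""
    if po2 <= 0:
        return 0.0
    return 1.0 / (1.0 + 23_400.0 / (po2 ** 3 + 150.0 * po2))


def po2_from_o2_content(target_co2: float, hb: float,
                        bracket: tuple[float, float] = (0.0, 700.0)) -> tuple[float, float]:
    """Invert the O2 content formula jointly with the Severinghaus ODC.

    Returns the (pO2 [mmHg], sO2 fraction) pair whose content
    ``1.36*hb*sO2(pO2) + 0.003*pO2`` equals ``target_co2``; the content
    is strictly increasing in pO2 so the solution is unique.
    """
    if target_co2 < 0:
        raise ValueError("O2 content cannot be negative")
    if target_co2 == 0.0:
        return 0.0, 0.0

    def f(p: float) -> float:
        return HUEFNER * hb * severinghaus_so2(p) + O2_SOLUBILITY * p - target_co2

    lo, hi = bracket
    if f(hi) < 0:
        raise ValueError(
            f"O2 content {target_co2:.3f} ml/100 ml not reachable below {hi} mmHg"
        )
    po2 = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return po2, severinghaus_so2(po2)
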