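"""Single-file brute-force oracle for whole-blood CO2 content.

Straight transcription of the Dash-Bassingthwaighte blood CO2 chemistry,
kept deliberately independent of the package implementation: every
compartment is computed step by step in scalar arithmetic with the
constants written inline.  Used only as a cross-check in tests.

Model: total CO2 carried per litre of blood is the sum of
  * CO2 dissolved in plasma water and in erythrocyte water,
  * bicarbonate in plasma water and in erythrocyte water
    (Henderson-Hasselbalch with the RBC interior more acidic than
    plasma by a fixed Donnan H+ ratio),
  * carbamino CO2 bound to the four alpha-amino termini of hemoglobin,
    with separate equilibrium constants for oxy- and deoxyhemoglobin
    (the Haldane effect).
Output is ml CO2 (STPD) per 100 ml blood.
"""

import math

# physical constants, inline on purpose
_ALPHA_CO2_37 = 3.07e-5      # M/mmHg, CO2 solubility in plasma at 37 C
_W_PLASMA = 0.94             # water fraction of plasma
_W_RBC = 0.65                # water fraction of erythrocytes
_R_RBC = 0.69                # Donnan ratio [H+]plasma/[H+]rbc
_K1 = 10.0 ** (-6.1)         # M, apparent CO2 hydration constant (pK' 6.1)
_K2 = 2.95e-5                # carbamate equilibrium, deoxyHb: K2=[HbNHCOO-][H+]/([HbNH2][CO2])
_K3 = 2.51e-5                # carbamate equilibrium, oxyHb
_K5 = 2.63e-8                # M, alpha-amino ionization HbNH3+ <-> HbNH2, deoxyHb
_K6 = 1.91e-8                # M, alpha-amino ionization, oxyHb
_MW_HB = 64458.0             # g/mol, hemoglobin tetramer
_MCHC = 34.0                 # g/dl, mean corpuscular Hb concentration
_ML_PER_MOL = 22256.0        # ml CO2 (STPD) per mol


def alpha_co2(temp_c):
    dt = temp_c - 37.0
    return 3.07e-5 - 5.7e-7 * dt + 2.0e-9 * dt * dt


def oracle_co2_content(pco2, ph, hb, so2, temp):
    """Whole-blood CO2 content [ml/100 ml] by direct summation."""
    alpha = alpha_co2(temp)
    co2_free = alpha * pco2                     # M, per litre of water-equivalent
    h_plasma = 10.0 ** (-ph)
    h_rbc = h_plasma / _R_RBC

    hct = hb / _MCHC                            # hematocrit from Hb, MCHC fixed

    # plasma compartment (per litre of plasma)
    dis_pl = _W_PLASMA * co2_free
    hco3_pl = dis_pl * _K1 / h_plasma

    # erythrocyte compartment (per litre of cells)
    dis_rbc = _W_RBC * co2_free
    hco3_rbc = dis_rbc * _K1 / h_rbc

    # carbamino: site concentration = 4 amino termini per tetramer
    sites = 4.0 * (_MCHC * 10.0 / _MW_HB)       # M inside the cell
    zd = _K2 * co2_free / h_rbc                 # deoxy carbamate / free-amine
    zo = _K3 * co2_free / h_rbc                 # oxy
    s_deoxy = zd / (1.0 + h_rbc / _K5 + zd)
    s_oxy = zo / (1.0 + h_rbc / _K6 + zo)
    s_carb = so2 * s_oxy + (1.0 - so2) * s_deoxy
    carb_rbc = sites * s_carb

    total_molar = (1.0 - hct) * (dis_pl + hco3_pl) \
        + hct * (dis_rbc + hco3_rbc + carb_rbc)      # mol per litre blood
    return total_molar * _ML_PER_MOL / 10.0          # ml per 100 ml


def oracle_pco2_from_content(target, ph, hb, so2, temp, lo=0.0, hi=200.0):
    """Bisection inverse of the oracle, |residual| < 1e-10."""
    flo = oracle_co2_content(lo, ph, hb, so2, temp) - target
    fhi = oracle_co2_content(hi, ph, hb, so2, temp) - target
    if flo * fhi > 0:
        raise ValueError("target outside bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        fm = oracle_co2_content(mid, ph, hb, so2, temp) - target
        if abs(fm) < 1e-12 or hi - lo < 1e-13:
            return mid
        if flo * fm <= 0:
            hi = mid
        else:
            lo, flo = mid, fm
    return 0.5 * (lo + hi)


if __name__ == "__main__":
    for args in [(40, 7.4, 15, 1.0, 37), (50, 7.28, 9, 0.876, 36.8),
                 (0, 7.4, 15, 1.0, 37), (50, 7.4, 15, 1.0, 37),
                 (40, 7.4, 15, 0.0, 37)]:
        print(args, "->", round(oracle_co2_content(*args), 4))
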