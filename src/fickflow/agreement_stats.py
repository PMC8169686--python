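"""Method-agreement and regression statistics.

Bland-Altman bias and 95 % limits of agreement with their confidence
intervals, a proportional-bias regression (difference on mean), the
least significant change of a method from replicate measurements, and
the multiple linear regression relating gas-side VCO2 to blood flow
and CO2 content difference.  Ordinary least squares goes through
statsmodels; the Bland-Altman interval formulas are coded here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AgreementResult",
    "RegressionResult",
    "bland_altman",
    "proportional_bias",
    "least_significant_change",
    "fit_vco2_model",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman agreement between two methods (same units as input)."""

    bias: float
    loa_lower: float
    loa_upper: float
    ci_bias: tuple[float, float]
    ci_loa_lower: tuple[float, float]
    ci_loa_upper: tuple[float, float]
    sd_diff: float
    n: int


@dataclass(frozen=True)
class RegressionResult:
    """An OLS fit with Pearson r^2 and per-coefficient p-values."""

    intercept: float
    coefficients: dict[str, float]
    r2: float
    p_values: dict[str, float]
    collinear: bool = False


def _paired(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError(f"length mismatch: {xa.shape} vs {ya.shape}")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    return xa, ya


def bland_altman(x: Sequence[float], y: Sequence[float],
                 loa_multiplier: float = 1.96) -> AgreementResult:
    """Bias = mean(x - y); limits of agreement = bias +- 1.96 SD.

    Confidence intervals use the standard Bland-Altman variance
    formulas: Var(bias) = SD^2/n and
    Var(LoA) = SD^2 (1/n + z^2 / (2(n-1))), with t(n-1) quantiles.
    """
    xa, ya = _paired(x, y)
    d = xa - ya
    n = d.size
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    z = loa_multiplier
    loa_lo, loa_hi = bias - z * sd, bias + z * sd
    t = stats.t.ppf(0.975, n - 1)
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + z * z / (2.0 * (n - 1)))
    return AgreementResult(
        bias=bias, loa_lower=loa_lo, loa_upper=loa_hi,
        ci_bias=(bias - t * se_bias, bias + t * se_bias),
        ci_loa_lower=(loa_lo - t * se_loa, loa_lo + t * se_loa),
        ci_loa_upper=(loa_hi - t * se_loa, loa_hi + t * se_loa),
        sd_diff=sd, n=n,
    )


def proportional_bias(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Regress the difference (x - y) on the pairwise mean.

    A non-zero slope indicates a bias that scales with the magnitude
    of the measurement (e.g. flow-dependent under- or overestimation).
    """
    xa, ya = _paired(x, y)
    mean = (xa + ya) / 2.0
    if np.ptp(mean) == 0:
        raise ValueError("the pairwise means have zero variance")
    return _ols(pd.DataFrame({"mean": mean}), xa - ya)


def least_significant_change(replicates: Iterable[Sequence[float]],
                             multiplier: float = 1.96) -> float:
    """LSC = 1.96 x sqrt(2) x within-condition SD, pooled over conditions.

    ``replicates`` is an iterable of replicate-measurement groups, one
    group per experimental condition (each of size >= 2).  The pooled
    precision SD uses the usual degrees-of-freedom weighting.
    """
    ss = 0.0
    dof = 0
    n_groups = 0
    for group in replicates:
        g = np.asarray(group, dtype=float)
        if g.size < 2:
            raise ValueError("each condition needs at least 2 replicates")
        ss += float(np.sum((g - g.mean()) ** 2))
        dof += g.size - 1
        n_groups += 1
    if n_groups == 0:
        raise ValueError("no replicate groups supplied")
    sd_within = np.sqrt(ss / dof)
    return float(multiplier * np.sqrt(2.0) * sd_within)


def _ols(X: pd.DataFrame, y: np.ndarray) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    coeffs = {k: float(v) for k, v in model.params.items() if k != "const"}
    pvals = {k: float(v) for k, v in model.pvalues.items() if k != "const"}
    collinear = bool(np.linalg.cond(
        sm.add_constant(X, has_constant="add").to_numpy()) > 1e10)
    return RegressionResult(
        intercept=float(model.params["const"]),
        coefficients=coeffs,
        r2=float(model.rsquared),
        p_values=pvals,
        collinear=collinear,
    )


def fit_vco2_model(records: pd.DataFrame,
                   vco2_col: str = "vco2_gas",
                   delta_col: str = "delta_cco2",
                   flow_col: str = "q") -> RegressionResult:
    """VCO2 = Intercept + b1 dcCO2 + b2 Q + b3 dcCO2 x Q, by OLS.

    Relates gas-side CO2 elimination to its blood-side components
    (content difference and blood flow).  Collinear designs are
    flagged via the condition number but coefficients are still
    returned.
    """
    for col in (vco2_col, delta_col, flow_col):
        if col not in records.columns:
            raise KeyError(f"records lack required column '{col}'")
    if len(records) < 5:
        raise ValueError("need at least 5 records for the 3-term model")
    X = pd.DataFrame({
        "delta_cco2": records[delta_col].to_numpy(float),
        "flow": records[flow_col].to_numpy(float),
    })
    X["interaction"] = X["delta_cco2"] * X["flow"]
    return _ols(X, records[vco2_col].to_numpy(float))


def bland_altman_plot(x: Sequence[float], y: Sequence[float], path: str,
                      xlabel: str = "Mean of methods [ml/min]",
                      ylabel: str = "Difference of methods [ml/min]") -> None:
    """Save a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xa, ya = _paired(x, y)
    res = bland_altman(xa, ya)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter((xa + ya) / 2.0, xa - ya, s=18, alpha=0.7)
    for value, style in ((res.bias, "-"), (res.loa_lower, "--"),
                         (res.loa_upper, "--")):
        ax.axhline(value, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
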