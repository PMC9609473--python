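"""Temperature dependence: Arrhenius activation energies and standard
thermodynamic functions of release.

Given rate constants measured at several temperatures:

* Arrhenius: OLS of ln k on 1/T; ``E_a = -slope * R``.
* van't Hoff: OLS of ln K on 1/T with K = k1/k_minus1;
  ``dH = -slope * R``.
* ``dG(T) = -R T ln K(T)`` and ``dS(T) = (dH - dG(T)) / T``.

Energies are held in J/mol; report-level rendering converts to kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy.stats import linregress

from .models import R_GAS

__all__ = [
    "ArrheniusResult",
    "VantHoffResult",
    "ThermoResult",
    "arrhenius_fit",
    "vant_hoff_enthalpy",
    "gibbs_energy",
    "entropy",
    "thermo_report",
]


@dataclass(frozen=True)
class ArrheniusResult:
    """Arrhenius regression: E_a (J/mol), ln A, fit quality."""

    activation_energy: float
    ln_pre_exponential: float
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("Arrhenius fit needs at least 2 points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


@dataclass(frozen=True)
class VantHoffResult:
    """van't Hoff regression: dH (J/mol), intercept, fit quality."""

    delta_H: float
    ln_K_infinity: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class ThermoResult:
    """Standard thermodynamic functions of the release equilibrium.

    ``delta_S`` is tabulated per temperature but is constant by
    construction when ``delta_H`` comes from a single van't Hoff line —
    temperature dependence would only appear with a curved ln K vs 1/T
    plot.  The identity dG(T) = dH - T dS(T) is asserted on every
    report.
    """

    delta_H: float
    delta_G: Dict[float, float]
    delta_S: Dict[float, float]
    vant_hoff_r_squared: float

    def __post_init__(self) -> None:
        scale = max(abs(self.delta_H), 1.0)
        for T in self.delta_G:
            resid = self.delta_G[T] - (self.delta_H - T * self.delta_S[T])
            if abs(resid) > 1e-6 * scale:
                raise ValueError(
                    f"dG = dH - T dS identity violated at T={T}: residual {resid:.3e} J/mol"
                )


def _regress_log_vs_invT(
    series: Sequence[Tuple[float, float]], what: str
) -> Tuple[float, float, float, int]:
    arr = np.asarray(series, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{what} series must be (temperature, value) pairs")
    T, k = arr[:, 0], arr[:, 1]
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    if np.any(k <= 0):
        raise ValueError(f"all {what} values must be positive for a log fit")
    if np.unique(T).size < 2:
        raise ValueError(f"{what} fit needs at least 2 distinct temperatures")
    fit = linregress(1.0 / T, np.log(k))
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 1.0
    return float(fit.slope), float(fit.intercept), min(r2, 1.0), int(T.size)


def arrhenius_fit(series: Sequence[Tuple[float, float]]) -> ArrheniusResult:
    """Activation energy from (temperature K, rate constant 1/h) pairs.

    Ordinary least squares of ln k on 1/T; E_a = -slope * R.  A
    temperature-independent rate constant gives E_a = 0.
    """
    slope, intercept, r2, n = _regress_log_vs_invT(series, "rate constant")
    return ArrheniusResult(
        activation_energy=-slope * R_GAS,
        ln_pre_exponential=intercept,
        r_squared=r2,
        n_points=n,
    )


def vant_hoff_enthalpy(series: Sequence[Tuple[float, float]]) -> VantHoffResult:
    """Standard release enthalpy from (temperature K, K) pairs.

    OLS of ln K on 1/T; dH = -slope * R (J/mol).
    """
    slope, intercept, r2, n = _regress_log_vs_invT(series, "equilibrium constant")
    return VantHoffResult(delta_H=-slope * R_GAS, ln_K_infinity=intercept, r_squared=r2, n_points=n)


def gibbs_energy(K: float, temperature: float) -> float:
    """Standard Gibbs energy of release, dG = -R T ln K, J/mol.

    Positive when K < 1 (release unfavourable; most drug stays bound).
    """
    if not K > 0:
        raise ValueError(f"K must be positive, got {K}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return -R_GAS * temperature * np.log(K)


def entropy(delta_H: float, delta_G: float, temperature: float) -> float:
    """Standard entropy of release, dS = (dH - dG) / T, J mol^-1 K^-1."""
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return (delta_H - delta_G) / temperature


def thermo_report(
    k1_series: Sequence[Tuple[float, float]],
    k_minus1_series: Sequence[Tuple[float, float]],
) -> ThermoResult:
    """Full thermodynamic chain from matched k1 and k_minus1 series.

    Builds K(T) = k1(T)/k_minus1(T) on the shared temperature grid, runs
    the van't Hoff regression for dH, then evaluates dG and dS at each
    temperature.  The two series must be sampled at identical
    temperatures.
    """
    a1 = np.asarray(k1_series, dtype=float)
    a2 = np.asarray(k_minus1_series, dtype=float)
    if a1.shape != a2.shape or a1.ndim != 2:
        raise ValueError("k1 and k_minus1 series must have identical shapes")
    if not np.array_equal(a1[:, 0], a2[:, 0]):
        raise ValueError("k1 and k_minus1 series must share the same temperature grid")
    T = a1[:, 0]
    if np.any(a2[:, 1] <= 0):
        raise ValueError("k_minus1 values must be positive")
    K = a1[:, 1] / a2[:, 1]
    vh = vant_hoff_enthalpy(list(zip(T, K)))
    dG = {float(Ti): float(gibbs_energy(Ki, Ti)) for Ti, Ki in zip(T, K)}
    dS = {Ti: entropy(vh.delta_H, dGi, Ti) for Ti, dGi in dG.items()}
    return ThermoResult(
        delta_H=vh.delta_H,
        delta_G=dG,
        delta_S=dS,
        vant_hoff_r_squared=vh.r_squared,
    )
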