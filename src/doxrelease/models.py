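"""Reversible first-order kinetics of ionic drug binding and release.

Doxorubicin carried in the corona of an amphiphilic
N-vinyl-2-pyrrolidone/acrylic-acid copolymer nanoparticle exchanges
between an electrostatically bound state and free solution::

    bound  <--k1-->  free        k_-1 = k'_-1 * C_COOH

with first-order release (``k1``) and pseudo-first-order binding
(``k_minus1``).  The free-drug conversion ``xi = C_free / C_max``
follows a single-exponential approach to its equilibrium value::

    xi(t) = xi_inf * (1 - exp(-(k1 + k_minus1) t)),   xi_inf = K / (1 + K)

where ``K = k1 / k_minus1`` is the release equilibrium constant.  This
module holds the domain types and the exact algebra; fitting lives in
:mod:`doxrelease.fitting` and temperature analysis in
:mod:`doxrelease.thermo`.

Units are fixed package-wide: time in hours, rate constants in 1/h,
concentrations in mol/L (copolymer mass loading in g/mL), energies in
J/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "R_GAS",
    "M_ACRYLIC_ACID",
    "M_VINYLPYRROLIDONE",
    "ExperimentCondition",
    "ConcentrationState",
    "RateConstants",
    "EquilibriumEstimate",
    "conversion_profile",
    "ode_release_oracle",
    "equilibrium_constant",
    "split_rate_constants",
    "normalized_binding_constant",
    "cooh_concentration",
]

#: Molar gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Molar mass of an acrylic-acid repeat unit (CH2-CH-COOH), g mol^-1.
M_ACRYLIC_ACID = 72.06

#: Molar mass of an N-vinyl-2-pyrrolidone repeat unit, g mol^-1.
M_VINYLPYRROLIDONE = 111.14


@dataclass(frozen=True)
class ExperimentCondition:
    """Medium and carrier parameters defining one release experiment.

    Parameters
    ----------
    temperature : float
        Absolute temperature, K.
    pH : float
        Buffer pH, in [0, 14].
    x_aa : float
        Mole fraction of acrylic-acid residues in the copolymer chain.
    copolymer_conc : float
        Copolymer mass concentration, g/mL.
    drug_load : float
        Initial doxorubicin hydrochloride mass concentration, g/mL.
        Default matches 0.01 g of drug in a 10 mL mixed volume.
    label : str
        Free-text identifier.
    """

    temperature: float
    pH: float
    x_aa: float
    copolymer_conc: float
    drug_load: float = 1e-3
    label: str = ""

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if not 0.0 <= self.pH <= 14.0:
            raise ValueError(f"pH must lie in [0, 14], got {self.pH}")
        if not 0.0 <= self.x_aa <= 1.0:
            raise ValueError(f"x_aa must lie in [0, 1], got {self.x_aa}")
        if self.copolymer_conc < 0:
            raise ValueError(f"copolymer_conc must be >= 0, got {self.copolymer_conc}")
        if not self.drug_load > 0:
            raise ValueError(f"drug_load must be positive, got {self.drug_load}")


@dataclass(frozen=True)
class ConcentrationState:
    """Free/bound drug concentrations along a trajectory.

    ``c_free + c_bound = c_max`` (mass conservation) is enforced at
    construction to within ``conservation_rtol * c_max`` at every
    sample.
    """

    c_free: np.ndarray
    c_bound: np.ndarray
    c_max: float
    conservation_rtol: float = 1e-9

    def __post_init__(self) -> None:
        object.__setattr__(self, "c_free", np.asarray(self.c_free, dtype=float))
        object.__setattr__(self, "c_bound", np.asarray(self.c_bound, dtype=float))
        if not self.c_max > 0:
            raise ValueError(f"c_max must be positive, got {self.c_max}")
        if self.c_free.shape != self.c_bound.shape:
            raise ValueError("c_free and c_bound must have identical shapes")
        if np.any(self.c_free < -self.conservation_rtol * self.c_max) or np.any(
            self.c_bound < -self.conservation_rtol * self.c_max
        ):
            raise ValueError("concentrations must be non-negative")
        err = np.max(np.abs(self.c_free + self.c_bound - self.c_max))
        if err > self.conservation_rtol * self.c_max:
            raise ValueError(
                f"mass conservation violated: |c_free + c_bound - c_max| = {err:.3e} "
                f"exceeds {self.conservation_rtol:.1e} * c_max"
            )


@dataclass(frozen=True)
class RateConstants:
    """Release/binding rate-constant pair with derived quantities.

    Attributes
    ----------
    k1 : float
        Release rate constant, 1/h.
    k_minus1 : float
        Pseudo-first-order binding rate constant, 1/h.
    k_minus1_prime : float, optional
        Binding constant normalized to carboxyl concentration,
        L mol^-1 h^-1 (``k_minus1 = k_minus1_prime * C_COOH``).
    """

    k1: float
    k_minus1: float
    k_minus1_prime: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError(f"k1 must be >= 0, got {self.k1}")
        if self.k_minus1 < 0:
            raise ValueError(f"k_minus1 must be >= 0, got {self.k_minus1}")

    @property
    def k_total(self) -> float:
        """Sum k1 + k_minus1, the observed equilibration rate, 1/h."""
        return self.k1 + self.k_minus1

    @property
    def K(self) -> float:
        """Release equilibrium constant k1 / k_minus1 (inf if binding is absent)."""
        if self.k_minus1 == 0:
            return math.inf if self.k1 > 0 else math.nan
        return self.k1 / self.k_minus1

    @property
    def xi_inf(self) -> float:
        """Equilibrium release conversion K / (1 + K) = k1 / (k1 + k_minus1)."""
        if self.k_total == 0:
            return math.nan
        return self.k1 / self.k_total


@dataclass(frozen=True)
class EquilibriumEstimate:
    """Estimated equilibrium conversion with its provenance.

    ``method`` is ``"plateau"`` (mean of tail points) or ``"nonlinear"``
    (exponential least squares); ``plateau_sd`` is the dispersion of the
    tail points used for (or initializing) the estimate.
    """

    xi_inf: float
    method: str
    plateau_sd: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.xi_inf < 1.0:
            raise ValueError(f"xi_inf must lie in (0, 1), got {self.xi_inf}")
        if self.method not in ("plateau", "nonlinear"):
            raise ValueError(f"unknown method {self.method!r}")


def _as_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError("times must be one-dimensional")
    if np.any(t < 0):
        raise ValueError("times must all be >= 0")
    return t


def conversion_profile(constants: RateConstants, times: Sequence[float]) -> np.ndarray:
    """Closed-form release conversion xi(t) = xi_inf (1 - e^{-(k1+k-1) t}).

    Parameters
    ----------
    constants : RateConstants
        Must have ``k_total > 0``.
    times : array-like of float
        Sample times in hours, all non-negative.

    Returns
    -------
    numpy.ndarray
        Conversions in ``[0, xi_inf)``, non-decreasing along increasing
        times.
    """
    t = _as_times(times)
    k = constants.k_total
    if not k > 0:
        raise ValueError("k1 + k_minus1 must be positive for a release profile")
    return constants.xi_inf * (-np.expm1(-k * t))


def ode_release_oracle(
    constants: RateConstants,
    c_max: float,
    times: Sequence[float],
    rtol: float = 1e-10,
    atol_factor: float = 1e-13,
) -> ConcentrationState:
    """Numerically integrate the reversible release rate law.

    Solves the two-state linear system from a fully bound start::

        dC_free/dt  = k1 C_bound - k_minus1 C_free
        dC_bound/dt = -dC_free/dt

    with an implicit stiff solver.  Intended as an independent check on
    :func:`conversion_profile`; both states are integrated so that mass
    conservation is a genuine accuracy diagnostic.

    Raises
    ------
    RuntimeError
        If the integrator reports failure (never returns silent NaN).
    """
    t = _as_times(times)
    if not c_max > 0:
        raise ValueError(f"c_max must be positive, got {c_max}")
    k1, km1 = constants.k1, constants.k_minus1

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        flux = k1 * y[1] - km1 * y[0]
        return [flux, -flux]

    t_span = (0.0, float(t[-1]) if t.size and t[-1] > 0 else 1.0)
    sol = solve_ivp(
        rhs,
        t_span,
        [0.0, c_max],
        t_eval=t,
        method="Radau",
        rtol=rtol,
        atol=atol_factor * c_max,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    c_free, c_bound = sol.y
    if np.any(~np.isfinite(c_free)):
        raise RuntimeError("ODE integration produced non-finite concentrations")
    return ConcentrationState(c_free=c_free, c_bound=c_bound, c_max=c_max)


def equilibrium_constant(xi_inf: float) -> float:
    """Release equilibrium constant from the equilibrium conversion.

    K = xi_inf / (1 - xi_inf); the ratio of free to bound drug at
    equilibrium.  Strictly increasing in ``xi_inf`` on (0, 1).
    """
    if not 0.0 < xi_inf < 1.0:
        raise ValueError(f"xi_inf must lie in (0, 1) for K to be defined, got {xi_inf}")
    return xi_inf / (1.0 - xi_inf)


def split_rate_constants(k_total: float, K: float) -> RateConstants:
    """Decompose the summed rate constant using the equilibrium constant.

    k1 = k_total * K / (1 + K)  and  k_minus1 = k_total / (1 + K), so
    that ``k1 + k_minus1 = k_total`` and ``k1 / k_minus1 = K``.
    """
    if not k_total > 0:
        raise ValueError(f"k_total must be positive, got {k_total}")
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    k1 = k_total * K / (1.0 + K)
    k_minus1 = k_total / (1.0 + K)
    return RateConstants(k1=k1, k_minus1=k_minus1)


def normalized_binding_constant(k_minus1: float, c_cooh: float) -> float:
    """Binding constant per mole of carboxyl groups, L mol^-1 h^-1.

    k'_-1 = k_-1 / C_COOH, inverting the pseudo-first-order lumping
    ``k_minus1 = k_minus1_prime * C_COOH``.
    """
    if not c_cooh > 0:
        raise ValueError(f"c_cooh must be positive, got {c_cooh}")
    if k_minus1 < 0:
        raise ValueError(f"k_minus1 must be >= 0, got {k_minus1}")
    return k_minus1 / c_cooh


def cooh_concentration(condition: ExperimentCondition) -> float:
    """Carboxyl-group concentration of the dissolved copolymer, mol/L.

    Computed from the mass loading and the composition-weighted mean
    repeat-unit molar mass (end groups neglected)::

        C_COOH = 1000 * copolymer_conc / (x_aa M_AA + (1-x_aa) M_VP) * x_aa

    This convention is the package's own; it scales ``k_minus1_prime``
    and nothing else.
    """
    if condition.x_aa == 0:
        return 0.0
    mean_mass = condition.x_aa * M_ACRYLIC_ACID + (1.0 - condition.x_aa) * M_VINYLPYRROLIDONE
    grams_per_L = condition.copolymer_conc * 1000.0
    return grams_per_L / mean_mass * condition.x_aa
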