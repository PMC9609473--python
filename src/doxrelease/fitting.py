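"""Estimation of rate constants from a measured release curve.

The inference chain mirrors how reversible first-order release data are
analysed by hand:

1. estimate the equilibrium conversion ``xi_inf`` (plateau mean or
   nonlinear exponential fit),
2. ``K = xi_inf / (1 - xi_inf)``,
3. estimate the summed rate constant ``k1 + k_minus1`` — by default from
   the joint exponential least-squares fit, classically from the slope
   of ``ln(xi_inf - xi)`` against ``t``,
4. split the sum into ``k1`` and ``k_minus1`` using ``K``.

:func:`fit_release_curve` composes the stages.  The semilog slope is
the textbook route and is always computed as a linearity diagnostic,
but as the *estimator* of the summed constant it degrades sharply once
the curve reaches its plateau: the log transform amplifies additive
measurement noise by ``1/(xi_inf - xi)``, without bound as
``xi -> xi_inf``.  The default ``method="nonlinear"`` therefore takes
both ``xi_inf`` and the rate sum from the two-parameter fit of
``xi_inf (1 - e^{-k t})`` in the observation domain, which is the
maximum-likelihood estimator under additive homoscedastic noise;
``method="linearized"`` and ``method="plateau"`` reproduce the
classical analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .models import (
    EquilibriumEstimate,
    ExperimentCondition,
    RateConstants,
    cooh_concentration,
    equilibrium_constant,
    normalized_binding_constant,
    split_rate_constants,
)

__all__ = [
    "ReleaseCurve",
    "LinearFitResult",
    "FitDiagnostics",
    "PlateauWarning",
    "estimate_equilibrium_conversion",
    "linearized_fit",
    "fit_release_curve",
    "binding_efficiency",
]


class PlateauWarning(UserWarning):
    """The curve has not clearly levelled off; xi_inf may be extrapolated."""


@dataclass(frozen=True)
class ReleaseCurve:
    """A sampled release time series.

    Parameters
    ----------
    times : array-like
        Sample times in hours; strictly increasing, first >= 0.
    xi : array-like
        Release conversions in [0, 1], one per time.
    condition : ExperimentCondition, optional
        Experimental metadata; enables the carboxyl-normalized binding
        constant in downstream fits.
    """

    times: np.ndarray
    xi: np.ndarray
    condition: Optional[ExperimentCondition] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        x = np.asarray(self.xi, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "xi", x)
        if t.ndim != 1 or x.ndim != 1 or t.shape != x.shape:
            raise ValueError("times and xi must be one-dimensional and equal-length")
        if t.size < 4:
            raise ValueError(f"a release curve needs at least 4 points, got {t.size}")
        if t[0] < 0:
            raise ValueError("times must start at or after 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((x < 0) | (x > 1)):
            raise ValueError("conversions must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class LinearFitResult:
    """OLS result for the semilog linearization ln(xi_inf - xi) vs t."""

    slope: float
    intercept: float
    r_squared: float
    n_used: int
    n_excluded: int

    def __post_init__(self) -> None:
        if self.n_used < 3:
            raise ValueError("linear fit requires at least 3 used points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError(f"r_squared out of range: {self.r_squared}")


@dataclass(frozen=True)
class FitDiagnostics:
    """Per-curve fit provenance carried into results tables.

    ``linear`` is the semilog regression (None when too few points lie
    below xi_inf for it to run); ``intercept_gap`` is
    ``|intercept - ln xi_inf|``, a model-adequacy check that is zero for
    an exact single-exponential curve.
    """

    equilibrium: EquilibriumEstimate
    linear: Optional[LinearFitResult]
    intercept_gap: float


def _plateau_points(curve: ReleaseCurve, tail_fraction: float) -> np.ndarray:
    span = curve.times[-1] - curve.times[0]
    cutoff = curve.times[-1] - tail_fraction * span
    return curve.xi[curve.times >= cutoff]


def _exponential_fit(curve: ReleaseCurve, xi0: float, k0: float) -> tuple[float, float]:
    """Least squares of xi_inf (1 - e^{-k t}); returns (xi_inf, k)."""

    def model(t: np.ndarray, xi_inf: float, k: float) -> np.ndarray:
        return xi_inf * (-np.expm1(-k * t))

    popt, _ = curve_fit(
        model,
        curve.times,
        curve.xi,
        p0=(xi0, k0),
        bounds=([1e-12, 1e-9], [1.0, np.inf]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1])


def _rate_guess(curve: ReleaseCurve, plateau_mean: float) -> float:
    # time of first crossing of half the plateau sets the scale
    above = np.nonzero(curve.xi >= 0.5 * plateau_mean)[0]
    if above.size and curve.times[above[0]] > 0:
        return float(np.log(2.0) / curve.times[above[0]])
    return 3.0 / max(float(curve.times[-1]), 1e-6)


def estimate_equilibrium_conversion(
    curve: ReleaseCurve,
    method: str = "nonlinear",
    tail_fraction: float = 0.25,
    plateau_slope_tol: float = 0.02,
) -> EquilibriumEstimate:
    """Estimate the asymptote xi_inf of a release curve.

    ``method="plateau"`` averages the points in the final
    ``tail_fraction`` of the time span (requires >= 3 such points).
    ``method="nonlinear"`` (default) fits xi_inf (1 - e^{-k t}) by least
    squares, initialized at the plateau mean; it extrapolates correctly
    when the horizon ends before full equilibration.

    A :class:`PlateauWarning` is emitted when the tail still rises by
    more than ``plateau_slope_tol`` of the plateau value per tail span —
    the estimate is then an extrapolation, not a reading.
    """
    tail = _plateau_points(curve, tail_fraction)
    if tail.size < 3:
        raise ValueError(
            f"plateau estimation needs >= 3 points in the final "
            f"{tail_fraction:.0%} of the time span, got {tail.size}"
        )
    plateau_mean = float(np.mean(tail))
    plateau_sd = float(np.std(tail, ddof=1)) if tail.size > 1 else 0.0
    if plateau_mean > 0 and tail.size >= 2:
        rise = float(tail[-1] - tail[0])
        if rise > plateau_slope_tol * plateau_mean:
            warnings.warn(
                f"release curve is still rising in its tail "
                f"(relative rise {rise / plateau_mean:.3f}); xi_inf is extrapolated",
                PlateauWarning,
                stacklevel=2,
            )

    if method == "plateau":
        return EquilibriumEstimate(xi_inf=plateau_mean, method="plateau", plateau_sd=plateau_sd)
    if method != "nonlinear":
        raise ValueError(f"unknown method {method!r}; expected 'plateau' or 'nonlinear'")

    xi0 = min(max(plateau_mean, 1e-6), 1.0 - 1e-9)
    xi_inf, _k = _exponential_fit(curve, xi0, _rate_guess(curve, xi0))
    return EquilibriumEstimate(xi_inf=xi_inf, method="nonlinear", plateau_sd=plateau_sd)


def linearized_fit(curve: ReleaseCurve, xi_inf: float) -> LinearFitResult:
    """OLS of ln(xi_inf - xi) on t; the slope estimates -(k1 + k_minus1).

    Points with ``xi >= xi_inf`` (possible under noise) have no
    logarithm and are excluded rather than clipped — clipping would bias
    the slope; the count is reported in ``n_excluded``.  The intercept
    is left free: its gap from ``ln(xi_inf)`` is a model-adequacy
    diagnostic, not a constraint.
    """
    if not 0.0 < xi_inf < 1.0:
        raise ValueError(f"xi_inf must lie in (0, 1), got {xi_inf}")
    mask = curve.xi < xi_inf
    n_used = int(np.sum(mask))
    n_excluded = len(curve) - n_used
    if n_used < 3:
        raise ValueError(
            f"only {n_used} points lie below xi_inf={xi_inf:.4g}; "
            "at least 3 are required for the semilog fit"
        )
    t = curve.times[mask]
    y = np.log(xi_inf - curve.xi[mask])
    fit = linregress(t, y)
    r2 = float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0
    return LinearFitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=min(r2, 1.0),
        n_used=n_used,
        n_excluded=n_excluded,
    )


def fit_release_curve(
    curve: ReleaseCurve,
    method: str = "nonlinear",
    full_output: bool = False,
):
    """Full inference chain from a release curve to rate constants.

    Parameters
    ----------
    curve : ReleaseCurve
    method : {"nonlinear", "linearized", "plateau"}
        * ``"nonlinear"`` (default): xi_inf and the rate sum both come
          from the joint exponential least-squares fit (MLE under
          additive Gaussian noise); the semilog regression is run only
          as a linearity diagnostic.
        * ``"linearized"``: xi_inf from the nonlinear fit, rate sum
          from the semilog OLS slope (the textbook pipeline).
        * ``"plateau"``: xi_inf from the tail mean, rate sum from the
          semilog slope (the fully classical hand analysis).
    full_output : bool
        Also return :class:`FitDiagnostics`.

    In every mode ``K`` derives from the estimated xi_inf, so the
    returned constants satisfy ``k1 / k_minus1 == K`` identically.
    When the curve carries an
    :class:`~doxrelease.models.ExperimentCondition` with nonzero
    acrylic-acid content, the carboxyl-normalized binding constant is
    filled in as well.

    Returns
    -------
    RateConstants, or (RateConstants, FitDiagnostics) if ``full_output``.
    """
    if method not in ("nonlinear", "linearized", "plateau"):
        raise ValueError(f"unknown method {method!r}")
    xi_method = "plateau" if method == "plateau" else "nonlinear"
    try:
        est = estimate_equilibrium_conversion(curve, method=xi_method)
    except ValueError as exc:
        raise ValueError(f"equilibrium-conversion stage failed: {exc}") from exc
    K = equilibrium_constant(est.xi_inf)

    lin: Optional[LinearFitResult]
    try:
        lin = linearized_fit(curve, est.xi_inf)
    except ValueError as exc:
        if method == "nonlinear":
            lin = None  # diagnostic only in this mode
        else:
            raise ValueError(f"linearization stage failed: {exc}") from exc

    if method == "nonlinear":
        xi0 = min(max(est.xi_inf, 1e-6), 1.0 - 1e-9)
        _xi, k_total = _exponential_fit(curve, xi0, _rate_guess(curve, xi0))
    else:
        assert lin is not None
        k_total = -lin.slope
    if not k_total > 0:
        raise ValueError(
            f"rate-sum stage produced a non-positive value ({k_total:.4g}); "
            "the curve does not rise toward a plateau"
        )
    rc = split_rate_constants(k_total, K)
    cond = curve.condition
    if cond is not None and cond.x_aa > 0 and cond.copolymer_conc > 0:
        kp = normalized_binding_constant(rc.k_minus1, cooh_concentration(cond))
        rc = RateConstants(k1=rc.k1, k_minus1=rc.k_minus1, k_minus1_prime=kp)
    if full_output:
        gap = abs(lin.intercept - np.log(est.xi_inf)) if lin is not None else float("nan")
        return rc, FitDiagnostics(equilibrium=est, linear=lin, intercept_gap=float(gap))
    return rc


def binding_efficiency(K: float) -> float:
    """Equilibrium bound fraction 1 - xi_inf = 1 / (1 + K).

    The fraction of drug remaining electrostatically immobilized once
    release has equilibrated.
    """
    if K < 0:
        raise ValueError(f"K must be >= 0, got {K}")
    return 1.0 / (1.0 + K)
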